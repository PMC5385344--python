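"""Ground-truth simulator for two-sample phage-display amplicon sequencing.

The generator emulates the structure of a one-round selection experiment:

* a repertoire of clonal lineages — founder peptides on a shared VHH-like
  scaffold (fixed EVQLVES / T(L/Q)VTVSS primer-encoded flanks, shared
  framework interior, three CDR-like hypervariable windows randomised per
  lineage) plus point-substitution variants within each lineage;
* heavy-tailed clone abundances (log-normal by default, Zipf optional); a
  binder subset whose abundance is multiplied by the enrichment ratio in the
  selection sample and left at baseline in the control sample;
* per-read error processes on the amplicon: PCR point substitutions in the
  interior (the primer-annealed ends are overwritten by the primers and stay
  error-free), single-nucleotide frameshift indels, premature stop codons,
  and unjoinable pairs whose reverse mate is replaced by random sequence.

Every emitted read id encodes its provenance (sample, lineage, variant,
injected errors), so each pipeline stage can be validated against truth.
All randomness derives from one integer seed; identical seeds give
bit-identical reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._util import encode, revcomp
from .consensus import reverse_translate
from .read_processing import FR1_AA, FR1_PRIMER, FR4_PRIMER, FR4_TAILS, ReadPair

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOP_CODONS = ("TAA", "TAG", "TGA")

# CDR-like hypervariable windows, as fractions of the trimmed interior
_CDR_FRACTIONS = ((0.18, 0.255), (0.42, 0.52), (0.83, 0.96))

SELECTION = "SEL"
CONTROL = "CTRL"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated selection experiment."""

    n_lineages: int = 440
    n_binders: int = 40
    variants_per_lineage: int = 10
    intra_lineage_divergence: float = 0.02
    scaffold_len: int = 120  # full peptide length, flanks included
    binder_enrichment: float = 50.0
    reads_per_sample: int = 200_000
    substitution_rate: float = 0.005  # per base, amplicon interior
    frameshift_indel_rate: float = 0.02  # per read
    premature_stop_rate: float = 0.005  # per read
    unjoinable_rate: float = 0.02  # per read
    read_len: int = 250
    seed: int = 0
    abundance_law: str = "lognormal"  # or "zipf"
    abundance_sigma: float = 1.0  # log-normal spread of clone abundances
    # joint pre-selection mass of the binder lineages: specific clones are
    # rare before selection, so their base abundance is rescaled to this
    # library fraction (None disables the rescaling)
    binder_base_fraction: float | None = 0.02
    zipf_exponent: float = 1.2
    base_quality: int = 40
    quality_decay: int = 0  # Phred drop from 5' to 3' along each mate
    fr4_variant: str = "L"

    def __post_init__(self) -> None:
        for name in ("intra_lineage_divergence", "substitution_rate",
                     "frameshift_indel_rate", "premature_stop_rate", "unjoinable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_binders > self.n_lineages:
            raise ValueError("n_binders cannot exceed n_lineages")
        if self.scaffold_len % 1 or self.scaffold_len < 50:
            raise ValueError("scaffold_len must be an integer >= 50")


@dataclass(frozen=True)
class VariantTruth:
    lineage_id: int
    variant_id: int
    peptide_trimmed: str
    peptide_full: str
    dna: str  # error-free amplicon, FR1 primer through FR4 primer


@dataclass
class LineageTruth:
    lineage_id: int
    is_binder: bool
    founder_trimmed: str
    variants: list[VariantTruth] = field(default_factory=list)


@dataclass
class SimTruth:
    config: SimConfig
    lineages: list[LineageTruth]
    variants: list[VariantTruth]  # flat, indexed by rows of the abundance arrays
    abundance: dict[str, np.ndarray]  # sample -> expected read fractions

    def majority_variant(self, lineage_id: int, sample: str = SELECTION) -> VariantTruth:
        """The lineage's most abundant variant in a sample (expected counts)."""
        idx = [i for i, v in enumerate(self.variants) if v.lineage_id == lineage_id]
        best = max(idx, key=lambda i: self.abundance[sample][i])
        return self.variants[best]

    def peptide_lookup(self) -> dict[str, VariantTruth]:
        return {v.peptide_trimmed: v for v in self.variants}


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    sample: str
    lineage_id: int
    variant_id: int
    n_substitutions: int
    frameshift: bool
    premature_stop: bool
    unjoinable: bool


@dataclass
class SimReads:
    truth: SimTruth
    pairs: dict[str, list[ReadPair]]
    provenance: list[ReadProvenance]
    drawn_counts: dict[str, np.ndarray]  # sample -> reads drawn per variant


# ---------------------------------------------------------------------------
# repertoire

def _cdr_windows(interior_len: int) -> list[tuple[int, int]]:
    return [
        (int(round(a * interior_len)), int(round(b * interior_len)))
        for a, b in _CDR_FRACTIONS
    ]


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=n))


def _amplicon(trimmed: str, fr4_variant: str) -> str:
    """Error-free amplicon DNA: literal primers flank the reverse-translated interior."""
    tail = FR4_TAILS[fr4_variant]
    fr4_sense = revcomp(FR4_PRIMER).replace("W", "T" if fr4_variant == "L" else "A")
    dna = FR1_PRIMER + reverse_translate(trimmed) + fr4_sense
    assert len(dna) == 21 + 3 * len(trimmed) + 21
    return dna


def _hamming(a: str, b: str) -> int:
    return int((encode(a) != encode(b)).sum())


def simulate_repertoire(config: SimConfig, max_retries: int = 20) -> SimTruth:
    """Generate lineage founders, clonal variants, and per-sample abundances."""
    rng = np.random.default_rng(config.seed)
    interior_len = config.scaffold_len - 14
    windows = _cdr_windows(interior_len)
    framework = list(_random_peptide(rng, interior_len))

    founders: list[str] = []
    for _ in range(config.n_lineages):
        for attempt in range(max_retries):
            interior = framework.copy()
            for a, b in windows:
                interior[a:b] = _random_peptide(rng, b - a)
            cand = "".join(interior)
            # reject founders colliding with an existing lineage (>= 95% identity)
            if all(1 - _hamming(cand, f) / interior_len < 0.95 for f in founders):
                founders.append(cand)
                break
        else:
            raise RuntimeError("could not place non-colliding lineage founders")

    max_subs = int(np.ceil(config.intra_lineage_divergence * interior_len))
    lineages: list[LineageTruth] = []
    variants: list[VariantTruth] = []
    for lid, founder in enumerate(founders):
        lin = LineageTruth(
            lineage_id=lid, is_binder=lid < config.n_binders, founder_trimmed=founder
        )
        seen = {founder}
        for vid in range(config.variants_per_lineage):
            if vid == 0:
                pep = founder
            else:
                for _ in range(max_retries):
                    k = int(rng.integers(1, max_subs + 1)) if max_subs else 0
                    pos = rng.choice(interior_len, size=k, replace=False)
                    chars = list(founder)
                    for p in pos:
                        choices = AA20.replace(chars[p], "")
                        chars[p] = choices[rng.integers(0, len(choices))]
                    pep = "".join(chars)
                    if pep not in seen:
                        break
                else:
                    continue  # divergence 0: no distinct variant possible
                seen.add(pep)
            full = FR1_AA + pep + FR4_TAILS[config.fr4_variant]
            vt = VariantTruth(
                lineage_id=lid,
                variant_id=vid,
                peptide_trimmed=pep,
                peptide_full=full,
                dna=_amplicon(pep, config.fr4_variant),
            )
            lin.variants.append(vt)
            variants.append(vt)
        lineages.append(lin)

    # heavy-tailed abundances: lineage mass x within-lineage variant mass
    n_var = len(variants)
    if config.abundance_law == "lognormal":
        lineage_w = rng.lognormal(0.0, config.abundance_sigma, size=config.n_lineages)
    elif config.abundance_law == "zipf":
        ranks = rng.permutation(config.n_lineages) + 1
        lineage_w = 1.0 / ranks.astype(float) ** config.zipf_exponent
    else:
        raise ValueError(f"unknown abundance law {config.abundance_law!r}")
    variant_w = rng.lognormal(0.0, 1.0, size=n_var)

    is_binder = np.array([lineages[v.lineage_id].is_binder for v in variants])
    base = np.array([lineage_w[v.lineage_id] * variant_w[i] for i, v in enumerate(variants)])
    if config.binder_base_fraction is not None and is_binder.any() and (~is_binder).any():
        # rescale so binders jointly hold the configured pre-selection mass
        target = config.binder_base_fraction
        base[is_binder] *= (target / (1 - target)) * (
            base[~is_binder].sum() / base[is_binder].sum()
        )
    enriched = np.where(is_binder, base * config.binder_enrichment, base)
    abundance = {
        CONTROL: base / base.sum(),
        SELECTION: enriched / enriched.sum(),
    }
    return SimTruth(config=config, lineages=lineages, variants=variants, abundance=abundance)


# ---------------------------------------------------------------------------
# reads

def _apply_substitutions(
    rng: np.random.Generator, mat: np.ndarray, lo: int, hi: int, rate: float
) -> np.ndarray:
    """Substitute interior bases of an (n, L) uint8 amplicon matrix in place."""
    if rate == 0.0:
        return np.zeros(mat.shape[0], dtype=np.int64)
    region = mat[:, lo:hi]
    mask = rng.random(region.shape) < rate
    if mask.any():
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        idx = np.searchsorted(np.sort(bases), region[mask])  # ACGT are sorted bytes
        shift = rng.integers(1, 4, size=idx.size)
        region[mask] = bases[(idx + shift) % 4]
    return mask.sum(axis=1)


def _quality_string(read_len: int, base_q: int, decay: int) -> str:
    q = np.linspace(base_q, base_q - decay, read_len).round().astype(int)
    return "".join(chr(33 + int(v)) for v in q)


def simulate_selection_and_reads(truth: SimTruth, config: SimConfig | None = None) -> SimReads:
    """Draw per-variant read counts and emit error-injected read pairs.

    Counts per sample are multinomial draws from the sample's expected
    abundances; each read's amplicon copy then receives substitution,
    premature-stop, and frameshift errors at the configured per-read rates,
    and a configured fraction of pairs get a random reverse mate so they
    cannot be joined.
    """
    config = config or truth.config
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    rng = np.random.default_rng(int(np.random.default_rng(config.seed).integers(2**30)) + 1)
    read_len = config.read_len
    qual_str = _quality_string(read_len, config.base_quality, config.quality_decay)
    qual_arr = np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(np.int16) - 33

    pairs: dict[str, list[ReadPair]] = {}
    provenance: list[ReadProvenance] = []
    drawn: dict[str, np.ndarray] = {}
    for sample in (CONTROL, SELECTION):
        counts = rng.multinomial(config.reads_per_sample, truth.abundance[sample])
        drawn[sample] = counts
        sample_pairs: list[ReadPair] = []
        serial = 0
        for vi, n in enumerate(counts):
            if n == 0:
                continue
            v = truth.variants[vi]
            template = encode(v.dna)
            amp_len = template.size
            mat = np.tile(template, (int(n), 1))
            n_subs = _apply_substitutions(
                rng, mat, 21, amp_len - 21, config.substitution_rate
            )
            stop_flags = rng.random(int(n)) < config.premature_stop_rate
            fs_flags = rng.random(int(n)) < config.frameshift_indel_rate
            uj_flags = rng.random(int(n)) < config.unjoinable_rate
            plain = np.flatnonzero(~fs_flags)
            # premature stops: overwrite one interior codon with a stop
            for i in np.flatnonzero(stop_flags):
                cod = int(rng.integers(7, amp_len // 3 - 7))
                stop = _STOP_CODONS[int(rng.integers(0, 3))]
                mat[i, 3 * cod : 3 * cod + 3] = encode(stop)

            r1_mat = mat[plain, :read_len] if read_len <= amp_len else None
            r2_mat = mat[plain, amp_len - read_len :] if read_len <= amp_len else None
            row_of = {int(r): k for k, r in enumerate(plain)}
            for i in range(int(n)):
                rid = (
                    f"{sample}|L{v.lineage_id}|V{v.variant_id}|{serial}"
                    f"|s{int(n_subs[i])}f{int(fs_flags[i])}"
                    f"t{int(stop_flags[i])}u{int(uj_flags[i])}"
                )
                serial += 1
                if fs_flags[i]:
                    seq = bytearray(mat[i].tobytes())
                    p = int(rng.integers(0, len(seq)))
                    if rng.random() < 0.5:
                        del seq[p]
                    else:
                        seq.insert(p, b"ACGT"[int(rng.integers(0, 4))])
                    amplicon = seq.decode("ascii")
                    r1 = amplicon[:read_len]
                    r2 = revcomp(amplicon[-read_len:])
                else:
                    k = row_of[i]
                    if r1_mat is not None:
                        r1 = r1_mat[k].tobytes().decode("ascii")
                        r2 = revcomp(r2_mat[k].tobytes().decode("ascii"))
                    else:
                        amplicon = mat[i].tobytes().decode("ascii")
                        r1, r2 = amplicon, revcomp(amplicon)
                if uj_flags[i]:
                    r2 = "".join(
                        "ACGT"[j] for j in rng.integers(0, 4, size=len(r2))
                    )
                q1 = qual_arr[: len(r1)]
                q2 = qual_arr[: len(r2)]
                sample_pairs.append(
                    ReadPair(id=rid, fwd_seq=r1, fwd_qual=q1, rev_seq=r2,
                             rev_qual=q2, sample=sample)
                )
                provenance.append(
                    ReadProvenance(
                        read_id=rid, sample=sample, lineage_id=v.lineage_id,
                        variant_id=v.variant_id, n_substitutions=int(n_subs[i]),
                        frameshift=bool(fs_flags[i]), premature_stop=bool(stop_flags[i]),
                        unjoinable=bool(uj_flags[i]),
                    )
                )
        pairs[sample] = sample_pairs
    return SimReads(truth=truth, pairs=pairs, provenance=provenance, drawn_counts=drawn)


def simulate(config: SimConfig) -> SimReads:
    """Repertoire + selection + reads in one call."""
    return simulate_selection_and_reads(simulate_repertoire(config), config)


# ---------------------------------------------------------------------------
# output

def write_fastq(pairs: Sequence[ReadPair], r1_path, r2_path) -> None:
    """Write mates to two FASTQ files (gzipped when the name ends in .gz)."""
    import gzip

    def opener(path):
        path = str(path)
        return gzip.open(path, "wt") if path.endswith(".gz") else open(path, "w")

    with opener(r1_path) as f1, opener(r2_path) as f2:
        for p in pairs:
            q1 = "".join(chr(33 + int(v)) for v in p.fwd_qual)
            q2 = "".join(chr(33 + int(v)) for v in p.rev_qual)
            f1.write(f"@{p.id}\n{p.fwd_seq}\n+\n{q1}\n")
            f2.write(f"@{p.id}\n{p.rev_seq}\n+\n{q2}\n")


def write_truth_tables(reads: SimReads, outdir) -> None:
    """Truth TSVs: lineages, variants with abundances, per-read provenance."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = reads.truth
    with open(outdir / "truth_lineages.tsv", "w") as fh:
        fh.write("lineage_id\tis_binder\tfounder_trimmed\n")
        for lin in truth.lineages:
            fh.write(f"{lin.lineage_id}\t{int(lin.is_binder)}\t{lin.founder_trimmed}\n")
    with open(outdir / "truth_variants.tsv", "w") as fh:
        fh.write(
            "lineage_id\tvariant_id\tpeptide_trimmed\t"
            f"abundance_{CONTROL}\tabundance_{SELECTION}\t"
            f"drawn_{CONTROL}\tdrawn_{SELECTION}\n"
        )
        for i, v in enumerate(truth.variants):
            fh.write(
                f"{v.lineage_id}\t{v.variant_id}\t{v.peptide_trimmed}\t"
                f"{truth.abundance[CONTROL][i]!r}\t{truth.abundance[SELECTION][i]!r}\t"
                f"{int(reads.drawn_counts[CONTROL][i])}\t{int(reads.drawn_counts[SELECTION][i])}\n"
            )
    with open(outdir / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tsample\tlineage_id\tvariant_id\tn_substitutions\t"
                 "frameshift\tpremature_stop\tunjoinable\n")
        for p in reads.provenance:
            fh.write(
                f"{p.read_id}\t{p.sample}\t{p.lineage_id}\t{p.variant_id}\t"
                f"{p.n_substitutions}\t{int(p.frameshift)}\t{int(p.premature_stop)}\t"
                f"{int(p.unjoinable)}\n"
            )


def parse_read_id(read_id: str) -> dict:
    """Recover the provenance encoded in a simulated read id."""
    sample, lin, var, serial, flags = read_id.split("|")
    import re

    m = re.fullmatch(r"s(\d+)f([01])t([01])u([01])", flags)
    if m is None:
        raise ValueError(f"not a simulator read id: {read_id!r}")
    return {
        "sample": sample,
        "lineage_id": int(lin[1:]),
        "variant_id": int(var[1:]),
        "serial": int(serial),
        "n_substitutions": int(m.group(1)),
        "frameshift": m.group(2) == "1",
        "premature_stop": m.group(3) == "1",
        "unjoinable": m.group(4) == "1",
    }


# ---------------------------------------------------------------------------
# labelled public-set stand-in for threshold calibration

def simulate_labeled_set(
    n_families: int = 20,
    members_per_family: int = 5,
    interior_len: int = 106,
    intra_divergence: float = 0.08,
    n_duplicates: int = 0,
    seed: int = 0,
):
    """Synthetic stand-in for a curated labelled nanobody collection.

    Families play the role of relatedness groups (same antigen + publication
    + submission); sequences within a family diverge by at most
    ``intra_divergence`` while families differ in their CDR windows.
    Optional exact duplicates exercise deduplication.  Returns a list of
    :class:`~nbmine.calibration.PublicEntry`.
    """
    from .calibration import PublicEntry

    cfg = SimConfig(
        n_lineages=n_families,
        n_binders=0,
        variants_per_lineage=members_per_family,
        intra_lineage_divergence=intra_divergence,
        scaffold_len=interior_len + 14,
        reads_per_sample=1,
        seed=seed,
    )
    truth = simulate_repertoire(cfg)
    entries = []
    for lin in truth.lineages:
        for v in lin.variants:
            entries.append(
                PublicEntry(
                    id=f"F{lin.lineage_id}M{v.variant_id}",
                    peptide=v.peptide_trimmed,
                    antigens=frozenset({f"antigen{lin.lineage_id}"}),
                    publications=frozenset({f"pub{lin.lineage_id}"}),
                    submissions=frozenset({f"sub{lin.lineage_id}"}),
                )
            )
    rng = np.random.default_rng(seed + 1)
    for k in range(n_duplicates):
        src = entries[int(rng.integers(0, len(entries)))]
        entries.append(replace(src, id=f"{src.id}dup{k}"))
    return entries
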