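"""Paired-end amplicon reads to validated nanobody peptides.

The stages mirror a standard amplicon clean-up for VHH (nanobody) libraries
sequenced with 2 x 250 bp chemistry:

1. merge each forward/reverse pair on their best overlap (minimum overlap
   length, maximum mismatch rate);
2. discard merged reads with low mean Phred quality or short length;
3. orient reads from the FR1 PCR primer to the FR4 PCR primer, honouring
   IUPAC degeneracy in the primers;
4. translate in frame +1 from the first base of the FR1 primer and keep only
   peptides that end in frame with the FR4 primer and contain no stop codon;
5. trim seven residues from each end (the primer-encoded positions) and tally
   unique trimmed peptides per sample.

Every read is accounted for exactly once: the per-stage counts reported by
:func:`process_read_pairs` satisfy raw = merged + unjoinable,
merged = qc_pass + qc_fail, qc_pass = oriented + no_primer + partial_amplicon,
oriented = validated + frameshift + premature_stop + ambiguous + too_short.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import IUPAC, encode, revcomp

# ---------------------------------------------------------------------------
# domain types

# FR1 forward primer (encodes EVQLVES) and FR4 reverse primer; W = A/T, so the
# amplicon sense strand ends in ACCC(A/T)GGTCACCGTCTCCTCA encoding T(L/Q)VTVSS.
FR1_PRIMER = "GAGGTGCAGCTGGTGGAGTCT"
FR4_PRIMER = "TGAGGAGACGGTGACCWGGGT"

FR1_AA = "EVQLVES"
FR4_TAILS = {"L": "TLVTVSS", "Q": "TQVTVSS"}

TRIM_EACH_SIDE = 7  # primer-encoded residues removed from each peptide end


@dataclass(frozen=True)
class PrimerSpec:
    """The FR1/FR4 amplification primer pair (FR4 given on the antisense strand)."""

    fr1_dna: str = FR1_PRIMER
    fr4_dna: str = FR4_PRIMER

    def __post_init__(self) -> None:
        if str(Seq(self.fr1_dna).translate()) != FR1_AA:
            raise ValueError("FR1 primer must encode " + FR1_AA)
        if len(self.fr4_dna) != 21:
            raise ValueError("FR4 primer must be a 21-mer")

    @property
    def fr4_rc(self) -> str:
        """FR4 primer on the amplicon sense strand (reverse complement)."""
        return revcomp(self.fr4_dna)


@dataclass
class ReadPair:
    id: str
    fwd_seq: str
    fwd_qual: np.ndarray
    rev_seq: str
    rev_qual: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.fwd_qual = np.asarray(self.fwd_qual, dtype=np.int16)
        self.rev_qual = np.asarray(self.rev_qual, dtype=np.int16)
        if len(self.fwd_seq) != self.fwd_qual.size or len(self.rev_seq) != self.rev_qual.size:
            raise ValueError("sequence and quality lengths differ")
        if not self.fwd_seq or not self.rev_seq:
            raise ValueError("empty mate sequence")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: np.ndarray
    sample: str = ""
    overlap_len: int = 0
    mismatches_in_overlap: int = 0


@dataclass(frozen=True)
class ValidatedPeptide:
    full_peptide: str
    trimmed_peptide: str
    sample: str = ""


@dataclass(frozen=True)
class Rejection:
    """A read dropped at a pipeline stage, with the stage and the reason."""

    id: str
    stage: str
    reason: str


@dataclass
class StageCounts:
    """Per-sample read accounting across the clean-up stages."""

    raw: int = 0
    merged: int = 0
    unjoinable: int = 0
    qc_pass: int = 0
    qc_fail: int = 0
    oriented: int = 0
    no_primer: int = 0
    partial_amplicon: int = 0
    validated: int = 0
    frameshift: int = 0
    premature_stop: int = 0
    ambiguous: int = 0
    too_short: int = 0
    unique: int = 0

    def check_conservation(self) -> None:
        assert self.raw == self.merged + self.unjoinable
        assert self.merged == self.qc_pass + self.qc_fail
        assert self.qc_pass == self.oriented + self.no_primer + self.partial_amplicon
        assert self.oriented == (
            self.validated + self.frameshift + self.premature_stop
            + self.ambiguous + self.too_short
        )


@dataclass
class ProcessResult:
    sample: str
    counts: StageCounts
    tally: Counter = field(default_factory=Counter)
    rejections: list[Rejection] = field(default_factory=list)


# ---------------------------------------------------------------------------
# codon translation

_CODON_AA: dict[str, str] = {}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            _cod = _a + _b + _c
            _CODON_AA[_cod] = str(Seq(_cod).translate())

# 5-symbol base index (A,C,G,T,other) -> 125-entry codon lookup used by the
# vectorised batch translator; any codon touching an uncalled base gives 'X'.
_BASE_IDX = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _BASE_IDX[ord(_ch)] = _i
_CODON_LUT = np.full(125, ord("X"), dtype=np.uint8)
for _i, _a in enumerate("ACGT"):
    for _j, _b in enumerate("ACGT"):
        for _k, _c in enumerate("ACGT"):
            _CODON_LUT[_i * 25 + _j * 5 + _k] = ord(_CODON_AA[_a + _b + _c])


def translate_frame(dna: str) -> str:
    """Translate a DNA string in frame +1; codons with N become ``X``."""
    if len(dna) % 3:
        raise ValueError("length not a multiple of 3")
    return "".join(_CODON_AA.get(dna[i : i + 3], "X") for i in range(0, len(dna), 3))


def _translate_matrix(mat: np.ndarray) -> list[str]:
    """Translate rows of an (n, 3k) uint8 sequence matrix to peptide strings."""
    idx = _BASE_IDX[mat]
    cod = idx[:, 0::3].astype(np.int32) * 25 + idx[:, 1::3] * 5 + idx[:, 2::3]
    aa = _CODON_LUT[cod]
    return [row.tobytes().decode("ascii") for row in aa]


# ---------------------------------------------------------------------------
# pair merging

_FWD_N_SENTINEL = 1  # distinct sentinels so N never matches anything,
_REV_N_SENTINEL = 2  # not even another N on the opposite mate


def _overlap_scan(
    fwd: np.ndarray,
    rev: np.ndarray,
    min_overlap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts for every admissible overlap of a batch of pairs.

    ``fwd``/``rev`` are (n, Lf) and (n, Lr) uint8 matrices, the reverse mate
    already reverse-complemented.  Returns (overlap lengths descending,
    mismatch-count matrix of shape (n_overlaps, n)).
    """
    n, lf = fwd.shape
    lr = rev.shape[1]
    fs = fwd.copy()
    fs[fs == ord("N")] = _FWD_N_SENTINEL
    rs = rev.copy()
    rs[rs == ord("N")] = _REV_N_SENTINEL
    max_o = min(lf, lr)
    overlaps = np.arange(max_o, min_overlap - 1, -1)
    mism = np.empty((overlaps.size, n), dtype=np.int32)
    for row, o in enumerate(overlaps):
        mism[row] = (fs[:, lf - o :] != rs[:, :o]).sum(axis=1)
    return overlaps, mism


def _merge_batch(
    ids: Sequence[str],
    fwd: np.ndarray,
    fq: np.ndarray,
    rev: np.ndarray,
    rq: np.ndarray,
    sample: str,
    min_overlap: int,
    max_mismatch_rate: float,
) -> tuple[list[MergedRead], list[str]]:
    """Merge a batch of equal-length pairs; returns (merged, unjoinable ids)."""
    n, lf = fwd.shape
    lr = rev.shape[1]
    if min(lf, lr) < min_overlap:
        return [], list(ids)
    overlaps, mism = _overlap_scan(fwd, rev, min_overlap)
    rates = mism / overlaps[:, None]
    # overlaps are scanned longest-first, so argmin picks the longest overlap
    # among equal mismatch fractions
    best = np.argmin(rates, axis=0)
    cols = np.arange(n)
    best_rate = rates[best, cols]
    best_o = overlaps[best]
    best_mism = mism[best, cols]
    ok = best_rate <= max_mismatch_rate

    merged: list[MergedRead] = []
    rejected = [ids[i] for i in np.flatnonzero(~ok)]
    for o in np.unique(best_o[ok]):
        sel = np.flatnonzero(ok & (best_o == o))
        af, ar = fwd[sel, lf - o :], rev[sel, :o]
        qf, qr = fq[sel, lf - o :], rq[sel, :o]
        agree = af == ar
        take_rev = ~agree & (qr > qf)
        base = np.where(take_rev, ar, af)
        qual = np.where(agree, np.maximum(qf, qr), np.abs(qf - qr))
        seq_mat = np.hstack([fwd[sel, : lf - o], base, rev[sel, o:]])
        qual_mat = np.hstack([fq[sel, : lf - o], qual, rq[sel, o:]])
        for k, i in enumerate(sel):
            merged.append(
                MergedRead(
                    id=ids[i],
                    seq=seq_mat[k].tobytes().decode("ascii"),
                    qual=qual_mat[k],
                    sample=sample,
                    overlap_len=int(o),
                    mismatches_in_overlap=int(best_mism[i]),
                )
            )
    return merged, rejected


def merge_read_pair(
    pair: ReadPair,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.25,
) -> MergedRead | Rejection:
    """Join a read pair on its best overlap.

    The reverse mate is reverse-complemented, all overlaps of at least
    ``min_overlap`` bases are scanned, and the overlap with the lowest
    mismatch fraction wins (ties go to the longer overlap).  The pair is
    rejected as ``unjoinable`` when even the best overlap exceeds
    ``max_mismatch_rate``.  Within the overlap the higher-quality base is
    kept: agreeing bases get max(q1, q2), disagreeing bases get |q1 - q2|.
    """
    rc = revcomp(pair.rev_seq)
    merged, rejected = _merge_batch(
        [pair.id],
        encode(pair.fwd_seq)[None, :],
        pair.fwd_qual[None, :],
        encode(rc)[None, :],
        pair.rev_qual[::-1][None, :],
        pair.sample,
        min_overlap,
        max_mismatch_rate,
    )
    if merged:
        return merged[0]
    return Rejection(pair.id, "merge", "unjoinable")


# ---------------------------------------------------------------------------
# quality / length filter

def quality_length_filter(
    read: MergedRead,
    min_mean_phred: float = 38,
    min_len: int = 150,
) -> tuple[bool, str]:
    """Pass iff mean Phred >= ``min_mean_phred`` and length >= ``min_len``."""
    if len(read.seq) == 0:
        return False, "empty"
    if len(read.seq) < min_len:
        return False, "short"
    if float(np.mean(read.qual)) < min_mean_phred:
        return False, "low_quality"
    return True, ""


# ---------------------------------------------------------------------------
# primer detection and orientation

def _iupac_regex(primer: str) -> re.Pattern[str]:
    parts = []
    for ch in primer.upper():
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else "[" + opts + "]")
    return re.compile("".join(parts))


def _mismatch_find(seq: str, primer_sets: list[str], max_mm: int, last: bool) -> int:
    """Positions of a primer allowing up to ``max_mm`` mismatches (slow path)."""
    k = len(primer_sets)
    span = range(len(seq) - k, -1, -1) if last else range(len(seq) - k + 1)
    for pos in span:
        mm = 0
        for j in range(k):
            if seq[pos + j] not in primer_sets[j]:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return pos
    return -1


class PrimerMatcher:
    """Locates the FR1 primer and the FR4 primer (sense strand) in a read."""

    def __init__(self, primers: PrimerSpec | None = None, max_mismatches: int = 0):
        self.primers = primers or PrimerSpec()
        self.max_mismatches = max_mismatches
        self._fr1_re = _iupac_regex(self.primers.fr1_dna)
        self._fr4_re = _iupac_regex(self.primers.fr4_rc)
        self._fr1_sets = [IUPAC[c] for c in self.primers.fr1_dna]
        self._fr4_sets = [IUPAC[c] for c in self.primers.fr4_rc]

    def find_fr1(self, seq: str) -> int:
        if self.max_mismatches == 0:
            m = self._fr1_re.search(seq)
            return m.start() if m else -1
        return _mismatch_find(seq, self._fr1_sets, self.max_mismatches, last=False)

    def find_fr4_end(self, seq: str, after: int = 0) -> int:
        """End coordinate of the last FR4 match starting at or after ``after``."""
        if self.max_mismatches == 0:
            end = -1
            for m in self._fr4_re.finditer(seq, after):
                end = m.end()
            return end
        pos = _mismatch_find(seq[after:], self._fr4_sets, self.max_mismatches, last=True)
        return -1 if pos < 0 else after + pos + len(self._fr4_sets)


def orient_read(
    read: MergedRead,
    primers: PrimerSpec | None = None,
    max_primer_mismatches: int = 0,
    matcher: PrimerMatcher | None = None,
) -> MergedRead | Rejection:
    """Turn a merged read into FR1 -> FR4 orientation and trim to the primers.

    The returned read begins at the first base of the FR1 primer and ends at
    the last base of the FR4 primer match; a read matching on the antisense
    strand is flipped first.  Rejected with ``no_primer`` when neither primer
    is found on either strand, and with ``partial_amplicon`` when only one of
    the two is present.
    """
    m = matcher or PrimerMatcher(primers, max_primer_mismatches)
    candidates = ((read.seq, read.qual), (revcomp(read.seq), read.qual[::-1]))
    saw_any = False
    for seq, qual in candidates:
        p1 = m.find_fr1(seq)
        if p1 < 0:
            continue
        saw_any = True
        p4 = m.find_fr4_end(seq, p1 + len(m.primers.fr1_dna))
        if p4 < 0:
            continue
        return MergedRead(
            id=read.id,
            seq=seq[p1:p4],
            qual=np.asarray(qual[p1:p4]),
            sample=read.sample,
            overlap_len=read.overlap_len,
            mismatches_in_overlap=read.mismatches_in_overlap,
        )
    if not saw_any:
        # FR1 absent everywhere; FR4 alone still makes it a partial amplicon
        for seq, _ in candidates:
            if m.find_fr4_end(seq) >= 0:
                return Rejection(read.id, "orient", "partial_amplicon")
        return Rejection(read.id, "orient", "no_primer")
    return Rejection(read.id, "orient", "partial_amplicon")


# ---------------------------------------------------------------------------
# translation and validation

def _classify_peptide(
    peptide: str,
    min_trimmed_len: int,
) -> tuple[str | None, str]:
    """(rejection reason or None, trimmed peptide)."""
    if "*" in peptide:
        return "premature_stop", ""
    if "X" in peptide:
        return "ambiguous", ""
    trimmed = peptide[TRIM_EACH_SIDE:-TRIM_EACH_SIDE]
    if len(trimmed) < min_trimmed_len:
        return "too_short", ""
    return None, trimmed


def translate_validate(
    read: MergedRead,
    min_trimmed_len: int = 36,
) -> ValidatedPeptide | Rejection:
    """Translate an oriented read in frame +1 and validate the frame.

    Valid reads span FR1 start to FR4 end in a multiple of 3 with no stop
    codon anywhere; codons containing uncalled bases are rejected as
    ``ambiguous``.  The trimmed peptide removes the seven primer-encoded
    residues from each end.
    """
    if not read.seq:
        raise ValueError("empty read")
    if len(read.seq) % 3:
        return Rejection(read.id, "translate", "frameshift")
    peptide = translate_frame(read.seq)
    reason, trimmed = _classify_peptide(peptide, min_trimmed_len)
    if reason is not None:
        return Rejection(read.id, "translate", reason)
    return ValidatedPeptide(full_peptide=peptide, trimmed_peptide=trimmed, sample=read.sample)


# ---------------------------------------------------------------------------
# whole-sample processing

@dataclass
class ProcessParams:
    min_overlap: int = 10
    max_mismatch_rate: float = 0.25
    min_mean_phred: float = 38.0
    min_len: int = 150
    max_primer_mismatches: int = 0
    min_trimmed_len: int = 36
    primers: PrimerSpec = field(default_factory=PrimerSpec)


def process_read_pairs(
    pairs: Iterable[ReadPair],
    sample: str,
    params: ProcessParams | None = None,
) -> ProcessResult:
    """Run merge -> quality/length -> orient -> translate over read pairs.

    Pairs are batched by mate lengths so merging and translation run
    vectorised; the outcome per read is identical to applying the
    single-read operations in sequence.
    """
    params = params or ProcessParams()
    counts = StageCounts()
    result = ProcessResult(sample=sample, counts=counts)
    matcher = PrimerMatcher(params.primers, params.max_primer_mismatches)

    groups: dict[tuple[int, int], list[ReadPair]] = defaultdict(list)
    for pair in pairs:
        counts.raw += 1
        groups[(len(pair.fwd_seq), len(pair.rev_seq))].append(pair)

    merged_all: list[MergedRead] = []
    chunk = 32768  # bounds the overlap-scan working set
    for (lf, lr), grp in sorted(groups.items()):
        for start in range(0, len(grp), chunk):
            sub = grp[start : start + chunk]
            ids = [p.id for p in sub]
            fwd = np.vstack([encode(p.fwd_seq) for p in sub])
            fq = np.vstack([p.fwd_qual for p in sub])
            rev = np.vstack([encode(revcomp(p.rev_seq)) for p in sub])
            rq = np.vstack([p.rev_qual[::-1] for p in sub])
            merged, unjoinable = _merge_batch(
                ids, fwd, fq, rev, rq, sample, params.min_overlap, params.max_mismatch_rate
            )
            merged_all.extend(merged)
            counts.unjoinable += len(unjoinable)
            result.rejections.extend(Rejection(i, "merge", "unjoinable") for i in unjoinable)
    counts.merged = len(merged_all)

    oriented: list[MergedRead] = []
    for read in merged_all:
        ok, reason = quality_length_filter(read, params.min_mean_phred, params.min_len)
        if not ok:
            counts.qc_fail += 1
            result.rejections.append(Rejection(read.id, "quality", reason))
            continue
        counts.qc_pass += 1
        out = orient_read(read, matcher=matcher)
        if isinstance(out, Rejection):
            result.rejections.append(out)
            if out.reason == "no_primer":
                counts.no_primer += 1
            else:
                counts.partial_amplicon += 1
            continue
        oriented.append(out)
    counts.oriented = len(oriented)

    # vectorised translation, grouped by oriented span length
    by_len: dict[int, list[MergedRead]] = defaultdict(list)
    for read in oriented:
        if len(read.seq) % 3:
            counts.frameshift += 1
            result.rejections.append(Rejection(read.id, "translate", "frameshift"))
        else:
            by_len[len(read.seq)].append(read)
    for length, grp in sorted(by_len.items()):
        mat = np.vstack([encode(r.seq) for r in grp])
        for read, peptide in zip(grp, _translate_matrix(mat)):
            reason, trimmed = _classify_peptide(peptide, params.min_trimmed_len)
            if reason is None:
                counts.validated += 1
                result.tally[trimmed] += 1
            else:
                setattr(counts, reason, getattr(counts, reason) + 1)
                result.rejections.append(Rejection(read.id, "translate", reason))

    counts.unique = len(result.tally)
    counts.check_conservation()
    return result


# ---------------------------------------------------------------------------
# FASTQ I/O

def _open_text(path) -> Iterator[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(r1_path, r2_path, sample: str = "") -> Iterator[ReadPair]:
    """Iterate synchronized mates from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path) as h1, _open_text(r2_path) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
            qa1 = encode(q1).astype(np.int16) - 33
            qa2 = encode(q2).astype(np.int16) - 33
            yield ReadPair(
                id=id1.split()[0],
                fwd_seq=s1.upper(),
                fwd_qual=qa1,
                rev_seq=s2.upper(),
                rev_qual=qa2,
                sample=sample,
            )


def process_sample(
    r1_path,
    r2_path,
    sample: str,
    params: ProcessParams | None = None,
) -> ProcessResult:
    """Process one demultiplexed sample from its paired FASTQ files."""
    return process_read_pairs(read_fastq_pairs(r1_path, r2_path, sample), sample, params)


def write_peptides_fasta(tally: Mapping[str, int], sample: str, path) -> None:
    """Validated trimmed peptides as FASTA, header ``sample|count``."""
    with open(path, "w") as fh:
        for i, pep in enumerate(sorted(tally)):
            fh.write(f">{sample}|{tally[pep]}|u{i}\n{pep}\n")


def write_rejection_log(rejections: Sequence[Rejection], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstage\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.stage}\t{r.reason}\n")
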