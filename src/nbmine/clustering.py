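"""Greedy incremental peptide clustering at a sequence identity threshold.

This re-implements the CD-HIT clustering rule as used for nanobody
repertoires: sequences are sorted long-to-short and processed sequentially;
the first founds a cluster, and each subsequent sequence is compared against
all previously founded representatives of the same length (no length
difference allowed, the -s 1 setting) and joins the representative of highest
identity at or above the threshold (the slow/accurate -g 1 behaviour), else
founds a new cluster.

Identity between two equal-length peptides is the maximum number of identical
aligned residue pairs over all global alignments, divided by the length.
That maximum equals the length of the longest common subsequence, computed
here with the Allison–Dix bit-parallel recurrence (O(n^2 / wordsize)).
Gap-containing alignments can therefore beat the plain Hamming count, e.g.
for sequences differing by an adjacent transposition.

Determinism: the input order is total — length descending, then total read
count descending, then lexicographic — and best-representative ties go to the
lowest cluster id, so identical inputs give byte-identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import encode

IDENTITY_GRID = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00)
_EPS = 1e-9


# ---------------------------------------------------------------------------
# pairwise identity

def lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length (Allison–Dix bit-parallel)."""
    if not a or not b:
        return 0
    masks: dict[str, int] = {}
    bit = 1
    for ch in b:
        masks[ch] = masks.get(ch, 0) | bit
        bit <<= 1
    r = 0
    for ch in a:
        m = masks.get(ch)
        if m is None:
            continue
        x = r | m
        r = x & ~(x - ((r << 1) | 1))
    return r.bit_count()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two equal-length peptides, in [0, 1].

    identity = (max identical aligned pairs over all global alignments) / len.
    Symmetric; 1.0 iff the sequences are equal.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if len(a) != len(b):
        raise ValueError("pairwise_identity requires equal lengths (s = 1)")
    if a == b:
        return 1.0
    return lcs_length(a, b) / len(a)


# ---------------------------------------------------------------------------
# domain types

@dataclass
class SequenceTally:
    """Unique trimmed peptides with per-sample validated read counts."""

    samples: tuple[str, ...]
    entries: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_counters(cls, counters: Mapping[str, Mapping[str, int]]) -> "SequenceTally":
        """Pool per-sample peptide counters into one tally."""
        samples = tuple(counters)
        tally = cls(samples=samples)
        for si, sample in enumerate(samples):
            for pep, n in counters[sample].items():
                row = tally.entries.get(pep)
                if row is None:
                    row = np.zeros(len(samples), dtype=np.int64)
                    tally.entries[pep] = row
                row[si] += n
        return tally

    def add(self, peptide: str, sample: str, count: int = 1) -> None:
        row = self.entries.get(peptide)
        if row is None:
            row = np.zeros(len(self.samples), dtype=np.int64)
            self.entries[peptide] = row
        row[self.samples.index(sample)] += count

    @property
    def sample_totals(self) -> dict[str, int]:
        tot = np.zeros(len(self.samples), dtype=np.int64)
        for row in self.entries.values():
            tot += row
        return dict(zip(self.samples, tot.tolist()))

    def total_count(self, peptide: str) -> int:
        return int(self.entries[peptide].sum())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.90
    length_cutoff: float = 1.0  # -s; only 1.0 (equal lengths) is supported
    accurate_mode: bool = True  # -g 1; join the best representative, not the first

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity threshold must be in (0, 1]")
        if self.length_cutoff != 1.0:
            raise ValueError("only length_cutoff 1.0 is supported")


@dataclass
class ClusterMember:
    peptide: str
    counts: np.ndarray  # per-sample read counts, aligned with tally.samples
    identity: float


@dataclass
class Cluster:
    cluster_id: int
    representative: str
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.representative)

    @property
    def n_members(self) -> int:
        return len(self.members)

    def sample_counts(self) -> np.ndarray:
        return np.sum([m.counts for m in self.members], axis=0)


# ---------------------------------------------------------------------------
# greedy engine

class _RepGroup:
    """Representatives of one common length, with conservative prescreens.

    The amino-acid composition intersection bounds the LCS from above
    (a common subsequence is a common multiset), and length minus Hamming
    distance bounds it from below; exact identities are only computed for
    representatives whose bound interval can reach the threshold.
    """

    def __init__(self, length: int):
        self.length = length
        self.cluster_ids: list[int] = []
        self.rep_strings: list[str] = []
        self._cap = 16
        self._n = 0
        self._mat = np.zeros((self._cap, length), dtype=np.uint8)
        self._comp = np.zeros((self._cap, 26), dtype=np.int32)
        self._masks: list[dict[str, int] | None] = []

    def add(self, cluster_id: int, peptide: str, arr: np.ndarray, comp: np.ndarray) -> None:
        if self._n == self._cap:
            self._cap *= 2
            self._mat = np.vstack([self._mat, np.zeros_like(self._mat)])
            self._comp = np.vstack([self._comp, np.zeros_like(self._comp)])
        self._mat[self._n] = arr
        self._comp[self._n] = comp
        self._n += 1
        self.cluster_ids.append(cluster_id)
        self.rep_strings.append(peptide)
        self._masks.append(None)

    def _rep_masks(self, i: int) -> dict[str, int]:
        masks = self._masks[i]
        if masks is None:
            masks = {}
            bit = 1
            for ch in self.rep_strings[i]:
                masks[ch] = masks.get(ch, 0) | bit
                bit <<= 1
            self._masks[i] = masks
        return masks

    def _identity_vs(self, i: int, peptide: str, hamming: int) -> float:
        if hamming == 0:
            return 1.0
        if hamming == 1:  # a single substitution cannot be beaten by gaps
            return (self.length - 1) / self.length
        masks = self._rep_masks(i)
        r = 0
        for ch in peptide:
            m = masks.get(ch)
            if m is None:
                continue
            x = r | m
            r = x & ~(x - ((r << 1) | 1))
        return r.bit_count() / self.length

    def best_match(self, peptide: str, arr: np.ndarray, comp: np.ndarray,
                   threshold: float) -> tuple[int, float] | None:
        """(cluster_id, identity) of the best representative >= threshold.

        Exact identities are only computed for representatives whose upper
        bound reaches both the threshold and the best Hamming-based lower
        bound; any representative achieving the maximum identity (when that
        maximum clears the threshold) necessarily survives this filter, so
        the result equals the brute-force argmax with the same tie rule.
        """
        n, length = self._n, self.length
        mat = self._mat[:n]
        hamming = (mat != arr).sum(axis=1)
        lower_best = (length - int(hamming.min())) / length
        upper = np.minimum(self._comp[:n], comp).sum(axis=1) / length
        floor = max(threshold, lower_best)
        cand = np.flatnonzero(upper >= floor - _EPS)
        if cand.size == 0:
            return None
        best_id, best_ident = -1, -1.0
        for i in cand:
            ident = self._identity_vs(int(i), peptide, int(hamming[i]))
            if ident > best_ident + _EPS:
                best_ident = ident
                best_id = self.cluster_ids[i]
        if best_ident >= threshold - _EPS:
            return best_id, best_ident
        return None


def sorted_tally_order(tally: SequenceTally) -> list[str]:
    """The deterministic processing order: length desc, count desc, lexicographic."""
    return sorted(
        tally.entries, key=lambda p: (-len(p), -int(tally.entries[p].sum()), p)
    )


def _composition(arr: np.ndarray) -> np.ndarray:
    return np.bincount(arr - ord("A"), minlength=26).astype(np.int32)


def greedy_cluster(tally: SequenceTally, params: ClusterParams | None = None) -> list[Cluster]:
    """Cluster unique peptides with the sorted greedy rule.

    Read counts are carried along as member metadata and never influence the
    geometry beyond their role in the (total) deterministic input ordering.
    """
    params = params or ClusterParams()
    if len(tally) == 0:
        raise ValueError("empty tally")
    c = params.identity_threshold
    clusters: list[Cluster] = []
    groups: dict[int, _RepGroup] = {}
    for peptide in sorted_tally_order(tally):
        counts = tally.entries[peptide]
        arr = encode(peptide)
        comp = _composition(arr)
        group = groups.get(len(peptide))
        hit = group.best_match(peptide, arr, comp, c) if group is not None else None
        if hit is None:
            cid = len(clusters)
            cluster = Cluster(cluster_id=cid, representative=peptide)
            cluster.members.append(ClusterMember(peptide, counts, 1.0))
            clusters.append(cluster)
            if group is None:
                group = _RepGroup(len(peptide))
                groups[len(peptide)] = group
            group.add(cid, peptide, arr, comp)
        else:
            cid, ident = hit
            clusters[cid].members.append(ClusterMember(peptide, counts, ident))
    return clusters


def cluster_at_grid(
    tally: SequenceTally,
    thresholds: Iterable[float] = IDENTITY_GRID,
) -> dict[float, list[Cluster]]:
    """One independent clustering per identity threshold, same input order."""
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold grid")
    return {
        t: greedy_cluster(tally, ClusterParams(identity_threshold=t)) for t in thresholds
    }


# ---------------------------------------------------------------------------
# tally / member tables (the on-disk handoff between pipeline stages)

def write_tally_tsv(tally: SequenceTally, path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"count_{s}" for s in tally.samples)
        fh.write(f"peptide\t{cols}\n")
        for pep in sorted(tally.entries):
            vals = "\t".join(str(int(v)) for v in tally.entries[pep])
            fh.write(f"{pep}\t{vals}\n")


def read_tally_tsv(path) -> SequenceTally:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = tuple(h.removeprefix("count_") for h in header[1:])
        tally = SequenceTally(samples=samples)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tally.entries[parts[0]] = np.array([int(v) for v in parts[1:]], dtype=np.int64)
    return tally


def write_members_tsv(clusters: Sequence[Cluster], samples: Sequence[str], path) -> None:
    """Full membership table; sufficient to reconstruct the clustering."""
    with open(path, "w") as fh:
        cols = "\t".join(f"count_{s}" for s in samples)
        fh.write(f"cluster_id\tpeptide\tidentity\tis_representative\t{cols}\n")
        for cl in clusters:
            for m in cl.members:
                vals = "\t".join(str(int(v)) for v in m.counts)
                fh.write(
                    f"{cl.cluster_id}\t{m.peptide}\t{m.identity!r}\t"
                    f"{int(m.peptide == cl.representative)}\t{vals}\n"
                )


def read_members_tsv(path) -> tuple[list[Cluster], tuple[str, ...]]:
    clusters: dict[int, Cluster] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = tuple(h.removeprefix("count_") for h in header[4:])
        for line in fh:
            cid_s, pep, ident, is_rep, *counts = line.rstrip("\n").split("\t")
            cid = int(cid_s)
            member = ClusterMember(pep, np.array([int(v) for v in counts], dtype=np.int64),
                                   float(ident))
            cl = clusters.get(cid)
            if cl is None:
                cl = clusters[cid] = Cluster(cluster_id=cid, representative="")
            cl.members.append(member)
            if is_rep == "1":
                cl.representative = pep
    return [clusters[k] for k in sorted(clusters)], samples


# ---------------------------------------------------------------------------
# reports

def write_cluster_tsv(clusters: Sequence[Cluster], samples: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"count_{s}" for s in samples)
        fh.write(f"cluster_id\trepresentative\tlength\tn_members\t{cols}\n")
        for cl in clusters:
            counts = cl.sample_counts()
            vals = "\t".join(str(int(v)) for v in counts)
            fh.write(f"{cl.cluster_id}\t{cl.representative}\t{cl.length}\t{cl.n_members}\t{vals}\n")


def write_clstr(clusters: Sequence[Cluster], path) -> None:
    """CD-HIT ``.clstr``-compatible listing for interoperability."""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">Cluster {cl.cluster_id}\n")
            for i, m in enumerate(cl.members):
                tag = "*" if m.peptide == cl.representative else f"at {100.0 * m.identity:.2f}%"
                fh.write(f"{i}\t{len(m.peptide)}aa, >c{cl.cluster_id}m{i}... {tag}\n")


def write_representatives_fasta(clusters: Sequence[Cluster], path) -> None:
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">cluster_{cl.cluster_id}\n{cl.representative}\n")
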