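"""Identity-threshold calibration on a labelled nanobody set.

The working identity threshold for repertoire clustering is justified by an
inverse argument: rather than proving relatedness, cluster a large, diverse,
labelled collection of published nanobody sequences across a grid of
thresholds and count, per cluster, how many members are *unrelated* to the
rest.  Two entries are related when they share a target antigen, a source
publication, or a database submission; relatedness is taken transitively
(connected components of the share-a-label graph), and a cluster's unrelated
count is its size minus its largest related component.  A threshold is
acceptable when clusters stop mixing unrelated sequences; lowering the
threshold monotonically increases mixing.

The module consumes any peptide FASTA plus a metadata table and uses the same
trimming convention and the same clustering engine as the main pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .clustering import (
    IDENTITY_GRID,
    Cluster,
    ClusterParams,
    SequenceTally,
    greedy_cluster,
)

UNKNOWN = ""


@dataclass
class PublicEntry:
    """A curated public nanobody sequence with relatedness labels.

    Unknown labels are empty; an entry with all labels unknown is treated as
    related to nothing (and flagged in reports).
    """

    id: str
    peptide: str
    antigens: frozenset[str] = frozenset()
    publications: frozenset[str] = frozenset()
    submissions: frozenset[str] = frozenset()

    def all_unknown(self) -> bool:
        return not (self.antigens or self.publications or self.submissions)


@dataclass
class CalibrationResult:
    threshold: float
    n_clusters: int
    # per cluster: (size, n_unrelated, has_all_unknown_member)
    per_cluster: list[tuple[int, int, bool]] = field(default_factory=list)

    @property
    def n_mixed_clusters(self) -> int:
        """Clusters containing at least one unrelated member."""
        return sum(1 for _, u, _ in self.per_cluster if u > 0)

    @property
    def n_unrelated_total(self) -> int:
        return sum(u for _, u, _ in self.per_cluster)


def deduplicate(entries: Iterable[PublicEntry]) -> list[PublicEntry]:
    """Collapse exact-duplicate peptides, merging their labels (union)."""
    by_pep: dict[str, PublicEntry] = {}
    for e in entries:
        if not e.peptide:
            raise ValueError(f"entry {e.id} has an empty peptide")
        prev = by_pep.get(e.peptide)
        if prev is None:
            by_pep[e.peptide] = e
        else:
            by_pep[e.peptide] = PublicEntry(
                id=prev.id,
                peptide=prev.peptide,
                antigens=prev.antigens | e.antigens,
                publications=prev.publications | e.publications,
                submissions=prev.submissions | e.submissions,
            )
    return list(by_pep.values())


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def relatedness_partition(members: Sequence[PublicEntry]) -> tuple[int, int]:
    """(largest related component size, number of unrelated members).

    Members sharing any antigen, publication, or submission label are joined;
    components are the transitive closure.  Unrelated = cluster size minus
    the largest component.
    """
    if not members:
        raise ValueError("empty cluster")
    uf = _UnionFind(len(members))
    for kind in ("antigens", "publications", "submissions"):
        seen: dict[str, int] = {}
        for i, m in enumerate(members):
            for label in getattr(m, kind):
                j = seen.setdefault(label, i)
                if j != i:
                    uf.union(j, i)
    sizes: dict[int, int] = {}
    for i in range(len(members)):
        r = uf.find(i)
        sizes[r] = sizes.get(r, 0) + 1
    largest = max(sizes.values())
    return largest, len(members) - largest


def calibrate(
    entries: Sequence[PublicEntry],
    thresholds: Iterable[float] = IDENTITY_GRID,
) -> list[CalibrationResult]:
    """Cluster a non-redundant labelled set at each threshold and score mixing.

    Uses the identical greedy engine and parameters as the main pipeline
    (every entry weighted once; equal lengths enforced by the engine).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold grid")
    entries = list(entries)
    tally = SequenceTally(samples=("public",))
    for e in entries:
        tally.add(e.peptide, "public", 1)
    if len(tally) != len(entries):
        raise ValueError("entries must be deduplicated before calibration")
    by_pep = {e.peptide: e for e in entries}

    results = []
    for t in sorted(thresholds, reverse=True):
        clusters = greedy_cluster(tally, ClusterParams(identity_threshold=t))
        per_cluster = []
        for cl in clusters:
            members = [by_pep[m.peptide] for m in cl.members]
            _, n_unrelated = relatedness_partition(members)
            per_cluster.append(
                (cl.n_members, n_unrelated, any(m.all_unknown() for m in members))
            )
        results.append(
            CalibrationResult(threshold=t, n_clusters=len(clusters), per_cluster=per_cluster)
        )
    return results


# ---------------------------------------------------------------------------
# I/O: peptide FASTA + metadata TSV (id, antigen, publication, submission)

def _split_labels(cell: str) -> frozenset[str]:
    cell = (cell or "").strip()
    if not cell or cell.lower() in {"unknown", "na", "nan"}:
        return frozenset()
    return frozenset(part.strip() for part in cell.split(";") if part.strip())


def load_labeled_set(fasta_path, metadata_path, trim: int = 7) -> list[PublicEntry]:
    """Read a labelled peptide set; peptides are trimmed like pipeline reads.

    ``trim`` residues are removed from each end (the primer-encoded FR1/FR4
    positions); pass 0 for pre-trimmed input.
    """
    meta: dict[str, dict[str, str]] = {}
    with open(metadata_path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["id"]] = row
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.get(rec.id, {})
        pep = str(rec.seq).upper()
        if trim:
            pep = pep[trim:-trim]
        entries.append(
            PublicEntry(
                id=rec.id,
                peptide=pep,
                antigens=_split_labels(row.get("antigen", "")),
                publications=_split_labels(row.get("publication", "")),
                submissions=_split_labels(row.get("submission", "")),
            )
        )
    return entries


def write_calibration_tsv(results: Sequence[CalibrationResult], path) -> None:
    """Per-threshold summary plus Figure-style per-cluster bubble data."""
    with open(path, "w") as fh:
        fh.write("threshold\tn_clusters\tn_mixed_clusters\tn_unrelated_total\n")
        for r in results:
            fh.write(f"{r.threshold}\t{r.n_clusters}\t{r.n_mixed_clusters}\t{r.n_unrelated_total}\n")


def write_bubble_tsv(results: Sequence[CalibrationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tcluster_size\tn_unrelated\thas_all_unknown\n")
        for r in results:
            for size, unrelated, unknown in r.per_cluster:
                fh.write(f"{r.threshold}\t{size}\t{unrelated}\t{int(unknown)}\n")
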