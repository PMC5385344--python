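"""Majority-rule consensus peptides and synthesis-ready DNA.

Because clustering allows no length differences, all members of a cluster are
already columnwise comparable without a multiple alignment.  Each column's
consensus residue is the one with the greatest weight — selection-sample read
counts by default, so the information of the most enriched sequences is
captured while sporadic PCR and read errors are voted away.  Ties go to the
representative's residue, then alphabetically.

The seven primer-encoded residues trimmed before clustering are restored
around the consensus (EVQLVES and T(L/Q)VTVSS), and the full peptide is
reverse-translated with the most frequent codon per residue from a packaged
E. coli usage table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._util import encode
from .clustering import Cluster
from .read_processing import FR1_AA, FR4_TAILS, translate_frame

Weighting = Literal["reads", "unique"]


@dataclass
class ConsensusRecord:
    cluster_id: int
    consensus_trimmed: str
    consensus_full: str = ""
    dna: str = ""
    # per column: list of (residue, weight fraction), best first
    support: list[list[tuple[str, float]]] = field(default_factory=list)


def majority_consensus(
    cluster: Cluster,
    weighting: Weighting = "reads",
    sample_index: int | None = None,
) -> ConsensusRecord:
    """Columnwise majority vote over a cluster's equal-length members.

    ``weighting='reads'`` weights each member by its read count in the sample
    selected by ``sample_index`` (all samples summed when None);
    ``weighting='unique'`` gives every unique member weight 1.
    """
    if cluster.n_members == 0:
        raise ValueError("empty cluster")
    length = cluster.length
    if weighting == "unique":
        weights = np.ones(cluster.n_members)
    else:
        if sample_index is None:
            weights = np.array([float(m.counts.sum()) for m in cluster.members])
        else:
            weights = np.array([float(m.counts[sample_index]) for m in cluster.members])
        if weights.sum() == 0:  # cluster unseen in the weighting sample
            weights = np.ones(cluster.n_members)

    mat = np.vstack([encode(m.peptide) for m in cluster.members])
    rep = encode(cluster.representative)
    total = weights.sum()
    out = np.empty(length, dtype=np.uint8)
    support: list[list[tuple[str, float]]] = []
    for col in range(length):
        residues, inv = np.unique(mat[:, col], return_inverse=True)
        w = np.bincount(inv, weights=weights, minlength=residues.size)
        best_w = w.max()
        top = residues[np.isclose(w, best_w)]
        if rep[col] in top:  # tie-break: representative's residue
            winner = rep[col]
        else:
            winner = int(top.min())  # then lexicographic
        out[col] = winner
        order = np.argsort(-w, kind="stable")
        support.append([(chr(residues[i]), float(w[i] / total)) for i in order])
    return ConsensusRecord(
        cluster_id=cluster.cluster_id,
        consensus_trimmed=out.tobytes().decode("ascii"),
        support=support,
    )


def restore_flanks(consensus_trimmed: str, fr4_variant: Literal["L", "Q"] = "L") -> str:
    """Re-attach the primer-encoded FR1 head and FR4 tail (7 residues each)."""
    if not consensus_trimmed:
        raise ValueError("empty consensus")
    return FR1_AA + consensus_trimmed + FR4_TAILS[fr4_variant]


# Most frequent codon per residue in the E. coli K-12 codon usage table
# (per-mille frequencies from the Kazusa codon usage database); packaged so no
# download is needed.  Deterministic: one codon per residue.
ECOLI_TOP_CODON = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
}

CODON_TABLES = {"E. coli": ECOLI_TOP_CODON, "e_coli": ECOLI_TOP_CODON}


def reverse_translate(peptide: str, codon_table: str = "E. coli") -> str:
    """Deterministic reverse translation (most frequent codon per residue).

    Round-trip exact: translating the result reproduces the input peptide.
    """
    table = CODON_TABLES[codon_table]
    try:
        dna = "".join(table[aa] for aa in peptide)
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None
    assert translate_frame(dna) == peptide
    return dna


def consensus_for_clusters(
    clusters: Sequence[Cluster],
    weighting: Weighting = "reads",
    sample_index: int | None = None,
    fr4_variant: Literal["L", "Q"] = "L",
    codon_table: str = "E. coli",
) -> list[ConsensusRecord]:
    """Full consensus records (trimmed, flanked, DNA) for a set of clusters."""
    records = []
    for cl in clusters:
        rec = majority_consensus(cl, weighting=weighting, sample_index=sample_index)
        rec.consensus_full = restore_flanks(rec.consensus_trimmed, fr4_variant)
        rec.dna = reverse_translate(rec.consensus_full, codon_table)
        records.append(rec)
    return records


def write_consensus_fastas(records: Sequence[ConsensusRecord], peptide_path, dna_path) -> None:
    with open(peptide_path, "w") as fp, open(dna_path, "w") as fd:
        for r in records:
            fp.write(f">cluster_{r.cluster_id}_consensus\n{r.consensus_full}\n")
            fd.write(f">cluster_{r.cluster_id}_consensus\n{r.dna}\n")


def write_support_tsv(records: Sequence[ConsensusRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcolumn\tresidue\tweight_fraction\n")
        for r in records:
            for col, entries in enumerate(r.support):
                for residue, frac in entries:
                    fh.write(f"{r.cluster_id}\t{col}\t{residue}\t{frac!r}\n")
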