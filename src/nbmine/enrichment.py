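"""Cross-sample enrichment of clusters and candidate selection.

A cluster's enrichment factor compares its (depth-normalised) read count in
the selection sample against its count in the negative-control sample:

    f  = control_total / selection_total          (normalisation factor)
    EF = (count_sel * f) / max(count_ctrl, 1)     (pseudocounted denominator)

The pseudocount applies only to the control side, so clusters absent from the
control still get a finite EF while selection-side zeros give EF = 0.
Candidates must clear both gates: selection-sample size >= min_size and
EF >= min_ef (boundary values included).

Hit rates over screened candidates are reported with exact Clopper-Pearson
binomial confidence intervals (beta-distribution quantiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import beta as _beta

from ._util import pct, round_half_up
from .clustering import Cluster


@dataclass
class EnrichmentRecord:
    cluster_id: int
    count_sel: int
    count_ctrl: int
    count_ctrl_adj: int
    norm_factor: float
    count_sel_norm: float
    enrichment_factor: float
    is_candidate: bool
    representative: str = ""


def normalization_factor(ref_total: int, sel_total: int) -> float:
    """Depth-normalisation factor: reference (control) total over selection total.

    Full precision is returned; reports round half-up to 2 decimals
    (3.4e6 / 2.8e6 prints as 1.21).
    """
    if ref_total <= 0 or sel_total <= 0:
        raise ValueError("sample totals must be positive")
    return ref_total / sel_total


def enrichment_factor(count_sel: int, count_ctrl: int, f: float) -> float:
    """EF = normalised selection count over pseudocounted control count."""
    if count_sel < 0 or count_ctrl < 0:
        raise ValueError("counts must be non-negative")
    if f <= 0:
        raise ValueError("normalisation factor must be positive")
    return (count_sel * f) / max(count_ctrl, 1)


def enrichment_records(
    clusters: Sequence[Cluster],
    samples: Sequence[str],
    selection: str,
    control: str,
    min_size: int = 10,
    min_ef: float = 10.0,
    norm_factor: float | None = None,
) -> list[EnrichmentRecord]:
    """Per-cluster enrichment relative to the control sample.

    When ``norm_factor`` is not given it is computed from the totals of the
    clustered counts themselves (control total / selection total).
    """
    si = list(samples).index(selection)
    ci = list(samples).index(control)
    counts = np.array([cl.sample_counts() for cl in clusters], dtype=np.int64)
    if norm_factor is None:
        norm_factor = normalization_factor(int(counts[:, ci].sum()), int(counts[:, si].sum()))
    records = []
    for cl, row in zip(clusters, counts):
        n_sel, n_ctrl = int(row[si]), int(row[ci])
        ef = enrichment_factor(n_sel, n_ctrl, norm_factor)
        records.append(
            EnrichmentRecord(
                cluster_id=cl.cluster_id,
                count_sel=n_sel,
                count_ctrl=n_ctrl,
                count_ctrl_adj=max(n_ctrl, 1),
                norm_factor=norm_factor,
                count_sel_norm=n_sel * norm_factor,
                enrichment_factor=ef,
                is_candidate=(n_sel >= min_size and ef >= min_ef),
                representative=cl.representative,
            )
        )
    return records


def select_candidates(
    records: Sequence[EnrichmentRecord],
    min_size: int = 10,
    min_ef: float = 10.0,
) -> list[EnrichmentRecord]:
    """Clusters clearing both inclusion gates, strongest enrichment first."""
    hits = [r for r in records if r.count_sel >= min_size and r.enrichment_factor >= min_ef]
    return sorted(hits, key=lambda r: (-r.enrichment_factor, -r.count_sel, r.cluster_id))


# ---------------------------------------------------------------------------
# cluster size census

@dataclass
class SizeCategory:
    count: int
    fraction_of_sequences: float
    mean_size: float


@dataclass
class ClusterSizeSummary:
    sample: str
    n_clusters: int
    total_sequences: int
    mean_size: float
    orphan: SizeCategory
    medium: SizeCategory
    large: SizeCategory


def _category(sizes: np.ndarray, total: int) -> SizeCategory:
    if sizes.size == 0:
        return SizeCategory(0, 0.0, 0.0)
    return SizeCategory(
        count=int(sizes.size),
        fraction_of_sequences=float(sizes.sum() / total) if total else 0.0,
        mean_size=float(sizes.mean()),
    )


def summarize_clusters(clusters: Sequence[Cluster], samples: Sequence[str], sample: str) -> ClusterSizeSummary:
    """Census of cluster sizes in one sample.

    A cluster's size is that sample's read count; clusters with zero reads in
    the sample are excluded.  Orphans have one read, medium clusters
    1 < n <= 10, large clusters n > 10.
    """
    si = list(samples).index(sample)
    sizes = np.array([int(cl.sample_counts()[si]) for cl in clusters], dtype=np.int64)
    sizes = sizes[sizes > 0]
    total = int(sizes.sum())
    return ClusterSizeSummary(
        sample=sample,
        n_clusters=int(sizes.size),
        total_sequences=total,
        mean_size=float(sizes.mean()) if sizes.size else 0.0,
        orphan=_category(sizes[sizes == 1], total),
        medium=_category(sizes[(sizes > 1) & (sizes <= 10)], total),
        large=_category(sizes[sizes > 10], total),
    )


# ---------------------------------------------------------------------------
# proportion confidence intervals

def proportion_ci(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, as fractions.

    The lower bound is exactly 0 when successes = 0 and the upper bound
    exactly 1 when successes = n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes out of range")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(_beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(_beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def proportion_report(successes: int, n: int, confidence: float = 0.95) -> dict[str, float]:
    """Hit rate and CI as whole percentages (half-up), report style."""
    lo, hi = proportion_ci(successes, n, confidence)
    return {
        "percent": pct(successes, n),
        "ci_lower_percent": round_half_up(100 * lo),
        "ci_upper_percent": round_half_up(100 * hi),
    }


def write_enrichment_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\trepresentative\tcount_sel\tcount_ctrl\tcount_ctrl_adj\t"
            "norm_factor\tcount_sel_norm\tenrichment_factor\tis_candidate\n"
        )
        for r in records:
            fh.write(
                f"{r.cluster_id}\t{r.representative}\t{r.count_sel}\t{r.count_ctrl}\t"
                f"{r.count_ctrl_adj}\t{r.norm_factor!r}\t{r.count_sel_norm!r}\t"
                f"{r.enrichment_factor!r}\t{int(r.is_candidate)}\n"
            )
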