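"""End-to-end orchestration: process -> cluster -> enrich -> consensus.

`run_all` drives the whole analysis from a structured config (two paired
FASTQ samples in, candidate consensus FASTAs and summary tables out) and
produces a run manifest whose per-stage counts satisfy the read-conservation
identities of the processing stage; every percentage in the manifest is
recomputed from its integer numerator and denominator, so the human-readable
tables can never drift from the underlying counts.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from ._util import pct, round_half_up
from .clustering import (
    Cluster,
    ClusterParams,
    SequenceTally,
    greedy_cluster,
    write_cluster_tsv,
    write_clstr,
    write_members_tsv,
    write_representatives_fasta,
    write_tally_tsv,
)
from .consensus import consensus_for_clusters, write_consensus_fastas, write_support_tsv
from .enrichment import (
    ClusterSizeSummary,
    EnrichmentRecord,
    enrichment_records,
    normalization_factor,
    select_candidates,
    summarize_clusters,
    write_enrichment_tsv,
)
from .read_processing import (
    ProcessParams,
    ProcessResult,
    ReadPair,
    StageCounts,
    process_read_pairs,
    process_sample,
    write_peptides_fasta,
    write_rejection_log,
)

logger = logging.getLogger("nbmine")


class InputError(ValueError):
    """Invalid or empty pipeline input (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


@dataclass
class PipelineParams:
    processing: ProcessParams = field(default_factory=ProcessParams)
    identity_threshold: float = 0.90
    min_size: int = 10
    min_ef: float = 10.0
    weighting: str = "reads"
    fr4_variant: str = "L"
    reference_sample: str = "control"  # which sample's total is the numerator of f

    @classmethod
    def from_mapping(cls, m: Mapping) -> "PipelineParams":
        m = dict(m or {})
        proc_keys = {
            "min_overlap", "max_mismatch_rate", "min_mean_phred", "min_len",
            "max_primer_mismatches", "min_trimmed_len",
        }
        proc = ProcessParams(**{k: m.pop(k) for k in list(m) if k in proc_keys})
        return cls(processing=proc, **m)


@dataclass
class RunResult:
    manifest: dict
    tally: SequenceTally
    clusters: list[Cluster]
    records: list[EnrichmentRecord]
    candidates: list[EnrichmentRecord]
    consensus: list
    summaries: dict[str, ClusterSizeSummary]
    process_results: dict[str, ProcessResult]


def _stage_counts_dict(c: StageCounts) -> dict:
    d = {k: getattr(c, k) for k in vars(c)}
    d["joinable_pct"] = pct(c.merged, c.raw)
    d["unique_pct"] = pct(c.unique, c.validated)
    return d


def build_manifest(
    process_results: Mapping[str, ProcessResult],
    config_snapshot: Mapping,
    seed: int | None = None,
    selection_output_sizes: Mapping[str, float] | None = None,
) -> dict:
    samples = {}
    for label, res in process_results.items():
        entry = _stage_counts_dict(res.counts)
        size = (selection_output_sizes or {}).get(label)
        if size:
            entry["selection_output_size"] = size
            entry["unique_per_output_size_pct"] = pct(res.counts.unique, size)
        samples[label] = entry
    return {
        "tool": "nbmine",
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dict(config_snapshot),
        "samples": samples,
    }


def report_table1(manifest: dict) -> str:
    """Raw-data processing summary, one column per sample."""
    labels = list(manifest["samples"])
    rows = [
        ("Raw reads (counts)", "raw"),
        ("Joined reads (counts)", "merged"),
        ("Joinable fraction (%)", "joinable_pct"),
        ("Full-length nanobody sequences (counts)", "validated"),
        ("Unique sequences (counts)", "unique"),
        ("Fraction unique sequences (%)", "unique_pct"),
    ]
    if all("unique_per_output_size_pct" in manifest["samples"][s] for s in labels):
        rows.insert(0, ("Selection output size (cfu)", "selection_output_size"))
        rows.append(("Unique sequences/selection output size (%)", "unique_per_output_size_pct"))
    width = max(len(r[0]) for r in rows)
    lines = ["".ljust(width) + "\t" + "\t".join(labels)]
    for title, key in rows:
        vals = []
        for s in labels:
            v = manifest["samples"][s].get(key, "")
            vals.append(str(int(v)) if isinstance(v, float) and float(v).is_integer() else str(v))
        lines.append(title.ljust(width) + "\t" + "\t".join(vals))
    return "\n".join(lines) + "\n"


def report_table2(summaries: Mapping[str, ClusterSizeSummary]) -> str:
    """Cluster census (orphan / medium / large), one column per sample."""
    labels = list(summaries)
    def fmt(x: float, nd: int = 1) -> str:
        r = round_half_up(x, nd)
        return str(int(r)) if float(r).is_integer() else str(r)

    rows = [
        ("All clusters (count)", lambda s: str(s.n_clusters)),
        ("Mean cluster size (# sequences)", lambda s: fmt(s.mean_size)),
        ("Orphan clusters (1 member) (count)", lambda s: str(s.orphan.count)),
        ("  Fraction of total sequences (%)", lambda s: fmt(100 * s.orphan.fraction_of_sequences, 0)),
        ("Medium clusters (1 < n <= 10 members) (count)", lambda s: str(s.medium.count)),
        ("  Fraction of total sequences (%)", lambda s: fmt(100 * s.medium.fraction_of_sequences, 0)),
        ("  Mean cluster size (# sequences)", lambda s: fmt(s.medium.mean_size)),
        ("Large clusters (n > 10 members) (count)", lambda s: str(s.large.count)),
        ("  Fraction of total sequences (%)", lambda s: fmt(100 * s.large.fraction_of_sequences, 0)),
        ("  Mean cluster size (# sequences)", lambda s: fmt(s.large.mean_size)),
    ]
    width = max(len(r[0]) for r in rows)
    lines = ["".ljust(width) + "\t" + "\t".join(labels)]
    for title, getter in rows:
        lines.append(title.ljust(width) + "\t" + "\t".join(getter(summaries[s]) for s in labels))
    return "\n".join(lines) + "\n"


def run_from_pairs(
    pairs_by_sample: Mapping[str, Sequence[ReadPair]],
    selection: str,
    control: str,
    params: PipelineParams | None = None,
    output_dir: str | Path | None = None,
    config_snapshot: Mapping | None = None,
    seed: int | None = None,
    selection_output_sizes: Mapping[str, float] | None = None,
) -> RunResult:
    """The full analysis over in-memory read pairs (the core of `run_all`)."""
    params = params or PipelineParams()

    process_results: dict[str, ProcessResult] = {}
    for label, pairs in pairs_by_sample.items():
        logger.info("processing sample %s", label)
        res = process_read_pairs(pairs, label, params.processing)
        if res.counts.raw == 0 or res.counts.validated == 0:
            raise InputError(f"empty sample {label!r}: no validated reads")
        logger.info(
            "sample %s: raw=%d merged=%d validated=%d unique=%d",
            label, res.counts.raw, res.counts.merged, res.counts.validated, res.counts.unique,
        )
        process_results[label] = res

    tally = SequenceTally.from_counters(
        {label: res.tally for label, res in process_results.items()}
    )

    logger.info("clustering %d unique peptides at c=%s", len(tally), params.identity_threshold)
    try:
        clusters = greedy_cluster(tally, ClusterParams(params.identity_threshold))
    except Exception as exc:  # pragma: no cover - defensive stage tagging
        raise StageError(f"clustering failed: {exc}") from exc
    logger.info("%d clusters", len(clusters))

    totals = tally.sample_totals
    ref = control if params.reference_sample == "control" else selection
    other = selection if ref == control else control
    f = normalization_factor(totals[ref], totals[other])
    records = enrichment_records(
        clusters, tally.samples, selection, control,
        min_size=params.min_size, min_ef=params.min_ef, norm_factor=f,
    )
    candidates = select_candidates(records, params.min_size, params.min_ef)
    logger.info("%d candidate clusters (size >= %d, EF >= %s)",
                len(candidates), params.min_size, params.min_ef)

    by_id = {cl.cluster_id: cl for cl in clusters}
    sel_index = list(tally.samples).index(selection)
    consensus = consensus_for_clusters(
        [by_id[r.cluster_id] for r in candidates],
        weighting=params.weighting,
        sample_index=sel_index,
        fr4_variant=params.fr4_variant,
    )

    summaries = {
        label: summarize_clusters(clusters, tally.samples, label)
        for label in tally.samples
    }

    manifest = build_manifest(
        process_results, config_snapshot or {}, seed=seed,
        selection_output_sizes=selection_output_sizes,
    )
    manifest["normalization_factor"] = f
    manifest["normalization_factor_2dp"] = round_half_up(f, 2)
    manifest["n_clusters"] = len(clusters)
    manifest["n_candidates"] = len(candidates)

    result = RunResult(
        manifest=manifest, tally=tally, clusters=clusters, records=records,
        candidates=candidates, consensus=consensus, summaries=summaries,
        process_results=process_results,
    )
    if output_dir is not None:
        write_run_outputs(result, output_dir)
    return result


def write_run_outputs(result: RunResult, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = result.tally.samples
    for label, res in result.process_results.items():
        write_rejection_log(res.rejections, out / f"rejected_{label}.tsv")
        write_peptides_fasta(res.tally, label, out / f"peptides_{label}.fasta")
    write_tally_tsv(result.tally, out / "tally.tsv")
    write_cluster_tsv(result.clusters, samples, out / "clusters.tsv")
    write_members_tsv(result.clusters, samples, out / "members.tsv")
    write_clstr(result.clusters, out / "clusters.clstr")
    write_representatives_fasta(result.clusters, out / "representatives.fasta")
    write_enrichment_tsv(result.records, out / "enrichment.tsv")
    write_enrichment_tsv(result.candidates, out / "candidates.tsv")
    # scatter data for the EF-vs-size candidate plot
    with open(out / "scatter_ef_size.tsv", "w") as fh:
        fh.write("cluster_id\tcount_sel\tenrichment_factor\tis_candidate\n")
        for r in result.records:
            fh.write(f"{r.cluster_id}\t{r.count_sel}\t{r.enrichment_factor!r}\t{int(r.is_candidate)}\n")
    write_consensus_fastas(result.consensus, out / "consensus_peptides.fasta",
                           out / "consensus_dna.fasta")
    write_support_tsv(result.consensus, out / "consensus_support.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
        fh.write("\n")
    with open(out / "table1.txt", "w") as fh:
        fh.write(report_table1(result.manifest))
    with open(out / "table2.txt", "w") as fh:
        fh.write(report_table2(result.summaries))


def run_all(config: Mapping, output_dir: str | Path | None = None) -> RunResult:
    """Run the pipeline from a structured config (see README for the schema).

    Required keys: ``samples.selection`` and ``samples.control``, each with
    ``label``, ``r1`` and ``r2`` FASTQ paths.  Optional: ``params`` (any
    :class:`PipelineParams` / processing field), ``output_dir``, ``seed``,
    ``selection_output_sizes``.
    """
    try:
        sel = config["samples"]["selection"]
        ctrl = config["samples"]["control"]
    except KeyError as exc:
        raise InputError(f"config missing samples section: {exc}") from None
    for role, entry in (("selection", sel), ("control", ctrl)):
        for key in ("label", "r1", "r2"):
            if key not in entry:
                raise InputError(f"samples.{role} missing {key!r}")
        for key in ("r1", "r2"):
            if not Path(entry[key]).exists():
                raise InputError(f"samples.{role}.{key}: no such file {entry[key]!r}")

    params = PipelineParams.from_mapping(config.get("params", {}))
    output_dir = output_dir or config.get("output_dir")

    pairs_by_sample = {}
    from .read_processing import read_fastq_pairs

    for entry in (sel, ctrl):
        pairs_by_sample[entry["label"]] = read_fastq_pairs(
            entry["r1"], entry["r2"], entry["label"]
        )
    return run_from_pairs(
        pairs_by_sample,
        selection=sel["label"],
        control=ctrl["label"],
        params=params,
        output_dir=output_dir,
        config_snapshot=config,
        seed=config.get("seed"),
        selection_output_sizes=config.get("selection_output_sizes"),
    )


def setup_logging(verbose: bool = True, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
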