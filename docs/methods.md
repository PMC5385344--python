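# Methods

This note documents the models and procedures implemented in `nbmine`, the
parameter choices that matter, and what the synthetic-data validation does
and does not demonstrate.

## Read processing

**Pair merging.** The reverse mate is reverse-complemented and every overlap
of at least `min_overlap` (default 10) bases is scored; the overlap with the
lowest mismatch fraction wins, ties going to the longer overlap. Pairs whose
best overlap still exceeds `max_mismatch_rate` (default 0.25) are rejected as
unjoinable. Within the overlap the higher-quality base is kept; the merged
quality is max(q₁, q₂) where the mates agree and |q₁ − q₂| where they
disagree — the standard behaviour of overlap mergers, which quantifies how
much evidence survives a disagreement. An uncalled base (N) never counts as a
match, not even against another N, so ambiguous positions always register as
overlap mismatches.

**Filtering order.** The mean-Phred (≥ 38) and length (≥ 150 bp) filter is
applied to the *merged* read, before primer detection. The alternative order
(orient first, filter the primer-trimmed span) changes which bases enter the
mean; the merged-read convention is the conservative one because it judges
the read as sequenced. Phred scores are offset-33 throughout.

**Orientation.** Reads are turned into FR1→FR4 orientation by locating the
FR1 primer and the reverse complement of the FR4 primer, honouring IUPAC
degeneracy (the FR4 primer's W matches A or T). Matching is exact by default;
a configurable tolerance (`max_primer_mismatches`) exists for robustness but
is off because a mismatched primer base cannot be distinguished from a
mutated template. The returned read is trimmed to the primer span, so frame
+1 of the returned read is the FR1 primer's reading frame.

**Validation.** The primer-to-primer span must be a multiple of 3
(otherwise: frameshift), contain no stop codon anywhere including the final
codon (premature stop), and contain no codon with an uncalled base
(ambiguous — exact peptide tallying needs unambiguous residues). Seven
residues are trimmed from each end of the translated peptide — the
primer-encoded positions, which carry no clonal information. A guard rejects
trimmed peptides shorter than 36 residues (degenerate amplicons that happen
to satisfy all other checks); it never triggers on realistic input and is
logged when it does. Every input read is accounted for exactly once across
the stage counters, which is asserted at run time.

## Clustering

Unique trimmed peptides are clustered by the greedy incremental rule of
CD-HIT run in slow/accurate mode with no length differences: sequences are
processed in a total order (length descending, then total read count
descending, then lexicographic — the count and lexicographic keys make the
otherwise input-order-dependent algorithm reproducible); the first sequence
founds cluster 0; each subsequent sequence is compared against **all**
existing representatives of the same length and joins the one with the
highest identity ≥ *c* (ties to the lowest cluster id), else founds a new
cluster. Read counts are carried as metadata and never affect the geometry
beyond the input ordering.

**Identity.** For equal-length peptides, identity is defined as the maximum
number of identical aligned residue pairs over all global alignments, divided
by the length. That maximum equals the longest-common-subsequence length, so
gap-containing alignments are honoured (two sequences differing by an
adjacent transposition are 90% identical at length 10, although their Hamming
agreement is 80%). The implementation uses the Allison–Dix bit-parallel LCS
recurrence; a Hamming fast path is used only where provably exact (0 or 1
mismatches).

**Prescreens.** Two conservative bounds avoid most exact computations: the
amino-acid composition intersection bounds the LCS from above (a common
subsequence is a common multiset), and length minus Hamming distance bounds
it from below. Exact identities are computed only for representatives whose
upper bound reaches both the threshold and the best lower bound; the chosen
cluster and the reported identities are therefore *identical* to the
brute-force computation (verified against a naive quadratic reference in the
test suite), never an approximation.

**Pooling.** The two samples are pooled into one tally before clustering, so
a cluster's per-sample counts refer to the same sequence geometry and the
enrichment ratio is well defined. Clustering each sample separately and
matching clusters afterwards would make the ratio depend on a cluster
correspondence heuristic.

## Threshold calibration

The working threshold is justified inversely: rather than proving that
cluster members are related, a large labelled nanobody collection is
clustered across *c* ∈ {0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 1.00} and each
cluster is scored for members *unrelated* to the rest. Two entries are
related if they share a target antigen, a source publication, or a database
submission; relatedness is closed transitively (connected components of the
share-a-label graph), and a cluster's unrelated count is its size minus its
largest component. Entries with no labels at all are counted as unrelated to
everything and flagged separately. Calibration runs through the identical
clustering engine and trimming convention as the main pipeline. On labelled
fixtures the number of mixed clusters increases monotonically as the
threshold drops; 0.90 is the default working threshold.

## Enrichment and candidate selection

With validated-sequence totals N_ctrl and N_sel, the depth-normalization
factor is f = N_ctrl / N_sel (reported half-up to two decimals; full
precision used in arithmetic). Per cluster,

    EF = (count_sel × f) / max(count_ctrl, 1)

The pseudocount applies only to the control side: clusters absent from the
control get a finite EF, while clusters absent from the selection get EF = 0
and can never be candidates. Candidates must satisfy count_sel ≥ 10 **and**
EF ≥ 10, boundary values included; cluster "size" for the gate is the raw
(pre-normalization) selection-sample count. Cluster censuses split clusters
into orphan (1 read), medium (2–10), and large (> 10) by the per-sample read
count, excluding clusters unseen in that sample.

Screened hit rates are reported with exact Clopper–Pearson binomial
intervals (beta-distribution quantiles), rounded half-up to whole
percentages. Half-up rounding is used for all human-readable reports;
machine-readable TSVs carry full precision.

## Consensus and reverse translation

Because no length differences are allowed within clusters, members are
columnwise comparable without alignment. Each column's consensus residue is
the one with the greatest weight; weights default to selection-sample read
counts (candidates are selection-driven and the most enriched sequences
should dominate the vote), with a unique-member mode for comparison. Ties go
to the representative's residue, then alphabetically — a deterministic rule
that also makes the consensus invariant under member reordering. Per-column
support fractions are emitted alongside.

The trimmed consensus is flanked with EVQLVES and TLVTVSS (or TQVTVSS; the
FR4 primer's degenerate W position encodes L or Q, and L is the default) and
reverse-translated one-codon-per-residue from a packaged E. coli K-12
most-frequent-codon table, so the DNA round-trips exactly to the peptide. No
codon optimization beyond that is attempted.

## Synthetic data

The simulator generates what the analysis assumes the laboratory produced:

* **Repertoire** — lineage founder peptides on a shared scaffold (fixed
  primer-encoded flanks, one shared framework interior, three CDR-like
  windows ≈ 25% of the interior randomised per lineage), giving
  inter-lineage identities around 0.75–0.80, the regime the threshold
  calibration is about. Founders colliding at ≥ 95% identity are resampled.
  Within a lineage, variants differ from the founder by 1…⌈divergence × L⌉
  point substitutions (default divergence 0.02).
* **Abundances** — log-normal clone masses (σ = 1.0; Zipf optional) times
  log-normal within-lineage variant masses. Binder lineages are rescaled to
  jointly hold 2% of the pre-selection library (`binder_base_fraction`):
  antigen-specific clones are rare before selection, and this is what makes
  a 50× enrichment measurable as EF ≫ 10 after renormalization — if binders
  already dominated the base library, enriching them would mostly renormalize
  away.
* **Reads** — per-variant read counts are multinomial draws from each
  sample's expected fractions; each read's amplicon copy receives point
  substitutions in the interior (the primer-annealed ends are overwritten by
  the primers and stay error-free), a premature stop codon, or a 1-nt
  frameshift indel at the configured per-read rates, and a configured
  fraction of pairs get a random reverse mate so they cannot be joined.
  Substitutions are applied at the amplicon (template/PCR) level, so both
  mates of a pair agree — consistent with PCR errors dominating over
  sequencing errors at Q40. Qualities are constant Q40 by default with an
  optional 3′ decay to exercise the mean-quality filter.

Every read id encodes its sample, lineage, variant, and injected errors, so
rejection logs and tallies can be audited against ground truth.

**What passing tests show — and don't.** The simulator realises exactly the
error processes the pipeline filters, with independent errors and a shared
scaffold geometry. Real libraries have position-dependent error spectra,
PCR chimeras/recombination (excluded by default), length-variant CDR3s
beyond the fixed-scaffold approximation, and biological relatedness that the
three-label calibration rule only approximates. Recovery of planted binders
therefore validates the *machinery* (accounting, clustering exactness,
enrichment arithmetic, consensus correction), not the biological error model.

## Validation scale and numerical choices

The end-to-end recovery study uses 440 lineages (40 binders at 50×
enrichment) and 2 × 10⁵ reads per sample — about 15× fewer reads than a
MiSeq run, chosen so the whole study executes in minutes while keeping
per-cluster counts (hundreds of reads) in the regime where the gates are
meaningful. Identity comparisons use an absolute tolerance of 1e-9 when
compared against thresholds (identities are rationals k/L, so distinct
values at realistic lengths differ by ≥ 1/L). The consensus error-correction
guarantee (truth recovered in ≥ 99% of clusters at substitution rate 0.01
with 50 reads) is measured over 1,000 seeded replicates.

## Known limitations

* Clustering requires equal lengths (the no-length-difference setting);
  peptides of different lengths never co-cluster, which is intended here but
  makes the engine unsuitable for s < 1 use cases.
* The greedy partition depends on the processing order by construction; the
  package's total ordering makes it reproducible, but it is one of several
  defensible conventions.
* Barcode demultiplexing and adapter clipping are out of scope; inputs are
  per-sample, adapter-free FASTQ.
* No statistical test accompanies the enrichment factor; the size/EF gates
  are the inclusion rule, as in the underlying analysis design.
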