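# Methods

This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic data does and does not emulate.

## Coordinates and formats

Internally every interval is 0-based half-open; conversions happen only at
the I/O boundary (GFF3 is 1-based inclusive; narrowPeak/BED are 0-based
half-open; the narrowPeak summit offset is converted to an absolute
position, with a `-1` offset replaced by the interval midpoint under a
warning). The TSS is the first transcribed base: `start` on the plus
strand, `end − 1` internally on the minus strand. Signed TSS distances are
strand-oriented with negative = upstream.

## Peak filtering and replicate matching

Per-replicate filtering keeps peaks with fold enrichment strictly > 2 and
q-value strictly < 10⁻³ (`min_fold`, `max_q`); the reproducibility
thresholds — summit distance ≤ 200/≤ 100 bp, IDR ≤ 0.05 (`d_vl2`, `d_vl3`,
`idr_max`) — are non-strict. The strict/non-strict split follows how each
threshold is conventionally stated.

Matching is one-to-one: all cross-replicate peak pairs overlapping by
≥ 1 bp are enumerated, sorted by (summit distance, larger overlap,
lexicographic names), and accepted greedily while both members are unused.
Sorting on a symmetric key makes the matched set invariant under swapping
the replicates and independent of input order; the quadratic all-pairs
variant of the same rule serves as the test oracle. A matched pair's
interval is the union of the two peaks; its working summit is the midpoint
of the two replicate summits.

## IDR model

Scores (fold enrichment by default, −log₁₀ q as an option — the choice is a
config knob because either is defensible) are reduced to ranks,
`u = rank/(n+1)`, and inverted through the marginal mixture CDF onto latent
values z. The latent pairs follow a mixture of a reproducible component
N((μ,μ), σ²[[1,ρ],[ρ,1]]) with weight p and a fixed independent standard
normal null. EM starts from p=0.5, μ=1, σ=1, ρ=0.2 and re-inverts the
marginal each iteration.

Numerical choices, each with its reason:

* **Relative convergence tolerance** 10⁻⁶·(1+|loglik|), or 10⁻⁶ on the
  parameter vector: re-inverting the marginal on a finite grid (4096
  points) leaves the pseudo-likelihood stationary only to ~10⁻⁴ in
  absolute terms, so an absolute criterion never fires.
* **Up to 2000 iterations**: convergence is geometric and measured runs at
  n≈2000 pairs need roughly a thousand iterations; non-convergence raises
  an error carrying the full log-likelihood trace.
* **Box constraints** p∈[10⁻³, 1−10⁻³], μ∈[1, 20], σ∈[0.2, 20],
  ρ∈[0, 0.99]. The σ floor keeps the likelihood bounded (with no
  irreproducible pairs present, σ otherwise collapses to 0 at the mean).
  The μ floor is the identifiability anchor: with μ free, on uncorrelated
  replicates the "reproducible" component drifts onto the null (μ→0, ρ→0)
  and the mixture becomes unidentifiable with p drifting to 1; requiring
  at least one latent SD of separation defines what reproducible means and
  makes pure-noise inputs come out, correctly, as almost entirely
  irreproducible. ρ ≥ 0 because reproducible replicates co-vary
  positively.
* Fewer than 20 pairs, or fully tied scores in a replicate, are errors —
  the fit is meaningless there.

Global IDR is the cumulative mean of local idr along the local-idr
ordering, which is non-decreasing by construction. IDR is computed on the
two true biological replicates only (no pseudo-replicates).

## Peak annotation and promoter windows

Feature classification evaluates the pair summit against a fixed priority:
promoter 0–1 kb > 1–2 kb > 2–3 kb > 5′UTR > 3′UTR-and-exon handling inside
the gene body (UTRs outrank plain exon, exon outranks intron) > downstream
0–3 kb > distal intergenic. Among genes yielding the same category the
nearer TSS wins, then lexicographic gene id. Promoter membership is tested
at the summit (interval containment is available as `by="interval"`),
because the summit is the best point estimate of the binding position.

The promoter window for target assignment spans −2000…+100 bp of the TSS
in transcription direction, endpoints inclusive; one peak may support
several genes (divergent promoters). TSS profiles histogram the signed
distance to the nearest TSS over ±3 kb in 50-bp bins; equidistant TSSs
resolve toward the upstream gene, then lexicographic id. Both "peaks
within 3 kb upstream" readings (per peak and per peak–gene pair) can be
derived from the per-peak annotation table.

## DEG selection and classification

A contrast qualifies when |log₂FC| ≥ 1 and FDR ≤ 0.05 (inclusive, as
stated). "Consistent across the experiment" is genuinely ambiguous between
*qualifying in some stage in every RNAi line* and *qualifying in every
stage*; both are implemented (`stage_rule="any_stage"` default,
`"both_stages"` available, `require_both_lines` likewise) and the choice is
recorded in the pipeline output metadata. Direction is `down`/`up` when all
qualifying contrasts agree in sign, otherwise `mixed`; the up/down
percentages are computed over the directionally consistent direct targets,
with the mixed bucket reported separately.

Per level, direct = selected ∧ bound-at-that-level-or-better, indirect =
selected ∧ unbound; bound-not-DE and neither complete the partition, and
`n_direct + n_indirect = n_selected` always. Homoeolog collapse counts
distinct homoeolog groups per class; genes missing from the (explicitly
supplied) homoeolog map are tallied as unmapped rather than dropped, since
both octoploid-gene and collapsed counts are of interest. Percentages are
rounded half-up to one decimal; with zero selected DEGs they are NA, never
zero.

## Subgenome bias

For each homoeologous chromosome group, expected counts are
`E_s = N_group · L_s / Σ L` (real-valued; rounding is display-only), and the
statistic is the χ² goodness of fit with df = (#subgenomes − 1) = 3.
Per-group tests are the primary report — group-level structure is what the
question is about — uncorrected by default with a Bonferroni option (the
report states which was used). A pooled genome-wide test (counts and
lengths aggregated by subgenome) is provided for genome-wide dominance
questions and is what the power simulation exercises, since a uniform
per-subgenome multiplier is a genome-wide signal that per-group tests see
only at one-seventh the sample size. Expected-count cells of zero are an
error advising pooling. The same machinery accepts any peak subset, e.g.
promoter-window peaks only.

## Enrichment and proximity filtering

Bin enrichment truncates hierarchical bin paths to the requested level and
tests each bin with the one-sided hypergeometric upper tail
(`P[X ≥ k]` for k of n list genes among K of N universe genes), BH-adjusted
across tested bins; the test is named in the output because ontology tools
differ here. The universe defaults to all annotated genes and is caller-
configurable (e.g. expressed genes only). No ontology is bundled — any
two-column gene→path map works.

The proximity filter retains a protein group iff it is present in all bait
replicates (configurable to k-of-n) and absent from every control
replicate. Presence is boolean evidence from upstream identification; raw
count tables binarize at ≥ `min_count` (default 1). A peptide-level mode
applies the same rule per peptide row and keeps groups with ≥ 1 passing
peptide. Groups sharing peptides with a removed group are kept (no
parsimony re-grouping). Unique-protein counts deduplicate members across
retained groups.

## Synthetic data

The generator emulates the study design at reduced scale: 7 homoeologous
groups × 4 subgenomes (28 chromosomes of 600 kb), 100 genes per chromosome
in complete homoeolog quartets on a fixed 6-kb slot grid. The grid
guarantees, by construction, that neighbouring promoter windows and planted
peak placements never collide, so zero-noise recovery tests are exact
rather than probabilistic. Defaults preserve the structural ratios the
analysis cares about rather than absolute genome size: 150 planted
promoter-bound DEGs over 980 selected DEGs (≈15% direct), 61% of planted
effects downregulated, 30% per-replicate irreproducible peaks, 30-bp summit
jitter (so a few planted peaks fall from VL3 to VL2 at defaults), effect
sizes |log₂FC| ≥ 1 guaranteed for the planted core with FDR ≤ 0.05 in both
lines and stages, null effects N(0, 0.2) with uniform FDR (false selection
< 1%), and a 20-interactor / 60-background proteomics design with 3
replicates per condition.

All randomness flows from one seed through named substreams (genome, chip,
deg, proteomics), so changing one stage's parameters leaves the other
stages' draws untouched and same-seed runs are byte-identical on disk.

What the generator does **not** emulate: read-level data, fragment-length
and GC effects, mappability, count-based DE inference (FDRs are assigned,
not fitted — DE modelling is out of scope), chained or overlapping gene
structures, isoforms, and peak-width variation. Passing tests therefore
demonstrate the correctness and calibration of the decision logic and
statistics on data satisfying the model's assumptions, not robustness to
upstream artefacts of real sequencing data.

## Known limitations

* IDR supports exactly two replicates; pseudo-replicate workflows are not
  implemented.
* Chromosome-scale inputs with very many candidate overlaps rely on
  interval trees (O(n log n)); no streaming mode.
* The annotation priority table is a convention; tools differ, and a peak
  near a divergent promoter is attributed to the nearer TSS.
* The pipeline consumes upstream tabular outputs (peaks, DE tables, MS
  evidence); alignment, peak calling, DE fitting and spectral
  identification are out of scope by design.
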