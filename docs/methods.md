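# Methods

## Coordinates and coverage

All internal coordinates are 0-based half-open; GTF's 1-based closed
convention is converted only at the file boundary, and the conversion
is an involution (write ∘ read preserves printed coordinates).
Coverage is per-base float64, one array per chromosome; a stranded
track stores separate '+' and '−' arrays and DoG scanning reads the
host gene's strand, while an unstranded track stores one array.
bedGraph is the canonical coverage format because it is text and
diff-able at test scale; overlapping intervals are summed.

Pooling sums tracks base-wise. To make pooling exactly commutative at
fixed precision, contributions are summed in a canonical order (sorted
by array content). Exact associativity additionally requires
integer-valued depths (read counts), where float64 addition is exact;
with arbitrary float depths associativity holds only to rounding, and
the tests reflect that distinction.

Depth matching between libraries is done by binomial thinning of
coverage units (each unit kept independently with probability
target/total, seeded), not by resampling reads — an approximation,
since no read-level data exist at this scale; its first two moments
match read subsampling for single-base reads. Upsampling is refused.

## DoG calling

Parameters: window 200 bp, window pass threshold 0.6 (fraction of
bases with depth > 0), minimum run 5000 bp, adjacency filter 5 kb.
Choices worth stating:

- A window passes on *covered-base fraction*, not mean depth: "60%
  coverage" is a breadth criterion. A depth-weighted variant would be
  a config change in `_window_passes` but is not exposed.
- The run must start at the first window after the TES. "Continuous
  read density downstream of the 3′ end" is read literally: no gaps
  inside a run, and a failing first window means no call even if a
  passing run exists farther downstream.
- Extension strength is window-quantized (a multiple of 200 bp); the
  region is not trimmed back to the last covered base. Cohort medians
  near 10 kb make 200-bp granularity immaterial.
- A trailing partial window at the chromosome edge ends the run; a gene
  with no room for even one full window is skipped with a warning.
- The adjacency filter removes a call when any other gene overlaps
  (TES, TES+5 kb] in the direction of transcription; in stranded mode
  only same-strand genes count, since antisense neighbours cannot
  contaminate strand-resolved signal. The filter is non-increasing and
  idempotent, and both properties are tested.
- Group-level calling mirrors pooled-library practice: downsample each
  member to the group-minimum total, pool, then call.

The caller is verified against an independent brute-force oracle (an
explicit per-base loop over every window) for exact call-set equality
on 100+ seeded genomes, and for monotonicity in both thresholds.

## Quantification

Counts are coverage sums over intervals — a stand-in for read counting
that is exact for single-base reads and proportional otherwise. TPM
divides per-feature rates (count/length) by their sum; RPKM is provided
for figure-style tracks. The gene-vs-DoG "read depth ratio" is the
ratio of the median DoG TPM to the median host TPM over paired
DoG-producing genes; because the orientation of this ratio is
ambiguous in common usage, it is an explicit flag
(`dog_over_gene` default, `gene_over_dog` available) and no attempt is
made to reproduce any particular published value of it. Log2 condition
ratios use a pseudocount of 1 TPM (configurable) so condition-specific
DoGs stay finite.

## Differential expression

The NB engine is deliberately minimal and is validated by its operating
characteristics, not by equivalence with a reference tool:

- Size factors: median-of-ratios against the geometric-mean reference,
  over features positive in all samples.
- Dispersion: method of moments on the pooled within-group variance of
  normalized counts, α = (s² − μ̄)/μ̄², floored at 1e-8. No shrinkage,
  no outlier filtering.
- Test: Wald statistic log₂FC / SE with the delta-method standard
  error SE² = Σ_g (μ_g + αμ_g²) / (n_g (μ_g + pc)² ln²2), referred to a
  t distribution with n₁+n₂−2 degrees of freedom. The t reference is a
  small-sample correction chosen a priori: with five samples per group
  the normal reference rejects ~8–9% of null features at p < 0.05,
  while the t reference sits at ~5% (verified by simulation in the
  acceptance suite: null rejection inside the 99% binomial band over
  2000 features, ≥90% power at planted |log₂FC| = 2 with means ≥ 100).
- Features with all-zero counts get NA p-values and are excluded from
  BH; BH itself is the statsmodels step-up, cross-checked exactly
  against an independent textbook implementation.

Call thresholds are |log₂FC| > 0.58 (1.5-fold) at q < 0.05. The host
concordance grid uses closed "not changed" bounds
(−0.58 ≤ log₂FC ≤ 0.58 with q ≥ 0.05 as its nominal cell); (FC, q)
combinations covered by neither extreme cell — significant but small
fold changes, large but non-significant ones — are conservatively
assigned "not changed". Row percentages are computed within each
DoG-call row.

## Pausing

Pause indices are density ratios of coverage sums; windows are offset
along the direction of transcription and clipped at chromosome edges
(a vanished window yields NA, as does a zero-signal reference window).
PI > 2 flags a paused gene. For readthrough genes the TES reference
window runs from TES+1500 to the end of the called DoG; for others, to
TES+10 kb. Alternate presets (e.g. 0–3 kb vs 3–8 kb past the TES) are
constructed by overriding the TES offsets on `PauseWindows`.

Expression grouping splits at the bottom and top quartiles
(linear-interpolation quantiles): low ≤ Q1, high ≥ Q3, medium between.
When every value ties at both bounds the tie rule assigns medium. This
three-group reading (rather than literal quartile bins) matches how
such groupings are labeled in practice and is invariant to monotone
transformations.

Metagene profiles use per-base fixed-width flanks around a gene body
rescaled to a fixed number of bins (mean per bin); minus-strand genes
are reversed so profiles read 5′→3′, and genes shorter than one bin
are skipped.

## Cohort statistics

The hypergeometric overlap test is the upper tail P(X ≥ k), computed
via scipy's survival function (log-space internally) and verified
against direct combinatorial summation on the full grid of N ≤ 12.
Rank-sum tests use exact enumeration when the combined sample size is
≤ 12 without cross-sample ties, otherwise the normal approximation with
continuity and tie correction. Median splits send values equal to the
median to "low" (deterministic and documented; not inferable from
common usage), rebalancing only when a side would otherwise be empty;
all-identical values are an error. Survival uses lifelines'
product-limit estimator and two-group log-rank test; median survival is
the smallest time with S(t) ≤ 0.5, NA when never reached. The
over-representation helper runs one hypergeometric test per annotated
set against a user-supplied universe with BH across sets — no gene-set
database is shipped.

## Synthetic data: what it does and does not emulate

The generator states one world and the tests measure the package
against it. Defaults: ~10% of genes produce readthrough, planted
lengths are log-normal with median 9 kb clipped to 5–20 kb, and window
covered-base fractions are drawn around 0.85 (sd 0.08) — emulating a
landscape where one to a few thousand of ~20,000 protein-coding genes
produce DoGs with median extension 8–10 kb. Counts are NB with
dispersion 0.1, planted 4-fold effects on 10% of features, and size
factors uniform in [0.5, 2]; pausing profiles plant a ratio-4 pause
over [TSS−50, TSS+300); survival is exponential with hazard ratio 2
and 20% censoring, the stratifying feature drawn from normals 4 sd
apart.

Genes are packed left-to-right with reserved downstream space so a
planted region plus the 5 kb adjacency buffer can never touch the next
gene — except when the adjacent-gene trap deliberately places a small
same-strand gene 3 kb past a host's TES to exercise the filter. The
truth table records each planted region's per-window realized coverage
and its callability under the default parameters, computed directly
from those fractions rather than by scanning the coverage array, so
caller recall/precision can be scored without circularity.

Not emulated: read-level artifacts (mapping ambiguity, paired-end
fragments, GC bias), splice structure, antisense transcription,
sequence content, and correlated expression between neighbouring
genes. A green test therefore establishes that the algorithms implement
their definitions and recover planted structure — not that they are
robust to alignment artifacts in real libraries.

## Numerical notes

- TPM computes `1e6 * (rate / total)` so a single-feature sample is
  exactly 1e6.
- Window pass comparisons use `>=` on exact fractions of integer base
  counts, so generator-side and caller-side threshold arithmetic agree
  bit-for-bit.
- Seeds: every stochastic routine takes or derives from an explicit
  seed; the simulator uses `default_rng([seed, tag])` substreams so the
  coverage, count, pausing and survival draws are independent but
  jointly reproducible.

## Known limitations

- The caller forbids gaps inside a run; tools that tolerate isolated
  failing windows will call longer regions on sparse data.
- The NB engine's dispersion is per-feature method-of-moments with no
  information sharing; at very low counts its power is below that of
  shrinkage-based engines, and exact equivalence with them is a
  non-goal.
- Downsampling thins coverage units, not reads.
- The analysis drivers compare two *independently simulated* genomes
  as "conditions"; shared-host overlap between them is therefore at
  chance level, which the overlap test correctly reports.
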