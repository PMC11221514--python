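# dogscape

Readthrough-transcription analysis from coverage tracks: call
downstream-of-gene (DoG) RNAs, quantify and differentially test them,
relate them to their host genes, measure RNA polymerase II pausing, and
tie readthrough burden to patient survival.

## The problem

When RNA polymerase II fails to terminate at a gene's 3′ end it
continues into downstream intergenic space, producing a noncoding RNA
continuous with the mRNA — a DoG RNA. Termination failure is a feature
of cellular stress and of tumors, and the genes affected, the length of
the readthrough, and its coupling to host-gene transcription and to
polymerase pausing are all informative phenotypes. This package
implements that analysis chain for anyone with a gene annotation (GTF)
and per-base coverage (bedGraph), at desk scale, with a synthetic-data
generator providing ground truth for every step.

## The core methods

**DoG calling.** Downstream of each gene's transcription end site
(TES), walk consecutive windows of *w* = 200 bp in the direction of
transcription. A window passes when ≥ 60% of its bases have non-zero
signal (`min_dog_cov = 0.6`); the run of passing windows must begin at
the TES and ends at the first failing window. A DoG is called when the
run spans ≥ 5 kb (`min_dog_len = 5000`); its length is the *extension
strength*. Calls with another gene annotated within 5 kb downstream of
the TES are filtered out (same-strand only, in stranded mode).

**Differential expression.** A minimal negative-binomial engine:
median-of-ratios size factors, method-of-moments dispersion
(Var = μ + αμ²), a Wald statistic on log₂FC with a delta-method
standard error, BH correction. Calls use |log₂FC| > 0.58 at *q* < 0.05.
Each differentially expressed DoG is classified against its host gene
(silenced / not changed / activated, same thresholds).

**Pausing.** PI_TSS = (counts in [TSS−50, TSS+300) / 350) /
(counts in [TSS+300, gene end) / body length); PI_TES uses
[TES+500, TES+1500) against [TES+1500, end of DoG] (or TES+10 kb for
non-DoG genes). PI > 2 flags a paused gene.

**Cohort statistics.** Upper-tail hypergeometric overlap tests between
condition-specific DoG host sets, Wilcoxon rank-sum comparisons (exact
for small samples), median-split stratification, and Kaplan–Meier /
log-rank survival analysis.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_call_readthrough.py
```

which prints (seeded, so exactly reproducible):

```
control: 150 genes, 19 planted readthrough regions (17 callable)
defect:  150 genes, 40 planted readthrough regions (40 callable)
...
ctrl: 17 readthrough regions, median extension 8.0 kb, recall 1.00, precision 1.00
defect: 40 readthrough regions, median extension 11.1 kb, recall 1.00, precision 1.00
extension strengths ctrl < defect: one-sided rank-sum p = 0.0405
```

The control condition plants readthrough at ~10% of genes with median
length ~9 kb; the termination-defect condition raises prevalence and
length. The caller recovers every region the truth table marks callable
(≥ 60% window coverage sustained for ≥ 5 kb) and nothing else, and the
defect condition's longer extensions are detected by the one-sided
rank-sum test. Scripts 03–05 continue the chain: NB differential
expression with host-concordance classification, pause-index profiles
(a planted pause ratio of 4 is recovered as mean PI ≈ 3.9), and a
median-split survival comparison where a true hazard ratio of 2 is
recovered as a median-survival ratio of 2.24 with log-rank
p ≈ 1e-7.

The same operations are available as a CLI for ad-hoc use:

```bash
dogscape simulate --preset caller --seed 7 --outdir sim/
dogscape call-dogs --annotation sim/genes.gtf --coverage sim/coverage.bedGraph \
    --chrom-sizes sim/chrom.sizes --out dogs.bed
dogscape overlap --set-a a.txt --set-b b.txt --universe genes.txt
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantity
from scratch — the upper-tail hypergeometric p-value for an overlap of
38 host genes between condition-specific readthrough sets of sizes 532
and 555 within a universe of 20,046 protein-coding genes — and writes
it as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
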