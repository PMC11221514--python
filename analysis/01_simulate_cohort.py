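"""Simulate a two-condition readthrough cohort.

Builds a synthetic genome with a control condition and a
termination-defect condition (higher readthrough prevalence and longer
planted regions), plus a paired host/readthrough count matrix and a
survival cohort.  Everything downstream (02-05) reads from
results/sim/.
"""

import pathlib

import pandas as pd

from dogscape import (
    SimulationConfig,
    simulate_annotation_and_coverage,
    simulate_counts,
    simulate_pause_profiles,
    simulate_survival,
    write_coverage,
    write_gene_annotation,
)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "sim"
OUT.mkdir(parents=True, exist_ok=True)

SEED = 2024

# control: baseline readthrough landscape (~10% of genes, median ~9 kb)
ctrl_cfg = SimulationConfig(seed=SEED, n_genes=150)
# defect: termination failure raises prevalence and planted lengths
defect_cfg = SimulationConfig(
    seed=SEED + 1, n_genes=150, dog_prevalence=0.25,
    dog_length_log_mean=__import__("math").log(11000.0),
)

genes, track, truth = simulate_annotation_and_coverage(ctrl_cfg)
write_gene_annotation(genes, OUT / "genes_ctrl.gtf")
write_coverage(track, OUT / "coverage_ctrl.bedGraph")
truth.to_csv(OUT / "truth_ctrl.tsv", sep="\t", index=False)
with open(OUT / "chrom_ctrl.sizes", "w") as fh:
    for c, n in track.chrom_sizes.items():
        fh.write(f"{c}\t{n}\n")

genes_d, track_d, truth_d = simulate_annotation_and_coverage(defect_cfg)
write_gene_annotation(genes_d, OUT / "genes_defect.gtf")
write_coverage(track_d, OUT / "coverage_defect.bedGraph")
truth_d.to_csv(OUT / "truth_defect.tsv", sep="\t", index=False)
with open(OUT / "chrom_defect.sizes", "w") as fh:
    for c, n in track_d.chrom_sizes.items():
        fh.write(f"{c}\t{n}\n")

design = pd.Series({f"ctrl{i}": "A" for i in range(1, 6)}
                   | {f"case{i}": "B" for i in range(1, 6)}, name="group")
counts, de_truth, sf = simulate_counts(
    SimulationConfig(seed=SEED + 2, n_features=2000, affected_fraction=0.1),
    design, paired=True,
)
counts.to_csv(OUT / "counts.tsv", sep="\t")
de_truth.to_csv(OUT / "de_truth.tsv", sep="\t")
design.to_frame().to_csv(OUT / "design.tsv", sep="\t")

pg, ptrack = simulate_pause_profiles(SimulationConfig(seed=SEED + 3, pause_ratio=4.0),
                                     n_genes=100)
write_gene_annotation(pg, OUT / "genes_pause.gtf")
write_coverage(ptrack, OUT / "coverage_pause.bedGraph")
with open(OUT / "chrom_pause.sizes", "w") as fh:
    for c, n in ptrack.chrom_sizes.items():
        fh.write(f"{c}\t{n}\n")

cohort, hr = simulate_survival(SimulationConfig(seed=SEED + 4, hazard_ratio=2.0))
cohort.to_csv(OUT / "survival.tsv", sep="\t")

print(f"control: {len(genes)} genes, {len(truth)} planted readthrough regions "
      f"({truth['expected_callable'].sum()} callable)")
print(f"defect:  {len(genes_d)} genes, {len(truth_d)} planted readthrough regions "
      f"({truth_d['expected_callable'].sum()} callable)")
print(f"counts:  {counts.shape[0]} features x {counts.shape[1]} samples "
      f"({(de_truth['true_log2fc'] != 0).sum()} with planted effects)")
print(f"survival: {len(cohort)} subjects, true hazard ratio {hr}")
print(f"wrote inputs to {OUT}")
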