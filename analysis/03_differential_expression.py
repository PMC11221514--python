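"""Differential expression of readthrough regions and host concordance.

Runs the minimal NB engine on the paired host/readthrough count matrix
(|log2FC| > 0.58, q < 0.05), scores calls against the planted truth,
and classifies each differentially expressed readthrough RNA by its
host gene's class (silenced / not changed / activated).
"""

import pathlib

import pandas as pd

from dogscape import classify_concordance, nb_test

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
SIM = BASE / "sim"

counts = pd.read_csv(SIM / "counts.tsv", sep="\t", index_col=0)
design = pd.read_csv(SIM / "design.tsv", sep="\t", index_col=0)["group"]
truth = pd.read_csv(SIM / "de_truth.tsv", sep="\t", index_col=0)

res = nb_test(counts, design)
res.to_csv(BASE / "de_results.tsv", sep="\t")

n_up, n_down = (res["call"] == "up").sum(), (res["call"] == "down").sum()
print(f"{n_up} up- and {n_down} down-regulated features at |log2FC|>0.58, q<0.05")

planted = truth[truth["true_log2fc"] != 0]
tp = (res.loc[planted.index, "q_value"] < 0.05).mean()
null = truth[truth["true_log2fc"] == 0]
fp = (res.loc[null.index, "q_value"] < 0.05).mean()
print(f"planted-effect detection {tp:.1%}; false call rate on null features {fp:.2%}")

dogs = res.loc[[i for i in res.index if i.startswith("do")]]
hosts = res.loc[[i for i in res.index if not i.startswith("do")]]
pairs, table = classify_concordance(dogs, hosts, host_of=lambda f: f[2:])
table.to_csv(BASE / "concordance_table.tsv", sep="\t")
print("host concordance of differentially expressed readthrough RNAs:")
print(table.round(1).to_string())
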