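"""Individual-marker baseline and proteomic rate of return.

Ranks individually differentially expressed genes (fold-change filter +
pooled-sd t ranking), intersects gene sets with a proteome, and fits the
"rate of return" — the slope of differentially-expressed-protein count
against candidate-set size.
"""

import numpy as np
import pandas as pd

import cranesig as cs

rng = np.random.default_rng(9)
n_genes, n_per = 300, 20
genes = [f"G{i:04d}" for i in range(n_genes)]
samples = [f"s{i}" for i in range(2 * n_per)]
vals = np.exp(rng.normal(5, 0.3, size=(n_genes, 2 * n_per)))
vals[:30, n_per:] *= rng.uniform(2.2, 4.0, size=(30, 1))  # 30 genes up in LTS
expr = cs.ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
labels = cs.PhenotypeLabels(
    pd.Series(["STS"] * n_per + ["LTS"] * n_per, index=samples), 225, 635
)

ranking = cs.rank_individual_gene_markers(expr, labels, fc_threshold=2, top_n=100)
print(f"{len(ranking)} genes pass the two-fold filter; top 5 by |t|:")
print(ranking.head(5)[["gene", "fold_change", "t"]].round(2).to_string(index=False))

# a proteome that detected a third of all genes; DE calls concentrated in
# the truly changed genes
proteome = set(rng.choice(genes, 100, replace=False)) | set(genes[:15])
de_set = set(genes[:12]) & proteome
sizes = range(5, len(ranking) + 1, 5)
yc = cs.proteomic_yield_analysis(list(ranking["gene"]), proteome, de_set, sizes=sizes)
print("\nyield of ranking prefixes:")
print(yc.table.to_string(index=False))
print(f"rate of return: {yc.rate_percent:.1f}% DE proteins per candidate gene")

count, shared = cs.signature_overlap(ranking["gene"].head(50), genes[:30])
print(f"\noverlap of top-50 markers with the 30 truly changed genes: {count}")
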