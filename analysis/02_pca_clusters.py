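#!/usr/bin/env python
"""PCA of the five performance parameters with k-means clustering.

Finding: three components carry 51%, 22% and 20% of the variance (93%
cumulative).  k-means (k=3) on the component scores isolates the
D = 0.1 1/h fermentations in their own cluster, so dilution rate — not
the plasmid-maintenance strategy — dominates steady-state performance.
"""

from pathlib import Path

import pandas as pd

from fermstab import (PERFORMANCE_PARAMETERS, cluster_condition_crosstab,
                      kmeans, load_paper_dataset, pca, performance_matrix)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

records = load_paper_dataset()
res = pca(performance_matrix(records), 3, PERFORMANCE_PARAMETERS)
for i, v in enumerate(res.variance_fractions, 1):
    print(f"PC{i}: {100 * v:.1f}% of variance")
print(f"cumulative: {100 * res.cumulative_variance:.1f}%")

pd.DataFrame(res.loadings, columns=PERFORMANCE_PARAMETERS,
             index=["PC1", "PC2", "PC3"]).to_csv(OUT / "pca_loadings.csv")

model = kmeans(res.scores, k=3, seed=0)
scores = pd.DataFrame(res.scores, columns=["PC1", "PC2", "PC3"])
scores.insert(0, "ferm_id", [r.ferm_id for r in records])
scores["cluster"] = model.assignments
scores.to_csv(OUT / "pca_scores_clusters.csv", index=False)

tab = cluster_condition_crosstab(model, records)
tab.to_csv(OUT / "cluster_condition_crosstab.csv")
print("\ncluster x condition counts:")
print(tab)
print(f"\nwrote PCA outputs to {OUT}")
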