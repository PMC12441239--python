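#!/usr/bin/env python
"""Classify the plots into three structural types and compare them.

Log-transforms the eight indices, drops near-collinear columns
(|r| >= 0.9, the Gini coefficient outranking CV), runs correlation-matrix
PCA, cuts the Ward tree at k = 3 on the leading PCs, and compares every
index and carbon pool across the resulting types (ANOVA + Tukey-Kramer,
compact letters).  Writes results/study/classification/.
"""

import argparse
from pathlib import Path

import pandas as pd

from standcarbon.stand_typing import (
    cluster_stands,
    compare_groups,
    log_transform,
    pca,
    redundancy_filter,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--k", type=int, default=3)
args = parser.parse_args()

profiles = pd.read_csv(args.study / "structural_profiles.csv").set_index("plot_id")
pools = pd.read_csv(args.study / "carbon_pools.csv").set_index("plot_id")
features = profiles[["W", "U", "M", "C", "CV", "SK", "GC", "H"]]

logged, shifts = log_transform(features)
filtered, dropped = redundancy_filter(logged)
for col, kept, r in dropped:
    print(f"redundancy: dropped {col} (r = {r:+.2f} with {kept})")
res = pca(filtered)
print("PC variance shares:", [f"{v:.2f}" for v in res.explained_ratio[:4]])
labels = cluster_stands(res.scores, k=args.k, explained_ratio=res.explained_ratio)

out = args.study / "classification"
out.mkdir(parents=True, exist_ok=True)
labels.rename_axis("plot_id").to_frame().to_csv(out / "stand_types.csv", lineterminator="\n")
res.loadings.rename_axis("variable").to_csv(out / "loadings.csv", lineterminator="\n")

rows = []
for var in list(features.columns) + list(pools.columns):
    values = features[var] if var in features.columns else pools[var]
    cmp = compare_groups(values.loc[labels.index], labels)
    rows.append(
        {
            "variable": var,
            "F": cmp.f_statistic,
            "p": cmp.p_value,
            "letters": ";".join(f"{g}:{l}" for g, l in sorted(cmp.letters.items())),
        }
    )
anova = pd.DataFrame(rows)
anova.to_csv(out / "anova_tukey.csv", index=False, lineterminator="\n")

print("\ntype sizes:", labels.value_counts().sort_index().to_dict())
print(anova.round(4).to_string(index=False))
print(f"\nwrote {out}")
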