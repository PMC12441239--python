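#!/usr/bin/env python
"""Associate structural diversity with the carbon pools.

Permutation Mantel tests between plot distances in structure space
(spatial and non-spatial index sets, z-scored Euclidean) and distances in
each carbon pool, plus the pairwise Pearson correlation matrix of the
eight indices.  Writes results/study/association/.
"""

import argparse
from pathlib import Path

import pandas as pd

from standcarbon.association import correlation_matrix, mantel_table
from standcarbon.stand_typing import log_transform

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-perm", type=int, default=999)
args = parser.parse_args()

profiles = pd.read_csv(args.study / "structural_profiles.csv").set_index("plot_id")
pools = pd.read_csv(args.study / "carbon_pools.csv").set_index("plot_id")
features = profiles[["W", "U", "M", "C", "CV", "SK", "GC", "H"]]
logged, _ = log_transform(features)

mantel = mantel_table(
    {"spatial": logged[["W", "U", "M", "C"]], "nonspatial": logged[["CV", "SK", "GC", "H"]]},
    pools,
    n_perm=args.n_perm,
    seed=args.seed,
)
out = args.study / "association"
out.mkdir(parents=True, exist_ok=True)
mantel.to_csv(out / "mantel.csv", index=False, lineterminator="\n")
r, p = correlation_matrix(features)
r.rename_axis("variable").to_csv(out / "correlation_r.csv", lineterminator="\n")
p.rename_axis("variable").to_csv(out / "correlation_p.csv", lineterminator="\n")

print(mantel.round(3).to_string(index=False))
sig = mantel[mantel["p"] < 0.05]
print(f"\n{len(sig)} of {len(mantel)} Mantel tests significant at p < 0.05")
print(f"r(CV, GC) = {r.loc['CV', 'GC']:.2f}")
print(f"wrote {out}")
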