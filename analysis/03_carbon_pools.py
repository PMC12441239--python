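#!/usr/bin/env python
"""Account the five carbon pools per plot (Mg C ha^-1).

Tree carbon from DBH allometry and species carbon fractions, shrub/herb/
litter from subplot harvests, soil from the layered stock equation.
Writes results/study/carbon_pools.csv.
"""

import argparse
from pathlib import Path

from standcarbon.carbon_accounting import (
    plot_carbon_pools,
    pools_table,
    read_harvest_table,
    read_soil_table,
)
from standcarbon.stand_io import read_allometry, read_carbon_fractions, read_stem_map

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--study", type=Path, default=Path("results/study"))
args = parser.parse_args()

inputs = args.study / "inputs"
allometry = read_allometry(inputs / "allometry.csv")
fractions = read_carbon_fractions(inputs / "carbon_fractions.csv")
harvests = read_harvest_table(inputs / "harvest.csv")
soils = read_soil_table(inputs / "soil.csv")

pools = []
for path in sorted(inputs.glob("stem_map_*.csv")):
    plot_id = path.stem.replace("stem_map_", "")
    sm = read_stem_map(path, plot_id=plot_id)
    recs = [h for h in harvests if h.plot_id == plot_id]
    pools.append(plot_carbon_pools(sm, recs, soils[plot_id], allometry, fractions))

table = pools_table(pools).set_index("plot_id")
table.to_csv(args.study / "carbon_pools.csv", lineterminator="\n")
print(table.round(2).to_string())
print(f"\ntotal carbon across plots: {table['total'].mean():.1f} ± {table['total'].std():.1f} Mg C ha^-1")
print(f"wrote {args.study / 'carbon_pools.csv'}")
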