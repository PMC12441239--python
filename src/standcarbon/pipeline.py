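"""End-to-end orchestration: simulate (or read) → structure → carbon →
classify → associate, with a run manifest for reproducibility.

Stages communicate only through CSV files under the output directory, so
deleting intermediates and rerunning from the same config and seed
reproduces every byte.  Any stage failure aborts naming the stage and the
offending plot.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

import standcarbon
from standcarbon.association import correlation_matrix, mantel_table
from standcarbon.carbon_accounting import (
    plot_carbon_pools,
    pools_table,
    read_harvest_table,
    read_soil_table,
)
from standcarbon.errors import StandCarbonError
from standcarbon.nonspatial_structure import diameter_profile
from standcarbon.spatial_structure import CrownModel, EdgePolicy, spatial_indices
from standcarbon.stand_io import read_allometry, read_carbon_fractions, read_stem_map
from standcarbon.stand_typing import (
    cluster_stands,
    compare_groups,
    log_transform,
    pca,
    redundancy_filter,
)
from standcarbon.synthetic_stands import generate_study

SPATIAL_COLS = ["W", "U", "M", "C"]
NONSPATIAL_COLS = ["CV", "SK", "GC", "H"]
INDEX_COLS = SPATIAL_COLS + NONSPATIAL_COLS


@dataclass(frozen=True)
class PipelineConfig:
    """One pipeline run: either synthetic generation or existing input files.

    In synthetic mode (``input_dir`` unset) a full study bundle is
    generated and written first.  ``edge`` defaults to toroidal wrapping,
    appropriate for stationary synthetic stands; field data should use a
    buffer (e.g. ``buffer:5``).
    """

    out_dir: str = "results/run"
    seed: int = 0
    input_dir: str | None = None
    n_plots: int = 13
    type_sizes: tuple[int, ...] = (4, 5, 4)
    k_neighbors: int = 4
    alpha0: float = 72.0
    edge: str = "torus"
    crown_c0: float = 0.5
    crown_c1: float = 0.05
    min_dbh: float = 5.0
    n_types: int = 3
    redundancy_threshold: float = 0.9
    retain_variance: float = 0.9
    n_perm: int = 999

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RunManifest:
    """Record of one pipeline run: config, seed, and digests of every output."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, plot_id: str | None = None):
    where = f"stage {name!r}" + (f", plot {plot_id!r}" if plot_id else "")
    return where


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis and return the manifest of outputs.

    Outputs under ``config.out_dir``:

    * ``inputs/`` — the study input bundle (synthetic mode only),
    * ``structural_profiles.csv`` — the 8 diversity indices per plot,
    * ``carbon_pools.csv`` — the five pools and total per plot,
    * ``classification/`` — labels, loadings, variance, ANOVA/Tukey,
    * ``association/`` — Mantel table and Pearson correlation matrices,
    * ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate (or locate inputs) -------------------------------
    if config.input_dir is None:
        bundle = generate_study(
            n_plots=config.n_plots, type_sizes=config.type_sizes, seed=config.seed
        )
        input_dir = out / "inputs"
        bundle.write(input_dir)
    else:
        input_dir = Path(config.input_dir)

    stem_paths = sorted(input_dir.glob("stem_map_*.csv"))
    if not stem_paths:
        raise StandCarbonError(f"{_stage('simulate')}: no stem_map_*.csv under {input_dir}")
    allometry = read_allometry(input_dir / "allometry.csv")
    fractions = read_carbon_fractions(input_dir / "carbon_fractions.csv")
    harvests = read_harvest_table(input_dir / "harvest.csv")
    soils = read_soil_table(input_dir / "soil.csv")

    edge_policy = EdgePolicy.parse(config.edge)
    crown = CrownModel(config.crown_c0, config.crown_c1)

    # --- stage: structure -------------------------------------------------
    rows = []
    stem_maps = {}
    for path in stem_paths:
        plot_id = path.stem.replace("stem_map_", "")
        try:
            sm = read_stem_map(path, plot_id=plot_id, min_dbh=config.min_dbh)
            stem_maps[plot_id] = sm
            _, means = spatial_indices(
                sm,
                k=config.k_neighbors,
                alpha0=config.alpha0,
                crown_model=crown,
                edge_policy=edge_policy,
            )
            profile = diameter_profile([t.dbh for t in sm.trees])
        except Exception as exc:
            raise StandCarbonError(f"{_stage('structure', plot_id)}: {exc}") from exc
        rows.append(
            {
                "plot_id": plot_id,
                **means,
                "CV": profile["CV"],
                "SK": profile["SK"],
                "GC": profile["GC"],
                "H": profile["H"],
                "n_trees": profile["n_trees"],
                "density_ha": sm.density_per_ha,
            }
        )
    profiles = pd.DataFrame(rows).set_index("plot_id").sort_index()
    profiles.to_csv(out / "structural_profiles.csv", lineterminator="\n")

    # --- stage: carbon ----------------------------------------------------
    pools = []
    for plot_id, sm in sorted(stem_maps.items()):
        try:
            recs = [h for h in harvests if h.plot_id == plot_id]
            pools.append(plot_carbon_pools(sm, recs, soils[plot_id], allometry, fractions))
        except Exception as exc:
            raise StandCarbonError(f"{_stage('carbon', plot_id)}: {exc}") from exc
    pool_df = pools_table(pools).set_index("plot_id").sort_index()
    pool_df.to_csv(out / "carbon_pools.csv", lineterminator="\n")

    # --- stage: classify --------------------------------------------------
    cls_dir = out / "classification"
    cls_dir.mkdir(exist_ok=True)
    features = profiles[INDEX_COLS]
    logged, shifts = log_transform(features)
    filtered, dropped = redundancy_filter(logged, threshold=config.redundancy_threshold)
    pca_res = pca(filtered)
    labels = cluster_stands(
        pca_res.scores,
        k=config.n_types,
        explained_ratio=pca_res.explained_ratio,
        retain_variance=config.retain_variance,
    )
    labels.rename_axis("plot_id").to_frame().to_csv(cls_dir / "stand_types.csv", lineterminator="\n")
    pca_res.loadings.rename_axis("variable").to_csv(cls_dir / "loadings.csv", lineterminator="\n")
    pd.DataFrame(
        {
            "pc": [f"PC{i + 1}" for i in range(len(pca_res.explained_ratio))],
            "explained_ratio": pca_res.explained_ratio,
        }
    ).to_csv(cls_dir / "explained_variance.csv", index=False, lineterminator="\n")
    if dropped:
        pd.DataFrame(dropped, columns=["dropped", "kept", "r"]).to_csv(
            cls_dir / "redundancy_dropped.csv", index=False, lineterminator="\n"
        )

    anova_rows = []
    for var in list(features.columns) + list(pool_df.columns):
        values = features[var] if var in features.columns else pool_df[var]
        cmp = compare_groups(values.loc[labels.index], labels)
        anova_rows.append(
            {
                "variable": var,
                "F": cmp.f_statistic,
                "p": cmp.p_value,
                "df_between": cmp.df_between,
                "df_within": cmp.df_within,
                "letters": ";".join(f"{g}:{l}" for g, l in sorted(cmp.letters.items())),
                "degenerate": cmp.degenerate,
            }
        )
    pd.DataFrame(anova_rows).to_csv(cls_dir / "anova_tukey.csv", index=False, lineterminator="\n")

    # --- stage: associate -------------------------------------------------
    assoc_dir = out / "association"
    assoc_dir.mkdir(exist_ok=True)
    structure_sets = {
        "spatial": logged[[c for c in SPATIAL_COLS if c in logged.columns]],
        "nonspatial": logged[[c for c in NONSPATIAL_COLS if c in logged.columns]],
    }
    mantel = mantel_table(
        structure_sets, pool_df, n_perm=config.n_perm, seed=config.seed
    )
    mantel.to_csv(assoc_dir / "mantel.csv", index=False, lineterminator="\n")
    r_mat, p_mat = correlation_matrix(features)
    r_mat.rename_axis("variable").to_csv(assoc_dir / "correlation_r.csv", lineterminator="\n")
    p_mat.rename_axis("variable").to_csv(assoc_dir / "correlation_p.csv", lineterminator="\n")

    # --- manifest ---------------------------------------------------------
    outputs = {
        str(p.relative_to(out)): _digest(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        version=standcarbon.__version__,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
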