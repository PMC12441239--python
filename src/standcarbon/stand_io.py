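"""Reading and writing stem maps, allometry/carbon-fraction configs and result tables.

All tabular files are comma-separated with a required header row and a
decimal point; coordinates are plot-local metres with the origin at the
plot's southwest corner and inclusive boundaries.  Species absent from an
allometry or carbon-fraction table resolve to the table's fallback entry
with a logged warning, never an error: a subtropical secondary stand can
carry dozens of woody species while published biomass models cover only
the dominant ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from standcarbon.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Minimum diameter at breast height (cm) for a stem to enter the analysis.
#: Stems below this are tallied but excluded, matching the standard field
#: eligibility threshold for structural and basal-area work.
DEFAULT_MIN_DBH = 5.0

#: Species token that marks the fallback row of a config table.
FALLBACK_SPECIES = "DEFAULT"

STEM_MAP_COLUMNS = ["id", "x", "y", "species", "dbh_cm"]


@dataclass(frozen=True)
class Tree:
    """A mapped stem: position, species label and diameter at breast height.

    Parameters
    ----------
    tree_id : str
        Token unique within its plot.
    x, y : float
        Plot-local coordinates in metres.
    species : str
        Species code.
    dbh : float
        Diameter at breast height, cm; must be positive.
    """

    tree_id: str
    x: float
    y: float
    species: str
    dbh: float

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise ValidationError(f"tree {self.tree_id!r}: dbh must be > 0, got {self.dbh}")
        if not self.species:
            raise ValidationError(f"tree {self.tree_id!r}: missing species label")


@dataclass(frozen=True)
class StemMap:
    """A plot's tree collection plus its rectangular extent.

    The extent is (width, height) in metres; trees must lie inside or on
    the boundary.  Tree ids must be unique.
    """

    plot_id: str
    trees: tuple[Tree, ...]
    extent: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        w, h = self.extent
        if not (w > 0 and h > 0):
            raise ValidationError(f"plot {self.plot_id!r}: extent must be positive, got {self.extent}")
        outside = [t.tree_id for t in self.trees if not (0 <= t.x <= w and 0 <= t.y <= h)]
        if outside:
            raise ValidationError(
                f"plot {self.plot_id!r}: trees outside the {w} m x {h} m extent: {outside}"
            )
        ids = [t.tree_id for t in self.trees]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"plot {self.plot_id!r}: duplicate tree ids: {dupes}")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def area_m2(self) -> float:
        return self.extent[0] * self.extent[1]

    @property
    def density_per_ha(self) -> float:
        """Stem density scaled to trees per hectare."""
        return len(self.trees) * 10_000.0 / self.area_m2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [t.tree_id for t in self.trees],
                "x": [t.x for t in self.trees],
                "y": [t.y for t in self.trees],
                "species": [t.species for t in self.trees],
                "dbh_cm": [t.dbh for t in self.trees],
            }
        )


@dataclass(frozen=True)
class AllometryEntry:
    """Power-law biomass model ``biomass_kg = a * DBH_cm ** b`` for one species.

    ``components`` optionally splits the model into stem/branch/leaf/root
    terms, each its own (a, b) pair; the species total is their sum.
    """

    species: str
    a: float
    b: float
    components: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        pairs = [(self.a, self.b)]
        if self.components:
            pairs += list(self.components.values())
        for a, b in pairs:
            if not (a > 0 and b > 0):
                raise ValidationError(
                    f"allometry {self.species!r}: coefficients must be positive, got a={a}, b={b}"
                )


@dataclass(frozen=True)
class AllometryTable:
    """Species-indexed allometric models with a mandatory fallback entry."""

    entries: Mapping[str, AllometryEntry]
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if FALLBACK_SPECIES not in self.entries:
            raise ValidationError(f"allometry table lacks the fallback entry {FALLBACK_SPECIES!r}")

    def resolve(self, species: str) -> AllometryEntry:
        """Return the entry for ``species``, or the fallback with a warning."""
        try:
            return self.entries[species]
        except KeyError:
            if species not in self._warned:
                self._warned.add(species)
                logger.warning("species %r not in allometry table; using fallback", species)
            return self.entries[FALLBACK_SPECIES]

    def __contains__(self, species: str) -> bool:
        return species in self.entries


@dataclass(frozen=True)
class CarbonFractionTable:
    """Carbon mass fraction of dry biomass per species or pool label.

    Fractions are dimensionless in (0, 1); unlisted labels resolve to the
    fallback (default 0.5, the usual rounded carbon content of dry wood).
    """

    fractions: Mapping[str, float]
    fallback: float = 0.5
    _warned: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.fractions.items() if not 0 < v < 1}
        if bad:
            raise ValidationError(f"carbon fractions must lie in (0, 1): {bad}")
        if not 0 < self.fallback < 1:
            raise ValidationError(f"fallback carbon fraction must lie in (0, 1): {self.fallback}")

    def resolve(self, label: str) -> float:
        if label in self.fractions:
            return self.fractions[label]
        if label not in self._warned:
            self._warned.add(label)
            logger.warning("label %r not in carbon-fraction table; using fallback %.3f", label, self.fallback)
        return self.fallback


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path | str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_stem_map(
    path: str | Path,
    plot_id: str,
    extent: tuple[float, float] = (20.0, 20.0),
    min_dbh: float = DEFAULT_MIN_DBH,
) -> StemMap:
    """Read a stem map CSV (columns ``id,x,y,species,dbh_cm``) into a StemMap.

    Stems with DBH below ``min_dbh`` are excluded and counted in the log;
    trees outside the extent or duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "species": str}, float_precision="round_trip")
    _require_columns(df, STEM_MAP_COLUMNS, path)
    for col in ("x", "y", "dbh_cm"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    keep = df["dbh_cm"] >= min_dbh
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "plot %s: excluded %d stem(s) with DBH < %.1f cm (retained %d of %d)",
            plot_id, n_excluded, min_dbh, int(keep.sum()), len(df),
        )
    trees = tuple(
        Tree(tree_id=str(r.id), x=float(r.x), y=float(r.y), species=str(r.species), dbh=float(r.dbh_cm))
        for r in df[keep].itertuples()
    )
    return StemMap(plot_id=plot_id, trees=trees, extent=extent)


def write_stem_map(stem_map: StemMap, path: str | Path) -> None:
    """Write a StemMap to CSV in the canonical column order.

    Floats use 17 significant digits so a write/read cycle is lossless.
    """
    stem_map.to_frame().to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_allometry(path: str | Path) -> AllometryTable:
    """Read an allometry config CSV with columns ``species,component,a,b``.

    ``component`` may be empty / ``total`` for a single-model species, or
    name a biomass component (stem/branch/leaf/root) to build a split
    entry.  A row with species ``DEFAULT`` is the mandatory fallback.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"species": str, "component": str}, float_precision="round_trip")
    _require_columns(df, ["species", "a", "b"], path)
    if "component" not in df.columns:
        df["component"] = "total"
    df["component"] = df["component"].fillna("total").replace("", "total")

    entries: dict[str, AllometryEntry] = {}
    for species, group in df.groupby("species", sort=False):
        comps = dict(zip(group["component"], zip(group["a"].astype(float), group["b"].astype(float))))
        if len(comps) != len(group):
            raise ValidationError(f"{path}: duplicate rows for species {species!r}")
        if "total" in comps:
            if len(comps) > 1:
                raise ValidationError(
                    f"{path}: species {species!r} mixes a 'total' row with component rows"
                )
            a, b = comps["total"]
            entries[species] = AllometryEntry(species=species, a=a, b=b)
        else:
            # representative (a, b) only; totals always come from the
            # component sum.
            a, b = next(iter(comps.values()))
            entries[species] = AllometryEntry(species=species, a=a, b=b, components=comps)
    return AllometryTable(entries=entries)


def write_allometry(table: AllometryTable, path: str | Path) -> None:
    """Write an AllometryTable to CSV; inverse of :func:`read_allometry`."""
    rows = []
    for species, entry in table.entries.items():
        if entry.components:
            for comp, (a, b) in entry.components.items():
                rows.append({"species": species, "component": comp, "a": a, "b": b})
        else:
            rows.append({"species": species, "component": "total", "a": entry.a, "b": entry.b})
    pd.DataFrame(rows, columns=["species", "component", "a", "b"]).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_carbon_fractions(path: str | Path) -> CarbonFractionTable:
    """Read a carbon-fraction config CSV with columns ``label,fraction``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"label": str}, float_precision="round_trip")
    _require_columns(df, ["label", "fraction"], path)
    if df["label"].duplicated().any():
        dupes = sorted(df.loc[df["label"].duplicated(), "label"].unique())
        raise ValidationError(f"{path}: duplicate label(s) {dupes}")
    fractions = dict(zip(df["label"], df["fraction"].astype(float)))
    fallback = fractions.pop(FALLBACK_SPECIES, 0.5)
    return CarbonFractionTable(fractions=fractions, fallback=fallback)


def write_carbon_fractions(table: CarbonFractionTable, path: str | Path) -> None:
    rows = [{"label": k, "fraction": v} for k, v in table.fractions.items()]
    rows.append({"label": FALLBACK_SPECIES, "fraction": table.fallback})
    pd.DataFrame(rows, columns=["label", "fraction"]).to_csv(path, index=False, lineterminator="\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write named result tables as CSV files under ``out_dir``.

    Column order is preserved as given; output bytes are deterministic for
    a fixed input.  Returns the mapping from table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        target = out_dir / f"{name}.csv"
        df.to_csv(target, index=False, lineterminator="\n")
        written[name] = target
    return written
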