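"""Data model for gridded communities: cells, species, occurrence matrices and
per-cell environment tables, with CSV/TSV readers and the county x elevation
species-to-cell assignment rule."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GROWTH_FORMS = ("emergent", "floating", "submerged", "floating-leaved", "hygrophyte")

#: variable -> category map for the default 11-variable environment table:
#: energy-water (annual mean temperature, annual precipitation, precipitation
#: of the driest month, potential evapotranspiration), climate seasonality
#: (mean diurnal range, temperature seasonality, precipitation seasonality),
#: human activities (human footprint) and topography (wetland area, elevation
#: variation coefficient, slope).
DEFAULT_CATEGORIES: dict[str, str] = {
    "AMT": "energy-water",
    "AP": "energy-water",
    "PDM": "energy-water",
    "PET": "energy-water",
    "MDR": "climate seasonality",
    "TS": "climate seasonality",
    "PS": "climate seasonality",
    "HF": "human activities",
    "WA": "topography",
    "EVC": "topography",
    "Slope": "topography",
}

ENV_CATEGORIES = ("energy-water", "climate seasonality", "human activities", "topography")


class FormatError(ValueError):
    """Raised when a tabular input file violates its format contract."""


@dataclass
class GridCell:
    """One grid cell of the study lattice.

    ``land_fraction`` drives the exclusion rule (cells with less than half
    their area on land are dropped before assignment); ``counties`` and the
    closed elevation interval drive species assignment; ``protected`` feeds
    the conservation-gap overlay.
    """

    cell_id: str
    row: int
    col: int
    land_fraction: float = 1.0
    elev_min: float = 0.0
    elev_max: float = 0.0
    counties: frozenset[str] = field(default_factory=frozenset)
    protected: bool = False

    def __post_init__(self):
        if self.elev_min > self.elev_max:
            raise ValueError(f"cell {self.cell_id}: elev_min > elev_max")
        if not 0.0 <= self.land_fraction <= 1.0:
            raise ValueError(f"cell {self.cell_id}: land_fraction outside [0, 1]")
        self.counties = frozenset(self.counties)


@dataclass
class SpeciesRecord:
    """A species with its horizontal (county set) and vertical (elevation
    interval) range, endemic flag and growth form."""

    species_id: str
    counties: frozenset[str] = field(default_factory=frozenset)
    elev_min: float = 0.0
    elev_max: float = 0.0
    endemic: bool = False
    growth_form: str = "hygrophyte"

    def __post_init__(self):
        if self.elev_min > self.elev_max:
            raise ValueError(f"species {self.species_id}: elev_min > elev_max")
        self.counties = frozenset(self.counties)


class OccurrenceMatrix:
    """Binary cells x species incidence matrix with label registries."""

    def __init__(self, cells: list[str], species: list[str], incidence: np.ndarray):
        incidence = np.asarray(incidence)
        if incidence.shape != (len(cells), len(species)):
            raise ValueError("incidence shape does not match label lists")
        if not np.isin(incidence, (0, 1)).all():
            raise FormatError("incidence entries must be 0 or 1")
        if len(set(cells)) != len(cells):
            raise ValueError("duplicate cell ids")
        if len(set(species)) != len(species):
            raise ValueError("duplicate species ids")
        self.cells = list(cells)
        self.species = list(species)
        self.incidence = incidence.astype(np.int8)
        empty = [s for s, n in zip(self.species, self.incidence.sum(axis=0)) if n == 0]
        if empty:
            log.warning("%d species have zero occurrences: %s", len(empty), ", ".join(empty[:5]))
        self.empty_species = empty

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def richness(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(np.int64)

    def range_sizes(self) -> np.ndarray:
        """Per-species number of occupied cells (0 for flagged empty species)."""
        return self.incidence.sum(axis=0).astype(np.int64)

    def assemblage(self, cell_id: str) -> list[str]:
        i = self.cells.index(cell_id)
        return [s for s, v in zip(self.species, self.incidence[i]) if v]

    def subset_species(self, keep: list[str]) -> "OccurrenceMatrix":
        idx = [self.species.index(s) for s in keep]
        return OccurrenceMatrix(self.cells, keep, self.incidence[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=pd.Index(self.cells, name="cell_id"),
                            columns=self.species)


def read_occurrence(path) -> OccurrenceMatrix:
    """Read a cells x species 0/1 table (CSV or TSV; first column cell_id)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no cells") from None
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no cells")
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(
            f"{path}: non-binary value {values[r, c]!r} at row {r + 2} "
            f"(cell {df.index[r]!r}, species {df.columns[c]!r})")
    return OccurrenceMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_occurrence(matrix: OccurrenceMatrix, path):
    matrix.to_frame().to_csv(path)
    return path


def assign_species_to_cells(species: list[SpeciesRecord], cells: list[GridCell],
                            min_land_fraction: float = 0.5) -> OccurrenceMatrix:
    """Assign species to grid cells by joint county / elevation overlap.

    A species is recorded in a cell iff its county set intersects the cell's
    and its closed elevation interval overlaps the cell's.  Cells with
    ``land_fraction`` below ``min_land_fraction`` are removed first.
    """
    kept = [c for c in cells if c.land_fraction >= min_land_fraction]
    inc = np.zeros((len(kept), len(species)), dtype=np.int8)
    for i, cell in enumerate(kept):
        for j, sp in enumerate(species):
            if (sp.counties & cell.counties
                    and sp.elev_min <= cell.elev_max and cell.elev_min <= sp.elev_max):
                inc[i, j] = 1
    return OccurrenceMatrix([c.cell_id for c in kept], [s.species_id for s in species], inc)


# --------------------------------------------------------------- environment

class CellEnvironment:
    """Per-cell environmental table with a variable -> category map.

    The table holds one row per cell (indexed by cell_id) and one column per
    environmental variable, plus an ``elevation`` column kept outside the
    four driver categories.
    """

    def __init__(self, table: pd.DataFrame, categories: dict[str, str] | None = None):
        if table.index.name != "cell_id":
            table = table.copy()
            table.index.name = "cell_id"
        self.table = table
        cats = dict(categories or DEFAULT_CATEGORIES)
        for var in self.variables:
            if var not in cats:
                raise ValueError(f"variable {var!r} has no category")
            if cats[var] not in ENV_CATEGORIES:
                raise ValueError(f"unknown category {cats[var]!r} for {var!r}")
        self.categories = {v: cats[v] for v in self.variables}
        if "EVC" in table.columns and (table["EVC"] < 0).any():
            raise ValueError("EVC must be nonnegative")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.table.columns if c != "elevation"]

    @property
    def elevation(self) -> pd.Series:
        return self.table["elevation"]

    def by_category(self, category: str) -> list[str]:
        return [v for v in self.variables if self.categories[v] == category]

    def to_csv(self, path):
        self.table.to_csv(path)
        return path

    @classmethod
    def read_csv(cls, path, categories: dict[str, str] | None = None) -> "CellEnvironment":
        return cls(pd.read_csv(path, index_col=0), categories)


# ----------------------------------------------------------------- checklist

def _binomial(name: str) -> str:
    """Collapse an infraspecific name to its binomial (first two epithets)."""
    parts = name.strip().split()
    return " ".join(parts[:2]) if len(parts) >= 2 else name.strip()


def parse_checklist(path) -> list[SpeciesRecord]:
    """Parse a tabular species checklist into :class:`SpeciesRecord` objects.

    Expected columns (extra columns ignored): ``species`` (name, possibly
    infraspecific), ``growth_form``, and optionally ``endemic`` (0/1 or
    true/false), ``counties`` (semicolon-separated), ``elev_min``/``elev_max``.
    Infraspecific taxa are merged into their parent binomial: county sets are
    unioned, elevation intervals take the envelope, the endemic flag is kept
    if any member carries it.  Unknown growth forms are kept with a warning
    and classed as hygrophytes.
    """
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except UnicodeDecodeError as exc:
        raise FormatError(f"{path}: unreadable encoding: {exc}") from exc
    if "species" not in df.columns:
        raise FormatError(f"{path}: missing 'species' column")
    merged: dict[str, SpeciesRecord] = {}
    counts: dict[str, int] = {}
    for _, row in df.iterrows():
        sid = _binomial(row["species"])
        if not sid:
            continue
        gf = row.get("growth_form", "hygrophyte").strip() or "hygrophyte"
        if gf not in GROWTH_FORMS:
            warnings.warn(f"unknown growth form {gf!r} for {sid!r}; classed as hygrophyte")
            gf = "hygrophyte"
        counties = frozenset(c.strip() for c in row.get("counties", "").split(";") if c.strip())
        endemic = str(row.get("endemic", "")).strip().lower() in {"1", "true", "yes"}
        lo = float(row["elev_min"]) if row.get("elev_min", "") else 0.0
        hi = float(row["elev_max"]) if row.get("elev_max", "") else lo
        if sid in merged:
            old = merged[sid]
            merged[sid] = SpeciesRecord(
                sid, old.counties | counties, min(old.elev_min, lo), max(old.elev_max, hi),
                old.endemic or endemic, old.growth_form)
        else:
            merged[sid] = SpeciesRecord(sid, counties, lo, hi, endemic, gf)
            counts[gf] = counts.get(gf, 0) + 1
    aquatic = sum(n for g, n in counts.items() if g != "hygrophyte")
    log.info("checklist: %d species (%d aquatic, %d hygrophytes)",
             len(merged), aquatic, counts.get("hygrophyte", 0))
    return list(merged.values())
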