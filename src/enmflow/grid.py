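"""Raster and occurrence data model.

The analysis grid is an axis-aligned, north-up rectangular raster.  Cell
indices are row-major from the north-west origin; a point (lon, lat) maps to
the cell whose half-open interval ``[x0 + j*dx, x0 + (j+1)*dx)`` (and the
analogous southward latitude band) contains it.  All layers entering a stack
must be congruent: same shape, same geotransform, same CRS.

GeoTIFF I/O is backed by :mod:`tifffile`; the geotransform, CRS and nodata
value travel in the TIFF ImageDescription tag as a small JSON document, so a
write→read round trip is bit-exact.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "GridTransform",
    "RasterGrid",
    "RasterStack",
    "OccurrenceSet",
    "BiasGrid",
    "read_raster",
    "write_raster",
    "resample_bilinear",
    "aggregate_landcover_fractions",
    "filter_temporal",
    "thin_one_per_cell",
    "balance_by_region",
    "build_bias_grid",
    "correlation_prune",
]

DESCRIPTORS = ("climate", "topography", "landcover", "human", "prey")


@dataclass(frozen=True)
class GridTransform:
    """North-up affine geotransform: top-left corner and positive cell sizes."""

    x0: float
    y0: float
    dx: float
    dy: float

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) by half-open cell intervals."""
        col = np.floor((np.asarray(lon, float) - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - np.asarray(lat, float)) / self.dy).astype(int)
        return row, col

    def center_of(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.x0 + (np.asarray(col, float) + 0.5) * self.dx
        lat = self.y0 - (np.asarray(row, float) + 0.5) * self.dy
        return lon, lat

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.dx, self.dy)


@dataclass
class RasterGrid:
    """A single 2-D layer with geotransform, CRS and nodata sentinel.

    Nodata cells are excluded from every statistic computed here.
    """

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def congruent(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def summary(self) -> dict:
        v = self.valid_values()
        if v.size == 0:
            return {"n_valid": 0, "min": None, "max": None, "mean": None}
        return {
            "n_valid": int(v.size),
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
        }


@dataclass
class RasterStack:
    """An ordered, congruent collection of named layers.

    ``descriptor_map`` assigns each layer to one environmental descriptor
    (climate, topography, landcover, human, prey).
    """

    layers: dict[str, RasterGrid]
    descriptor_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.layers)
        if not names:
            raise ValueError("RasterStack needs at least one layer")
        ref = self.layers[names[0]]
        bad = [n for n in names[1:] if not self.layers[n].congruent(ref)]
        if bad:
            raise ValueError(
                f"layers not congruent with '{names[0]}': {', '.join(bad)}"
            )
        for name, d in self.descriptor_map.items():
            if d not in DESCRIPTORS:
                raise ValueError(f"unknown descriptor '{d}' for layer '{name}'")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.first.shape

    @property
    def first(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    @property
    def transform(self) -> GridTransform:
        return self.first.transform

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.shape, bool)
        for g in self.layers.values():
            m &= g.valid_mask
        return m

    def values_at(self, rows: np.ndarray, cols: np.ndarray, names=None) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at cell indices."""
        names = list(names) if names is not None else self.names
        out = np.empty((len(rows), len(names)))
        for k, n in enumerate(names):
            out[:, k] = self.layers[n].values[rows, cols]
        return out

    def subset(self, names) -> "RasterStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack(
            {n: self.layers[n] for n in names},
            {n: self.descriptor_map[n] for n in names if n in self.descriptor_map},
        )

    def by_descriptor(self, descriptor: str) -> list[str]:
        return [n for n in self.names if self.descriptor_map.get(n) == descriptor]


@dataclass
class OccurrenceSet:
    """Presence records for one species, tied to an analysis grid.

    ``records`` columns: lon, lat, year, region, source_id plus the derived
    cell indices row, col.  Every record must fall inside the grid.
    """

    species: str
    records: pd.DataFrame
    grid_ref: RasterGrid

    REQUIRED = ("lon", "lat", "year", "region", "source_id")

    def __post_init__(self) -> None:
        df = self.records.copy().reset_index(drop=True)
        for c in self.REQUIRED:
            if c not in df.columns:
                raise ValueError(f"occurrence table missing column '{c}'")
        row, col = self.grid_ref.transform.cell_of(df["lon"].values, df["lat"].values)
        nrow, ncol = self.grid_ref.shape
        inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        if not inside.all():
            raise ValueError(
                f"{(~inside).sum()} record(s) of '{self.species}' fall outside the grid"
            )
        df["row"], df["col"] = row, col
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def cells(self) -> np.ndarray:
        """(n, 2) array of (row, col) per record."""
        return self.records[["row", "col"]].to_numpy()

    def with_records(self, df: pd.DataFrame) -> "OccurrenceSet":
        return OccurrenceSet(self.species, df.drop(columns=["row", "col"], errors="ignore"), self.grid_ref)

    def to_csv(self, path) -> None:
        self.records[list(self.REQUIRED)].assign(species=self.species)[
            ["species", *self.REQUIRED]
        ].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_ref: RasterGrid, species: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        if species is not None:
            df = df[df["species"] == species]
        elif df["species"].nunique() != 1:
            raise ValueError("CSV holds multiple species; pass species=")
        name = species if species is not None else df["species"].iloc[0]
        if "source_id" not in df.columns:
            df = df.assign(source_id=np.arange(len(df)))
        if "region" not in df.columns:
            df = df.assign(region=0)
        return cls(name, df.drop(columns=["species"]), grid_ref)


@dataclass
class BiasGrid:
    """Relative sampling-effort raster taking exactly two values: 1 for cells
    holding at least one occurrence record of any species, and a background
    effort ``b`` (0.1 for the BM01 variant, 0.01 for BM001) everywhere else."""

    grid: RasterGrid
    b: float

    def __post_init__(self) -> None:
        vals = np.unique(self.grid.valid_values())
        if not np.all(np.isin(vals, [1.0, self.b])):
            raise ValueError("bias grid must contain only {1, b}")


# ---------------------------------------------------------------------------
# I/O


def write_raster(grid: RasterGrid, path) -> str:
    """Write one layer as single-band GeoTIFF (georeferencing in the
    description tag); round-trips bit-exactly through :func:`read_raster`."""
    meta = {
        "geotransform": grid.transform.as_tuple(),
        "crs": grid.crs,
        "nodata": grid.nodata,
    }
    tifffile.imwrite(str(path), grid.values, description=json.dumps(meta))
    return str(path)


def read_raster(path) -> RasterGrid:
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path}: no georeferencing metadata")
        meta = json.loads(desc.value)
    return RasterGrid(
        values=np.asarray(values, np.float64),
        transform=GridTransform(*meta["geotransform"]),
        crs=meta["crs"],
        nodata=float(meta["nodata"]),
    )


# ---------------------------------------------------------------------------
# Resampling and aggregation


def resample_bilinear(grid: RasterGrid, target: GridTransform, shape: tuple[int, int]) -> RasterGrid:
    """Bilinear resampling onto a target grid.

    Each target cell center is interpolated from the four nearest source cell
    centers.  If any contributing corner is nodata, or the target center falls
    outside the hull of source centers, the output cell is nodata.
    """
    nrow_t, ncol_t = shape
    rows_t, cols_t = np.meshgrid(np.arange(nrow_t), np.arange(ncol_t), indexing="ij")
    lon, lat = target.center_of(rows_t.ravel(), cols_t.ravel())
    # fractional position in source cell-center coordinates
    fx = (lon - grid.transform.x0) / grid.transform.dx - 0.5
    fy = (grid.transform.y0 - lat) / grid.transform.dy - 0.5
    nrow_s, ncol_s = grid.shape
    i0 = np.floor(fy).astype(int)
    j0 = np.floor(fx).astype(int)
    ty = fy - i0
    tx = fx - j0
    out = np.full(lon.shape, grid.nodata)
    ok = (i0 >= 0) & (i0 + 1 < nrow_s) & (j0 >= 0) & (j0 + 1 < ncol_s)
    if ok.any():
        i0k, j0k = i0[ok], j0[ok]
        v00 = grid.values[i0k, j0k]
        v01 = grid.values[i0k, j0k + 1]
        v10 = grid.values[i0k + 1, j0k]
        v11 = grid.values[i0k + 1, j0k + 1]
        corners = np.stack([v00, v01, v10, v11])
        finite = ~(np.isnan(corners) | (corners == grid.nodata)).any(axis=0)
        txk, tyk = tx[ok], ty[ok]
        interp = (
            v00 * (1 - txk) * (1 - tyk)
            + v01 * txk * (1 - tyk)
            + v10 * (1 - txk) * tyk
            + v11 * txk * tyk
        )
        vals = np.full(i0k.shape, grid.nodata)
        vals[finite] = interp[finite]
        out[ok] = vals
    return RasterGrid(out.reshape(shape), target, grid.crs, grid.nodata)


def aggregate_landcover_fractions(
    classes: RasterGrid,
    class_merge: dict,
    factor: int,
    class_names: dict | None = None,
) -> RasterStack:
    """Fractional cover per merged class on a ``factor``-times-coarser grid.

    ``class_merge`` maps raw integer class → merged class id, or the string
    ``"drop"``.  Fractions are computed over ALL fine pixels in each coarse
    cell: merged-away classes contribute to their merge target, dropped
    classes yield no layer but still count in the denominator.
    """
    if not (isinstance(factor, (int, np.integer)) and factor >= 1):
        raise ValueError("aggregation factor must be a positive integer")
    nrow, ncol = classes.shape
    if nrow % factor or ncol % factor:
        raise ValueError("grid shape must be an integer multiple of factor")
    merged = {}
    raw = classes.values.astype(int)
    for cls, target in class_merge.items():
        if target == "drop":
            continue
        merged.setdefault(target, []).append(cls)
    t = classes.transform
    coarse_t = GridTransform(t.x0, t.y0, t.dx * factor, t.dy * factor)
    blocks = raw.reshape(nrow // factor, factor, ncol // factor, factor)
    layers = {}
    for target, members in merged.items():
        frac = np.isin(blocks, members).mean(axis=(1, 3))
        name = (class_names or {}).get(target, f"lc_{target}")
        layers[name] = RasterGrid(frac, coarse_t, classes.crs, classes.nodata)
    return RasterStack(layers, {n: "landcover" for n in layers})


# ---------------------------------------------------------------------------
# Occurrence filtering


def filter_temporal(occ: OccurrenceSet, cutoff_year: int = 1990) -> OccurrenceSet:
    """Keep records strictly after ``cutoff_year``; records with a missing
    year are dropped with a warning."""
    df = occ.records
    missing = df["year"].isna()
    if missing.any():
        logger.warning("%s: dropping %d record(s) with missing year", occ.species, missing.sum())
    kept = df[~missing & (df["year"] > cutoff_year)]
    return occ.with_records(kept)


def thin_one_per_cell(occ: OccurrenceSet, seed: int) -> OccurrenceSet:
    """Spatial thinning to at most one record per grid cell (the RD dataset);
    the retained record is chosen uniformly at random within each cell."""
    rng = np.random.default_rng(seed)
    df = occ.records
    if df.empty:
        return occ.with_records(df)
    keep_idx = []
    for _, idx in sorted(df.groupby(["row", "col"]).groups.items()):
        keep_idx.append(rng.choice(np.asarray(idx)))
    return occ.with_records(df.loc[sorted(keep_idx)])


def balance_by_region(occ: OccurrenceSet, region_map: RasterGrid, seed: int) -> OccurrenceSet:
    """Equalize per-region record density (the RDbal dataset).

    Density = records / valid region cells.  Every region is randomly
    down-sampled toward the minimum positive regional density; regions that
    had records always keep at least one.
    """
    rng = np.random.default_rng(seed)
    df = occ.records
    if df.empty:
        return occ.with_records(df)
    regions = region_map.values.astype(int)
    valid = region_map.valid_mask
    rec_region = regions[df["row"].values, df["col"].values]
    densities = {}
    for r in np.unique(rec_region):
        n_cells = int((valid & (regions == r)).sum())
        if n_cells == 0:
            raise ValueError(f"region {r} has records but zero valid cells")
        densities[r] = (rec_region == r).sum() / n_cells
    target = min(densities.values())
    keep = np.zeros(len(df), bool)
    for r, dens in densities.items():
        idx = np.flatnonzero(rec_region == r)
        n_cells = (rec_region == r).sum() / dens
        n_keep = max(1, int(round(target * n_cells)))
        if n_keep >= len(idx):
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=n_keep, replace=False)] = True
    return occ.with_records(df[keep])


def build_bias_grid(occ_all_species: list[OccurrenceSet], variant: str) -> BiasGrid:
    """Sampling-effort bias raster from the pooled records of all species.

    Cells holding at least one record get effort 1; all other valid cells get
    0.1 (variant ``BM01``) or 0.01 (``BM001``).
    """
    values = {"BM01": 0.1, "BM001": 0.01}
    if variant not in values:
        raise ValueError(f"unknown bias variant '{variant}' (expected BM01 or BM001)")
    b = values[variant]
    if not occ_all_species:
        raise ValueError("need at least one occurrence set")
    ref = occ_all_species[0].grid_ref
    vals = np.full(ref.shape, b)
    for occ in occ_all_species:
        if not occ.grid_ref.congruent(ref):
            raise ValueError("occurrence sets use different grids")
        vals[occ.records["row"].values, occ.records["col"].values] = 1.0
    vals[~ref.valid_mask] = ref.nodata
    return BiasGrid(RasterGrid(vals, ref.transform, ref.crs, ref.nodata), b)


def correlation_prune(
    stack: RasterStack,
    cells: np.ndarray,
    threshold: float = 0.65,
    priority: list[str] | None = None,
    per_descriptor: bool = True,
) -> list[str]:
    """Drop one variable of every highly correlated pair (|Pearson r| >
    threshold), retaining the higher-priority variable.

    A greedy pass walks the variables in priority order and keeps a candidate
    only if it is not over-correlated with an already-retained variable.
    Applied within each descriptor independently by default.  A constant
    layer has undefined r; it is treated as r = 0 and logged.
    """
    priority = list(priority) if priority is not None else stack.names
    unknown = [p for p in priority if p not in stack.layers]
    if unknown:
        raise KeyError(f"priority names not in stack: {unknown}")
    rows, cols = cells[:, 0], cells[:, 1]
    X = stack.values_at(rows, cols, priority)
    sd = X.std(axis=0)
    for k, name in enumerate(priority):
        if sd[k] == 0:
            logger.warning("layer '%s' constant over sample; correlation treated as 0", name)
    groups: dict[str, list[int]]
    if per_descriptor:
        groups = {}
        for k, name in enumerate(priority):
            groups.setdefault(stack.descriptor_map.get(name, "_none"), []).append(k)
    else:
        groups = {"_all": list(range(len(priority)))}
    retained: list[str] = []
    for _, idxs in groups.items():
        kept_in_group: list[int] = []
        for k in idxs:
            ok = True
            for j in kept_in_group:
                if sd[k] == 0 or sd[j] == 0:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = np.corrcoef(X[:, k], X[:, j])[0, 1]
                if np.isfinite(r) and abs(r) > threshold:
                    ok = False
                    break
            if ok:
                kept_in_group.append(k)
        retained.extend(priority[k] for k in kept_in_group)
    return [n for n in priority if n in set(retained)]
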