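"""Synthetic landscapes, species, protected areas and climate series.

Every generator is a pure function of its arguments, including the seed, so
downstream stages can be tested against a known ground truth: spatially
autocorrelated and mutually correlated predictors, species occurrences drawn
from a known Gibbs suitability surface (optionally coupled to a detection-bias
layer), regional record clustering, protected-area masks with paired polygon
and raster representations, and per-period climate stacks with additive or
multiplicative drift plus pseudo-GCM noise.

Random fields are built by smoothing white noise with a Gaussian kernel of
width ``autocorr_range`` and then linearly mixing the independent fields via
the Cholesky factor of the target correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon, mapping

from .grid import GridTransform, OccurrenceSet, RasterGrid, RasterStack

__all__ = [
    "SyntheticLandscape",
    "SpeciesTemplate",
    "ScenarioSeries",
    "generate_env_stack",
    "generate_species_occurrences",
    "generate_protected_mask",
    "generate_climate_series",
    "generate_prey_occurrences",
    "polygons_to_geojson",
]


@dataclass
class SyntheticLandscape:
    """A fully synthetic study area with known generative parameters."""

    env_stack: RasterStack
    region_map: RasterGrid
    landcover_fractions: RasterStack
    correlation_target: np.ndarray
    seed: int


@dataclass
class SpeciesTemplate:
    """Ground-truth niche of a synthetic species.

    ``coefficients`` maps variable name → (linear, quadratic) weights on the
    standardized predictor scale; cell-level suitability is
    exp(Σ a·z + b·z²), i.e. the same Gibbs form the niche model fits.
    """

    name: str
    coefficients: dict[str, tuple[float, float]]
    prevalence: float = 100.0
    bias_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.prevalence < 1:
            raise ValueError("prevalence must be >= 1")
        if not any(a != 0 or b != 0 for a, b in self.coefficients.values()):
            raise ValueError("template needs at least one nonzero coefficient")


@dataclass
class ScenarioSeries:
    """Climate stacks per time period per pseudo-GCM.

    ``stacks[period]`` is a list with one congruent RasterStack per GCM; the
    "current" period has exactly one stack, identical to the landscape's
    climatic layers.
    """

    periods: list[str]
    stacks: dict[str, list[RasterStack]]
    drift: dict
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.periods)) != len(self.periods):
            raise ValueError("period labels must be unique")


def _smooth_fields(rng: np.random.Generator, k: int, shape, autocorr_range: float) -> np.ndarray:
    """k independent standardized Gaussian random fields with autocorrelation."""
    fields = np.empty((k, *shape))
    for i in range(k):
        f = gaussian_filter(rng.standard_normal(shape), sigma=autocorr_range, mode="wrap")
        fields[i] = (f - f.mean()) / f.std()
    return fields


def generate_env_stack(
    shape: tuple[int, int],
    k: int,
    correlation_target: np.ndarray | None = None,
    autocorr_range: float = 3.0,
    seed: int = 0,
    descriptor_map: dict[str, str] | None = None,
    n_regions: int = 4,
    n_landcover: int = 3,
    cell_size: float = 0.1,
) -> SyntheticLandscape:
    """Generate a landscape of ``k`` correlated continuous predictors plus a
    region map and fractional land-cover layers.

    Raises a validation error if the correlation target is not symmetric
    positive-definite.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if correlation_target is None:
        correlation_target = np.eye(k)
    correlation_target = np.asarray(correlation_target, float)
    if correlation_target.shape != (k, k) or not np.allclose(
        correlation_target, correlation_target.T
    ):
        raise ValueError("correlation_target must be a symmetric k x k matrix")
    try:
        L = np.linalg.cholesky(correlation_target)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation_target must be positive-definite") from e

    rng = np.random.default_rng(seed)
    transform = GridTransform(0.0, shape[0] * cell_size, cell_size, cell_size)
    raw = _smooth_fields(rng, k, shape, autocorr_range)
    mixed = np.tensordot(L, raw, axes=1)
    # re-standardize so each layer is exactly mean 0 / sd 1; the linear mix
    # preserves correlations
    names = [f"v{i + 1}" for i in range(k)]
    layers = {}
    for i, name in enumerate(names):
        z = (mixed[i] - mixed[i].mean()) / mixed[i].std()
        layers[name] = RasterGrid(z, transform)
    dmap = descriptor_map or {n: "climate" for n in names}
    env_stack = RasterStack(layers, dmap)

    # region map: nearest-center (Voronoi) partition, mimics country borders
    centers = rng.uniform(0, 1, size=(n_regions, 2)) * np.array(shape)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d2 = (rr[None] - centers[:, 0, None, None]) ** 2 + (cc[None] - centers[:, 1, None, None]) ** 2
    region_map = RasterGrid(np.argmin(d2, axis=0).astype(float), transform)

    # fractional land cover via softmax of smoothed fields: sums to 1 per cell
    lc_raw = _smooth_fields(rng, n_landcover, shape, autocorr_range)
    e = np.exp(lc_raw * 2.0)
    frac = e / e.sum(axis=0)
    lc_layers = {
        f"lc{i + 1}": RasterGrid(frac[i], transform) for i in range(n_landcover)
    }
    landcover = RasterStack(lc_layers, {n: "landcover" for n in lc_layers})
    return SyntheticLandscape(env_stack, region_map, landcover, correlation_target, seed)


def _suitability(landscape: SyntheticLandscape, template: SpeciesTemplate) -> np.ndarray:
    stack = landscape.env_stack
    missing = [v for v in template.coefficients if v not in stack.layers]
    if missing:
        raise KeyError(f"template variables not in landscape: {missing}")
    score = np.zeros(stack.shape)
    for v, (a, b) in template.coefficients.items():
        z = stack.layers[v].values
        score += a * z + b * z**2
    return np.exp(score - score.max())


def generate_species_occurrences(
    landscape: SyntheticLandscape,
    template: SpeciesTemplate,
    bias_layer: RasterGrid | None = None,
    seed: int = 0,
    year_range: tuple[int, int] = (1991, 2020),
) -> OccurrenceSet:
    """Sample presence records cell-wise with probability proportional to
    exp(linear + quadratic score) x bias^bias_strength; the record count is
    Poisson with mean ``template.prevalence``."""
    rng = np.random.default_rng(seed)
    stack = landscape.env_stack
    suit = _suitability(landscape, template)
    if bias_layer is not None and template.bias_strength > 0:
        if bias_layer.shape != stack.shape:
            raise ValueError("bias layer not congruent with landscape")
        suit = suit * np.power(np.clip(bias_layer.values, 0, None), template.bias_strength)
    valid = stack.valid_mask
    p = np.where(valid, suit, 0.0).ravel()
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    p = p / total
    n = max(1, rng.poisson(template.prevalence))
    flat = rng.choice(p.size, size=n, p=p, replace=True)
    rows, cols = np.unravel_index(flat, stack.shape)
    t = stack.transform
    lon = t.x0 + (cols + rng.uniform(0.05, 0.95, n)) * t.dx
    lat = t.y0 - (rows + rng.uniform(0.05, 0.95, n)) * t.dy
    df = pd.DataFrame(
        {
            "lon": lon,
            "lat": lat,
            "year": rng.integers(year_range[0], year_range[1] + 1, n),
            "region": landscape.region_map.values[rows, cols].astype(int),
            "source_id": np.arange(n),
        }
    )
    return OccurrenceSet(template.name, df, stack.first)


def generate_protected_mask(
    landscape: SyntheticLandscape,
    n_polygons: int = 5,
    total_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[RasterGrid, list[Polygon]]:
    """Random square protected areas covering ≈ ``total_fraction`` of the grid.

    Returns the binary raster (cell protected iff its center lies inside a
    polygon — the rasterization rule) and the polygons themselves; the two
    representations agree cell-for-cell by construction.  Side lengths are
    rescaled by bisection so the rasterized fraction lands within ±0.05 of
    the request.
    """
    if not 0 < total_fraction < 1:
        raise ValueError("total_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    t = landscape.env_stack.transform
    nrow, ncol = landscape.env_stack.shape
    width, height = ncol * t.dx, nrow * t.dy
    centers_x = rng.uniform(t.x0, t.x0 + width, n_polygons)
    centers_y = rng.uniform(t.y0 - height, t.y0, n_polygons)
    weights = rng.uniform(0.5, 1.5, n_polygons)
    weights /= weights.sum()

    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    cx, cy = t.center_of(rr.ravel(), cc.ravel())

    def rasterize(scale: float) -> tuple[np.ndarray, list[Polygon]]:
        polys = []
        for x, y, w in zip(centers_x, centers_y, weights):
            half = 0.5 * np.sqrt(w * total_fraction * width * height) * scale
            polys.append(
                Polygon(
                    [
                        (x - half, y - half),
                        (x + half, y - half),
                        (x + half, y + half),
                        (x - half, y + half),
                    ]
                )
            )
        union = shapely.union_all(polys)
        inside = shapely.contains_xy(union, cx, cy)
        return inside.reshape(nrow, ncol), polys

    lo, hi = 0.25, 4.0
    for _ in range(40):
        scale = np.sqrt(lo * hi)
        mask, polys = rasterize(scale)
        frac = mask.mean()
        if abs(frac - total_fraction) < 0.01:
            break
        if frac < total_fraction:
            lo = scale
        else:
            hi = scale
    grid = RasterGrid(mask.astype(float), t)
    return grid, polys


def polygons_to_geojson(polys: list[Polygon], path, properties: list[dict] | None = None) -> str:
    import json

    feats = []
    for i, p in enumerate(polys):
        props = properties[i] if properties else {"id": i, "status": "Designated"}
        feats.append({"type": "Feature", "geometry": mapping(p), "properties": props})
    doc = {"type": "FeatureCollection", "features": feats}
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return str(path)


def generate_climate_series(
    landscape: SyntheticLandscape,
    drift: dict[str, dict[str, dict]],
    n_gcms: int = 1,
    gcm_sd: float = 0.0,
    seed: int = 0,
) -> ScenarioSeries:
    """Per-period climate stacks: the "current" stack equals the landscape's
    climatic layers exactly; every other period applies the declared per-
    variable additive/multiplicative drift plus smooth per-GCM noise fields
    of standard deviation ``gcm_sd``.

    ``drift`` maps period label → {variable: {"add": a, "mul": m}}.
    """
    rng = np.random.default_rng(seed)
    stack = landscape.env_stack
    climate_names = stack.by_descriptor("climate") or stack.names
    current = stack.subset(climate_names)
    for period, spec in drift.items():
        unknown = [v for v in spec if v not in climate_names]
        if unknown:
            raise KeyError(f"drift for period '{period}' names unknown variables: {unknown}")
    periods = ["current", *[p for p in drift if p != "current"]]
    stacks: dict[str, list[RasterStack]] = {"current": [current]}
    for period in periods[1:]:
        spec = drift[period]
        per_gcm = []
        for _ in range(n_gcms):
            layers = {}
            for name in climate_names:
                vals = current.layers[name].values.copy()
                d = spec.get(name, {})
                vals = vals * d.get("mul", 1.0) + d.get("add", 0.0)
                if gcm_sd > 0:
                    noise = gaussian_filter(rng.standard_normal(vals.shape), 3.0, mode="wrap")
                    vals = vals + gcm_sd * noise / noise.std()
                layers[name] = current.layers[name].with_values(vals)
            per_gcm.append(RasterStack(layers, {n: "climate" for n in layers}))
        stacks[period] = per_gcm
    return ScenarioSeries(periods, stacks, drift, seed)


def mass_group(mass_g: float) -> str:
    """Body-mass class of a rodent prey species: small ≤ 70 g,
    70 g < medium < 150 g, large ≥ 150 g (the boundary mass 150 g is
    assigned to 'large' to close the partition)."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    if mass_g <= 70:
        return "small"
    if mass_g < 150:
        return "medium"
    return "large"


def generate_prey_occurrences(
    landscape: SyntheticLandscape,
    groups: list[tuple[str, float, SpeciesTemplate]],
    seed: int = 0,
) -> dict[str, OccurrenceSet]:
    """Sample prey occurrences pooled into body-size groups.

    ``groups`` lists (species label, body mass in grams, template).  Species
    are pooled into small/medium/large before sampling; the returned map has
    one OccurrenceSet per nonempty group holding the pooled records.
    """
    rng = np.random.default_rng(seed)
    pooled: dict[str, list] = {}
    for label, mass, template in groups:
        pooled.setdefault(mass_group(mass), []).append((label, template))
    out: dict[str, OccurrenceSet] = {}
    for g, members in pooled.items():
        frames = []
        for label, template in members:
            sub = generate_species_occurrences(
                landscape, template, seed=int(rng.integers(2**31))
            )
            frames.append(sub.records[list(OccurrenceSet.REQUIRED)])
        df = pd.concat(frames, ignore_index=True)
        df["source_id"] = np.arange(len(df))
        out[g] = OccurrenceSet(f"prey_{g}", df, landscape.env_stack.first)
    return out
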