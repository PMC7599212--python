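"""Binary presence maps and protected-area coverage.

A suitability surface is binarized at a presence threshold (MTP, P10 or ETS;
a cell is predicted present iff raw >= threshold, so the minimum-training-
presence threshold yields zero training omission by construction).  Coverage
is the proportion of predicted-presence cells that intersect protected areas;
cells are treated as equal-area.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

from .grid import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMap",
    "CoverageReport",
    "binarize",
    "pa_coverage",
    "coverage_report",
    "read_protected_geojson",
    "rasterize_protected",
]

EXCLUDED_STATUS = ("Proposed", "Not Reported")


@dataclass
class BinaryMap:
    grid: RasterGrid
    threshold_kind: str
    threshold_value: float
    source_model: str = ""

    @property
    def presence_count(self) -> int:
        return int((self.grid.values[self.grid.valid_mask] == 1).sum())


def binarize(surface: RasterGrid, threshold: float, kind: str = "", model_id: str = "") -> BinaryMap:
    """Presence iff raw >= threshold; nodata propagated."""
    valid = surface.valid_mask
    out = np.full(surface.shape, surface.nodata)
    out[valid] = (surface.values[valid] >= threshold).astype(float)
    return BinaryMap(surface.with_values(out), kind, float(threshold), model_id)


def pa_coverage(binary: BinaryMap, protected: RasterGrid) -> float | None:
    """Proportion of predicted-presence cells that are protected; None (with
    a warning) when the species has no predicted-presence cells."""
    if binary.grid.shape != protected.shape:
        raise ValueError("binary map and protected mask must share a grid")
    pres = (binary.grid.values == 1) & binary.grid.valid_mask
    n_pres = pres.sum()
    if n_pres == 0:
        logger.warning("no predicted-presence cells: coverage undefined")
        return None
    prot = (protected.values == 1) & protected.valid_mask
    return float((pres & prot).sum() / n_pres)


@dataclass
class CoverageReport:
    """Protected-area coverage per best model, summarized per threshold kind
    (sample sd with the n-1 denominator; 0 for a single model)."""

    table: pd.DataFrame  # columns: model_id, threshold_kind, coverage

    def summary(self) -> pd.DataFrame:
        if self.table.empty:
            return pd.DataFrame(columns=["threshold_kind", "mean", "sd", "n"])
        g = self.table.groupby("threshold_kind")["coverage"]
        out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                    n="count").reset_index()
        return out


def coverage_report(
    surfaces: dict[str, RasterGrid],
    thresholds: dict[str, dict[str, float]],
    protected: RasterGrid,
) -> CoverageReport:
    """Coverage of every best-model surface at every threshold kind.

    ``thresholds[model_id]`` maps kind (MTP/P10/ETS) to the threshold value
    of that model's current-time fit.
    """
    rows = []
    for model_id, surf in surfaces.items():
        for kind, t in thresholds[model_id].items():
            cov = pa_coverage(binarize(surf, t, kind, model_id), protected)
            if cov is not None:
                rows.append({"model_id": model_id, "threshold_kind": kind, "coverage": cov})
    return CoverageReport(pd.DataFrame(rows))


def read_protected_geojson(path, excluded_status: tuple = EXCLUDED_STATUS) -> list:
    """Load protected-area polygons, dropping features whose ``status``
    property is "Proposed" or "Not Reported"."""
    with open(path) as fh:
        doc = json.load(fh)
    polys = []
    for feat in doc.get("features", []):
        if feat.get("properties", {}).get("status") in excluded_status:
            continue
        polys.append(shape(feat["geometry"]))
    return polys


def rasterize_protected(polys: list, template: RasterGrid) -> RasterGrid:
    """Rasterize polygons onto the template grid: a cell is protected iff its
    center lies inside a polygon."""
    nrow, ncol = template.shape
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    x, y = template.transform.center_of(rr.ravel(), cc.ravel())
    if polys:
        union = shapely.union_all(polys)
        inside = shapely.contains_xy(union, x, y).reshape(nrow, ncol)
    else:
        inside = np.zeros((nrow, ncol), bool)
    vals = inside.astype(float)
    vals[~template.valid_mask] = template.nodata
    return template.with_values(vals)
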