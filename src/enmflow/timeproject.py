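"""Projection of climate-only models through time.

Fitted models are projected onto per-period, per-GCM climate stacks; the raw
surface is renormalized over each scenario grid, cells whose climate falls
outside the model's calibration range are flagged as non-analog (retained in
the surface, masked only on request), and suitable-area fractions are
computed at thresholds taken from the current-time fit.  Climate refugia are
cells that stay suitable across all periods for a quorum of model x GCM
combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import RasterGrid, RasterStack
from .maxent import FittedModel, predict_raw
from .synth import ScenarioSeries

logger = logging.getLogger(__name__)

__all__ = [
    "AnalogMask",
    "project_model",
    "suitable_fraction",
    "trend_table",
    "refugia_map",
]


@dataclass
class AnalogMask:
    """Non-analog flags: a cell is flagged iff at least one model variable is
    outside the calibration [min, max] of the fit."""

    flags: np.ndarray  # bool, True = non-analog
    per_variable: dict[str, np.ndarray]
    ranges: dict[str, tuple[float, float]]

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def project_model(model: FittedModel, scenario: RasterStack) -> tuple[RasterGrid, AnalogMask]:
    """Project a fitted model onto a scenario stack.

    Returns the renormalized raw surface plus the non-analog mask; flagged
    cells keep their raw values (downstream policies decide their fate).
    """
    surface = predict_raw(model, scenario)
    valid = scenario.subset(model.basis.variables).valid_mask
    per_var = {}
    flags = np.zeros(surface.shape, bool)
    for v in model.basis.variables:
        lo, hi = model.calibration_ranges[v]
        vals = scenario.layers[v].values
        out = valid & ((vals < lo) | (vals > hi))
        per_var[v] = out
        flags |= out
    if valid.any() and flags[valid].all():
        logger.warning("every valid cell is outside the calibration range")
    return surface, AnalogMask(flags, per_var, dict(model.calibration_ranges))


def suitable_fraction(
    surface: RasterGrid,
    threshold: float,
    analog_mask: AnalogMask | None = None,
    analog_policy: str = "include",
) -> float:
    """Fraction of valid cells with raw >= threshold (the current-time
    threshold for the matching kind).

    analog_policy: "include" counts flagged cells normally, "exclude" removes
    them from numerator and denominator, "zero" treats them as unsuitable.
    """
    if analog_policy not in ("include", "exclude", "zero"):
        raise ValueError("analog_policy must be include|exclude|zero")
    valid = surface.valid_mask
    suit = valid & (surface.values >= threshold)
    if analog_mask is not None and analog_policy != "include":
        if analog_policy == "exclude":
            valid = valid & ~analog_mask.flags
            suit = suit & ~analog_mask.flags
        else:  # zero
            suit = suit & ~analog_mask.flags
    denom = valid.sum()
    if denom == 0:
        raise ValueError("no valid cells in denominator")
    return float(suit.sum() / denom)


def trend_table(
    models: dict[str, FittedModel],
    series: ScenarioSeries,
    thresholds: dict[str, dict[str, float]],
    species: str = "",
    analog_policy: str = "include",
) -> pd.DataFrame:
    """Suitable-fraction rows for every model x period x GCM x threshold kind,
    sorted by the series' explicit period order.

    ``thresholds[model_id]`` holds the current-time MTP/P10/ETS values of
    that model.
    """
    rows = []
    for model_id, model in models.items():
        for period in series.periods:
            for g, stack in enumerate(series.stacks[period]):
                surf, mask = project_model(model, stack)
                for kind, t in thresholds[model_id].items():
                    rows.append(
                        {
                            "species": species,
                            "model_id": model_id,
                            "period": period,
                            "gcm": g,
                            "threshold_kind": kind,
                            "suitable_fraction": suitable_fraction(
                                surf, t, mask, analog_policy
                            ),
                        }
                    )
    df = pd.DataFrame(rows)
    order = {p: i for i, p in enumerate(series.periods)}
    return df.sort_values(
        ["model_id", "period", "gcm", "threshold_kind"],
        key=lambda s: s.map(order) if s.name == "period" else s,
    ).reset_index(drop=True)


def refugia_map(
    models: dict[str, FittedModel],
    series: ScenarioSeries,
    thresholds: dict[str, dict[str, float]],
    threshold_kind: str = "P10",
    quorum: float = 0.9,
) -> RasterGrid:
    """Cells suitable in ALL periods for at least ``quorum`` of the
    model x GCM combinations; refugia shrink (never grow) as quorum rises."""
    if not 0 < quorum <= 1:
        raise ValueError("quorum must be in (0, 1]")
    combo_maps = []
    template = None
    for model_id, model in models.items():
        t = thresholds[model_id][threshold_kind]
        n_gcms = max(len(series.stacks[p]) for p in series.periods)
        for g in range(n_gcms):
            stable = None
            for period in series.periods:
                stacks = series.stacks[period]
                stack = stacks[g % len(stacks)]
                surf, _ = project_model(model, stack)
                suit = surf.valid_mask & (surf.values >= t)
                stable = suit if stable is None else (stable & suit)
                if template is None:
                    template = surf
            combo_maps.append(stable)
    share = np.mean(combo_maps, axis=0)
    vals = (share >= quorum - 1e-12).astype(float)
    vals[~template.valid_mask] = template.nodata
    return template.with_values(vals)
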