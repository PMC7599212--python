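"""The modelling protocol: candidate enumeration over the tuning grid
(feature classes x regularization multipliers x occurrence filtering x bias
variants), model selection, single-descriptor models with permutation
importance, hybrid-model assembly under a correlation cap, and prey
suitability layers.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import BiasGrid, OccurrenceSet, RasterGrid, RasterStack, correlation_prune
from .maxent import (
    EvalReport,
    FittedModel,
    MaxentConfig,
    ThresholdSet,
    evaluate_candidate,
    permutation_importance_table,
    predict_raw,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "CandidateConfig",
    "CandidateResult",
    "HybridSpec",
    "enumerate_candidates",
    "select_best",
    "run_candidates",
    "run_single_descriptor",
    "assemble_hybrid",
    "prey_suitability_layers",
]


@dataclass(frozen=True)
class TuningGrid:
    """The candidate-model tuning factors; the default grid enumerates
    3 feature classes x 2 RMs x 2 filtered datasets x 2 bias variants = 24
    candidate models per species."""

    feature_classes: tuple = ("L", "LQ", "AUTO")
    rms: tuple = (1.0, 2.0)
    datasets: tuple = ("RD", "RDbal")
    bias_variants: tuple = ("BM01", "BM001")

    @property
    def n_candidates(self) -> int:
        return (
            len(self.feature_classes)
            * len(self.rms)
            * len(self.datasets)
            * len(self.bias_variants)
        )


@dataclass(frozen=True)
class CandidateConfig:
    feature_class: str
    rm: float
    dataset: str
    bias_variant: str

    @property
    def config_id(self) -> str:
        rm = int(self.rm) if float(self.rm).is_integer() else self.rm
        return f"{self.feature_class}_RM{rm}_{self.dataset}_{self.bias_variant}"


def enumerate_candidates(grid: TuningGrid) -> list[CandidateConfig]:
    """Cartesian product of the tuning factors, in stable declared order."""
    return [
        CandidateConfig(fc, rm, ds, bv)
        for fc, rm, ds, bv in itertools.product(
            grid.feature_classes, grid.rms, grid.datasets, grid.bias_variants
        )
    ]


@dataclass
class CandidateResult:
    config: CandidateConfig
    report: EvalReport
    models: list[FittedModel]

    @property
    def config_id(self) -> str:
        return self.config.config_id

    @property
    def mean_thresholds(self) -> dict[str, float]:
        ts = self.report.thresholds
        return {
            "MTP": float(np.mean([t.mtp for t in ts])),
            "P10": float(np.mean([t.p10 for t in ts])),
            "ETS": float(np.mean([t.ets for t in ts])),
        }


def select_best(
    candidates: list[CandidateResult],
    auc_floor: float = 0.7,
    ranking: tuple[str, str] = ("omission", "auc_diff"),
) -> list[CandidateResult]:
    """Model selection: keep candidates with mean AUCtest above the floor,
    rank survivors lexicographically by (mean omission across the three
    thresholds, mean AUCdiff) ascending — or the reverse ordering via
    ``ranking`` — break ties by higher AUCtest then config id, and return
    ALL tied-best candidates (the averaged "best models" set may be plural).
    """
    if set(ranking) != {"omission", "auc_diff"}:
        raise ValueError("ranking must order 'omission' and 'auc_diff'")
    surviving = [c for c in candidates if c.report.mean("auc_test") > auc_floor]
    if not surviving:
        logger.warning("no candidate exceeded the AUCtest floor %.2f", auc_floor)
        return []

    def key(c: CandidateResult):
        parts = {
            "omission": round(c.report.mean_omission_all, 12),
            "auc_diff": round(c.report.mean("auc_diff"), 12),
        }
        return (parts[ranking[0]], parts[ranking[1]],
                -round(c.report.mean("auc_test"), 12))

    ranked = sorted(surviving, key=lambda c: (*key(c), c.config_id))
    best_key = key(ranked[0])
    return [c for c in ranked if key(c) == best_key]


def run_candidates(
    stack: RasterStack,
    datasets: dict[str, OccurrenceSet],
    bias_grids: dict[str, BiasGrid],
    grid: TuningGrid,
    base_config: MaxentConfig,
    seed: int,
) -> list[CandidateResult]:
    """Evaluate every candidate of the tuning grid.

    ``datasets`` maps dataset label (RD/RDbal) to the filtered occurrences;
    ``bias_grids`` maps bias variant to its grid.  Each candidate is the
    replicate-evaluated combination of one dataset, one bias variant and one
    (feature class, RM) setting.
    """
    results = []
    for cand in enumerate_candidates(grid):
        if cand.dataset not in datasets:
            raise KeyError(f"dataset '{cand.dataset}' not provided")
        if cand.bias_variant not in bias_grids:
            raise KeyError(f"bias variant '{cand.bias_variant}' not provided")
        cfg = replace(base_config, feature_class=cand.feature_class, rm=cand.rm)
        occ = datasets[cand.dataset]
        report, models = evaluate_candidate(
            stack, occ.cells, cfg, seed, bias=bias_grids[cand.bias_variant].grid
        )
        results.append(CandidateResult(cand, report, models))
    return results


def candidate_table(results: list[CandidateResult]) -> pd.DataFrame:
    rows = []
    for c in results:
        r = c.report
        rows.append(
            {
                "config_id": c.config_id,
                "feature_class": c.config.feature_class,
                "rm": c.config.rm,
                "dataset": c.config.dataset,
                "bias_variant": c.config.bias_variant,
                "auc_train_mean": r.mean("auc_train"),
                "auc_test_mean": r.mean("auc_test"),
                "auc_test_sd": r.sd("auc_test"),
                "auc_diff_mean": r.mean("auc_diff"),
                "omission_mtp_mean": r.mean("MTP"),
                "omission_p10_mean": r.mean("P10"),
                "omission_ets_mean": r.mean("ETS"),
                "specificity_p10_mean": r.mean("specificity_p10"),
                "sedi_p10_mean": r.mean("sedi_p10"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SingleDescriptorResult:
    descriptor: str
    retained_variables: list[str]
    candidates: list[CandidateResult] | None  # None when descriptor skipped
    best: list[CandidateResult]
    importance: pd.Series  # mean permutation importance, sums to 100
    univariate_auc: pd.Series
    skipped: bool = False


def run_single_descriptor(
    descriptor: str,
    stack: RasterStack,
    datasets: dict[str, OccurrenceSet],
    bias_grids: dict[str, BiasGrid],
    grid: TuningGrid,
    base_config: MaxentConfig,
    seed: int,
    prune_threshold: float = 0.65,
    priority: list[str] | None = None,
) -> SingleDescriptorResult:
    """Model one environmental descriptor on its own.

    Variables are correlation-pruned (|r| > 0.65 drops the lower-priority
    one), the tuning grid is evaluated, permutation importances are averaged
    over the best models' replicates, and a univariate AUCtest cross-check is
    fitted per retained variable.  A descriptor with a single variable is
    skipped: the variable passes through with importance 100.
    """
    names = stack.by_descriptor(descriptor)
    if not names:
        raise ValueError(f"no variables with descriptor '{descriptor}'")
    rd = datasets["RD"] if "RD" in datasets else next(iter(datasets.values()))
    if len(names) == 1:
        return SingleDescriptorResult(
            descriptor, names, None, [],
            pd.Series({names[0]: 100.0}),
            pd.Series(dtype=float), skipped=True,
        )
    sub = stack.subset(names)
    bg_rows, bg_cols = np.nonzero(sub.valid_mask)
    rng = np.random.default_rng(seed)
    take = rng.choice(len(bg_rows), size=min(5000, len(bg_rows)), replace=False)
    sample_cells = np.column_stack([bg_rows[take], bg_cols[take]])
    retained = correlation_prune(sub, sample_cells, prune_threshold, priority or names)
    pruned = stack.subset(retained)

    results = run_candidates(pruned, datasets, bias_grids, grid, base_config, seed)
    best = select_best(results)
    ranked_source = best if best else results
    tables = []
    for c in ranked_source:
        for k, model in enumerate(c.models):
            tables.append(permutation_importance_table(model, seed + k))
    imp = pd.DataFrame(tables).mean()
    imp = 100.0 * imp / imp.sum() if imp.sum() > 0 else imp

    uni_auc = {}
    uni_cfg = replace(base_config, feature_class="L", rm=1.0)
    for v in retained:
        rep, _ = evaluate_candidate(
            stack.subset([v]), rd.cells, uni_cfg, seed,
            bias=bias_grids[next(iter(bias_grids))].grid if bias_grids else None,
        )
        uni_auc[v] = rep.mean("auc_test")
    return SingleDescriptorResult(
        descriptor, retained, results, best, imp, pd.Series(uni_auc)
    )


@dataclass
class HybridSpec:
    """Variable set of the hybrid model: the most important variable(s) of
    each descriptor, filtered so no selected pair exceeds the correlation
    cap."""

    selected: list[str]
    max_pairwise_r: float
    source_importance: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("hybrid spec selected no variables")


def assemble_hybrid(
    importance_tables: dict[str, pd.Series],
    stack: RasterStack,
    sample_cells: np.ndarray,
    k_per_descriptor: int = 1,
    r_cap: float = 0.65,
) -> HybridSpec:
    """Assemble the hybrid variable set.

    Candidates are taken per descriptor in decreasing importance; globally,
    higher-importance variables are placed first and a candidate correlated
    > ``r_cap`` with an already-selected variable is discarded in favour of
    its descriptor's next-best variable.
    """
    queues = {
        d: list(s.sort_values(ascending=False).index)
        for d, s in importance_tables.items()
    }
    rank = {}
    for d, s in importance_tables.items():
        for v in s.index:
            rank[v] = float(s[v])
    all_vars = [v for q in queues.values() for v in q]
    X = stack.values_at(sample_cells[:, 0], sample_cells[:, 1], all_vars)
    col = {v: i for i, v in enumerate(all_vars)}

    def corr(a: str, b: str) -> float:
        xa, xb = X[:, col[a]], X[:, col[b]]
        if xa.std() == 0 or xb.std() == 0:
            return 0.0
        return float(np.corrcoef(xa, xb)[0, 1])

    selected: list[str] = []
    accepted_per_d = {d: 0 for d in queues}
    # process candidates in global importance order, honouring per-descriptor
    # quotas and falling back to the next variable on a correlation conflict
    candidates = sorted(
        [(rank[v], d, v) for d, q in queues.items() for v in q], reverse=True
    )
    for imp, d, v in candidates:
        if accepted_per_d[d] >= k_per_descriptor or v in selected:
            continue
        if all(abs(corr(v, s)) <= r_cap for s in selected):
            selected.append(v)
            accepted_per_d[d] += 1
    max_r = 0.0
    for i in range(len(selected)):
        for j in range(i + 1, len(selected)):
            max_r = max(max_r, abs(corr(selected[i], selected[j])))
    return HybridSpec(selected, max_r, dict(importance_tables))


def prey_suitability_layers(
    prey_occ: dict[str, OccurrenceSet],
    stack: RasterStack,
    config: MaxentConfig,
    seed: int,
    scale: str = "minmax",
) -> RasterStack | None:
    """Prey suitability predictors: one maxent fit per pooled body-size
    group, raw surface min-max scaled to [0, 1] (or left raw with
    scale="raw") and labelled with descriptor "prey"."""
    from .maxent import fit_maxent, sample_background

    layers = {}
    for group, occ in sorted(prey_occ.items()):
        if len(occ) < 5:
            logger.info("prey group '%s' too small (%d records); no layer", group, len(occ))
            continue
        bg, _ = sample_background(stack, config.n_background, seed)
        model = fit_maxent(stack, occ.cells, bg, config, seed)
        surf = predict_raw(model, stack)
        vals = surf.values.copy()
        valid = surf.valid_mask
        if scale == "minmax":
            lo, hi = vals[valid].min(), vals[valid].max()
            vals[valid] = (vals[valid] - lo) / (hi - lo) if hi > lo else 0.0
        layers[f"prey_{group}"] = surf.with_values(vals)
    if not layers:
        logger.warning("no prey group produced a layer")
        return None
    return RasterStack(layers, {n: "prey" for n in layers})
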