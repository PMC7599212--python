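"""Presence-background maximum-entropy niche model.

The model is the Gibbs distribution q_lambda(x) = exp(lambda . f(x)) / Z over
the cells of the modelled landscape, where f(x) are feature transforms
(linear, quadratic, product, hinge) of the environmental predictors and Z
normalizes over the training cell set (background plus presences).  Fitting
maximizes the mean log raw probability of the presence sample minus an L1
penalty sum_j beta_j |lambda_j|, the classic regularized maxent estimator for
presence-only data.  The "raw" output is q_lambda itself: the relative
probability that a cell contains a presence record; it sums to one over the
modelled cells.

The per-feature penalty scale is beta_j = RM * beta_fc(m) * sd_j / sqrt(m),
with m the training-presence count, sd_j the feature's background standard
deviation, and beta_fc(m) the canonical sample-size-interpolated default
regularization table of maxent-style SDM software (stored below as data and
configurable).  The L1 problem is made smooth by the positive/negative split
lambda = u - v (u, v >= 0) and solved with L-BFGS-B.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata

from .grid import RasterGrid, RasterStack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureBasis",
    "MaxentConfig",
    "FittedModel",
    "ThresholdSet",
    "EvalReport",
    "build_features",
    "fit_maxent",
    "predict_raw",
    "split_subsample",
    "compute_auc",
    "compute_thresholds",
    "omission_rate",
    "sedi",
    "permutation_importance",
    "permutation_importance_table",
    "evaluate_candidate",
]

# default regularization schedules, interpolated by training-presence count
BETA_TABLE_LQP = ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05])
BETA_TABLE_HINGE = ([0, 1], [0.5, 0.5])

# AUTO feature schedule by training-presence count m
AUTO_SCHEDULE = ((10, "L"), (15, "LQ"), (80, "LQH"), (np.inf, "LQHP"))

_EPS = 1e-6


def resolve_auto(m: int) -> str:
    for bound, fc in AUTO_SCHEDULE:
        if m < bound:
            return fc
    return "LQHP"


@dataclass
class MaxentConfig:
    """Tuning knobs of one candidate model."""

    feature_class: str = "AUTO"  # subset of L,Q,P,H or AUTO
    rm: float = 1.0  # regularization multiplier
    n_background: int = 10_000
    train_fraction: float = 0.7
    n_replicates: int = 10
    max_iterations: int = 5000
    tol: float = 1e-7
    bias_mode: str = "sampling"  # "sampling" | "weights"
    n_hinge_knots: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be > 0")
        if self.bias_mode not in ("sampling", "weights"):
            raise ValueError("bias_mode must be 'sampling' or 'weights'")


@dataclass
class FeatureBasis:
    """Feature expansion fitted on the background sample.

    Standardization (per-variable mean/sd) is computed on background only;
    hinge knots are interior background quantiles.  A constant variable keeps
    its (zero) linear feature but contributes no quadratic/product/hinge
    features.
    """

    variables: list[str]
    feature_class: str
    means: np.ndarray
    sds: np.ndarray
    hinge_knots: dict[str, list[float]] = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    feature_kinds: list[str] = field(default_factory=list)

    @classmethod
    def fit(
        cls,
        X_bg: np.ndarray,
        variables: list[str],
        feature_class: str,
        n_presences: int,
        n_hinge_knots: int = 4,
    ) -> "FeatureBasis":
        fc = resolve_auto(n_presences) if feature_class.upper() == "AUTO" else feature_class.upper()
        if not set(fc) <= set("LQPH") or not fc:
            raise ValueError(f"invalid feature class '{feature_class}'")
        means = X_bg.mean(axis=0)
        sds = X_bg.std(axis=0)
        const = sds == 0
        if const.any():
            bad = [v for v, c in zip(variables, const) if c]
            logger.warning("constant variable(s) %s: quadratic/hinge features dropped", bad)
        sds = np.where(const, 1.0, sds)
        basis = cls(list(variables), fc, means, sds)
        Z = (X_bg - means) / sds
        names, kinds = [], []
        if "L" in fc:
            names += [f"L({v})" for v in variables]
            kinds += ["lqp"] * len(variables)
        if "Q" in fc:
            for i, v in enumerate(variables):
                if not const[i]:
                    names.append(f"Q({v})")
                    kinds.append("lqp")
        if "P" in fc:
            for i in range(len(variables)):
                for j in range(i + 1, len(variables)):
                    if not const[i] and not const[j]:
                        names.append(f"P({variables[i]},{variables[j]})")
                        kinds.append("lqp")
        if "H" in fc:
            qs = np.linspace(0, 1, n_hinge_knots + 2)[1:-1]
            for i, v in enumerate(variables):
                if const[i]:
                    continue
                knots = np.unique(np.quantile(Z[:, i], qs)).tolist()
                basis.hinge_knots[v] = knots
                for k, knot in enumerate(knots):
                    names += [f"HF({v},{k})", f"HR({v},{k})"]
                    kinds += ["hinge", "hinge"]
        basis.feature_names = names
        basis.feature_kinds = kinds
        return basis

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        Z = (X - self.means) / self.sds
        const = np.array([self.sds[i] == 1.0 and np.all(X[:, i] == X[0, i] if len(X) else True)
                          for i in range(len(self.variables))])
        cols = []
        fc = self.feature_class
        kvar = {v: i for i, v in enumerate(self.variables)}
        for name in self.feature_names:
            kind, arg = name.split("(", 1)
            arg = arg[:-1]
            if kind == "L":
                cols.append(Z[:, kvar[arg]])
            elif kind == "Q":
                cols.append(Z[:, kvar[arg]] ** 2)
            elif kind == "P":
                a, b = arg.split(",")
                cols.append(Z[:, kvar[a]] * Z[:, kvar[b]])
            elif kind in ("HF", "HR"):
                v, k = arg.rsplit(",", 1)
                knot = self.hinge_knots[v][int(k)]
                z = Z[:, kvar[v]]
                if kind == "HF":
                    cols.append(np.clip(z - knot, 0, None))
                else:
                    cols.append(np.clip(knot - z, 0, None))
        if not cols:
            return np.empty((len(X), 0))
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "feature_class": self.feature_class,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "hinge_knots": self.hinge_knots,
            "feature_names": self.feature_names,
            "feature_kinds": self.feature_kinds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureBasis":
        return cls(
            d["variables"], d["feature_class"], np.asarray(d["means"]),
            np.asarray(d["sds"]), {k: list(v) for k, v in d["hinge_knots"].items()},
            list(d["feature_names"]), list(d["feature_kinds"]),
        )


def build_features(
    stack: RasterStack,
    cells: np.ndarray,
    feature_class: str,
    n_presences: int | None = None,
    n_hinge_knots: int = 4,
) -> tuple[FeatureBasis, np.ndarray]:
    """Fit a feature basis on the environment at ``cells`` (background) and
    return it with the design matrix."""
    X = stack.values_at(cells[:, 0], cells[:, 1])
    m = n_presences if n_presences is not None else len(cells)
    basis = FeatureBasis.fit(X, stack.names, feature_class, m, n_hinge_knots)
    return basis, basis.transform(X)


@dataclass
class FittedModel:
    """One trained maxent replicate, fully serializable."""

    basis: FeatureBasis
    coefficients: np.ndarray
    log_z: float  # log normalizer over the training cell set
    calibration_ranges: dict[str, tuple[float, float]]
    config: MaxentConfig
    presence_cells: np.ndarray
    background_cells: np.ndarray
    seed: int
    converged: bool = True
    train_X: np.ndarray | None = None  # raw env values, presences then background
    train_weights: np.ndarray | None = None

    @property
    def n_presences(self) -> int:
        return len(self.presence_cells)

    def linear_predictor(self, X_raw: np.ndarray) -> np.ndarray:
        return self.basis.transform(X_raw) @ self.coefficients

    def raw_on_training(self) -> np.ndarray:
        """Raw (Gibbs) probabilities over the training cell set; sums to 1."""
        eta = self.linear_predictor(self.train_X)
        w = self.train_weights
        p = w * np.exp(eta - eta.max())
        return p / p.sum()

    def to_json(self, path=None) -> str:
        doc = {
            "basis": self.basis.to_dict(),
            "coefficients": self.coefficients.tolist(),
            "log_z": self.log_z,
            "calibration_ranges": {k: list(v) for k, v in self.calibration_ranges.items()},
            "config": asdict(self.config),
            "presence_cells": self.presence_cells.tolist(),
            "background_cells": self.background_cells.tolist(),
            "seed": self.seed,
            "converged": self.converged,
        }
        s = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, doc: str) -> "FittedModel":
        d = json.loads(doc)
        return cls(
            basis=FeatureBasis.from_dict(d["basis"]),
            coefficients=np.asarray(d["coefficients"]),
            log_z=d["log_z"],
            calibration_ranges={k: tuple(v) for k, v in d["calibration_ranges"].items()},
            config=MaxentConfig(**d["config"]),
            presence_cells=np.asarray(d["presence_cells"], int).reshape(-1, 2),
            background_cells=np.asarray(d["background_cells"], int).reshape(-1, 2),
            seed=d["seed"],
            converged=d["converged"],
        )


def _beta_vector(basis: FeatureBasis, F_bg: np.ndarray, m: int, rm: float) -> np.ndarray:
    sd = F_bg.std(axis=0)
    beta = np.empty(len(basis.feature_names))
    for j, kind in enumerate(basis.feature_kinds):
        xs, ys = BETA_TABLE_LQP if kind == "lqp" else BETA_TABLE_HINGE
        beta[j] = np.interp(m, xs, ys)
    return rm * beta * np.maximum(sd, _EPS) / np.sqrt(max(m, 1))


def sample_background(
    stack: RasterStack,
    n_background: int,
    seed: int,
    bias: RasterGrid | None = None,
    bias_mode: str = "sampling",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw background cells and their weights.

    In "sampling" mode cells are drawn with probability proportional to the
    bias grid (uniform without one) and carry unit weights; in "weights" mode
    cells are drawn uniformly and the bias values become likelihood weights.
    """
    rng = np.random.default_rng(seed)
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    n = min(n_background, len(rows))
    if bias is not None and bias_mode == "sampling":
        p = np.clip(bias.values[rows, cols], 0, None)
        p = p / p.sum()
        idx = rng.choice(len(rows), size=n, replace=len(rows) < n_background, p=p)
        w = np.ones(n)
    else:
        idx = rng.choice(len(rows), size=n, replace=False)
        w = (
            np.clip(bias.values[rows[idx], cols[idx]], _EPS, None)
            if bias is not None and bias_mode == "weights"
            else np.ones(n)
        )
    return np.column_stack([rows[idx], cols[idx]]), w


def fit_maxent(
    stack: RasterStack,
    presence_cells: np.ndarray,
    background_cells: np.ndarray,
    config: MaxentConfig,
    seed: int,
    background_weights: np.ndarray | None = None,
) -> FittedModel:
    """Fit the penalized Gibbs model to presences against a background sample.

    Non-convergence at the iteration cap is flagged in the model metadata,
    not fatal.
    """
    presence_cells = np.asarray(presence_cells, int).reshape(-1, 2)
    background_cells = np.asarray(background_cells, int).reshape(-1, 2)
    m = len(presence_cells)
    if m < 5:
        raise ValueError(f"need at least 5 presences, got {m}")
    X_pres = stack.values_at(presence_cells[:, 0], presence_cells[:, 1])
    X_bg = stack.values_at(background_cells[:, 0], background_cells[:, 1])
    basis = FeatureBasis.fit(X_bg, stack.names, config.feature_class, m, config.n_hinge_knots)
    F_pres = basis.transform(X_pres)
    F_bg = basis.transform(X_bg)

    # the modelled cell set: background plus presences, presences unit-weighted
    X_all = np.vstack([X_pres, X_bg])
    F_all = np.vstack([F_pres, F_bg])
    if background_weights is None:
        background_weights = np.ones(len(background_cells))
    w_all = np.concatenate([np.ones(m), background_weights])
    w_all = w_all / w_all.sum()

    beta = _beta_vector(basis, F_bg, m, config.rm)
    fbar = F_pres.mean(axis=0)
    p = F_all.shape[1]

    def objective(uv: np.ndarray):
        lam = uv[:p] - uv[p:]
        eta = F_all @ lam
        cmax = eta.max()
        ez = w_all * np.exp(eta - cmax)
        z = ez.sum()
        logz = np.log(z) + cmax
        nll = -fbar @ lam + logz
        grad_lam = -fbar + (ez @ F_all) / z
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return nll + beta @ np.abs(lam), grad

    x0 = np.zeros(2 * p)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": config.max_iterations, "ftol": config.tol, "gtol": 1e-9},
    )
    lam = res.x[:p] - res.x[p:]
    eta = F_all @ lam
    cmax = eta.max()
    log_z = np.log((w_all * np.exp(eta - cmax)).sum()) + cmax
    # calibration range = full current-conditions range of the study area,
    # so projecting onto the calibration stack never flags non-analog cells
    ranges = {}
    for v in stack.names:
        g = stack.layers[v]
        vv = g.valid_values()
        ranges[v] = (float(vv.min()), float(vv.max()))
    return FittedModel(
        basis=basis,
        coefficients=lam,
        log_z=log_z,
        calibration_ranges=ranges,
        config=config,
        presence_cells=presence_cells,
        background_cells=background_cells,
        seed=seed,
        converged=bool(res.success),
        train_X=X_all,
        train_weights=w_all,
    )


def predict_raw(model: FittedModel, stack: RasterStack) -> RasterGrid:
    """Raw suitability surface on a target stack, renormalized so the valid
    cells sum to one."""
    missing = [v for v in model.basis.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack missing model variable(s): {missing}")
    sub = stack.subset(model.basis.variables)
    valid = sub.valid_mask
    rows, cols = np.nonzero(valid)
    if len(rows) == 0:
        raise ValueError("target stack has no valid cells")
    X = sub.values_at(rows, cols)
    eta = model.linear_predictor(X)
    p = np.exp(eta - eta.max())
    p /= p.sum()
    ref = sub.first
    out = np.full(ref.shape, ref.nodata)
    out[rows, cols] = p
    return RasterGrid(out, ref.transform, ref.crs, ref.nodata)


def split_subsample(
    n: int, train_fraction: float, n_replicates: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent random train/test index partitions (subsample replication)."""
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    out = []
    for _ in range(n_replicates):
        perm = rng.permutation(n)
        out.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return out


def compute_auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(presence score > background score) + half ties
    (the Mann-Whitney statistic with midranks)."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


@dataclass
class ThresholdSet:
    """Presence thresholds on the raw-output scale."""

    mtp: float
    p10: float
    ets: float

    def as_dict(self) -> dict:
        return {"MTP": self.mtp, "P10": self.p10, "ETS": self.ets}


def _p10_threshold(train_scores: np.ndarray) -> float:
    """Largest observed training score whose omission (scores strictly below)
    is at most 10% of the training presences."""
    s = np.sort(np.asarray(train_scores, float))
    n = s.size
    if n < 10:
        warnings.warn("fewer than 10 training presences: P10 falls back to MTP")
        return float(s[0])
    best = s[0]
    for t in np.unique(s):
        if (s < t).mean() <= 0.10:
            best = t
    return float(best)


def compute_thresholds(
    train_presence_scores: np.ndarray,
    test_presence_scores: np.ndarray,
    background_scores: np.ndarray,
) -> ThresholdSet:
    """MTP (minimum training presence), P10 (10th-percentile training
    presence) and ETS (equal test sensitivity and specificity, brute-forced
    over the observed score values)."""
    train = np.asarray(train_presence_scores, float)
    test = np.asarray(test_presence_scores, float)
    bg = np.asarray(background_scores, float)
    mtp = float(train.min())
    p10 = _p10_threshold(train)
    cand = np.unique(np.concatenate([test, bg]))
    best_t, best_gap = cand[0], np.inf
    for t in cand:
        sens = (test >= t).mean()
        spec = (bg < t).mean()
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_gap, best_t = gap, t
    return ThresholdSet(mtp=mtp, p10=p10, ets=float(best_t))


def omission_rate(test_presence_scores: np.ndarray, threshold: float) -> float:
    """Fraction of test presences scored strictly below the threshold."""
    s = np.asarray(test_presence_scores, float)
    if s.size == 0:
        raise ValueError("no test presences")
    return float((s < threshold).mean())


def sedi(hit_rate: float, false_alarm_rate: float) -> float:
    """Symmetric extremal dependence index from hit rate H and false-alarm
    rate F; boundary rates are clamped to [1e-6, 1 - 1e-6] with a warning."""
    h, f = float(hit_rate), float(false_alarm_rate)
    if not (0 < h < 1) or not (0 < f < 1):
        warnings.warn("boundary hit/false-alarm rate clamped for SEDI")
        h = min(max(h, _EPS), 1 - _EPS)
        f = min(max(f, _EPS), 1 - _EPS)
    num = np.log(f) - np.log(h) - np.log1p(-f) + np.log1p(-h)
    den = np.log(f) + np.log(h) + np.log1p(-f) + np.log1p(-h)
    return float(num / den)


def permutation_importance_table(model: FittedModel, seed: int) -> dict[str, float]:
    """Permutation importance of every model variable, normalized to sum 100.

    Each variable's raw values are permuted across the training presence +
    background points, training AUC is recomputed, and the drop
    max(0, AUC - AUC_permuted) is the raw importance.
    """
    if model.train_X is None:
        raise ValueError("model was deserialized without training data")
    rng = np.random.default_rng(seed)
    m = model.n_presences
    eta = model.linear_predictor(model.train_X)
    auc0 = compute_auc(eta[:m], eta[m:])
    raw = {}
    for i, v in enumerate(model.basis.variables):
        Xp = model.train_X.copy()
        Xp[:, i] = rng.permutation(Xp[:, i])
        eta_p = model.linear_predictor(Xp)
        raw[v] = max(0.0, auc0 - compute_auc(eta_p[:m], eta_p[m:]))
    total = sum(raw.values())
    if total == 0:
        logger.warning("all permutation importances zero; returning zeros")
        return {v: 0.0 for v in raw}
    return {v: 100.0 * x / total for v, x in raw.items()}


def permutation_importance(model: FittedModel, variable: str, seed: int) -> float:
    table = permutation_importance_table(model, seed)
    if variable not in table:
        raise KeyError(f"variable '{variable}' not in model")
    return table[variable]


@dataclass
class EvalReport:
    """Replicate-level and aggregated evaluation of one candidate config."""

    auc_train: list[float]
    auc_test: list[float]
    omission: dict[str, list[float]]  # per threshold kind
    specificity_p10: list[float]
    sedi_p10: list[float]
    thresholds: list[ThresholdSet]

    @property
    def auc_diff(self) -> list[float]:
        return [a - b for a, b in zip(self.auc_train, self.auc_test)]

    def mean(self, what: str) -> float:
        vals = {
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "auc_diff": self.auc_diff,
            "specificity_p10": self.specificity_p10,
            "sedi_p10": self.sedi_p10,
        }
        if what in vals:
            return float(np.mean(vals[what]))
        return float(np.mean(self.omission[what]))

    def sd(self, what: str) -> float:
        vals = {
            "auc_train": self.auc_train,
            "auc_test": self.auc_test,
            "auc_diff": self.auc_diff,
            "specificity_p10": self.specificity_p10,
            "sedi_p10": self.sedi_p10,
        }
        arr = vals[what] if what in vals else self.omission[what]
        return float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0

    @property
    def mean_omission_all(self) -> float:
        """Mean omission across the three threshold kinds and replicates."""
        return float(np.mean([np.mean(self.omission[k]) for k in ("MTP", "P10", "ETS")]))


def evaluate_candidate(
    stack: RasterStack,
    occ_cells: np.ndarray,
    config: MaxentConfig,
    seed: int,
    bias: RasterGrid | None = None,
) -> tuple[EvalReport, list[FittedModel]]:
    """Run the replicate loop for one candidate configuration.

    Each replicate draws its own train/test split and background sample,
    fits, and is scored on the held-out presences: AUCs, omission at
    MTP/P10/ETS, and specificity and SEDI at P10 (background treated as
    pseudo-absence).
    """
    occ_cells = np.asarray(occ_cells, int).reshape(-1, 2)
    n = len(occ_cells)
    splits = split_subsample(n, config.train_fraction, config.n_replicates, seed)
    report = EvalReport([], [], {"MTP": [], "P10": [], "ETS": []}, [], [], [])
    models = []
    for r, (tr, te) in enumerate(splits):
        rep_seed = seed + 1000 * (r + 1)
        bg_cells, bg_w = sample_background(
            stack, config.n_background, rep_seed, bias, config.bias_mode
        )
        model = fit_maxent(stack, occ_cells[tr], bg_cells, config, rep_seed,
                           background_weights=bg_w if config.bias_mode == "weights" else None)
        # score cells on the raw (normalized) surface so thresholds are
        # directly comparable to predicted maps downstream
        surface = predict_raw(model, stack)
        eta_tr = surface.values[occ_cells[tr][:, 0], occ_cells[tr][:, 1]]
        eta_te = surface.values[occ_cells[te][:, 0], occ_cells[te][:, 1]]
        eta_bg = surface.values[bg_cells[:, 0], bg_cells[:, 1]]
        report.auc_train.append(compute_auc(eta_tr, eta_bg))
        report.auc_test.append(compute_auc(eta_te, eta_bg))
        ts = compute_thresholds(eta_tr, eta_te, eta_bg)
        report.thresholds.append(ts)
        for kind, t in ts.as_dict().items():
            report.omission[kind].append(omission_rate(eta_te, t))
        spec = float((eta_bg < ts.p10).mean())
        hit = float((eta_te >= ts.p10).mean())
        report.specificity_p10.append(spec)
        report.sedi_p10.append(sedi(hit, 1 - spec))
        models.append(model)
    return report, models
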