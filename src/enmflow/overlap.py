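"""Niche overlap in geographic and environmental space, and the niche
equivalency / similarity permutation tests.

Overlap metrics: Schoener's D = 1 - 0.5 * sum |p - q| and the Hellinger-based
I = 1 - 0.5 * sum (sqrt(p) - sqrt(q))^2, both on distributions normalized over
a shared cell set.  Environmental-space densities follow the
occurrence-density-grid approach: background environments are projected onto
the first two principal axes (axes fitted on the pooled background of all
compared species), occurrence and availability densities are kernel-smoothed
on an R x R grid, and occupancy is the availability-corrected, renormalized
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA

from .grid import OccurrenceSet, RasterGrid, RasterStack

__all__ = [
    "schoener_d",
    "hellinger_i",
    "OverlapResult",
    "geographic_overlap",
    "EnvSpace",
    "EnvDensityGrid",
    "env_density",
    "PermTestResult",
    "equivalency_test",
    "similarity_test",
]


def _as_distribution(x: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(x, float).ravel()
    if (v < 0).any():
        raise ValueError(f"{name} has negative mass")
    s = v.sum()
    if s <= 0:
        raise ValueError(f"{name} has zero total mass")
    if abs(s - 1.0) > 1e-9:
        warnings.warn(f"{name} not normalized (sum={s:.6g}); normalizing")
        v = v / s
    return v


def schoener_d(p: np.ndarray, q: np.ndarray) -> float:
    """Schoener's D in [0, 1]; 1 iff the distributions are identical."""
    p = _as_distribution(p, "p")
    q = _as_distribution(q, "q")
    if p.shape != q.shape:
        raise ValueError("distributions must share the same cell set")
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_i(p: np.ndarray, q: np.ndarray) -> float:
    """The modified Hellinger overlap I = 1 - H^2/2 in [0, 1]."""
    p = _as_distribution(p, "p")
    q = _as_distribution(q, "q")
    if p.shape != q.shape:
        raise ValueError("distributions must share the same cell set")
    return float(1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum())


@dataclass
class OverlapResult:
    """Pairwise D and I between two best-model sets: mean ± sd over all
    model-pair combinations (sd is 0, flagged, when only one pair exists)."""

    d_mean: float
    d_sd: float
    i_mean: float
    i_sd: float
    n_pairs: int
    sd_defined: bool

    def as_dict(self) -> dict:
        return {
            "D_mean": self.d_mean, "D_sd": self.d_sd,
            "I_mean": self.i_mean, "I_sd": self.i_sd,
            "n_pairs": self.n_pairs, "sd_defined": self.sd_defined,
        }


def geographic_overlap(
    surfaces_a: list[RasterGrid] | RasterGrid,
    surfaces_b: list[RasterGrid] | RasterGrid,
) -> OverlapResult:
    """Overlap between raw prediction surfaces, renormalized over the
    intersection of their valid cells; all pairwise combinations of the two
    model sets are summarized as mean ± sd."""
    la = [surfaces_a] if isinstance(surfaces_a, RasterGrid) else list(surfaces_a)
    lb = [surfaces_b] if isinstance(surfaces_b, RasterGrid) else list(surfaces_b)
    if not la or not lb:
        raise ValueError("both model sets must be nonempty")
    ds, is_ = [], []
    for a in la:
        for b in lb:
            if a.shape != b.shape:
                raise ValueError("surfaces must share a grid")
            mask = a.valid_mask & b.valid_mask
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds.append(schoener_d(a.values[mask], b.values[mask]))
                is_.append(hellinger_i(a.values[mask], b.values[mask]))
    n = len(ds)
    return OverlapResult(
        d_mean=float(np.mean(ds)),
        d_sd=float(np.std(ds, ddof=1)) if n > 1 else 0.0,
        i_mean=float(np.mean(is_)),
        i_sd=float(np.std(is_, ddof=1)) if n > 1 else 0.0,
        n_pairs=n,
        sd_defined=n > 1,
    )


@dataclass
class EnvDensityGrid:
    """Availability-corrected occurrence density over the 2-D environmental
    space; sums to one."""

    density: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray


class EnvSpace:
    """Shared 2-D environmental ordination for a set of compared species.

    Fitted once on the pooled background environments; every density grid for
    the comparison is built inside this space so the axes and availability
    are common to all species.

    Parameters
    ----------
    background_env:
        (n_cells, k) matrix of background environments of the whole study
        area (pooled across the compared species' areas).
    r:
        grid resolution per axis (default 100).
    mode:
        "pca" (default) projects onto the first two principal axes;
        "raw" uses the first two variables as-is.
    """

    def __init__(self, background_env: np.ndarray, r: int = 100, mode: str = "pca"):
        bg = np.asarray(background_env, float)
        if bg.ndim != 2 or bg.shape[1] < 2:
            raise ValueError("background_env must be (n, k>=2)")
        self.r = int(r)
        self.mode = mode
        if mode == "pca":
            self._pca = PCA(n_components=2, random_state=0)
            scores = self._pca.fit_transform(bg)
        elif mode == "raw":
            self._pca = None
            scores = bg[:, :2]
        else:
            raise ValueError("mode must be 'pca' or 'raw'")
        pad = 1e-9
        self.edges_x = np.linspace(scores[:, 0].min() - pad, scores[:, 0].max() + pad, r + 1)
        self.edges_y = np.linspace(scores[:, 1].min() - pad, scores[:, 1].max() + pad, r + 1)
        self.n_background = len(bg)
        self._avail = self._smooth_hist(scores)
        # availability floor guards against division blow-ups in empty bins
        self.eps = 1.0 / (10.0 * self.n_background)

    def project(self, env: np.ndarray) -> np.ndarray:
        env = np.asarray(env, float)
        return self._pca.transform(env) if self._pca is not None else env[:, :2]

    def _smooth_hist(self, scores: np.ndarray) -> np.ndarray:
        h, _, _ = np.histogram2d(
            np.clip(scores[:, 0], self.edges_x[0], self.edges_x[-1]),
            np.clip(scores[:, 1], self.edges_y[0], self.edges_y[-1]),
            bins=[self.edges_x, self.edges_y],
        )
        n = max(len(scores), 2)
        # Scott's rule per axis, converted to bin units
        sigmas = []
        for ax, edges in ((0, self.edges_x), (1, self.edges_y)):
            sd = scores[:, ax].std()
            bw = sd * n ** (-1.0 / 6.0) if sd > 0 else 1.0
            binw = edges[1] - edges[0]
            sigmas.append(max(bw / binw, 0.5))
        sm = gaussian_filter(h, sigma=sigmas, mode="constant")
        s = sm.sum()
        return sm / s if s > 0 else sm

    def density(self, env: np.ndarray) -> EnvDensityGrid:
        """Availability-corrected occupancy density of a point sample."""
        env = np.asarray(env, float)
        if len(env) < 3:
            raise ValueError("need at least 3 occurrences for a density grid")
        occ = self._smooth_hist(self.project(env))
        z = occ / np.maximum(self._avail, self.eps)
        z = z / z.sum()
        return EnvDensityGrid(z, self.edges_x, self.edges_y)


def env_density(
    occ: OccurrenceSet,
    background_cells: np.ndarray,
    stack: RasterStack,
    r: int = 100,
    mode: str = "pca",
    space: EnvSpace | None = None,
) -> EnvDensityGrid:
    """Occurrence density of one species in environmental space.

    When several species are compared, pass a pre-fitted shared ``space`` so
    axes and availability are common; otherwise a space is fitted on the
    given background cells.
    """
    bg_env = stack.values_at(background_cells[:, 0], background_cells[:, 1])
    if space is None:
        space = EnvSpace(bg_env, r=r, mode=mode)
    cells = occ.cells
    occ_env = stack.values_at(cells[:, 0], cells[:, 1])
    return space.density(occ_env)


@dataclass
class PermTestResult:
    """Observed overlap, permutation nulls and p-values for both metrics."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_value: dict[str, float]
    n: int
    seed: int
    direction: str = ""

    def __post_init__(self) -> None:
        for k, v in self.null.items():
            if len(v) != self.n:
                raise ValueError("null length must equal n")


def _metrics(za: EnvDensityGrid, zb: EnvDensityGrid) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "D": schoener_d(za.density, zb.density),
            "I": hellinger_i(za.density, zb.density),
        }


def equivalency_test(
    env_a: np.ndarray,
    env_b: np.ndarray,
    space: EnvSpace,
    n: int = 1000,
    seed: int = 0,
) -> PermTestResult:
    """Niche equivalency: pool both species' occurrence environments, resplit
    at random preserving the original sample sizes, and recompute the overlap
    each time.  The p-value is one-sided for lower-than-null overlap,
    (1 + #{null <= observed}) / (n + 1)."""
    if n < 100:
        warnings.warn("fewer than 100 permutation replicates: p-values unstable")
    rng = np.random.default_rng(seed)
    env_a = np.asarray(env_a, float)
    env_b = np.asarray(env_b, float)
    observed = _metrics(space.density(env_a), space.density(env_b))
    pooled = np.vstack([env_a, env_b])
    na = len(env_a)
    null = {"D": np.empty(n), "I": np.empty(n)}
    for i in range(n):
        perm = rng.permutation(len(pooled))
        m = _metrics(space.density(pooled[perm[:na]]), space.density(pooled[perm[na:]]))
        null["D"][i] = m["D"]
        null["I"][i] = m["I"]
    p = {k: float((1 + (null[k] <= observed[k]).sum()) / (n + 1)) for k in null}
    return PermTestResult(observed, null, p, n, seed)


def similarity_test(
    env_a: np.ndarray,
    env_b: np.ndarray,
    background_env_b: np.ndarray,
    space: EnvSpace,
    n: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> PermTestResult:
    """Niche similarity of species A against randomized B.

    Each null replicate draws |B| random cells from B's available study-area
    background, rebuilds B's occupancy density and recomputes the overlap
    with the observed A density.  The default p-value is one-sided for
    greater-than-null overlap (niches more similar than chance); the lower
    tail is available via ``alternative='less'``.  The test is directional:
    call it once per direction (swap A and B) for the paired comparison.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if n < 100:
        warnings.warn("fewer than 100 permutation replicates: p-values unstable")
    rng = np.random.default_rng(seed)
    env_a = np.asarray(env_a, float)
    env_b = np.asarray(env_b, float)
    bg_b = np.asarray(background_env_b, float)
    za = space.density(env_a)
    observed = _metrics(za, space.density(env_b))
    nb = len(env_b)
    null = {"D": np.empty(n), "I": np.empty(n)}
    for i in range(n):
        idx = rng.choice(len(bg_b), size=nb, replace=nb > len(bg_b))
        m = _metrics(za, space.density(bg_b[idx]))
        null["D"][i] = m["D"]
        null["I"][i] = m["I"]
    if alternative == "greater":
        p = {k: float((1 + (null[k] >= observed[k]).sum()) / (n + 1)) for k in null}
    else:
        p = {k: float((1 + (null[k] <= observed[k]).sum()) / (n + 1)) for k in null}
    return PermTestResult(observed, null, p, n, seed, direction="A_vs_randomB")
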