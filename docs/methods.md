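# Methods

This note documents the models and procedures implemented in `enmflow`,
the defaults and why they were chosen, the numerical decisions, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The maximum-entropy niche model

`enmflow.maxent` implements the presence–background maximum-entropy SDM as
a penalized Gibbs model. The modelled cell set is the union of the
training presences and a background sample; the raw output is

    q_λ(x) = exp(λ·f(x)) / Z,   Z = Σ_c w_c exp(λ·f(c)),

normalized over that set at training time and renormalized over the valid
cells of whatever grid is predicted. Fitting minimizes the penalized
negative log-likelihood

    −(1/m) Σ_presences λ·f(x) + log Z + Σ_j β_j |λ_j|.

**Features.** L = standardized predictor values, Q = their squares,
P = pairwise products, H = forward/reverse hinges at interior background
quantiles (4 knots per variable per direction by default).
Standardization statistics and hinge knots are computed on the background
only. The AUTO class resolves by training-presence count `m`: `m`<10 → L,
10≤`m`<15 → LQ, 15≤`m`<80 → LQH, `m`≥80 → LQHP — the canonical
sample-size schedule of maxent-style SDM software, stored as data. A
constant variable keeps its (vacuous) linear term but contributes no
Q/P/H features.

**Penalty.** β_j = RM · β_fc(m) · sd_j/√m, where sd_j is the feature's
background standard deviation and β_fc interpolates the published default
schedule (L/Q/P: β 1→1→0.2→0.05 at m = 0/10/30/100; hinge: 0.5). RM
defaults to 1; the tuning grid explores {1, 2}.

**Optimizer.** The L1 term is made smooth by the split λ = u − v with
u, v ≥ 0, and the objective is minimized with L-BFGS-B (analytic
gradient), `ftol` 1e-7, iteration cap 5000. Non-convergence at the cap is
flagged in the model metadata, not fatal. The training-set normalization
(raw sums to 1 within 1e-6) is asserted by tests.

**Background and bias.** Default 10,000 background cells. Two bias modes
exist because presence-only effort correction can enter either way:
`sampling` (default) draws background cells with probability proportional
to the bias grid; `weights` draws uniformly and uses bias values as
weights in Z. The default was chosen because it mirrors the common
"bias-file" usage of target-group background sampling; both modes share
one code path and are covered by tests.

## Evaluation, thresholds, selection

Replication uses the subsample strategy: `n_replicates` (default 10)
independent random 70/30 presence splits, each with its own background
draw. AUC is the rank statistic P(presence > background) + ½P(tie),
computed with midranks; AUCdiff = AUCtrain − AUCtest measures overfitting.
Scores entering thresholds are taken from the full-grid renormalized raw
surface so thresholds are directly comparable to predicted maps.

- **MTP** = minimum training-presence score. Binarization uses `raw ≥ t`,
  so MTP gives zero training omission by construction.
- **P10** = the largest observed training score that omits at most 10% of
  training presences (the order-statistic convention of the common SDM
  toolchains; equivalently `sorted[floor(0.1 n)]` in the untied case).
  With fewer than 10 training presences it falls back to MTP with a
  warning.
- **ETS** = the observed score value minimizing |sensitivity(test) −
  specificity(background)|, found by brute force; ties take the smallest
  threshold. Specificity treats the background sample as pseudo-absences —
  the only option in a presence-only design, and a documented limitation.
- **SEDI** at P10 from hit rate H and false-alarm rate F:
  (ln F − ln H − ln(1−F) + ln(1−H)) / (ln F + ln H + ln(1−F) + ln(1−H)),
  with boundary rates clamped to 1e-6.

**Selection.** Candidates below mean AUCtest 0.7 are dropped; survivors
are ranked lexicographically by (mean omission across the three
thresholds, mean AUCdiff), ascending. Omission ranks first because the
two criteria need an order and low false-negative rates are the stated
priority; the reverse ordering is available by config. Ties (to 1e-12)
are broken by higher AUCtest, then config id, and *all* tied-best
candidates are returned — downstream overlap and coverage statistics
average over the best-model set.

**Permutation importance** permutes one variable's raw values across the
training presence+background points, recomputes training AUC, takes
max(0, drop), and normalizes importances to sum to 100.

## Protocol

The tuning grid is the Cartesian product of feature classes {L, LQ, AUTO},
RM {1, 2}, filtered datasets {RD, RDbal} and bias variants {BM01, BM001} —
24 candidates per species by default. RD keeps one random record per grid
cell; RDbal further equalizes per-region record density to the minimum
positive regional density (each region that had records keeps at least
one). The temporal filter keeps records strictly after the cutoff year
(default 1990, i.e. year ≥ 1991), reading "after" literally; the cutoff is
configurable. Bias grids take exactly two values: 1 in cells with at least
one record of any modelled species, and 0.1 (BM01) or 0.01 (BM001)
elsewhere.

Single-descriptor models are fitted per descriptor with more than one
variable, after greedy correlation pruning: variables are walked in
priority order and a candidate is dropped if |Pearson r| > 0.65 with an
already-retained variable (constant layers count as r = 0). The hybrid
model takes the top `k` variables per descriptor by mean permutation
importance (default k = 1 — descriptors contribute few variables each),
discarding any pick correlated > 0.65 with a higher-ranked pick in favour
of that descriptor's next variable, then re-runs the tuning grid on the
selected set. Prey-suitability predictors are maxent fits to prey
occurrences pooled by body mass (small ≤ 70 g < medium < 150 g ≤ large;
the boundary mass 150 g is assigned to "large" to close the partition),
min–max scaled to [0, 1] by default (raw scaling is available, since
there is no canonical convention for re-using SDM output as a predictor).

## Niche overlap and conservatism tests

Geographic overlap normalizes two raw surfaces over the intersection of
their valid cells and reports Schoener's D and Hellinger-based I; with
plural best models, all pairwise combinations are summarized as
mean ± sample sd.

Environmental-space comparisons use an occurrence-density ordination:
the pooled background environments of the compared species are projected
onto their first two principal components (a raw two-variable mode
exists); occurrence and availability densities are Gaussian-smoothed
histograms on an R×R grid (R = 100, bandwidth by Scott's rule per axis,
floored at half a bin); occupancy is occurrence density divided by
availability floored at ε = 1/(10·n_background), renormalized.

The **equivalency test** pools both species' occurrences and resplits at
random preserving sample sizes; the **similarity test** compares the
observed overlap to overlaps with |B| random cells drawn from B's
available background, run in both directions. p-values use the
(1 + count)/(n + 1) convention (never exactly 0), one-sided: lower tail
for equivalency (is overlap lower than random resplits?), upper tail for
similarity (is overlap higher than random placement?), with the opposite
tail available. Default 1000 permutations. Calibration (type-I error at
nominal α = 0.05 within [0, 0.10] over 200 runs of 199 permutations) is
verified by the acceptance suite.

## Conservation and time projection

Binary maps use `raw ≥ threshold`. Protected-area coverage is
(# predicted-presence cells that are protected)/(# predicted-presence
cells); cells are treated as equal-area (a documented simplification —
no latitude-dependent cell-area weighting). sd across models uses the
sample (n−1) denominator. GeoJSON protected areas with status "Proposed"
or "Not Reported" are excluded at read time. Polygon rasterization marks
a cell protected iff its center lies inside a polygon.

Climate-only models are projected per period per GCM; the raw surface is
renormalized over each scenario grid, and cells with any model variable
outside the calibration range — the full current-conditions range of the
study area, so projecting onto the calibration stack never flags
anything — are marked non-analog. The default analog policy keeps flagged
cells with a flag ("include"), following the project-everywhere-but-warn
practice; "exclude" and "zero" are available and both are exercised in
tests. Thresholds always come from the current-time fit, and trend
comparisons require identical grid shapes so raw values stay
commensurable. Refugia are cells suitable in all periods for at least a
quorum (default 90%) of model × GCM combinations; refugia nest as the
quorum rises.

## Synthetic landscapes

`enmflow.synth` builds every input with known ground truth. Random
fields are white noise smoothed by a Gaussian kernel of width
`autocorr_range` (default 3 cells, periodic boundaries), standardized,
and linearly mixed through the Cholesky factor of the target correlation
matrix — simple, dependency-light, and controllable; empirical
correlations land within ±0.1 of the target on grids ≥ 100×100. Regions
are a nearest-center partition (country-like blocks); land-cover
fractions are a softmax of smoothed fields (sum to 1 per cell). Species
records are drawn cell-wise with probability ∝ exp(linear + quadratic
score) × bias^bias_strength — the same Gibbs form the model fits, which
is what makes parameter recovery a meaningful check — with Poisson record
counts (mean = prevalence) and within-cell coordinate jitter. Protected
areas are random squares rescaled by bisection so the rasterized fraction
lands within ±0.05 of the request. Climate series copy the current
climatic layers exactly, then apply per-period additive/multiplicative
drift plus smooth per-GCM noise.

What the generator does **not** emulate: real geography and coastlines
(all cells are valid land by default), non-Gaussian predictor
distributions, spatially varying observation effort beyond a single bias
layer, temporal autocorrelation of records, label noise in species
identity, or GCM physics. Passing tests therefore demonstrate the
*procedures* are correct and well-calibrated under the generative
assumptions, not that any real species' niche is recovered.

## Problem sizes in tests and the acceptance script

The default study conditions (10,000 background points, 10 replicates,
1000 permutations) are what a production run uses. The test suite and
acceptance script run the same code on scaled problems chosen as the
smallest sizes at which each property is statistically meaningful:
60×60 landscapes, 2000–5000 background cells, 3 replicates, 199-permutation
nulls with 200 calibration runs, and 20-seed recovery/trend checks.

## Known limitations

- No logistic/cloglog output transforms: the raw (relative occurrence
  rate) scale is the only prediction output.
- No categorical features, no feature classes beyond LQPH, no clamping
  (non-analog cells are flagged/masked, never clamped).
- No reprojection engine: all layers must share one affine grid; CRS
  strings are carried and checked for equality only.
- Specificity/SEDI use background as pseudo-absence, inheriting the usual
  presence-only caveats.
- Coarse grids overpredict fine-scale occupancy; binary-map areas should
  be read as potential, not occupied, range.
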