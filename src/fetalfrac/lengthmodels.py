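"""Fetal-fraction estimators built on fragment-length profiles.

Fetal cfDNA fragments are shorter than maternal ones, so the 171-vector of
length proportions (50-220 bp) carries fetal-fraction signal.  Five
estimators are provided, each as a Model class whose ``fit()`` returns a
Results object carrying the estimates and diagnostics:

* ``FracRatioModel`` — the FRAC statistic: the ratio of summed proportions
  over a "short" interval I1 to those over a second interval I2, with an
  exhaustive search over consecutive-interval pairs for the pair best
  correlated with the reference FF, and an OLS calibration of the raw
  ratio to FF units.
* ``NonlinearRatioModel`` (NLRM) — per-length weights inside the FRAC
  numerator and denominator, estimated by quasi-Newton least squares:
  FF_i = sum_r M_r L_{r,i} / sum_p N_p L_{p,i}.  The ratio is invariant to
  rescaling all weights, so the first denominator weight is fixed to 1.
* ``LinearLengthModel`` (LRM) — ordinary least squares of FF on all 171
  proportions (minimum-norm on rank deficiency).
* ``SvrLengthModel`` — linear-kernel epsilon-insensitive support-vector
  regression on standardized proportions (C=1.0, epsilon=0.01, tol=0.001).
* ``MlpLengthModel`` — multilayer perceptron on standardized proportions,
  two tanh hidden layers of 25 units, adaptive-gradient training, seeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .fragio import DEFAULT_LENGTH_RANGE, Dataset, LengthProfile, Standardizer

#: interval pair proposed by the earlier short/long-ratio publication
PUBLISHED_INTERVALS_BOUNDS = ((100, 150), (163, 168))
#: interval pair reported optimal on a large clinical NIPT cohort
OPTIMAL_INTERVALS_BOUNDS = ((131, 134), (97, 153))

_TIE_TOL = 1e-12


class ZeroDenominatorError(ValueError):
    """A profile has no mass in the FRAC denominator interval."""


class ConvergenceError(RuntimeError):
    """Optimizer exhausted its iteration budget; carries best-so-far params."""

    def __init__(self, message: str, params=None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class IntervalPair:
    """Two consecutive-length intervals [a1,b1], [a2,b2] in bp; overlap allowed."""

    i1: tuple[int, int]
    i2: tuple[int, int]

    def __post_init__(self) -> None:
        for a, b in (self.i1, self.i2):
            if a > b:
                raise ValueError(f"interval [{a},{b}] has a > b")

    @property
    def total_width(self) -> int:
        return (self.i1[1] - self.i1[0] + 1) + (self.i2[1] - self.i2[0] + 1)

    def slices(self, length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE) -> tuple[slice, slice]:
        lo, hi = length_range
        for a, b in (self.i1, self.i2):
            if a < lo or b > hi:
                raise ValueError(f"interval [{a},{b}] outside profile range {length_range}")
        return (
            slice(self.i1[0] - lo, self.i1[1] - lo + 1),
            slice(self.i2[0] - lo, self.i2[1] - lo + 1),
        )

    def to_dict(self) -> dict:
        return {"i1": list(self.i1), "i2": list(self.i2)}

    @classmethod
    def from_dict(cls, d) -> "IntervalPair":
        return cls(tuple(d["i1"]), tuple(d["i2"]))


PUBLISHED_INTERVALS = IntervalPair(*PUBLISHED_INTERVALS_BOUNDS)
OPTIMAL_INTERVALS = IntervalPair(*OPTIMAL_INTERVALS_BOUNDS)


def _as_matrix(profiles) -> np.ndarray:
    if isinstance(profiles, Dataset):
        return profiles.profile_matrix()
    if isinstance(profiles, LengthProfile):
        return profiles.proportions[None, :]
    arr = np.asarray(profiles, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


# ---------------------------------------------------------------------------
# FRAC statistic and interval search
# ---------------------------------------------------------------------------

def frac_statistic(profiles, intervals: IntervalPair,
                   length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE):
    """Ratio of summed proportions over I1 to summed proportions over I2.

    Accepts a single LengthProfile (returns a float) or a profile matrix /
    Dataset (returns a vector).
    """
    X = _as_matrix(profiles)
    s1, s2 = intervals.slices(length_range)
    num = X[:, s1].sum(axis=1)
    den = X[:, s2].sum(axis=1)
    if np.any(den <= 0):
        bad = int(np.nonzero(den <= 0)[0][0])
        raise ZeroDenominatorError(
            f"sample index {bad}: zero mass in denominator interval {intervals.i2}"
        )
    ratio = num / den
    if isinstance(profiles, LengthProfile) or (
        not isinstance(profiles, Dataset) and np.asarray(profiles).ndim == 1
    ):
        return float(ratio[0])
    return ratio


def enumerate_intervals(bounds: tuple[int, int], min_width: int = 1,
                        stride: int = 1) -> list[tuple[int, int]]:
    """All consecutive intervals with endpoints on the stride grid."""
    lo, hi = bounds
    grid = list(range(lo, hi + 1, stride))
    return [(a, b) for a in grid for b in grid if b - a + 1 >= min_width]


def search_best_intervals(
    profiles,
    targets: Sequence[float],
    bounds: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    min_width: int = 1,
    stride: int = 1,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> tuple[IntervalPair, float]:
    """Exhaustively search consecutive-interval pairs for the pair whose
    FRAC ratio has maximal Pearson correlation with the targets.

    The winning pair maximizes the (signed) correlation; candidates tied
    within 1e-12 are broken by smaller total width, then lexicographic
    (a1, b1, a2, b2).  I1 and I2 may overlap.
    """
    X = _as_matrix(profiles)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("profiles and targets are not aligned")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate")
    lo = length_range[0]
    intervals = enumerate_intervals(bounds, min_width=min_width, stride=stride)
    if not intervals:
        raise ValueError("no candidate intervals for the given bounds/stride/min_width")
    # prefix sums: S[:, j] = sum of columns < j within the bounds window
    cum = np.concatenate(
        [np.zeros((X.shape[0], 1)), np.cumsum(X[:, bounds[0] - lo: bounds[1] - lo + 1], axis=1)],
        axis=1,
    )

    def isum(a: int, b: int) -> np.ndarray:
        return cum[:, b - bounds[0] + 1] - cum[:, a - bounds[0]]

    yc = y - y.mean()
    ynorm = np.sqrt((yc ** 2).sum())
    if ynorm == 0:
        raise ValueError("targets are constant; correlation undefined")

    den_sums = np.column_stack([isum(a, b) for a, b in intervals])  # N x K
    ok_den = (den_sums > 0).all(axis=0)

    best = None  # (corr, total_width, a1, b1, a2, b2)
    for (a1, b1) in intervals:
        num = isum(a1, b1)[:, None]  # N x 1
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = num / den_sums  # N x K
            rc = ratios - ratios.mean(axis=0)
            denom = np.sqrt((rc ** 2).sum(axis=0)) * ynorm
            corrs = (yc @ rc) / denom
        corrs = np.where(ok_den & (denom > 0), corrs, -np.inf)
        w1 = b1 - a1 + 1
        for k, (a2, b2) in enumerate(intervals):
            c = corrs[k]
            if not np.isfinite(c):
                continue
            cand = (c, w1 + (b2 - a2 + 1), a1, b1, a2, b2)
            if best is None or c > best[0] + _TIE_TOL:
                best = cand
            elif c >= best[0] - _TIE_TOL and cand[1:] < best[1:]:
                best = (best[0], *cand[1:]) if c < best[0] else cand
    if best is None:
        raise ValueError("all candidate correlations undefined (constant FRAC everywhere)")
    corr, _, a1, b1, a2, b2 = best
    return IntervalPair((a1, b1), (a2, b2)), float(corr)


# ---------------------------------------------------------------------------
# FRAC model (search + OLS calibration to FF units)
# ---------------------------------------------------------------------------

@dataclass
class FracCalibration:
    """OLS mapping raw FRAC ratio -> FF units."""

    slope: float
    intercept: float

    def predict(self, ratios) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ratios, dtype=float)


def fit_frac_calibration(frac_values: Sequence[float], targets: Sequence[float]) -> FracCalibration:
    x = np.asarray(frac_values, float)
    y = np.asarray(targets, float)
    if np.ptp(x) == 0:
        raise ValueError("FRAC values are constant; calibration undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return FracCalibration(slope=float(slope), intercept=float(intercept))


class FracRatioModel:
    """FRAC estimator: interval-ratio statistic calibrated to FF units.

    Parameters
    ----------
    endog : array-like
        Reference fetal fractions (training targets).
    exog : Dataset or (N, 171) array
        Length profiles.
    intervals : IntervalPair, optional
        Fixed intervals; when None, ``fit`` runs the exhaustive search.
    """

    def __init__(self, endog, exog, intervals: IntervalPair | None = None,
                 bounds: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                 min_width: int = 1, stride: int = 2,
                 length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE):
        self.endog = np.asarray(endog, float)
        self.exog = _as_matrix(exog)
        self.intervals = intervals
        self.bounds = bounds
        self.min_width = min_width
        self.stride = stride
        self.length_range = length_range

    @classmethod
    def from_dataset(cls, dataset: Dataset, target: str = "reference_ff", **kw):
        return cls(dataset.attribute(target), dataset, **kw)

    def fit(self) -> "FracRatioResults":
        intervals = self.intervals
        search_corr = None
        if intervals is None:
            intervals, search_corr = search_best_intervals(
                self.exog, self.endog, bounds=self.bounds,
                min_width=self.min_width, stride=self.stride,
                length_range=self.length_range)
        ratios = frac_statistic(self.exog, intervals, self.length_range)
        calibration = fit_frac_calibration(ratios, self.endog)
        return FracRatioResults(self, intervals, calibration, search_corr)


class FracRatioResults:
    def __init__(self, model: FracRatioModel, intervals: IntervalPair,
                 calibration: FracCalibration, search_correlation: float | None):
        self.model = model
        self.intervals = intervals
        self.calibration = calibration
        self.search_correlation = search_correlation
        fitted = self.predict(model.exog)
        self.resid = model.endog - fitted
        self.mse = float(np.mean(self.resid ** 2))

    @property
    def params(self) -> dict:
        return {"intervals": self.intervals.to_dict(),
                "slope": self.calibration.slope,
                "intercept": self.calibration.intercept}

    def ratio(self, exog) -> np.ndarray:
        return frac_statistic(exog, self.intervals, self.model.length_range)

    def predict(self, exog) -> np.ndarray:
        return self.calibration.predict(self.ratio(exog))

    def summary(self) -> str:
        lines = ["FRAC ratio model",
                 f"  I1 = [{self.intervals.i1[0]}, {self.intervals.i1[1]}] bp",
                 f"  I2 = [{self.intervals.i2[0]}, {self.intervals.i2[1]}] bp",
                 f"  calibration: FF = {self.calibration.intercept:+.5f} "
                 f"{self.calibration.slope:+.5f} * ratio",
                 f"  training MSE = {self.mse:.3e}"]
        if self.search_correlation is not None:
            lines.insert(1, f"  search correlation = {self.search_correlation:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# NLRM — weighted-ratio nonlinear regression
# ---------------------------------------------------------------------------

@dataclass
class NLRMParams:
    """Numerator weights M (over I1) and denominator weights N (over I2).

    Identifiability: the ratio is invariant to scaling all weights by the
    same constant, so ``denominator_weights[0]`` is fixed to 1 during
    fitting.
    """

    intervals: IntervalPair
    numerator_weights: np.ndarray
    denominator_weights: np.ndarray

    def __post_init__(self) -> None:
        self.numerator_weights = np.asarray(self.numerator_weights, float)
        self.denominator_weights = np.asarray(self.denominator_weights, float)
        k1 = self.intervals.i1[1] - self.intervals.i1[0] + 1
        k2 = self.intervals.i2[1] - self.intervals.i2[0] + 1
        if self.numerator_weights.shape != (k1,) or self.denominator_weights.shape != (k2,):
            raise ValueError("weight vectors do not match interval widths")
        if not (np.all(np.isfinite(self.numerator_weights))
                and np.all(np.isfinite(self.denominator_weights))):
            raise ValueError("non-finite weights")

    @classmethod
    def unit(cls, intervals: IntervalPair) -> "NLRMParams":
        k1 = intervals.i1[1] - intervals.i1[0] + 1
        k2 = intervals.i2[1] - intervals.i2[0] + 1
        return cls(intervals, np.ones(k1), np.ones(k2))

    def to_dict(self) -> dict:
        return {"intervals": self.intervals.to_dict(),
                "numerator_weights": self.numerator_weights.tolist(),
                "denominator_weights": self.denominator_weights.tolist()}

    @classmethod
    def from_dict(cls, d) -> "NLRMParams":
        return cls(IntervalPair.from_dict(d["intervals"]),
                   np.asarray(d["numerator_weights"], float),
                   np.asarray(d["denominator_weights"], float))


def predict_nlrm(profiles, params: NLRMParams,
                 length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE):
    """Weighted-ratio prediction sum(M*L_I1) / sum(N*L_I2)."""
    X = _as_matrix(profiles)
    s1, s2 = params.intervals.slices(length_range)
    num = X[:, s1] @ params.numerator_weights
    den = X[:, s2] @ params.denominator_weights
    if np.any(den == 0):
        raise ZeroDenominatorError("zero weighted denominator")
    out = num / den
    if isinstance(profiles, LengthProfile) or (
        not isinstance(profiles, Dataset) and np.asarray(profiles).ndim == 1
    ):
        return float(out[0])
    return out


class NonlinearRatioModel:
    """NLRM: per-length weights in the FRAC numerator and denominator.

    FF_i = sum_{r in I1} M_r L_{r,i} / sum_{p in I2} N_p L_{p,i} + eps_i,
    estimated by quasi-Newton (BFGS) least squares from the all-ones
    (FRAC-equivalent) start, with the first denominator weight fixed to 1.
    A quadratic penalty keeps every sample's weighted denominator away from
    zero during optimization.
    """

    def __init__(self, endog, exog, intervals: IntervalPair = OPTIMAL_INTERVALS,
                 length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE):
        self.endog = np.asarray(endog, float)
        self.exog = _as_matrix(exog)
        self.intervals = intervals
        self.length_range = length_range
        s1, s2 = intervals.slices(length_range)
        self._X1 = self.exog[:, s1]
        self._X2 = self.exog[:, s2]
        self.k1 = self._X1.shape[1]
        self.k2 = self._X2.shape[1]
        self.df_model = self.k1 + self.k2 - 1
        if self.exog.shape[0] <= self.df_model:
            raise ValueError(
                f"need N > {self.df_model} free parameters, got N = {self.exog.shape[0]}"
            )

    @classmethod
    def from_dataset(cls, dataset: Dataset, target: str = "reference_ff", **kw):
        return cls(dataset.attribute(target), dataset, **kw)

    # free parameter vector: theta = [M (k1), N[1:] (k2-1)]; N[0] == 1
    def _split(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        M = theta[: self.k1]
        N = np.concatenate([[1.0], theta[self.k1:]])
        return M, N

    def _objective_and_grad(self, theta, den0, penalty_scale):
        """Mean squared residual (per-sample scale) plus denominator-floor
        penalty; returns (objective, gradient)."""
        M, N = self._split(theta)
        n_obs = self.endog.size
        num = self._X1 @ M
        den = self._X2 @ N
        floor = 1e-6 * den0
        pred = num / den
        r = pred - self.endog
        obj = float(r @ r) / n_obs
        dnum = 2.0 * r / den / n_obs
        dden = -2.0 * r * num / (den ** 2) / n_obs
        gM = self._X1.T @ dnum
        gN_full = self._X2.T @ dden
        viol = floor - den
        active = viol > 0
        if np.any(active):
            obj += penalty_scale * float((viol[active] ** 2).sum()) / n_obs
            gN_full += self._X2.T @ np.where(
                active, -2.0 * penalty_scale * viol / n_obs, 0.0)
        grad = np.concatenate([gM, gN_full[1:]])
        return obj, grad

    def fit(self, init: NLRMParams | None = None, maxiter: int = 500,
            gtol: float = 1e-8, ftol: float = 1e-10,
            penalty_scale: float = 1e6) -> "NonlinearRatioResults":
        if init is None:
            init = NLRMParams.unit(self.intervals)
        if init.denominator_weights[0] != 1.0:
            # renormalize to the constraint; predictions are scale-invariant
            c = init.denominator_weights[0]
            if c == 0:
                raise ValueError("initial first denominator weight must be nonzero")
            init = NLRMParams(self.intervals, init.numerator_weights / c,
                              init.denominator_weights / c)
        theta0 = np.concatenate([init.numerator_weights, init.denominator_weights[1:]])
        den0 = self._X2 @ init.denominator_weights
        if np.any(den0 <= 0):
            raise ZeroDenominatorError("initial weighted denominator non-positive")

        history: list[float] = []

        def fun(t):
            return self._objective_and_grad(t, den0, penalty_scale)

        def cb(t):
            history.append(fun(t)[0])

        res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B",
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": ftol, "maxls": 50},
                                callback=cb)
        M, N = self._split(res.x)
        params = NLRMParams(self.intervals, M, N)
        sse = float(np.sum((predict_nlrm(self.exog, params, self.length_range)
                            - self.endog) ** 2))
        if res.status == 1:  # iteration budget exhausted without meeting gtol
            raise ConvergenceError(
                f"NLRM did not converge within {maxiter} iterations (SSE={sse:.3e})",
                params=params)
        return NonlinearRatioResults(self, params, converged=bool(res.success),
                                     sse=sse, n_iter=int(res.nit),
                                     message=str(res.message),
                                     objective_history=history)


class NonlinearRatioResults:
    def __init__(self, model, params: NLRMParams, converged: bool, sse: float,
                 n_iter: int, message: str, objective_history: list[float]):
        self.model = model
        self.nlrm_params = params
        self.converged = converged
        self.sse = sse
        self.n_iter = n_iter
        self.message = message
        self.objective_history = objective_history

    @property
    def params(self) -> dict:
        return self.nlrm_params.to_dict()

    def predict(self, exog) -> np.ndarray:
        return predict_nlrm(exog, self.nlrm_params, self.model.length_range)

    def summary(self) -> str:
        p = self.nlrm_params
        return "\n".join([
            "Nonlinear ratio model (NLRM)",
            f"  I1 = {p.intervals.i1}, I2 = {p.intervals.i2} "
            f"({self.model.df_model} free weights, N[{p.intervals.i2[0]}] fixed at 1)",
            f"  converged = {self.converged} after {self.n_iter} iterations",
            f"  SSE = {self.sse:.6e}",
        ])


def fit_nlrm(dataset_or_profiles, targets, intervals: IntervalPair = OPTIMAL_INTERVALS,
             init: NLRMParams | None = None, **fit_kw) -> NLRMParams:
    """Functional wrapper returning just the fitted NLRM weights."""
    model = NonlinearRatioModel(targets, dataset_or_profiles, intervals=intervals)
    return model.fit(init=init, **fit_kw).nlrm_params


# ---------------------------------------------------------------------------
# LRM — ordinary least squares on all 171 proportions
# ---------------------------------------------------------------------------

@dataclass
class LinearModelParams:
    intercept: float
    coefficients: np.ndarray

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "coefficients": self.coefficients.tolist()}

    @classmethod
    def from_dict(cls, d) -> "LinearModelParams":
        return cls(float(d["intercept"]), np.asarray(d["coefficients"], float))


class LinearLengthModel:
    """LRM: least squares of FF on the full length-proportion vector.

    Minimum-norm solution under rank deficiency (the 171 proportions sum to
    one, so the design is always collinear with the intercept).
    """

    def __init__(self, endog, exog):
        self.endog = np.asarray(endog, float)
        self.exog = _as_matrix(exog)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog/exog not aligned")
        if self.exog.shape[0] < 2:
            raise ValueError("need at least 2 samples")

    @classmethod
    def from_dataset(cls, dataset: Dataset, target: str = "reference_ff"):
        return cls(dataset.attribute(target), dataset)

    def fit(self) -> "LinearLengthResults":
        A = np.column_stack([np.ones(self.exog.shape[0]), self.exog])
        beta, *_ = np.linalg.lstsq(A, self.endog, rcond=None)
        params = LinearModelParams(intercept=float(beta[0]), coefficients=beta[1:])
        return LinearLengthResults(self, params)


class LinearLengthResults:
    def __init__(self, model, lm_params: LinearModelParams):
        self.model = model
        self.lm_params = lm_params
        self.resid = model.endog - self.predict(model.exog)
        self.mse = float(np.mean(self.resid ** 2))

    @property
    def params(self) -> dict:
        return self.lm_params.to_dict()

    def predict(self, exog) -> np.ndarray:
        X = _as_matrix(exog)
        return self.lm_params.intercept + X @ self.lm_params.coefficients

    def summary(self) -> str:
        c = self.lm_params.coefficients
        return "\n".join([
            "Linear length-profile model (LRM)",
            f"  {c.size} coefficients, intercept = {self.lm_params.intercept:.5f}",
            f"  |coef| range [{np.abs(c).min():.3e}, {np.abs(c).max():.3e}]",
            f"  training MSE = {self.mse:.3e}",
        ])


def fit_lrm(features, targets) -> LinearLengthResults:
    return LinearLengthModel(targets, features).fit()


# ---------------------------------------------------------------------------
# SVR and MLP on standardized features
# ---------------------------------------------------------------------------

def _check_standardized(X: np.ndarray) -> None:
    var = X.var(axis=0)
    informative = var > 1e-12
    if informative.any():
        med = float(np.median(var[informative]))
        if not 0.2 < med < 5.0:
            warnings.warn(
                "features do not look standardized (median variance "
                f"{med:.3g}); fit the Standardizer on the training set first",
                stacklevel=3)


def _primal_svr_solve(X: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                      smoothing: float, gtol: float, sample_weight=None,
                      warm_start: tuple[np.ndarray, float] | None = None,
                      ) -> tuple[np.ndarray, float, int]:
    """Linear epsilon-insensitive SVR solved in the primal.

    Minimizes 0.5*||w||^2 + C * sum_i L_eps(y_i - w.x_i - b) by L-BFGS on a
    Huber-smoothed epsilon-insensitive loss (kinks rounded over a width
    ``smoothing``).  With d << n this is orders of magnitude faster than
    SMO on the dual and agrees with it to O(smoothing) in the predictions.
    Per-sample weights multiply C.
    """
    n, d = X.shape
    h = smoothing
    cw = np.full(n, C) if sample_weight is None else C * np.asarray(sample_weight, float)

    def fg(t):
        w, b = t[:d], t[d]
        r = X @ w + b - y
        s = np.abs(r) - epsilon
        lin = s >= h
        quad = (s > 0) & ~lin
        loss = np.zeros_like(r)
        loss[lin] = s[lin] - h / 2
        loss[quad] = s[quad] ** 2 / (2 * h)
        dl = np.sign(r) * np.clip(s / h, 0.0, 1.0) * (s > 0)
        obj = 0.5 * float(w @ w) + float(cw @ loss)
        gw = w + X.T @ (cw * dl)
        gb = float(cw @ dl)
        return obj, np.concatenate([gw, [gb]])

    if warm_start is None:
        t0 = np.zeros(d + 1)
    else:
        t0 = np.concatenate([warm_start[0], [warm_start[1]]])
    res = optimize.minimize(fg, t0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol})
    return res.x[:d], float(res.x[d]), int(res.nit)


class SvrLengthModel:
    """Linear-kernel epsilon-insensitive SVR on standardized profiles.

    Hyperparameter defaults: C=1.0, epsilon=0.01, tol=0.001.  Two solvers
    for the same convex objective: ``"primal"`` (default; smoothed primal
    via L-BFGS, fast for 171 features and thousands of samples) and
    ``"libsvm"`` (sklearn's SMO on the dual; exact kinks, slow at cohort
    scale).  The two agree to O(smoothing) in predictions.
    """

    def __init__(self, endog, exog_standardized, C: float = 1.0,
                 epsilon: float = 0.01, tol: float = 0.001,
                 solver: str = "primal", smoothing: float = 2e-3):
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog_standardized, float)
        _check_standardized(self.exog)
        if solver not in ("primal", "libsvm"):
            raise ValueError(f"unknown solver {solver!r}")
        self.C, self.epsilon, self.tol = C, epsilon, tol
        self.solver = solver
        self.smoothing = smoothing

    def fit(self, sample_weight=None, warm_start=None) -> "SvrLengthResults":
        if self.solver == "libsvm":
            est = SVR(kernel="linear", C=self.C, epsilon=self.epsilon, tol=self.tol)
            est.fit(self.exog, self.endog, sample_weight=sample_weight)
            return SvrLengthResults(self, est.coef_.ravel().copy(),
                                    float(est.intercept_[0]),
                                    n_support=len(est.support_))
        coef, intercept, nit = _primal_svr_solve(
            self.exog, self.endog, self.C, self.epsilon, self.smoothing,
            gtol=1e-8, sample_weight=sample_weight, warm_start=warm_start)
        return SvrLengthResults(self, coef, intercept, n_iter=nit)


class SvrLengthResults:
    def __init__(self, model, coef: np.ndarray, intercept: float,
                 n_support: int | None = None, n_iter: int | None = None):
        self.model = model
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_support = n_support
        self.n_iter = n_iter

    @property
    def params(self) -> dict:
        return {"coefficients": self.coef_.tolist(),
                "intercept": self.intercept_}

    def predict(self, exog_standardized) -> np.ndarray:
        return np.asarray(exog_standardized, float) @ self.coef_ + self.intercept_

    def summary(self) -> str:
        lines = [
            "Support-vector regression (linear kernel)",
            f"  C = {self.model.C}, epsilon = {self.model.epsilon}, "
            f"tol = {self.model.tol}, solver = {self.model.solver}",
        ]
        if self.n_support is not None:
            lines.append(f"  support vectors: {self.n_support} / {self.model.exog.shape[0]}")
        if self.n_iter is not None:
            lines.append(f"  L-BFGS iterations: {self.n_iter}")
        return "\n".join(lines)


def fit_svr(features_standardized, targets, sample_weight=None, warm_start=None,
            **hyper) -> SvrLengthResults:
    return SvrLengthModel(targets, features_standardized, **hyper).fit(
        sample_weight=sample_weight, warm_start=warm_start)


class MlpLengthModel:
    """MLP regressor on standardized profiles: two tanh hidden layers of 25
    units, adaptive-gradient training, fixed seed for reproducibility."""

    def __init__(self, endog, exog_standardized,
                 hidden_layer_sizes: tuple[int, ...] = (25, 25),
                 seed: int = 17, max_iter: int = 3000,
                 learning_rate_init: float = 3e-3, tol: float = 1e-9,
                 n_iter_no_change: int = 50):
        self.endog = np.asarray(endog, float)
        self.exog = np.asarray(exog_standardized, float)
        _check_standardized(self.exog)
        self.hidden_layer_sizes = hidden_layer_sizes
        self.seed = seed
        self.max_iter = max_iter
        self.learning_rate_init = learning_rate_init
        self.tol = tol
        self.n_iter_no_change = n_iter_no_change

    def fit(self) -> "MlpLengthResults":
        est = MLPRegressor(hidden_layer_sizes=self.hidden_layer_sizes,
                           activation="tanh", solver="adam",
                           random_state=self.seed, max_iter=self.max_iter,
                           learning_rate_init=self.learning_rate_init,
                           tol=self.tol,
                           n_iter_no_change=self.n_iter_no_change)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # non-convergence warnings handled below
            est.fit(self.exog, self.endog)
        if not np.isfinite(est.loss_):
            raise ConvergenceError("MLP training diverged (non-finite loss)")
        return MlpLengthResults(self, est)


class MlpLengthResults:
    def __init__(self, model, estimator: MLPRegressor):
        self.model = model
        self.estimator = estimator

    @property
    def params(self) -> dict:
        return {"coefs": [w.tolist() for w in self.estimator.coefs_],
                "intercepts": [b.tolist() for b in self.estimator.intercepts_],
                "activation": "tanh"}

    def predict(self, exog_standardized) -> np.ndarray:
        return self.estimator.predict(np.asarray(exog_standardized, float))

    def summary(self) -> str:
        return "\n".join([
            "Multilayer perceptron regressor",
            f"  hidden layers {self.model.hidden_layer_sizes}, tanh, adam, "
            f"seed {self.model.seed}",
            f"  final loss = {self.estimator.loss_:.3e} "
            f"after {self.estimator.n_iter_} iterations",
        ])


def fit_mlp(features_standardized, targets, seed: int = 17, **kw) -> MlpLengthResults:
    return MlpLengthModel(targets, features_standardized, seed=seed, **kw).fit()


def mlp_forward(params: dict, X: np.ndarray) -> np.ndarray:
    """Forward pass through serialized MLP weights (tanh hidden layers)."""
    a = np.asarray(X, float)
    coefs = [np.asarray(w, float) for w in params["coefs"]]
    intercepts = [np.asarray(b, float) for b in params["intercepts"]]
    for i, (W, b) in enumerate(zip(coefs, intercepts)):
        a = a @ W + b
        if i < len(coefs) - 1:
            a = np.tanh(a)
    return a.ravel()
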