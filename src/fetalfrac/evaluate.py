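"""Repeated train/test evaluation of fetal-fraction estimators.

The protocol: the cohort is split at random into 80% training / 20%
testing, every estimator is fitted on the training fold only (including
its standardizer, interval search and out-of-fold sub-predictions) and
scored on the test fold by Pearson correlation, MSE and MAE against the
Y-based reference FF; the split is repeated (default 100 times) with
every method seeing identical folds within a repeat, so method
comparisons are paired.  A stratified variant reports MAE separately for
low-FF (< 10%) and high-FF samples to quantify the effect of duplicating
low-FF training samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .combine import (LinearCombiner, WeightingConfig, oof_svm_predictions,
                      weight_training_set)
from .fragio import Dataset, apply_standardizer, fit_standardizer
from .lengthmodels import (IntervalPair, FracRatioModel, LinearLengthModel,
                           MlpLengthModel, NonlinearRatioModel, SvrLengthModel,
                           search_best_intervals)

DEFAULT_N_REPEATS = 100
DEFAULT_TRAIN_FRAC = 0.8
DEFAULT_STRATUM_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mse(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.mean((a - b) ** 2))


def mae(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.mean(np.abs(a - b)))


# ---------------------------------------------------------------------------
# method specs: fit(train Dataset, train targets) -> predict(test Dataset)
# ---------------------------------------------------------------------------

Predictor = Callable[[Dataset], np.ndarray]


@dataclass
class MethodSpec:
    name: str
    fit: Callable[[Dataset, np.ndarray, np.ndarray | None], Predictor]
    min_train: int = 3


def frac_method(intervals: IntervalPair | None = None,
                bounds=(50, 220), stride: int = 2, min_width: int = 2) -> MethodSpec:
    """FRAC ratio calibrated to FF units; searches intervals on the training
    fold when none are given."""

    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        res = FracRatioModel(y, train, intervals=intervals, bounds=bounds,
                             stride=stride, min_width=min_width).fit()
        return lambda test: res.predict(test)

    return MethodSpec("frac", fit)


def nlrm_method(intervals: IntervalPair, maxiter: int = 500) -> MethodSpec:
    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        res = NonlinearRatioModel(y, train, intervals=intervals).fit(maxiter=maxiter)
        return lambda test: res.predict(test)

    return MethodSpec("nlrm", fit, min_train=(intervals.total_width))


def lrm_method() -> MethodSpec:
    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        res = LinearLengthModel(y, train).fit()
        return lambda test: res.predict(test)

    return MethodSpec("lrm", fit)


def svr_method(**hyper) -> MethodSpec:
    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        X = train.profile_matrix()
        std = fit_standardizer(X)
        res = SvrLengthModel(y, std.transform(X), **hyper).fit(sample_weight=w)
        return lambda test: res.predict(apply_standardizer(std, test.profile_matrix()))

    return MethodSpec("svr", fit)


def mlp_method(seed: int = 17, **kw) -> MethodSpec:
    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        X = train.profile_matrix()
        std = fit_standardizer(X)
        res = MlpLengthModel(y, std.transform(X), seed=seed, **kw).fit()
        return lambda test: res.predict(apply_standardizer(std, test.profile_matrix()))

    return MethodSpec("mlp", fit)


def seqff_method() -> MethodSpec:
    """The externally supplied SeqFF value used directly as the prediction."""

    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        return lambda test: test.attribute("seqff_value")

    return MethodSpec("seqff", fit)


def combined_method(features: Sequence[str] = ("SVM", "SeqFF"),
                    out_of_fold: bool = True, n_splits: int = 5,
                    seed: int = 17, name: str | None = None) -> MethodSpec:
    """Linear combination of the SVM length-based prediction, the SeqFF
    value and/or sample attributes, trained leakage-free: the SVM feature
    for combiner training comes from out-of-fold predictions by default."""

    use_svm = "SVM" in features

    def fit(train: Dataset, y: np.ndarray, w=None) -> Predictor:
        X = train.profile_matrix()
        table = {"seqff_value": train.attribute("seqff_value"),
                 "ga": train.attribute("ga"), "bmi": train.attribute("bmi"),
                 "lc": train.attribute("lc")}
        svr_full = None
        if use_svm:
            std = fit_standardizer(X)
            svr_full = (std, SvrLengthModel(y, std.transform(X)).fit(sample_weight=w))
            if out_of_fold:
                ws = (svr_full[1].coef_, svr_full[1].intercept_)
                table["svm_ff"] = oof_svm_predictions(X, y, n_splits=n_splits,
                                                      seed=seed, sample_weight=w,
                                                      warm_start=ws)
            else:
                table["svm_ff"] = svr_full[1].predict(std.transform(X))
        res = LinearCombiner(y, pd.DataFrame(table), features=features).fit(
            sample_weight=w)

        def predict(test: Dataset) -> np.ndarray:
            ttable = {"seqff_value": test.attribute("seqff_value"),
                      "ga": test.attribute("ga"), "bmi": test.attribute("bmi"),
                      "lc": test.attribute("lc")}
            if use_svm:
                std, svr_res = svr_full
                ttable["svm_ff"] = svr_res.predict(
                    apply_standardizer(std, test.profile_matrix()))
            return res.predict(pd.DataFrame(ttable))

        return predict

    return MethodSpec(name or "combined:" + "+".join(features), fit,
                      min_train=len(features) + 2)


# ---------------------------------------------------------------------------
# repeated-split harness
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Tidy per-repeat metrics plus quartile summaries."""

    records: pd.DataFrame  # columns: repeat, method, metric, stratum, value
    n_repeats: int
    train_frac: float
    seed: int

    def summary(self) -> pd.DataFrame:
        g = (self.records.dropna(subset=["value"])
             .groupby(["method", "metric", "stratum"])["value"])
        out = g.agg(median="median",
                    q1=lambda s: s.quantile(0.25),
                    q3=lambda s: s.quantile(0.75),
                    n="count").reset_index()
        return out.sort_values(["method", "metric", "stratum"]).reset_index(drop=True)

    def median(self, method: str, metric: str, stratum: str = "all") -> float:
        m = self.records[(self.records["method"] == method)
                         & (self.records["metric"] == metric)
                         & (self.records["stratum"] == stratum)]["value"]
        return float(m.median())

    def pivot(self, metric: str, stratum: str = "all") -> pd.DataFrame:
        m = self.records[(self.records["metric"] == metric)
                         & (self.records["stratum"] == stratum)]
        return m.pivot(index="repeat", columns="method", values="value")

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        df["value"] = df["value"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        df.to_csv(path, sep="\t", index=False)


def split_sizes(n: int, train_frac: float = DEFAULT_TRAIN_FRAC) -> tuple[int, int]:
    n_train = int(np.floor(n * train_frac))
    return n_train, n - n_train


def repeated_split_evaluate(
    dataset: Dataset,
    methods: Sequence[MethodSpec],
    n_repeats: int = DEFAULT_N_REPEATS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 17,
    target: str = "reference_ff",
    stratum_threshold: float | None = None,
) -> EvaluationResult:
    """Paired repeated 80/20 evaluation of the given methods.

    Within each repeat every method is fitted on the identical training
    fold and scored on the identical test fold.  A method whose fit fails
    on a fold (e.g. too few samples) gets NaN metrics for that repeat and
    the run continues.
    """
    y_all = dataset.attribute(target)
    if np.any(np.isnan(y_all)):
        raise ValueError(f"dataset has missing values in target {target!r}")
    n = dataset.n
    n_train, _ = split_sizes(n, train_frac)
    if n_train < 2 or n_train >= n:
        raise ValueError(f"degenerate split sizes for N={n}, train_frac={train_frac}")
    child_seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    rows = []
    for rep, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        tr_idx, te_idx = perm[:n_train], perm[n_train:]
        train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
        y_tr, y_te = y_all[tr_idx], y_all[te_idx]
        for spec in methods:
            try:
                if n_train < spec.min_train:
                    raise ValueError(f"training fold ({n_train}) below method "
                                     f"minimum ({spec.min_train})")
                predictor = spec.fit(train, y_tr, None)
                pred = np.asarray(predictor(test), float)
                vals = {"pearson": pearson(y_te, pred), "mse": mse(y_te, pred),
                        "mae": mae(y_te, pred)}
            except (ValueError, RuntimeError):
                vals = {"pearson": np.nan, "mse": np.nan, "mae": np.nan}
                pred = None
            for metric, v in vals.items():
                rows.append((rep, spec.name, metric, "all", v))
            if stratum_threshold is not None:
                low = y_te < stratum_threshold
                for label, m in (("low", low), ("high", ~low)):
                    if pred is None or m.sum() == 0:
                        rows.append((rep, spec.name, "mae", label, np.nan))
                    else:
                        rows.append((rep, spec.name, "mae", label,
                                     mae(y_te[m], pred[m])))
    df = pd.DataFrame(rows, columns=["repeat", "method", "metric", "stratum", "value"])
    return EvaluationResult(df, n_repeats=n_repeats, train_frac=train_frac, seed=seed)


def attribute_correlations(dataset: Dataset, target: str = "reference_ff") -> pd.DataFrame:
    """Pearson correlation of each sample attribute (GA, BMI, LC) with the
    reference FF; attributes that are absent or constant are omitted with a
    note."""
    y = dataset.attribute(target)
    rows = []
    for name in ("ga", "bmi", "lc"):
        x = dataset.attribute(name)
        ok = ~(np.isnan(x) | np.isnan(y))
        note = ""
        r = np.nan
        if ok.sum() < 3:
            note = "absent"
        elif np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            note = "constant"
        else:
            r = pearson(x[ok], y[ok])
        rows.append((name, r, int(ok.sum()), note))
    return pd.DataFrame(rows, columns=["attribute", "r", "n", "note"])


def weighting_experiment(
    dataset: Dataset,
    multipliers: Sequence[int] = (1, 2, 3, 4),
    threshold: float = DEFAULT_STRATUM_THRESHOLD,
    n_repeats: int = DEFAULT_N_REPEATS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    seed: int = 17,
    target: str = "reference_ff",
    method_factory: Callable[[], MethodSpec] = svr_method,
) -> pd.DataFrame:
    """Stratified effect of duplicating low-FF training samples.

    For each multiplier k, samples with reference FF below ``threshold``
    appear k times in each training fold (integer sample weights); test MAE
    is reported separately for the low (< threshold) and high strata.
    Folds are shared across multipliers and with ``repeated_split_evaluate``
    at the same seed, so multiplier 1 reproduces the unweighted run.
    Returns tidy rows (repeat, multiplier, stratum, mae).
    """
    y_all = dataset.attribute(target)
    if np.any(np.isnan(y_all)):
        raise ValueError(f"dataset has missing values in target {target!r}")
    n = dataset.n
    n_train, _ = split_sizes(n, train_frac)
    spec = method_factory()
    child_seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    rows = []
    for rep, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        tr_idx, te_idx = perm[:n_train], perm[n_train:]
        train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
        y_tr, y_te = y_all[tr_idx], y_all[te_idx]
        low_te = y_te < threshold
        for k in multipliers:
            wts = weight_training_set(
                y_tr, WeightingConfig(ff_threshold=threshold, multiplier=int(k)))
            w = None if int(k) == 1 else wts.weights
            predictor = spec.fit(train, y_tr, w)
            pred = np.asarray(predictor(test), float)
            for label, m in (("low", low_te), ("high", ~low_te), ("all", slice(None))):
                sel = m if isinstance(m, slice) else np.asarray(m)
                if not isinstance(sel, slice) and sel.sum() == 0:
                    rows.append((rep, int(k), label, np.nan))
                else:
                    rows.append((rep, int(k), label, mae(y_te[sel], pred[sel])))
    return pd.DataFrame(rows, columns=["repeat", "multiplier", "stratum", "mae"])
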