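"""Linear combination of FF predictors and low-FF training-set weighting.

Length-based (SVM) and position-based (SeqFF) fetal-fraction predictors
exploit nearly unrelated fragment attributes, so a linear regression of the
Y-based reference FF on both predictions — optionally together with the
weak sample attributes gestational age (GA), maternal BMI and DNA library
concentration (LC) — outperforms either predictor alone.

The weighting utility duplicates low-FF training samples (below a
threshold on the Y-based reference, default 10%) so that estimators pay
more attention to the stratum where over-estimated FF risks false-negative
aneuploidy calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .fragio import Dataset
from .lengthmodels import fit_svr

#: canonical feature names (as used in the combined-model weight tables)
FEATURE_NAMES = ("SVM", "SeqFF", "BMI", "LC", "GA")
#: mapping from canonical names to SampleRecord / column attributes
FEATURE_COLUMNS = {"SVM": "svm_ff", "SeqFF": "seqff_value", "BMI": "bmi",
                   "LC": "lc", "GA": "ga"}

#: the four feature subsets examined for the combined estimator
MODEL_VARIANTS = {
    "SeqFF + SA": ("SeqFF", "BMI", "LC", "GA"),
    "SVM + SA": ("SVM", "BMI", "LC", "GA"),
    "SVM + SeqFF": ("SVM", "SeqFF"),
    "SeqFF + SVM + SA": ("SeqFF", "SVM", "BMI", "LC", "GA"),
}


class MissingFeatureError(ValueError):
    pass


@dataclass
class CombinerParams:
    """Coefficients of one combined linear model (structure of the weight
    table: one coefficient per included feature plus an intercept; features
    not in the model are absent, not zero)."""

    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_dict(self) -> dict:
        d = {name: self.coefficients[name] for name in FEATURE_NAMES
             if name in self.coefficients}
        d["Intercept"] = self.intercept
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CombinerParams":
        coeffs = {k: float(v) for k, v in d.items()
                  if k != "Intercept" and v is not None}
        unknown = set(coeffs) - set(FEATURE_NAMES)
        if unknown:
            raise MissingFeatureError(f"unknown combiner features: {sorted(unknown)}")
        return cls(coefficients=coeffs, intercept=float(d.get("Intercept", 0.0)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CombinerParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _feature_matrix(table: pd.DataFrame | Mapping, features: Sequence[str]) -> np.ndarray:
    cols = []
    for name in features:
        col = FEATURE_COLUMNS[name]
        key = name if (hasattr(table, "columns") and name in table.columns) or (
            isinstance(table, Mapping) and name in table) else col
        try:
            v = table[key]
        except (KeyError, IndexError):
            raise MissingFeatureError(f"required feature {name!r} ({col}) absent")
        v = np.atleast_1d(np.asarray(v, float))
        if np.any(np.isnan(v)):
            raise MissingFeatureError(f"feature {name!r} ({col}) has missing values")
        cols.append(v)
    return np.column_stack(cols)


class LinearCombiner:
    """OLS of the Y-based reference FF on a chosen set of predictor features.

    Parameters
    ----------
    endog : array-like
        Y-based reference fetal fractions.
    exog : DataFrame or mapping
        Feature table; columns named either canonically ("SVM", "SeqFF",
        "BMI", "LC", "GA") or by attribute ("svm_ff", "seqff_value", ...).
    features : sequence of canonical names, default ("SVM", "SeqFF")
    """

    def __init__(self, endog, exog, features: Sequence[str] = ("SVM", "SeqFF")):
        self.endog = np.asarray(endog, float)
        self.features = tuple(features)
        if not self.features:
            raise MissingFeatureError("combiner needs at least one feature")
        self.exog = _feature_matrix(exog, self.features)
        n, k = self.exog.shape
        if n <= k + 1:
            raise ValueError(f"need N > {k + 1} samples for {k} features")

    def fit(self, sample_weight=None) -> "LinearCombinerResults":
        n = self.exog.shape[0]
        A = np.column_stack([np.ones(n), self.exog])
        y = self.endog
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, float))
            A = A * w[:, None]
            y = y * w
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            warnings.warn("collinear combiner features; minimum-norm solution",
                          stacklevel=2)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        params = CombinerParams(
            coefficients=dict(zip(self.features, (float(b) for b in beta[1:]))),
            intercept=float(beta[0]))
        return LinearCombinerResults(self, params)


class LinearCombinerResults:
    def __init__(self, model: LinearCombiner, combiner_params: CombinerParams):
        self.model = model
        self.combiner_params = combiner_params
        self.fittedvalues = self.predict(
            pd.DataFrame(model.exog, columns=list(model.features)))
        self.resid = model.endog - self.fittedvalues
        self.mse = float(np.mean(self.resid ** 2))

    @property
    def params(self) -> dict:
        return self.combiner_params.to_dict()

    def predict(self, exog) -> np.ndarray:
        return predict_combined(exog, self.combiner_params)

    def summary(self) -> str:
        p = self.combiner_params
        lines = ["Combined FF estimator (OLS)"]
        for name in p.features:
            lines.append(f"  {name:<9s} {p.coefficients[name]:+.4f}")
        lines.append(f"  Intercept {p.intercept:+.4f}")
        lines.append(f"  training MSE = {self.mse:.3e}")
        return "\n".join(lines)


def fit_combiner(feature_table, targets,
                 features: Sequence[str] | None = None,
                 sample_weight=None) -> CombinerParams:
    """OLS coefficients for a feature subset; defaults to every canonical
    feature present in the table."""
    if features is None:
        present = []
        for name in FEATURE_NAMES:
            col = FEATURE_COLUMNS[name]
            if hasattr(feature_table, "columns"):
                if name in feature_table.columns or col in feature_table.columns:
                    present.append(name)
            elif name in feature_table or col in feature_table:
                present.append(name)
        features = present
    model = LinearCombiner(targets, feature_table, features=features)
    return model.fit(sample_weight=sample_weight).combiner_params


def predict_combined(record_or_table, params: CombinerParams):
    """Linear combiner score; unclipped (scores outside [0,1] are legal)."""
    X = _feature_matrix(record_or_table, params.features)
    out = params.intercept + X @ np.array(
        [params.coefficients[f] for f in params.features])
    if out.size == 1 and not hasattr(record_or_table, "columns"):
        return float(out[0])
    return out


# ---------------------------------------------------------------------------
# low-FF sample weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightingConfig:
    """Duplicate training samples whose reference FF is below the threshold."""

    ff_threshold: float = 0.10
    multiplier: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.ff_threshold < 1.0:
            raise ValueError("ff_threshold must be in (0,1)")
        if not 1 <= int(self.multiplier) <= 16:
            raise ValueError("multiplier must be a small positive integer")


@dataclass
class WeightedTrainingSet:
    """Row-expanded view of a training set with low-FF samples duplicated.

    ``indices`` lists original rows (in order) followed by the appended
    duplicates; ``weights`` is the equivalent per-original-sample integer
    weight vector for estimators that accept sample weights.
    """

    indices: np.ndarray
    weights: np.ndarray

    @property
    def n_rows(self) -> int:
        return int(self.indices.size)

    def take(self, arr):
        """Row-expand an aligned array/matrix/Dataset."""
        if isinstance(arr, Dataset):
            return [arr.records[i] for i in self.indices]
        return np.asarray(arr)[self.indices]


def weight_training_set(targets, config: WeightingConfig) -> WeightedTrainingSet:
    """Expansion of a training set per the weighting rule.

    Samples with target < threshold appear ``multiplier`` times (original in
    place, copies appended in dataset order); all others once.
    """
    y = np.asarray(targets, float)
    low = y < config.ff_threshold
    extra = np.repeat(np.nonzero(low)[0], config.multiplier - 1)
    indices = np.concatenate([np.arange(y.size), extra])
    weights = np.where(low, config.multiplier, 1).astype(float)
    return WeightedTrainingSet(indices=indices, weights=weights)


# ---------------------------------------------------------------------------
# out-of-fold SVM predictions for leakage-free combiner training
# ---------------------------------------------------------------------------

def oof_svm_predictions(profiles: np.ndarray, targets, n_splits: int = 5,
                        seed: int = 17, sample_weight=None,
                        warm_start=None) -> np.ndarray:
    """SVR predictions for each training sample from a model that never saw
    it (K-fold out-of-fold), so combiner training is leakage-free.

    The standardizer is refitted inside each fold.
    """
    from .fragio import fit_standardizer  # local import to avoid cycle at import time

    X = np.asarray(profiles, float)
    y = np.asarray(targets, float)
    out = np.empty_like(y)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in kf.split(X):
        std = fit_standardizer(X[tr])
        w = None if sample_weight is None else np.asarray(sample_weight, float)[tr]
        res = fit_svr(std.transform(X[tr]), y[tr], sample_weight=w,
                      warm_start=warm_start)
        out[te] = res.predict(std.transform(X[te]))
    return out
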