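"""Reference Y-based fetal-fraction estimator.

For a pregnancy with a male fetus, the fraction of reads mapping to
chromosome Y grows linearly with the fetal fraction between two baselines:
the mean chrY read fraction of pregnancies with euploid female fetuses
(fetal fraction 0, residual mismapping only) and that of adult male plasma
(fetal fraction 1).  The estimator inverts that line:

    FF = (%chrY - female_baseline) / (male_baseline - female_baseline)

Estimates can fall outside [0, 1] for noisy inputs; they are returned
unclipped together with an in-range flag so downstream regressions are not
censored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_INFORMATIVE_THRESHOLD = 0.04


class CalibrationError(ValueError):
    """Baselines cannot define a valid estimator."""


@dataclass(frozen=True)
class YBasedParams:
    """chrY read-fraction baselines for the linear FF model."""

    female_baseline: float
    male_baseline: float

    def __post_init__(self) -> None:
        f, m = self.female_baseline, self.male_baseline
        if not (0.0 <= f < m <= 1.0):
            raise CalibrationError(
                f"baselines must satisfy 0 <= female ({f}) < male ({m}) <= 1"
            )


def estimate_y_based(chry_fraction, params: YBasedParams):
    """Fetal fraction from the chrY read fraction (vectorised).

    Returns ``(ff, in_range)``: the unclipped estimate(s) and a boolean
    flag/array marking values inside [0, 1].
    """
    f, m = params.female_baseline, params.male_baseline
    denom = m - f
    if denom == 0:  # unreachable through the dataclass, kept for raw use
        raise CalibrationError("male and female baselines coincide")
    x = np.asarray(chry_fraction, dtype=float)
    ff = (x - f) / denom
    in_range = (ff >= 0.0) & (ff <= 1.0)
    if np.isscalar(chry_fraction) or x.ndim == 0:
        return float(ff), bool(in_range)
    return ff, in_range


def calibrate_y_params(
    male_chry_fractions: Sequence[float],
    female_fetus_chry_fractions: Sequence[float],
) -> YBasedParams:
    """Baselines as arithmetic means of male-adult and female-fetus samples."""
    males = np.asarray(male_chry_fractions, dtype=float)
    females = np.asarray(female_fetus_chry_fractions, dtype=float)
    if males.size == 0 or females.size == 0:
        raise CalibrationError("both calibration sets must be non-empty")
    m, f = float(males.mean()), float(females.mean())
    if m <= f:
        raise CalibrationError(
            f"male baseline mean ({m}) must exceed female baseline mean ({f})"
        )
    return YBasedParams(female_baseline=f, male_baseline=m)


def informative_mask(ff: np.ndarray, threshold: float = DEFAULT_INFORMATIVE_THRESHOLD) -> np.ndarray:
    """Samples whose FF clears the reliability threshold for aneuploidy calling."""
    return np.asarray(ff, float) >= threshold
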