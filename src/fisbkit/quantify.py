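"""Fluorescence copy-number calibration and labeling-efficiency estimation.

FisB copy numbers per cluster were obtained by imaging DNA-origami
standards carrying known numbers of mEGFP molecules alongside the cells:
the summed spot intensity grows linearly with copy number, and the
through-origin slope (au per fluorophore) converts background-corrected
cluster intensities into copies.  The standards themselves are imperfectly
labeled; the per-site labeling probability is estimated from photobleaching
step counts of few-site standards via a binomial maximum-likelihood fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .exceptions import DataError, DomainError

__all__ = [
    "CalibrationCurve",
    "SpotMeasurement",
    "BleachTraceSet",
    "LabelingEfficiency",
    "fit_calibration",
    "correct_spot_intensity",
    "intensity_to_copies",
    "estimate_labeling_efficiency",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Through-origin intensity calibration: slope in au per fluorophore."""

    slope: float
    r_squared: float
    n_points: int

    def __post_init__(self):
        if not self.slope > 0:
            raise DomainError(f"slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class SpotMeasurement:
    """Background-corrected summed spot intensity (au).

    ``corrected`` may legitimately be negative for dim spots on a bright
    background; ``negative`` flags that case.
    """

    spot_sum: float
    background_sum: float

    @property
    def corrected(self) -> float:
        return self.spot_sum - self.background_sum

    @property
    def negative(self) -> bool:
        return self.corrected < 0


@dataclass(frozen=True)
class BleachTraceSet:
    """Photobleaching step counts for standards with ``n_sites`` sites."""

    step_counts: np.ndarray
    n_sites: int

    def __post_init__(self):
        counts = np.asarray(self.step_counts, dtype=int)
        if counts.size < 1:
            raise DataError("need at least one bleach trace")
        if self.n_sites < 1:
            raise DataError("n_sites must be >= 1")
        if np.any(counts < 0) or np.any(counts > self.n_sites):
            raise DataError(
                f"step counts must lie in [0, n_sites={self.n_sites}]"
            )
        object.__setattr__(self, "step_counts", counts)


@dataclass(frozen=True)
class LabelingEfficiency:
    """Per-site labeling probability with a 95% profile-likelihood CI."""

    p_hat: float
    ci_low: float
    ci_high: float
    n_traces: int


def fit_calibration(
    copies: Sequence[float], intensities: Sequence[float]
) -> CalibrationCurve:
    """Least-squares slope of intensity vs copy number through the origin.

    R^2 is reported against the constrained (no-intercept) model,
    1 - SS_res / sum(intensity^2), which lies in [0, 1].
    """
    x = np.asarray(copies, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.shape != y.shape:
        raise DataError(
            f"copies and intensities differ in length ({len(x)} vs {len(y)})"
        )
    if x.size < 1:
        raise DataError("need at least one calibration point")
    if np.any(x <= 0):
        raise DomainError("copy numbers must be strictly positive")
    slope = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(slope=slope, r_squared=r2, n_points=int(x.size))


def correct_spot_intensity(spot_block, reference_block) -> SpotMeasurement:
    """Background subtraction over matched 6x6-pixel boxes.

    The spot intensity is the sum of pixel values in a 6x6 box around the
    spot; the same-size box on cluster-free membrane of the same cell
    provides the background, which is subtracted sum-for-sum.
    """
    spot = np.asarray(spot_block, dtype=float)
    ref = np.asarray(reference_block, dtype=float)
    if spot.shape != (6, 6) or ref.shape != (6, 6):
        raise DataError(
            f"both blocks must be 6x6 pixels, got {spot.shape} and {ref.shape}"
        )
    return SpotMeasurement(
        spot_sum=float(spot.sum()), background_sum=float(ref.sum())
    )


def intensity_to_copies(corrected: float, curve: CalibrationCurve) -> float:
    """Convert a background-corrected intensity to fluorophore copies.

    Copies are reported as real numbers; rounding, if wanted, belongs to
    the presentation layer.
    """
    if not curve.slope > 0:
        raise DomainError("calibration slope must be positive")
    return corrected / curve.slope


def estimate_labeling_efficiency(
    traces: BleachTraceSet, alpha: float = 0.05
) -> LabelingEfficiency:
    """Binomial MLE of the per-site labeling probability, with 95% CI.

    Step counts are modeled i.i.d. Binomial(n_sites, p); the MLE is the
    pooled fraction of occupied sites.  The CI inverts the likelihood-
    ratio statistic against chi-square(1) (profile likelihood), which
    remains sensible near the boundaries p = 0, 1 where Wald intervals
    collapse; at an exact boundary the interval is one-sided.
    """
    counts = traces.step_counts
    n_tot = int(counts.size) * traces.n_sites
    successes = int(counts.sum())
    p_hat = successes / n_tot

    crit = chi2.ppf(1.0 - alpha, df=1) / 2.0

    def loglik(p):
        if p <= 0.0:
            return 0.0 if successes == 0 else -math.inf
        if p >= 1.0:
            return 0.0 if successes == n_tot else -math.inf
        return successes * math.log(p) + (n_tot - successes) * math.log(1 - p)

    l_max = loglik(p_hat)

    def deficit(p):
        return l_max - loglik(p) - crit

    eps = 1e-12
    if successes == 0:
        ci_low = 0.0
    else:
        ci_low = brentq(deficit, eps, p_hat, xtol=1e-12)
    if successes == n_tot:
        ci_high = 1.0
    else:
        ci_high = brentq(deficit, p_hat, 1.0 - eps, xtol=1e-12)
    return LabelingEfficiency(
        p_hat=p_hat,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_traces=int(counts.size),
    )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_calibration_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Columns: copies, intensity_au."""
    df = pd.read_csv(path)
    for col in ("copies", "intensity_au"):
        if col not in df.columns:
            raise DataError(f"calibration CSV missing column {col!r}")
    return df["copies"].to_numpy(float), df["intensity_au"].to_numpy(float)


def read_spots_csv(path) -> pd.DataFrame:
    """Columns: spot_id, spot_sum_au, background_sum_au."""
    df = pd.read_csv(path)
    for col in ("spot_id", "spot_sum_au", "background_sum_au"):
        if col not in df.columns:
            raise DataError(f"spots CSV missing column {col!r}")
    return df


def read_bleach_csv(path, n_sites: int) -> BleachTraceSet:
    """Columns: trace_id, steps."""
    df = pd.read_csv(path)
    for col in ("trace_id", "steps"):
        if col not in df.columns:
            raise DataError(f"bleach CSV missing column {col!r}")
    return BleachTraceSet(
        step_counts=df["steps"].to_numpy(int), n_sites=n_sites
    )
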