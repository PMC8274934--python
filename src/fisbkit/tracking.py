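"""Mean-squared-displacement diffusion analysis and track-shape statistics.

FisB clusters were followed in time-lapse movies as 2D point tracks.  Two
mobility classes matter here: dim mobile clusters (DMCs, D ~ 2.8e3 nm^2/s)
and the immobile intense spot at the engulfment pole (ISEP, D ~ 28 nm^2/s).
This module estimates diffusion coefficients from the time-averaged MSD of
such tracks (2D convention, MSD = 4 D dt) and computes the radius-of-
gyration asymmetry statistic used to distinguish directed from random
motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DataError, DomainError

__all__ = [
    "Track",
    "MSDCurve",
    "DiffusionFit",
    "compute_msd",
    "fit_diffusion",
    "gyration_asymmetry",
    "read_tracks_csv",
    "write_tracks_csv",
    "ASYM_CAP",
]

#: cap applied to the asymmetry statistic for exactly collinear tracks,
#: where the normalized eigenvalue contrast reaches 1 and -log diverges
ASYM_CAP = 746.0

_TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_nm", "y_nm"]


@dataclass(frozen=True)
class Track:
    """A single particle trajectory: times in s, positions in nm."""

    track_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise DataError(f"track {self.track_id}: t/x/y length mismatch")
        if len(t) < 2:
            raise DataError(f"track {self.track_id}: needs >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise DataError(f"track {self.track_id}: t must strictly increase")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Frame interval; uniform within 1% or the track is rejected."""
        steps = np.diff(self.t)
        dt = float(np.median(steps))
        if np.any(np.abs(steps - dt) > 0.01 * dt):
            raise DataError(
                f"track {self.track_id}: non-uniform frame interval"
            )
        return dt


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble time-averaged MSD: delays in s, msd in nm^2."""

    delay: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delay_s": self.delay, "msd_nm2": self.msd, "n_pairs": self.n_pairs}
        )


@dataclass(frozen=True)
class DiffusionFit:
    """Diffusion coefficient (nm^2/s) with a 95% CI from the MSD slope."""

    D: float
    ci_low: float
    ci_high: float
    r_squared: float
    fit_window: float


def _common_dt(tracks: Sequence[Track]) -> float:
    dts = {}
    for tr in tracks:
        dts[tr.track_id] = tr.dt
    ref = float(np.median(list(dts.values())))
    bad = [tid for tid, d in dts.items() if abs(d - ref) > 0.01 * ref]
    if bad:
        raise DataError(
            f"tracks have frame intervals differing from the ensemble "
            f"median {ref:g} s by more than 1%: {bad}"
        )
    return ref


def compute_msd(
    tracks: Sequence[Track],
    max_delay_fraction: float = 1.0,
    overlapping: bool = True,
) -> MSDCurve:
    """Ensemble time-averaged MSD over a set of uniformly sampled tracks.

    For each track the squared displacement is averaged over all pairs at
    each delay -- overlapping pairs by default, or independent
    (non-overlapping) pairs with ``overlapping=False`` -- and the per-track
    curves are then averaged across tracks with equal weight.  Delays are
    limited to ``max_delay_fraction`` of the shortest track's span.
    """
    if not tracks:
        raise DataError("no tracks given")
    if not 0 < max_delay_fraction <= 1:
        raise DomainError("max_delay_fraction must be in (0, 1]")
    dt = _common_dt(tracks)
    min_len = min(tr.n_frames for tr in tracks)
    kmax = max(1, int(math.floor(max_delay_fraction * (min_len - 1))))
    delays = dt * np.arange(1, kmax + 1)
    per_track = np.empty((len(tracks), kmax))
    pair_counts = np.zeros(kmax, dtype=int)
    for i, tr in enumerate(tracks):
        for k in range(1, kmax + 1):
            if overlapping:
                dx = tr.x[k:] - tr.x[:-k]
                dy = tr.y[k:] - tr.y[:-k]
            else:
                dx = tr.x[k::k] - tr.x[:-k:k]
                dy = tr.y[k::k] - tr.y[:-k:k]
            sq = dx * dx + dy * dy
            per_track[i, k - 1] = sq.mean()
            pair_counts[k - 1] += len(sq)
    return MSDCurve(
        delay=delays, msd=per_track.mean(axis=0), n_pairs=pair_counts
    )


def fit_diffusion(
    curve: MSDCurve,
    window_s: float = 25.0,
    through_origin: bool = True,
) -> DiffusionFit:
    """Fit MSD = 4 D dt over delays within the initial window.

    Ordinary least squares through the origin by default (the 2D free-
    diffusion law has no intercept); a free-intercept mode is available
    for data with static localization noise.  The 95% CI comes from the
    slope's standard error (t distribution).
    """
    mask = curve.delay <= window_s
    tau = curve.delay[mask]
    msd = curve.msd[mask]
    if len(tau) < 3:
        raise DataError(
            f"need >= 3 delay points within {window_s} s, have {len(tau)}"
        )
    X = tau[:, None] if through_origin else sm.add_constant(tau)
    res = sm.OLS(msd, X).fit()
    slope = res.params[-1]
    lo, hi = res.conf_int(alpha=0.05)[-1]
    return DiffusionFit(
        D=slope / 4.0,
        ci_low=lo / 4.0,
        ci_high=hi / 4.0,
        r_squared=float(res.rsquared),
        fit_window=float(window_s),
    )


def gyration_asymmetry(track: Track, return_flag: bool = False):
    """Radius-of-gyration asymmetry of a 2D track.

    Builds the gyration tensor Rg(i, j) = <x_i x_j> - <x_i><x_j> of the
    positions, takes its eigenvalues lambda1 >= lambda2 (the squared
    principal radii of gyration R1^2, R2^2) and returns

        Asym = -ln(1 - (R1^2 - R2^2)^2 / (R1^2 + R2^2)^2).

    Isotropic tracks give 0; exactly collinear tracks saturate the
    normalized contrast at 1 and are capped at ``ASYM_CAP`` (with the
    degeneracy flag set when ``return_flag``).  All points identical is
    an undefined statistic and raises :class:`DomainError`.
    """
    if track.n_frames < 3:
        raise DataError(f"track {track.track_id}: needs >= 3 points for Asym")
    pts = np.column_stack([track.x, track.y])
    tensor = np.cov(pts.T, bias=True)
    lam = np.linalg.eigvalsh(tensor)
    lam2, lam1 = float(lam[0]), float(lam[1])
    if lam1 <= 0:
        raise DomainError(
            f"track {track.track_id}: all points identical, Asym undefined"
        )
    contrast = ((lam1 - lam2) / (lam1 + lam2)) ** 2
    if contrast >= 1.0:
        value, flag = ASYM_CAP, True
    else:
        value = -math.log(1.0 - contrast)
        flag = False
        if value > ASYM_CAP:
            value, flag = ASYM_CAP, True
    return (value, flag) if return_flag else value


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def read_tracks_csv(path) -> list:
    """Read tracks from CSV with columns track_id, frame, t_s, x_nm, y_nm."""
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"tracks CSV missing columns {missing}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                track_id=str(tid),
                t=sub["t_s"].to_numpy(float),
                x=sub["x_nm"].to_numpy(float),
                y=sub["y_nm"].to_numpy(float),
            )
        )
    if not tracks:
        raise DataError(f"no tracks found in {path}")
    return tracks


def write_tracks_csv(tracks: Sequence[Track], path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": np.arange(tr.n_frames),
                    "t_s": tr.t,
                    "x_nm": tr.x,
                    "y_nm": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
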