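"""Seeded generators for synthetic inputs to every analysis stage.

The package ships no measured data; these generators produce inputs with
the statistical structure each estimator assumes, at the study's stated
conditions, so the full pipeline is exercisable and testable end to end:

* 2D Brownian (optionally confined) cluster tracks at the DMC/ISEP
  diffusivity scales, 1 s frames;
* intensity-vs-copies calibration standards with multiplicative noise at
  the fitted slope, plus background-contaminated cluster spots;
* saturation-binding titrations over 1e-8 to 1e-4 M lipid;
* binomially labeled few-site photobleaching standards.

Each generator draws from its own RNG stream derived from
(seed, stage name), so regenerating one kind of fixture never perturbs
the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import TitrationDataset, langmuir_fraction_bound
from .exceptions import ConfigurationError
from .quantify import BleachTraceSet
from .tracking import Track

__all__ = [
    "SimulationSpec",
    "gen_brownian_tracks",
    "gen_titration",
    "gen_calibration_and_spots",
    "gen_bleach_traces",
    "stage_rng",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent RNG stream for (seed, stage), stable across sessions."""
    digest = int.from_bytes(
        hashlib.sha256(stage.encode()).digest()[:8], "little"
    )
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters for all synthetic fixtures.

    Defaults are the study conditions: 24 DMC-like tracks of 250 one-
    second frames at D = 2800 nm^2/s; titrations over 1e-8 to 1e-4 M
    lipid with Gaussian noise sd 0.05; calibration standards of
    4/20/40/56/80 fluorophores at 29.56 au per copy; cluster spots with
    40 emitters; 200 five-site bleaching standards labeled with
    probability 0.8.
    """

    seed: int

    # --- particle tracks ---
    n_tracks: int = 24
    n_frames: int = 250
    dt_s: float = 1.0
    diffusivity: float = 2800.0  # nm^2/s
    loc_noise_sd: float = 0.0  # nm, isotropic localization noise
    confinement_rate: float = 0.0  # 1/s, mean reversion toward the origin

    # --- binding titration ---
    true_kd: float = 1.0e-6  # M
    conc_min: float = 1e-8  # M
    conc_max: float = 1e-4  # M
    n_conc: int = 13
    titration_noise_sd: float = 0.05

    # --- calibration standards and spots ---
    slope: float = 29.56  # au per fluorophore
    copies: tuple = (4, 20, 40, 56, 80)
    n_per_copy: int = 10
    intensity_cv: float = 0.10
    emitters_per_spot: int = 40
    n_spots: int = 100
    background_mean: float = 500.0  # au per 6x6 box
    background_sd: float = 50.0

    # --- bleaching standards ---
    n_sites: int = 5
    labeling_p: float = 0.80
    n_traces: int = 200

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed is mandatory and must be an integer")
        positive = (
            "n_tracks n_frames dt_s diffusivity true_kd conc_min conc_max "
            "n_conc slope n_per_copy emitters_per_spot n_spots n_sites "
            "n_traces background_mean"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        nonneg = (
            "loc_noise_sd confinement_rate titration_noise_sd intensity_cv "
            "background_sd"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.labeling_p <= 1.0:
            raise ConfigurationError("labeling_p must lie in [0, 1]")
        if self.conc_min >= self.conc_max:
            raise ConfigurationError("conc_min must be below conc_max")
        if self.diffusivity > 0 and self.n_frames < 2:
            raise ConfigurationError("tracks need at least 2 frames")


def gen_brownian_tracks(spec: SimulationSpec) -> list:
    """Simulate independent 2D Brownian tracks.

    Per-axis increments are Gaussian with variance 2 D dt.  With
    ``confinement_rate`` k > 0 increments acquire a mean-reverting drift
    -k x dt (harmonic confinement), emulating ISEP-like near-immobile
    spots; with ``loc_noise_sd`` > 0 isotropic localization noise is
    added to the reported positions.
    """
    rng = stage_rng(spec.seed, "tracks")
    step_sd = np.sqrt(2.0 * spec.diffusivity * spec.dt_s)
    t = spec.dt_s * np.arange(spec.n_frames)
    tracks = []
    for i in range(spec.n_tracks):
        steps = rng.normal(0.0, step_sd, size=(spec.n_frames - 1, 2))
        pos = np.zeros((spec.n_frames, 2))
        if spec.confinement_rate > 0:
            k = spec.confinement_rate * spec.dt_s
            for j in range(1, spec.n_frames):
                pos[j] = pos[j - 1] * (1.0 - k) + steps[j - 1]
        else:
            pos[1:] = np.cumsum(steps, axis=0)
        if spec.loc_noise_sd > 0:
            pos = pos + rng.normal(0.0, spec.loc_noise_sd, size=pos.shape)
        tracks.append(
            Track(track_id=f"sim{i:03d}", t=t, x=pos[:, 0], y=pos[:, 1])
        )
    return tracks


def gen_titration(spec: SimulationSpec) -> TitrationDataset:
    """Langmuir isotherm on a log-spaced grid plus Gaussian noise.

    Noise is clipped to keep fractions in [0, 1], as a bounded assay
    readout would be.
    """
    rng = stage_rng(spec.seed, "titration")
    conc = np.geomspace(spec.conc_min, spec.conc_max, spec.n_conc)
    fb = langmuir_fraction_bound(conc, spec.true_kd)
    if spec.titration_noise_sd > 0:
        fb = fb + rng.normal(0.0, spec.titration_noise_sd, size=fb.shape)
    return TitrationDataset(
        lipid_conc=conc, fraction_bound=np.clip(fb, 0.0, 1.0)
    )


def gen_calibration_and_spots(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calibration standards and background-contaminated cluster spots.

    Standards: intensity = slope * copies * (1 + eta) with
    eta ~ Normal(0, cv), ``n_per_copy`` replicates per design copy
    number.  Spots: summed intensity of ``emitters_per_spot`` emitters
    with the same multiplicative noise, plus an additive background drawn
    per spot; the background sum is reported alongside so that
    background subtraction is exercised downstream.
    """
    rng = stage_rng(spec.seed, "calibration")
    copies = np.repeat(np.asarray(spec.copies, float), spec.n_per_copy)
    eta = rng.normal(0.0, spec.intensity_cv, size=copies.shape)
    calibration = pd.DataFrame(
        {"copies": copies, "intensity_au": spec.slope * copies * (1.0 + eta)}
    )
    bg = rng.normal(spec.background_mean, spec.background_sd, size=spec.n_spots)
    eta_s = rng.normal(0.0, spec.intensity_cv, size=spec.n_spots)
    signal = spec.slope * spec.emitters_per_spot * (1.0 + eta_s)
    spots = pd.DataFrame(
        {
            "spot_id": [f"spot{i:03d}" for i in range(spec.n_spots)],
            "spot_sum_au": signal + bg,
            "background_sum_au": bg,
        }
    )
    return calibration, spots


def gen_bleach_traces(spec: SimulationSpec) -> BleachTraceSet:
    """Photobleaching step counts ~ i.i.d. Binomial(n_sites, labeling_p)."""
    rng = stage_rng(spec.seed, "bleach")
    counts = rng.binomial(spec.n_sites, spec.labeling_p, size=spec.n_traces)
    return BleachTraceSet(step_counts=counts, n_sites=spec.n_sites)
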