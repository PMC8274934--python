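"""Equilibrium free-energy model of a protein-stabilized membrane neck.

At the end of engulfment in sporulating *B. subtilis* a thin cylindrical
membrane neck (radius R, length L) connects the engulfment membrane to the
rest of the mother-cell membrane.  The fission protein FisB accumulates in
the neck.  This module implements a minimal equilibrium model for that
accumulation: the membrane contributes Helfrich bending energy and tension,
and FisB proteins in the neck contribute translational entropy, a
Lennard-Jones-like *trans* attraction across the neck lumen (strength ``a``)
and a steep crowding penalty above the close-packing density ``phi_rmax``.

Internal units are thermal: energies in kBT, lengths in nm, surface
densities in nm^-2.  Use :func:`fisbkit.units.convert_units` (or
:meth:`ModelParams.from_dict`) to feed in laboratory values (N/m, um^-2).

The coupled stationarity conditions are

* density condition:  kBT[1 + ln(phi/phi0)] + 2 a phi V_LJ(R) + U'(phi) = 0
* radius condition:   gamma_eff - kappa/(2 R^2)
                      + a phi^2 [6 (sigma/R)^6 - 12 (sigma/R)^12]
                      - 2 gamma R / L = 0

with gamma_eff = gamma + kBT phi ln(phi/phi0) + U(phi).  The radius
condition is available in two variants: ``"printed"`` (the form above) and
``"variational"`` (the exact dF/dR of the implemented free energy, which
additionally carries an ``a phi^2 V_LJ(R)`` term).  Both are kept because
they bracket a genuine ambiguity in the model's published form; they give
very close equilibria at the reference parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import (
    ConfigurationError,
    DomainError,
    NoSolutionError,
    NoTransitionError,
)
from .units import DEFAULT_TEMPERATURE_K, convert_units

__all__ = [
    "ModelParams",
    "NeckGeometry",
    "EquilibriumState",
    "SweepResult",
    "GridSpec",
    "lj_potential",
    "phi_rmax_from_sigma",
    "crowding_penalty",
    "crowding_penalty_derivative",
    "free_energy",
    "density_residual",
    "solve_density",
    "radius_residual",
    "solve_equilibrium",
    "minimize_free_energy_grid",
    "sweep_interaction_strength",
    "find_critical_a",
    "reference_params",
]

_VARIANTS = ("printed", "variational")


# ---------------------------------------------------------------------------
# parameters and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the neck model, in internal units.

    Attributes
    ----------
    kappa : float
        Membrane bending modulus, kBT.
    gamma : float
        Membrane tension, kBT nm^-2.
    sigma_trans : float
        Length scale of the trans Lennard-Jones interaction, nm.
    sigma_cis : float
        Length scale of the cis (in-plane) repulsion setting the
        close-packing distance r_max = 2^(1/6) sigma_cis, nm.
    epsilon : float
        Energy scale of the crowding penalty, kBT nm^-2.
    a : float
        Trans homo-oligomerization strength, kBT nm^2 per protein density.
    phi0 : float
        Background FisB surface density in the surrounding sheets, nm^-2.
    L : float
        Neck length, nm.
    temperature : float
        Absolute temperature in K, used only for unit conversion.
    phi_rmax : float
        Onset-of-crowding density, nm^-2.  Derived from ``sigma_cis``
        unless explicitly overridden.
    """

    kappa: float
    gamma: float
    sigma_trans: float
    sigma_cis: float
    epsilon: float
    a: float
    phi0: float
    L: float
    temperature: float = DEFAULT_TEMPERATURE_K
    phi_rmax: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.phi_rmax is None:
            object.__setattr__(
                self, "phi_rmax", phi_rmax_from_sigma(self.sigma_cis)
            )
        for name in (
            "kappa",
            "gamma",
            "sigma_trans",
            "sigma_cis",
            "epsilon",
            "phi0",
            "L",
            "temperature",
            "phi_rmax",
        ):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise DomainError(f"{name} must be strictly positive, got {v}")
        if self.a < 0 or not math.isfinite(self.a):
            raise DomainError(f"a must be non-negative and finite, got {self.a}")

    @property
    def r_max(self) -> float:
        """Nearest-neighbour distance at the onset of crowding, nm."""
        return 2 ** (1 / 6) * self.sigma_cis

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build from a config mapping, converting annotated units.

        Values may be plain numbers (assumed already internal) or mappings
        ``{"value": x, "unit": "N/m"}``; tensions given in N/m and
        densities in um^-2 are converted at the configured temperature.
        """
        temperature = float(d.get("temperature", DEFAULT_TEMPERATURE_K))
        internal = {
            "gamma": "kBT/nm^2",
            "epsilon": "kBT/nm^2",
            "phi0": "nm^-2",
            "phi_rmax": "nm^-2",
        }
        kwargs: dict = {"temperature": temperature}
        known = {
            "kappa",
            "gamma",
            "sigma_trans",
            "sigma_cis",
            "epsilon",
            "a",
            "phi0",
            "L",
            "phi_rmax",
        }
        unknown = set(d) - known - {"temperature"}
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        for key in known:
            if key not in d:
                continue
            v = d[key]
            if isinstance(v, dict):
                value = float(v["value"])
                unit = v.get("unit")
                if unit is not None:
                    value = convert_units(
                        value, unit, internal.get(key, unit), temperature
                    )
                kwargs[key] = value
            else:
                kwargs[key] = float(v)
        return cls(**kwargs)


def reference_params(**overrides) -> ModelParams:
    """The reference parameter point of the stability analysis.

    kappa = 20 kBT, gamma = 1e-4 N/m, sigma = sigma_cis = 2.47 nm,
    epsilon = 32.78 kBT nm^-2, phi0 = 100 um^-2, L = 40 nm and
    a = 1e4 kBT nm^2; gamma and phi0 are converted to internal units
    at 298 K.  Keyword overrides replace individual fields.
    """
    temperature = overrides.pop("temperature", DEFAULT_TEMPERATURE_K)
    base = ModelParams(
        kappa=20.0,
        gamma=convert_units(1e-4, "N/m", "kBT/nm^2", temperature),
        sigma_trans=2.47,
        sigma_cis=2.47,
        epsilon=32.78,
        a=1e4,
        phi0=convert_units(100.0, "um^-2", "nm^-2"),
        L=40.0,
        temperature=temperature,
    )
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class NeckGeometry:
    """Cylindrical neck geometry: H = 1/R (twice the mean curvature)."""

    R: float
    L: float

    def __post_init__(self):
        if self.R <= 0 or self.L <= 0:
            raise DomainError("R and L must be strictly positive")

    @property
    def H(self) -> float:
        return 1.0 / self.R

    @property
    def area(self) -> float:
        return 2.0 * math.pi * self.R * self.L


@dataclass(frozen=True)
class EquilibriumState:
    """A solved neck equilibrium (or the open-neck outcome).

    For an open neck (no stable radius in the bracket) ``R`` is ``inf`` and
    the density/energy fields are NaN; ``n_in_neck`` is the molecule count
    2 pi R L phi for a closed neck.
    """

    R: float
    phi: float
    free_energy: float
    gamma_eff: float
    neck_open: bool
    n_in_neck: float

    @classmethod
    def open_neck(cls) -> "EquilibriumState":
        return cls(
            R=math.inf,
            phi=math.nan,
            free_energy=math.nan,
            gamma_eff=math.nan,
            neck_open=True,
            n_in_neck=math.nan,
        )


@dataclass
class SweepResult:
    """Equilibria along a sweep of the trans interaction strength ``a``."""

    a_values: list
    states: list
    a_critical: float | None = None
    failures: list = field(default_factory=list)

    def to_frame(self, L: float | None = None) -> pd.DataFrame:
        rows = []
        for a, st in zip(self.a_values, self.states):
            rows.append(
                {
                    "a": a,
                    "L": L,
                    "R_nm": st.R,
                    "phi_per_um2": convert_units(st.phi, "nm^-2", "um^-2")
                    if not st.neck_open
                    else math.nan,
                    "n_in_neck": st.n_in_neck,
                    "neck_open": st.neck_open,
                    "free_energy_kBT": st.free_energy,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary energy terms
# ---------------------------------------------------------------------------


def lj_potential(r, sigma):
    """Dimensionless Lennard-Jones factor (sigma/r)^12 - (sigma/r)^6."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("r must be strictly positive")
    if not sigma > 0:
        raise DomainError("sigma must be strictly positive")
    x6 = (sigma / r) ** 6
    out = x6 * x6 - x6
    return out if out.ndim else float(out)


def phi_rmax_from_sigma(sigma_cis: float) -> float:
    """Close-packing onset density 2^(2/3) / (3^(3/2) sigma_cis^2), nm^-2.

    This is the triangular-lattice density at nearest-neighbour spacing
    r_max = 2^(1/6) sigma_cis, the minimum of the in-plane LJ repulsion.
    """
    if not sigma_cis > 0:
        raise DomainError("sigma_cis must be strictly positive")
    return 2 ** (2 / 3) / (3**1.5 * sigma_cis**2)


def crowding_penalty(phi, params: ModelParams):
    """Crowding energy density U(phi), kBT nm^-2.

    Zero below the close-packing onset phi_rmax; above it,
    epsilon (phi^3 - phi_rmax^3)^2 / (4 phi_rmax^6).  Continuous and once
    differentiable at the onset.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise DomainError("phi must be non-negative")
    pr = params.phi_rmax
    excess = np.where(phi >= pr, phi**3 - pr**3, 0.0)
    out = params.epsilon * excess**2 / (4.0 * pr**6)
    return out if out.ndim else float(out)


def crowding_penalty_derivative(phi, params: ModelParams):
    """dU/dphi, kBT; zero below phi_rmax, smooth at the onset."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0):
        raise DomainError("phi must be non-negative")
    pr = params.phi_rmax
    excess = np.where(phi >= pr, phi**3 - pr**3, 0.0)
    out = params.epsilon * 1.5 * phi**2 * excess / pr**6
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# free energy and stationarity residuals
# ---------------------------------------------------------------------------


def free_energy(R, phi, params: ModelParams):
    """Total free energy of the neck relative to the open-neck reference, kBT.

    F = 2 pi R L [kappa/(2R^2) + gamma + phi ln(phi/phi0)
                  + a V_LJ(R) phi^2 + U(phi)] - 2 pi R^2 gamma.

    The trailing term accounts for the disc of sheet membrane (one per
    sheet) replaced when the neck widens; it is what makes tension favour
    neck expansion.
    """
    R = np.asarray(R, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(R <= 0) or np.any(phi <= 0):
        raise DomainError("R and phi must be strictly positive")
    p = params
    per_area = (
        p.kappa / (2.0 * R**2)
        + p.gamma
        + phi * np.log(phi / p.phi0)
        + p.a * lj_potential(R, p.sigma_trans) * phi**2
        + crowding_penalty(phi, p)
    )
    out = 2.0 * np.pi * R * p.L * per_area - 2.0 * np.pi * R**2 * p.gamma
    return out if out.ndim else float(out)


def density_residual(phi, R, params: ModelParams):
    """Left-hand side of the equilibrium-density condition, kBT.

    kBT[1 + ln(phi/phi0)] + 2 a phi V_LJ(R) + U'(phi); zero at the
    stationary density for the given radius.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0):
        raise DomainError("phi must be strictly positive")
    if not np.all(np.asarray(R) > 0):
        raise DomainError("R must be strictly positive")
    p = params
    out = (
        1.0
        + np.log(phi / p.phi0)
        + 2.0 * p.a * phi * lj_potential(R, p.sigma_trans)
        + crowding_penalty_derivative(phi, p)
    )
    return out if out.ndim else float(out)


def radius_residual(R, phi, params: ModelParams, variant: str = "printed"):
    """Radius force-balance residual, kBT nm^-2.

    ``"printed"``:  gamma_eff - kappa/(2R^2)
                    + a phi^2 [6 (sigma/R)^6 - 12 (sigma/R)^12] - 2 gamma R/L
    with gamma_eff = gamma + phi ln(phi/phi0) + U(phi).

    ``"variational"``: the exact dF/dR of :func:`free_energy` divided by
    2 pi L, which equals the printed form plus a phi^2 V_LJ(R).
    """
    if variant not in _VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose one of {_VARIANTS}"
        )
    R = np.asarray(R, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(R <= 0) or np.any(phi <= 0):
        raise DomainError("R and phi must be strictly positive")
    p = params
    x6 = (p.sigma_trans / R) ** 6
    gamma_eff = (
        p.gamma + phi * np.log(phi / p.phi0) + crowding_penalty(phi, p)
    )
    out = (
        gamma_eff
        - p.kappa / (2.0 * R**2)
        + p.a * phi**2 * (6.0 * x6 - 12.0 * x6 * x6)
        - 2.0 * p.gamma * R / p.L
    )
    if variant == "variational":
        out = out + p.a * phi**2 * (x6 * x6 - x6)
    return out if out.ndim else float(out)


def effective_gamma(R: float, phi: float, params: ModelParams) -> float:
    """Composite tension gamma_eff = gamma + phi ln(phi/phi0) + U(phi)."""
    p = params
    return float(
        p.gamma + phi * math.log(phi / p.phi0) + crowding_penalty(phi, p)
    )


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

_PHI_SCAN_POINTS = 256


def _density_roots(R: float, params: ModelParams, phi_cap: float) -> list:
    """All sign-change roots of the density condition on (0, phi_cap]."""
    p = params
    lo = min(p.phi0, p.phi_rmax) * 1e-8
    grid = np.geomspace(lo, phi_cap, _PHI_SCAN_POINTS)
    res = density_residual(grid, R, p)
    roots = []
    sign = np.sign(res)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        roots.append(
            brentq(
                lambda f: density_residual(f, R, p),
                grid[i],
                grid[i + 1],
                xtol=1e-16,
                rtol=1e-14,
            )
        )
    # exact grid hits (rare)
    for i in np.nonzero(sign == 0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def _stable_density_roots(R: float, params: ModelParams, phi_cap: float) -> list:
    """Density roots that are local minima of F in phi at fixed R.

    The density residual is dF/dphi per unit area and tends to -inf as
    phi -> 0, so sign-change roots alternate minimum / maximum starting
    with a minimum: the stable roots are the even-indexed ones.
    """
    return _density_roots(R, params, phi_cap)[0::2]


def solve_density(
    R: float, params: ModelParams, phi_cap: float | None = None
) -> float:
    """Stationary FisB density in the neck at fixed radius, nm^-2.

    Returns the root of the density condition on (0, phi_cap]
    (default cap 10 phi_rmax).  When both a dilute and a crowded branch
    exist, the one with the lower free energy at this R is returned.
    """
    if not R > 0:
        raise DomainError("R must be strictly positive")
    if phi_cap is None:
        phi_cap = 10.0 * params.phi_rmax
    roots = _density_roots(R, params, phi_cap)
    if not roots:
        raise NoSolutionError(
            f"no stationary density in (0, {phi_cap:g}] at R = {R:g} nm"
        )
    if len(roots) == 1:
        return roots[0]
    energies = [free_energy(R, f, params) for f in roots]
    return roots[int(np.argmin(energies))]


def _track_phi(R, params, phi_cap, branch):
    """Stable density root on the dilute ('lo') or crowded ('hi') branch."""
    roots = _stable_density_roots(R, params, phi_cap)
    if not roots:
        raise NoSolutionError(f"no stable density at R = {R:g} nm")
    return roots[0] if branch == "lo" else roots[-1]


def solve_equilibrium(
    params: ModelParams,
    variant: str = "printed",
    phi_cap: float | None = None,
    R_bracket: tuple = (None, 200.0),
    n_scan: int = 256,
    tol: float = 1e-8,
) -> EquilibriumState:
    """Solve the coupled density and radius conditions.

    The density condition is solved exactly (nested root find) at each
    radius, reducing the problem to 1D root finds on the radius residual
    along the density-stationary paths phi(R).  The density condition can
    admit two stable branches -- a dilute one near phi0/e and a crowded
    one near phi_rmax; each is scanned separately so that a metastable
    crowded cluster is still detected as a closed neck.  Closed equilibria
    are the crossings where the radius residual turns from negative to
    positive as R grows (free-energy minima along the branch); among
    several the lowest-energy one is returned.  If no such crossing exists
    in the bracket the neck is classified as open (R -> infinity in this
    model).

    The default bracket starts at sigma_trans: the hard trans repulsion
    forbids radii below the LJ core.
    """
    if variant not in _VARIANTS:
        raise ConfigurationError(
            f"unknown variant {variant!r}; choose one of {_VARIANTS}"
        )
    lo = R_bracket[0] if R_bracket[0] is not None else params.sigma_trans
    hi = R_bracket[1]
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid R bracket ({lo}, {hi})")
    if phi_cap is None:
        phi_cap = 10.0 * params.phi_rmax

    R_grid = np.geomspace(lo, hi, n_scan)
    candidates = []
    for branch in ("lo", "hi"):
        g = np.array(
            [
                radius_residual(
                    R, _track_phi(R, params, phi_cap, branch), params, variant
                )
                for R in R_grid
            ]
        )

        def g_of_R(R, _b=branch):
            return radius_residual(
                R, _track_phi(R, params, phi_cap, _b), params, variant
            )

        for i in np.nonzero((g[:-1] < 0) & (g[1:] >= 0))[0]:
            R_star = brentq(
                g_of_R, R_grid[i], R_grid[i + 1], xtol=1e-12, rtol=1e-14
            )
            phi_star = _track_phi(R_star, params, phi_cap, branch)
            if abs(
                radius_residual(R_star, phi_star, params, variant)
            ) < max(tol, 1e-8) * max(1.0, abs(params.gamma)):
                candidates.append((R_star, phi_star))
    if not candidates:
        return EquilibriumState.open_neck()
    energies = [free_energy(R, f, params) for R, f in candidates]
    R_star, phi_star = candidates[int(np.argmin(energies))]
    return EquilibriumState(
        R=R_star,
        phi=phi_star,
        free_energy=free_energy(R_star, phi_star, params),
        gamma_eff=effective_gamma(R_star, phi_star, params),
        neck_open=False,
        n_in_neck=2.0 * math.pi * R_star * params.L * phi_star,
    )


@dataclass(frozen=True)
class GridSpec:
    """Grid for brute-force free-energy minimization.

    ``R_max`` defaults to 50 nm: far above any closed-neck radius (which
    sits near r_max ~ 2.8 nm) yet below the radius at which the open
    branch, whose energy decreases without bound as tension removes sheet
    area, undercuts a closed minimum.
    """

    R_min: float | None = None  # defaults to sigma_trans
    R_max: float = 50.0
    n_R: int = 160
    phi_min: float | None = None  # defaults to 1e-3 * phi0
    phi_cap: float | None = None  # defaults to 10 * phi_rmax
    n_phi: int = 160
    n_refine: int = 3

    def axes(self, params: ModelParams):
        r_lo = self.R_min if self.R_min is not None else params.sigma_trans
        f_lo = self.phi_min if self.phi_min is not None else 1e-3 * params.phi0
        f_hi = (
            self.phi_cap
            if self.phi_cap is not None
            else 10.0 * params.phi_rmax
        )
        if not (0 < r_lo < self.R_max and 0 < f_lo < f_hi):
            raise ConfigurationError("degenerate grid specification")
        if self.n_R < 3 or self.n_phi < 3:
            raise ConfigurationError("grid needs at least 3 points per axis")
        return (
            np.geomspace(r_lo, self.R_max, self.n_R),
            np.geomspace(f_lo, f_hi, self.n_phi),
        )


def minimize_free_energy_grid(
    params: ModelParams, grid_spec: GridSpec | None = None
) -> EquilibriumState:
    """Brute-force argmin of the free energy on an (R, phi) grid.

    Serves as the independent equivalence oracle for
    :func:`solve_equilibrium`.  The grid argmin is refined by three
    levels of local grid zooming (factor ~10 per level).  An argmin on
    the upper R edge is classified as an open neck (the energy keeps
    decreasing with radius).
    """
    spec = grid_spec or GridSpec()
    R_ax, phi_ax = spec.axes(params)
    F = free_energy(R_ax[:, None], phi_ax[None, :], params)
    i, j = np.unravel_index(np.argmin(F), F.shape)
    if i == len(R_ax) - 1:
        return EquilibriumState.open_neck()

    R_best, phi_best = R_ax[i], phi_ax[j]
    dlogR = math.log(R_ax[1] / R_ax[0])
    dlogF = math.log(phi_ax[1] / phi_ax[0])
    for _ in range(spec.n_refine):
        r_loc = R_best * np.exp(np.linspace(-dlogR, dlogR, 21))
        f_loc = phi_best * np.exp(np.linspace(-dlogF, dlogF, 21))
        Floc = free_energy(r_loc[:, None], f_loc[None, :], params)
        ii, jj = np.unravel_index(np.argmin(Floc), Floc.shape)
        R_best, phi_best = r_loc[ii], f_loc[jj]
        dlogR /= 10.0
        dlogF /= 10.0
    return EquilibriumState(
        R=R_best,
        phi=phi_best,
        free_energy=free_energy(R_best, phi_best, params),
        gamma_eff=effective_gamma(R_best, phi_best, params),
        neck_open=False,
        n_in_neck=2.0 * math.pi * R_best * params.L * phi_best,
    )


def sweep_interaction_strength(
    a_values: Sequence[float],
    params: ModelParams,
    variant: str = "printed",
    refine_critical: bool = True,
) -> SweepResult:
    """Equilibria as a function of the trans interaction strength ``a``.

    ``a_values`` must be sorted ascending.  Solver failures at individual
    points are recorded in ``failures`` without aborting the sweep.  If
    the sweep brackets the open/closed transition, ``a_critical`` is
    refined by bisection between the bracketing points.
    """
    a_values = list(a_values)
    if any(b < a for a, b in zip(a_values, a_values[1:])):
        raise ConfigurationError("a_values must be sorted ascending")
    states, failures = [], []
    for a in a_values:
        try:
            states.append(solve_equilibrium(replace(params, a=a), variant))
        except Exception as exc:  # noqa: BLE001 - recorded per spec contract
            failures.append((a, repr(exc)))
            states.append(EquilibriumState.open_neck())
    result = SweepResult(a_values=a_values, states=states, failures=failures)
    closed = [not s.neck_open for s in states]
    if refine_critical and any(closed) and not all(closed):
        first_closed = closed.index(True)
        if first_closed > 0:
            try:
                result.a_critical = find_critical_a(
                    params,
                    variant,
                    bracket=(a_values[first_closed - 1], a_values[first_closed]),
                )
            except NoTransitionError:
                pass
    return result


def find_critical_a(
    params: ModelParams,
    variant: str = "printed",
    tol: float = 1e-5,
    bracket: tuple = (1e2, 1e6),
) -> float:
    """Critical trans interaction strength below which the neck opens.

    Bisection on the open/closed classification of
    :func:`solve_equilibrium`, to relative tolerance ``tol`` in ``a``.
    The default tolerance is tight because the L-dependence of the
    critical strength enters only through the weak sheet-tension term
    (-2 gamma R / L) and amounts to a few parts in a thousand.
    """
    a_lo, a_hi = bracket
    if not 0 < a_lo < a_hi:
        raise ConfigurationError(f"invalid a bracket {bracket}")

    def closed(a):
        return not solve_equilibrium(replace(params, a=a), variant).neck_open

    lo_closed, hi_closed = closed(a_lo), closed(a_hi)
    if lo_closed == hi_closed:
        state = "closed" if lo_closed else "open"
        raise NoTransitionError(
            f"neck is {state} at both ends of a bracket {bracket}"
        )
    # transition is monotone: open below, closed above
    while (a_hi - a_lo) > tol * a_hi:
        mid = math.sqrt(a_lo * a_hi)
        if closed(mid) == hi_closed:
            a_hi = mid
        else:
            a_lo = mid
    return math.sqrt(a_lo * a_hi)
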