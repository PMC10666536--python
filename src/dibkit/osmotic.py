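"""Osmotic water transport across a droplet interface bilayer.

Two aqueous droplets joined by a bilayer of contact area A exchange water
when their osmolyte concentrations differ. With impermeable solutes
(amounts n1, n2 fixed) the standard osmotic volume-flow law gives

    dV1/dt = Pf · V_w · A · (c1 − c2),   c_i = n_i / V_i,
    dV2/dt = −dV1/dt,

where Pf is the osmotic water permeability (μm/s) and V_w the molar volume
of water. Water flows into the more concentrated droplet; the pair relaxes
monotonically toward c1 = c2, i.e. V1/V2 = n1/n2, at fixed total volume.

Internal unit system: lengths μm, areas μm², volumes μm³, time s,
concentrations mol/m³ (numerically equal to mOsm/kg in the dilute
convention). The product V_w·Δc is dimensionless, so Pf·A·(V_w·Δc) is
directly a volume rate in μm³/s.

Inversion of observed shrinkage to Pf is offered two ways: an
initial-slope estimator (linear fit of early volumes) and a full-trajectory
least-squares fit against the forward model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, minimize_scalar

from .errors import (CannotEstimateError, DomainError, FitError,
                     IntegrationError, InvalidGeometryError)

__all__ = [
    "V_W_CM3_PER_MOL",
    "DropletPairState",
    "ShrinkageSeries",
    "PermeabilityEstimate",
    "osmolality_to_concentration",
    "volumes_from_radii",
    "radius_from_volume",
    "simulate_droplet_pair",
    "pf_initial_slope",
    "pf_fit_trajectory",
    "relative_change",
]

#: Molar volume of water, cm³/mol, at the 25–30 °C working range.
V_W_CM3_PER_MOL = 18.05

# V_w·c is dimensionless when V_w is in m³/mol and c in mol/m³.
_V_W_M3_PER_MOL = V_W_CM3_PER_MOL * 1e-6


def osmolality_to_concentration(osmolality: float) -> float:
    """Map osmolality (mOsm/kg) to concentration (mol/m³).

    Dilute-solution convention with water density 1 kg/L: 1 mOsm/kg of
    solvent ≡ 1 mmol/L of solution ≡ 1 mol/m³.
    """
    if osmolality < 0:
        raise DomainError(f"osmolality must be nonnegative, got {osmolality}")
    return float(osmolality)


def _cap_height(R: float, r: float) -> float:
    return R - math.sqrt(R * R - r * r)


def _cap_volume(R: float, r: float) -> float:
    h = _cap_height(R, r)
    return math.pi * h * h * (R - h / 3.0)


def _sphere_volume(R: float) -> float:
    return 4.0 / 3.0 * math.pi * R ** 3


def volumes_from_radii(R1: float, R2: float, r: float,
                       mode: str = "sphere") -> tuple[float, float]:
    """Reconstruct droplet volumes (μm³) from radii.

    ``mode="sphere"``: full-sphere volume (cap correction neglected;
    second-order for contact angles in the 25–37° range).
    ``mode="truncated"``: sphere minus the spherical cap cut off by the
    contact plane of radius ``r``.
    """
    if R1 <= 0 or R2 <= 0:
        raise InvalidGeometryError(f"radii must be positive, got {R1}, {R2}")
    if not 0.0 <= r <= min(R1, R2):
        raise InvalidGeometryError(f"contact radius {r} outside [0, min(R1,R2)]")
    if mode == "sphere":
        return _sphere_volume(R1), _sphere_volume(R2)
    if mode == "truncated":
        return (_sphere_volume(R1) - _cap_volume(R1, r),
                _sphere_volume(R2) - _cap_volume(R2, r))
    raise ValueError(f"mode must be 'sphere' or 'truncated', got {mode!r}")


def radius_from_volume(V: float, r: float = 0.0, mode: str = "sphere") -> float:
    """Invert :func:`volumes_from_radii` for one droplet.

    For ``"truncated"`` the radius solves V = (4/3)πR³ − cap(R, r)
    numerically (the truncated volume is monotone in R for R ≥ r).
    """
    if V <= 0:
        raise DomainError(f"volume must be positive, got {V}")
    R_sphere = (3.0 * V / (4.0 * math.pi)) ** (1.0 / 3.0)
    if mode == "sphere":
        return R_sphere
    if mode != "truncated":
        raise ValueError(f"mode must be 'sphere' or 'truncated', got {mode!r}")
    if r == 0.0:
        return R_sphere

    def f(R: float) -> float:
        return _sphere_volume(R) - _cap_volume(R, r) - V

    lo = max(R_sphere, r * (1 + 1e-12))
    hi = lo * 2.0
    while f(hi) < 0:
        hi *= 2.0
    if f(lo) > 0:
        lo = r * (1 + 1e-12)
    return brentq(f, lo, hi, xtol=1e-12 * R_sphere)


@dataclass(frozen=True)
class DropletPairState:
    """State of the closed two-droplet system at one instant.

    Volumes in μm³, solute amounts in (mol/m³)·μm³ (i.e. concentration
    × volume in internal units), bilayer contact area in μm², time in s.
    """

    V1: float
    V2: float
    n1: float
    n2: float
    A: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.V1 <= 0 or self.V2 <= 0:
            raise DomainError("droplet volumes must be positive")
        if self.n1 < 0 or self.n2 < 0:
            raise DomainError("solute amounts must be nonnegative")
        if self.A < 0:
            raise DomainError("contact area must be nonnegative")

    @property
    def c1(self) -> float:
        return self.n1 / self.V1

    @property
    def c2(self) -> float:
        return self.n2 / self.V2

    @classmethod
    def from_series(cls, series: "ShrinkageSeries",
                    mode: str = "sphere") -> "DropletPairState":
        """Initial state consistent with a series at t = 0."""
        V1, V2 = volumes_from_radii(series.R1[0], series.R2[0], series.r[0], mode)
        c1 = osmolality_to_concentration(series.osmolality1)
        c2 = osmolality_to_concentration(series.osmolality2)
        A = math.pi * series.r[0] ** 2
        return cls(V1=V1, V2=V2, n1=c1 * V1, n2=c2 * V2, A=A, t=float(series.t[0]))


@dataclass
class ShrinkageSeries:
    """Observed (or simulated) droplet-pair radius time series.

    ``t`` in s (strictly increasing), radii in μm, initial osmolalities in
    mOsm/kg.
    """

    t: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    r: np.ndarray
    osmolality1: float
    osmolality2: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.R1 = np.asarray(self.R1, dtype=float)
        self.R2 = np.asarray(self.R2, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.t)
        if not (len(self.R1) == len(self.R2) == len(self.r) == n):
            raise ValueError("t, R1, R2, r must have equal length")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.R1 <= 0) or np.any(self.R2 <= 0):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Result of a Pf inversion."""

    pf_hat: float           # μm/s
    method: str             # "initial-slope" | "trajectory-fit"
    se: float               # standard error, μm/s
    residual_norm: float    # RMS residual of the fit
    n_points: int


def _rhs_factory(n1: float, n2: float, V_tot: float, A: float, pf: float):
    k = pf * A * _V_W_M3_PER_MOL

    def rhs(t: float, y: np.ndarray) -> list[float]:
        V1 = y[0]
        V2 = V_tot - V1
        return [k * (n1 / V1 - n2 / V2)]

    return rhs


def simulate_droplet_pair(state0: DropletPairState, pf: float, t_end: float,
                          dt: float, noise_sd: float = 0.0,
                          seed: int | None = None,
                          geometry_mode: str = "sphere") -> ShrinkageSeries:
    """Forward-simulate osmotic shrinkage and sample it as a radius series.

    Integrates V1 with an adaptive solver (V2 by conservation, so total
    volume is conserved exactly); ``dt`` is the sampling interval, not the
    solver step. Radii are back-computed from volumes in ``geometry_mode``
    with the contact radius held at its initial value, and optionally
    perturbed by multiplicative Gaussian noise of relative scale
    ``noise_sd`` (seeded; ``noise_sd > 0`` requires a seed).
    """
    if pf < 0:
        raise DomainError(f"Pf must be nonnegative, got {pf}")
    if dt <= 0 or t_end <= 0:
        raise DomainError("t_end and dt must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be nonnegative")
    if noise_sd > 0 and seed is None:
        raise DomainError("noisy simulation requires an explicit seed")

    V_tot = state0.V1 + state0.V2
    t_eval = np.arange(0.0, t_end + 0.5 * dt, dt)
    rhs = _rhs_factory(state0.n1, state0.n2, V_tot, state0.A, pf)

    v_floor = 1e-9 * V_tot

    def hit_floor(t: float, y: np.ndarray) -> float:
        return min(y[0], V_tot - y[0]) - v_floor

    hit_floor.terminal = True  # type: ignore[attr-defined]

    sol = solve_ivp(rhs, (0.0, t_end), [state0.V1], t_eval=t_eval,
                    rtol=1e-10, atol=1e-6 * V_tot, events=hit_floor,
                    method="RK45")
    if sol.status == 1:
        raise IntegrationError(
            f"droplet volume driven nonpositive at t ≈ {sol.t_events[0][0]:.3g} s; "
            "reduce t_end or check osmolalities")
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}")

    V1 = sol.y[0]
    V2 = V_tot - V1
    r_contact = math.sqrt(state0.A / math.pi)
    R1 = np.array([radius_from_volume(v, r_contact, geometry_mode) for v in V1])
    R2 = np.array([radius_from_volume(v, r_contact, geometry_mode) for v in V2])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        R1 = R1 * (1.0 + noise_sd * rng.standard_normal(R1.shape))
        R2 = R2 * (1.0 + noise_sd * rng.standard_normal(R2.shape))
    return ShrinkageSeries(
        t=sol.t, R1=R1, R2=R2, r=np.full_like(sol.t, r_contact),
        osmolality1=state0.c1, osmolality2=state0.c2,
        meta={"pf": pf, "noise_sd": noise_sd, "seed": seed,
              "geometry_mode": geometry_mode})


def pf_initial_slope(series: ShrinkageSeries, A0: float, window: int = 5,
                     geometry_mode: str = "sphere") -> PermeabilityEstimate:
    """Estimate Pf from the initial rate of volume change.

    Fits a line to the first ``window`` samples of V1(t) and inverts
    Pf = (dV1/dt)|_0 / (V_w · A0 · Δc0). Exact in the noiseless small-time
    limit; biased low as the window grows (the driving force decays).
    """
    if window < 3:
        raise ValueError("window must span at least 3 points")
    if len(series) < window:
        raise ValueError(f"series has {len(series)} points, window needs {window}")
    dc0 = (osmolality_to_concentration(series.osmolality1)
           - osmolality_to_concentration(series.osmolality2))
    if dc0 == 0:
        raise CannotEstimateError("Δc = 0: no osmotic driving force, Pf unidentifiable")

    V1 = np.array([volumes_from_radii(series.R1[i], series.R2[i], series.r[i],
                                      geometry_mode)[0]
                   for i in range(window)])
    t = series.t[:window]
    if dc0 > 0 and np.any(np.diff(V1) < -0.02 * abs(V1[0] - V1[-1]) - 1e-12):
        warnings.warn("early volumes are nonmonotone beyond noise tolerance",
                      stacklevel=2)
    coef, cov = np.polyfit(t, V1, 1, cov=True)
    slope = coef[0]
    denom = _V_W_M3_PER_MOL * A0 * dc0
    pf_hat = slope / denom
    se = math.sqrt(cov[0, 0]) / abs(denom)
    resid = V1 - np.polyval(coef, t)
    return PermeabilityEstimate(
        pf_hat=max(pf_hat, 0.0), method="initial-slope", se=se,
        residual_norm=float(np.sqrt(np.mean(resid ** 2))), n_points=window)


def _trajectory_ssr(pf: float, series: ShrinkageSeries,
                    state0: DropletPairState, geometry_mode: str) -> float:
    V_tot = state0.V1 + state0.V2
    rhs = _rhs_factory(state0.n1, state0.n2, V_tot, state0.A, pf)
    sol = solve_ivp(rhs, (float(series.t[0]), float(series.t[-1])),
                    [state0.V1], t_eval=series.t, rtol=1e-10,
                    atol=1e-6 * V_tot)
    if not sol.success:
        raise IntegrationError(f"integration failed during fit: {sol.message}")
    r0 = math.sqrt(state0.A / math.pi)
    R1 = np.array([radius_from_volume(v, r0, geometry_mode) for v in sol.y[0]])
    R2 = np.array([radius_from_volume(v, r0, geometry_mode)
                   for v in V_tot - sol.y[0]])
    return float(np.sum((R1 - series.R1) ** 2 + (R2 - series.R2) ** 2))


def pf_fit_trajectory(series: ShrinkageSeries,
                      state0: DropletPairState | None = None,
                      geometry_mode: str = "sphere",
                      pf_max: float = 1000.0) -> PermeabilityEstimate:
    """Estimate Pf by least squares of radii against the forward model.

    Minimises Σ[(R1_model − R1_obs)² + (R2_model − R2_obs)²] over Pf ≥ 0.
    The standard error comes from the local curvature of the objective:
    se = sqrt(2 σ² / SSR″(Pf̂)) with σ² the residual variance.
    """
    if len(series) < 5:
        raise ValueError("trajectory fit needs at least 5 samples")
    if state0 is None:
        state0 = DropletPairState.from_series(series, geometry_mode)
    if state0.c1 == state0.c2:
        raise CannotEstimateError("Δc = 0: no osmotic driving force, Pf unidentifiable")

    def obj(pf: float) -> float:
        return _trajectory_ssr(pf, series, state0, geometry_mode)

    res = minimize_scalar(obj, bounds=(0.0, pf_max), method="bounded",
                          options={"xatol": 1e-6})
    if not res.success:
        raise FitError(f"trajectory fit did not converge: {res.message}",
                       best=float(res.x), residual=float(res.fun))
    pf_hat = float(res.x)
    ssr = float(res.fun)
    n = 2 * len(series)
    sigma2 = ssr / max(n - 1, 1)
    h = max(1e-3 * max(pf_hat, 1.0), 1e-3)
    try:
        curv = (obj(pf_hat + h) - 2 * ssr + obj(max(pf_hat - h, 0.0))) / h ** 2
        se = math.sqrt(2 * sigma2 / curv) if curv > 0 else math.inf
    except IntegrationError:
        se = math.inf
    return PermeabilityEstimate(
        pf_hat=pf_hat, method="trajectory-fit", se=se,
        residual_norm=math.sqrt(ssr / n), n_points=len(series))


def relative_change(pf: float, pf0: float) -> int:
    """Percent change 100·(Pf − Pf°)/Pf°, rounded to the nearest integer.

    Pf° is the permeability of the same bilayer without the drug; reports
    quote whole percents.
    """
    if pf0 <= 0:
        raise DomainError(f"reference permeability must be positive, got {pf0}")
    return int(round(100.0 * (pf - pf0) / pf0))
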