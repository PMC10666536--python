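"""DSC thermogram analysis for lipid main phase transitions.

Converts a raw endothermic heat-flow scan of a multilamellar-vesicle
dispersion into molar excess heat capacity, removes a linear instrumental
baseline anchored in two flanking windows, and extracts the main
gel → liquid-crystalline transition: Tm as the apex of the excess heat
capacity peak (parabolic interpolation through the maximum sample and its
neighbours, so Tm precision is decoupled from the temperature grid) and
ΔH as the trapezoidal integral of the peak.

Sign convention: endothermic-up. Scans recorded endothermic-down are
flipped at read time (see :mod:`dibkit.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .types import MembraneComposition

__all__ = [
    "J_PER_KCAL",
    "Thermogram",
    "CpCurve",
    "Transition",
    "excess_heat_capacity",
    "subtract_baseline",
    "transition_params",
    "transition_shift",
]

#: Joules per kilocalorie.
J_PER_KCAL = 4184.0


@dataclass
class Thermogram:
    """Raw DSC scan: temperature (°C, strictly increasing) vs heat flow (mW).

    ``scan_rate`` in °C/min, ``n_lipid`` in mol.
    """

    T: np.ndarray
    heat_flow: np.ndarray
    scan_rate: float
    n_lipid: float
    composition: MembraneComposition | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if len(self.T) != len(self.heat_flow):
            raise ValueError("T and heat_flow must have equal length")
        if len(self.T) < 20:
            raise ValueError("thermogram needs at least 20 samples")
        if not np.all(np.diff(self.T) > 0):
            raise ValueError("temperature axis must be strictly increasing")
        if self.scan_rate <= 0:
            raise DomainError("scan rate must be positive")
        if self.n_lipid <= 0:
            raise DomainError("lipid amount must be positive")


@dataclass
class CpCurve:
    """Molar excess heat capacity (kcal·mol⁻¹·°C⁻¹) on a temperature grid."""

    T: np.ndarray
    cp: np.ndarray
    baseline: tuple[float, float] | None = None  # (slope, intercept) removed

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)


@dataclass(frozen=True)
class Transition:
    """Extracted main-transition parameters.

    ``Tm`` is ``None`` when no peak rises above the noise floor ("no
    measurable transition"), in which case ``deltaH`` is 0.
    """

    Tm: float | None            # apex temperature, °C
    deltaH: float               # transition enthalpy, kcal/mol
    fwhm: float | None          # peak full width at half maximum, °C
    baseline: tuple[float, float] | None = None

    @property
    def found(self) -> bool:
        return self.Tm is not None


def excess_heat_capacity(thermo: Thermogram) -> CpCurve:
    """Normalise heat flow to molar excess heat capacity.

    Cp(T) = Φ / (β · n), with Φ the heat flow (mW → kcal/s) and β the scan
    rate (°C/min → °C/s); linear in Φ, inversely proportional to both β
    and n.
    """
    kcal_per_s = thermo.heat_flow * 1e-3 / J_PER_KCAL
    beta = thermo.scan_rate / 60.0
    return CpCurve(T=thermo.T.copy(), cp=kcal_per_s / (beta * thermo.n_lipid))


def _window_mask(T: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = min(window), max(window)
    return (T >= lo) & (T <= hi)


def subtract_baseline(curve: CpCurve, pre_window: tuple[float, float],
                      post_window: tuple[float, float]) -> CpCurve:
    """Remove the line through the mean points of two flanking windows.

    Each window must contain ≥ 3 samples and lie clear of the transition
    peak (checked: a window containing the global maximum while the peak is
    prominent is rejected). Peak areas are invariant to any linear ramp
    added to the input, by construction.
    """
    T, cp = curve.T, curve.cp
    m_pre, m_post = _window_mask(T, pre_window), _window_mask(T, post_window)
    if m_pre.sum() < 3 or m_post.sum() < 3:
        raise ValueError("each baseline window must contain at least 3 samples")
    x1, y1 = T[m_pre].mean(), cp[m_pre].mean()
    x2, y2 = T[m_post].mean(), cp[m_post].mean()
    slope = (y2 - y1) / (x2 - x1)
    intercept = y1 - slope * x1
    # a prominent peak inside a flanking window would corrupt the baseline:
    # prominence is judged against the scatter about the line in the windows
    resid = cp - (slope * T + intercept)
    i_max = int(np.argmax(resid))
    # robust scatter: a peak sitting inside a window must not inflate it
    mad = max(float(np.median(np.abs(resid[m_pre] - np.median(resid[m_pre])))),
              float(np.median(np.abs(resid[m_post] - np.median(resid[m_post])))))
    scatter = max(1.4826 * mad, 1e-300)
    if (m_pre[i_max] or m_post[i_max]) and resid[i_max] > 6.0 * scatter:
        raise ValueError("baseline window overlaps the transition peak")
    return CpCurve(T=T.copy(), cp=cp - (slope * T + intercept),
                   baseline=(slope, intercept))


def _parabolic_apex(T: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Apex of the parabola through samples i−1, i, i+1 (falls back to i)."""
    if i == 0 or i == len(y) - 1:
        return float(T[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # degenerate / flat
        return float(T[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    dT = T[i + 1] - T[i] if delta > 0 else T[i] - T[i - 1]
    apex_T = T[i] + delta * dT
    apex_y = y1 - 0.25 * (y0 - y2) * delta
    return float(apex_T), float(apex_y)


def _half_crossing(T: np.ndarray, y: np.ndarray, i_from: int, i_to: int,
                   half: float) -> float | None:
    """Linearly interpolated T where y crosses `half` between the indices."""
    step = 1 if i_to > i_from else -1
    for i in range(i_from, i_to, step):
        j = i + step
        if (y[i] - half) * (y[j] - half) <= 0 and y[i] != y[j]:
            f = (half - y[i]) / (y[j] - y[i])
            return float(T[i] + f * (T[j] - T[i]))
    return None


def transition_params(curve: CpCurve, noise_sd: float | None = None) -> Transition:
    """Extract (Tm, ΔH, FWHM) from a baseline-corrected Cp curve.

    The peak support is the contiguous region around the apex where
    cp > max(3·noise_sd, 1% of apex), extended outward to the baseline
    crossings; ΔH is the trapezoidal integral over that support. When no
    sample exceeds the noise floor the result is the no-transition record
    (ΔH = 0, Tm undefined).
    """
    T, cp = curve.T, curve.cp
    if noise_sd is None:
        k = max(3, len(cp) // 10)
        tails = np.concatenate([cp[:k], cp[-k:]])
        noise_sd = float(1.4826 * np.median(np.abs(tails - np.median(tails))))
    i_max = int(np.argmax(cp))
    apex_raw = cp[i_max]
    # significance floor grows with record length: the expected extreme of
    # n Gaussian noise samples is ~ sqrt(2 ln n) sd, so a flat 3 sd would
    # flag pure noise as a transition on long scans
    z = max(3.0, math.sqrt(2.0 * math.log(max(len(cp), 2))) + 1.0)
    floor = z * noise_sd
    if apex_raw <= floor or apex_raw <= 0:
        return Transition(Tm=None, deltaH=0.0, fwhm=None, baseline=curve.baseline)

    Tm, apex = _parabolic_apex(T, cp, i_max)
    thresh = max(floor, 0.01 * apex)

    lo = i_max
    while lo > 0 and cp[lo - 1] > thresh:
        lo -= 1
    while lo > 0 and cp[lo - 1] > 0:  # extend to baseline crossing
        lo -= 1
    hi = i_max
    while hi < len(cp) - 1 and cp[hi + 1] > thresh:
        hi += 1
    while hi < len(cp) - 1 and cp[hi + 1] > 0:
        hi += 1

    deltaH = float(np.trapezoid(np.clip(cp[lo:hi + 1], 0.0, None), T[lo:hi + 1]))

    half = 0.5 * apex
    t_lo = _half_crossing(T, cp, i_max, lo, half)
    t_hi = _half_crossing(T, cp, i_max, hi, half)
    fwhm = (t_hi - t_lo) if (t_lo is not None and t_hi is not None) else None
    return Transition(Tm=Tm, deltaH=deltaH, fwhm=fwhm, baseline=curve.baseline)


def transition_shift(a: Transition, b: Transition) -> tuple[float, int]:
    """Shift (ΔTm, percent ΔH change) from condition ``a`` to ``b``.

    ΔTm = Tm_b − Tm_a rounded to one decimal (°C); the enthalpy change is
    the whole-percent statistic 100·(ΔH_b − ΔH_a)/ΔH_a.
    """
    if not (a.found and b.found):
        raise DomainError("transition_shift requires a defined Tm in both inputs")
    if a.deltaH <= 0:
        raise DomainError("reference transition has no enthalpy")
    dTm = round(b.Tm - a.Tm, 1)
    dH_pct = int(round(100.0 * (b.deltaH - a.deltaH) / a.deltaH))
    return dTm, dH_pct
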