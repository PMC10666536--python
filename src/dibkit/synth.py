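"""Synthetic study generators: shrinkage series, thermograms, Raman spectra.

Every generator is a pure function of (config, seed): identical inputs give
identical outputs, and every fixture carries a truth record so recovery
tests are closed-loop. Default response tables hold the study's reported
condition values (osmotic permeabilities per composition and pH, DSC
transition parameters, Raman band structure); the response *shapes* —
Gaussian peaks, linear composition responses, noise models — are the
package's own emulation choices and are documented as such.

Modalities draw from independent seeded streams derived from one master
seed, so any one modality can be regenerated on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .dsc import J_PER_KCAL, Thermogram
from .osmotic import DropletPairState, ShrinkageSeries, simulate_droplet_pair, volumes_from_radii
from .raman import Spectrum
from .types import MembraneComposition

__all__ = [
    "SynthConfig",
    "chi_from_mole_ratio",
    "pf_true",
    "disorder_parameter",
    "gen_shrinkage",
    "gen_thermogram",
    "gen_raman",
    "gen_study",
    "PF_RESPONSE_DEFAULT",
    "DSC_RESPONSE_DEFAULT",
]

# stream offsets so each modality has an independent RNG stream
_STREAM = {"shrinkage": 1, "dsc": 2, "raman": 3}


def chi_from_mole_ratio(lipid_parts: float, asa_parts: float) -> float:
    """Aspirin mole fraction for a lipid:ASA mole ratio (e.g. 30:1 → 1/31)."""
    return asa_parts / (lipid_parts + asa_parts)


#: True osmotic permeability (μm/s) per (lipid, chol ratio, pH) at
#: chi_ASA = 0 and 0.5 — the study's reported condition values.
PF_RESPONSE_DEFAULT: dict[tuple[str, str, int], dict[float, float]] = {
    ("POPC", "1:0", 3): {0.0: 71.0, 0.5: 88.0},
    ("POPC", "1:0", 7): {0.0: 77.0, 0.5: 85.0},
    ("POPC", "10:1", 3): {0.0: 68.0, 0.5: 77.0},
    ("POPC", "10:1", 7): {0.0: 73.0, 0.5: 75.0},
    ("POPC", "4:1", 3): {0.0: 65.0, 0.5: 70.0},
    ("POPC", "1:1", 3): {0.0: 62.0, 0.5: 63.0},
}

#: DSC truth per (lipid, chol ratio, chi_ASA rounded to 4 dp) at pH 3:
#: (Tm °C or None, ΔH kcal/mol, Gaussian σ °C or None).
DSC_RESPONSE_DEFAULT: dict[tuple[str, str, float], tuple[float | None, float, float | None]] = {
    ("DOPC", "1:0", 0.0): (-17.58, 9.59, 0.8),
    ("DOPC", "1:0", round(chi_from_mole_ratio(30, 1), 4)): (-18.09, 7.67, 1.0),
    ("DOPC", "1:0", round(chi_from_mole_ratio(3, 1), 4)): (-23.23, 1.33, 1.6),
    ("DOPC", "10:1", 0.0): (-18.05, 6.14, 1.0),
    ("DOPC", "4:1", 0.0): (-19.36, 3.18, 1.3),
    ("DOPC", "1:1", 0.0): (None, 0.0, None),
}

# Raman band tables: (center cm⁻¹, amplitude, Gaussian σ cm⁻¹).
_LIPID_BANDS = [
    (1300.0, 0.40, 12.0),   # CH2 twist
    (1440.0, 0.55, 12.0),   # CH2 bend
    (1650.0, 0.35, 10.0),   # C=C stretch
    (2848.0, 1.00, 12.0),   # CH2 symmetric stretch (normalisation band)
    (2882.0, 0.75, 14.0),   # CH2 asymmetric stretch
    (2930.0, 0.45, 12.0),   # terminal CH3 stretch
]
_ASA_BANDS = [
    (1606.0, 1.00, 8.0),    # aromatic C=C (anchor)
    (1290.0, 0.30, 9.0),
    (1750.0, 0.35, 10.0),   # ester carbonyl
    (2940.0, 0.50, 11.0),   # ASA C–H, interferes with the lipid region
    (3005.0, 0.30, 10.0),
]


@dataclass
class SynthConfig:
    """Study-condition configuration for all generators.

    ``pf_response`` / ``dsc_response`` default to the reported condition
    values; ``noise`` holds per-modality scales: relative radius noise for
    shrinkage, absolute Cp noise (kcal·mol⁻¹·°C⁻¹) for DSC, absolute
    intensity noise (units of the normalised spectrum) for Raman.
    """

    seed: int
    pf_response: dict = field(default_factory=lambda: dict(PF_RESPONSE_DEFAULT))
    dsc_response: dict = field(default_factory=lambda: dict(DSC_RESPONSE_DEFAULT))
    noise: dict = field(default_factory=lambda: {
        "shrinkage": 0.01, "dsc": 0.002, "raman": 0.001})
    # Raman disorder response: slope of disorder vs chi_ASA per pH, and
    # cholesterol attenuation strength
    raman_slope: dict = field(default_factory=lambda: {3: 1.4, 7: 0.7})
    chol_attenuation: float = 4.0
    asa_scale: float = 0.8  # ASA band amplitude per unit chi_ASA in mixtures

    def rng(self, modality: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[modality], extra])


def pf_true(config: SynthConfig, composition: MembraneComposition) -> float:
    """True permeability for a composition; linear in chi between 0 and 0.5."""
    key = (composition.lipid, composition.chol_ratio, composition.pH)
    try:
        resp = config.pf_response[key]
    except KeyError:
        raise KeyError(f"no pf_response entry for composition {key}") from None
    chi = composition.chi_asa
    if chi > 0.5:
        raise KeyError(f"pf_response covers chi_asa in [0, 0.5], got {chi}")
    return resp[0.0] + (resp[0.5] - resp[0.0]) * (chi / 0.5)


def disorder_parameter(config: SynthConfig,
                       composition: MembraneComposition) -> float:
    """Acyl-chain disorder d in [0, 1]: linear in chi_ASA, steeper at pH 3
    (uncharged drug partitions deeper), attenuated by cholesterol."""
    slope = config.raman_slope[composition.pH]
    atten = 1.0 / (1.0 + config.chol_attenuation * composition.chol_mole_fraction)
    return min(1.0, slope * composition.chi_asa * atten)


def gen_shrinkage(config: SynthConfig, composition: MembraneComposition,
                  geometry: tuple[float, float, float] = (100.0, 100.0, 40.0),
                  osmolalities: tuple[float, float] = (300.0, 100.0),
                  n_points: int = 60, dt: float = 5.0,
                  seed: int | None = None,
                  noise_sd: float | None = None) -> tuple[ShrinkageSeries, dict]:
    """Simulate a droplet-pair shrinkage series for one composition.

    Returns ``(series, truth)`` where truth records the generating Pf.
    Default geometry: two 100 μm droplets with a 40 μm contact zone;
    droplet 1 at 300 mOsm/kg against 100 mOsm/kg, so droplet 1 swells.
    """
    pf = pf_true(config, composition)
    R1, R2, r = geometry
    V1, V2 = volumes_from_radii(R1, R2, r, "sphere")
    c1, c2 = osmolalities
    state0 = DropletPairState(V1=V1, V2=V2, n1=c1 * V1, n2=c2 * V2,
                              A=math.pi * r * r)
    if noise_sd is None:
        noise_sd = config.noise["shrinkage"]
    sub = seed if seed is not None else 0
    eff_seed = None if noise_sd == 0 else int(
        config.rng("shrinkage", sub).integers(2 ** 31))
    series = simulate_droplet_pair(state0, pf, t_end=n_points * dt, dt=dt,
                                   noise_sd=noise_sd, seed=eff_seed)
    series.meta.update(composition=composition, truth_pf=pf)
    return series, {"pf_true": pf, "composition": composition.key(),
                    "noise_sd": noise_sd}


def gen_thermogram(config: SynthConfig, composition: MembraneComposition,
                   grid: np.ndarray | None = None,
                   seed: int | None = None,
                   scan_rate: float = 5.0, n_lipid: float = 3e-7,
                   baseline: tuple[float, float] = (2e-3, 5e-5),
                   noise_sd: float | None = None) -> tuple[Thermogram, dict]:
    """Generate a heat-flow thermogram with a Gaussian transition peak.

    The excess heat capacity is ΔH·N(T; Tm, σ) plus a linear baseline and
    additive noise, mapped to instrument heat flow (mW) by the inverse of
    the molar normalisation. Composition must appear in ``dsc_response``.
    """
    key = (composition.lipid, composition.chol_ratio,
           round(composition.chi_asa, 4))
    try:
        Tm, dH, sigma = config.dsc_response[key]
    except KeyError:
        raise KeyError(f"no dsc_response entry for composition {key}") from None
    if grid is None:
        grid = np.arange(-40.0, 0.0 + 1e-9, 0.05)
    if noise_sd is None:
        noise_sd = config.noise["dsc"]
    a, b = baseline
    cp = a + b * grid
    if dH > 0:
        cp = cp + dH * np.exp(-0.5 * ((grid - Tm) / sigma) ** 2) / (
            sigma * math.sqrt(2 * math.pi))
    if noise_sd > 0:
        rng = config.rng("dsc", seed if seed is not None else 0)
        cp = cp + noise_sd * rng.standard_normal(grid.shape)
    heat_flow_mw = cp * n_lipid * (scan_rate / 60.0) * J_PER_KCAL * 1e3
    thermo = Thermogram(T=grid, heat_flow=heat_flow_mw, scan_rate=scan_rate,
                        n_lipid=n_lipid, composition=composition,
                        meta={"truth_Tm": Tm, "truth_dH": dH,
                              "truth_sigma": sigma, "baseline": baseline})
    return thermo, {"Tm_true": Tm, "dH_true": dH, "sigma_true": sigma,
                    "composition": composition.key()}


def _bands(grid: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    y = np.zeros_like(grid)
    for center, amp, sigma in bands:
        y += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return y


def _lipid_bands_disordered(d: float) -> list[tuple[float, float, float]]:
    """Lipid band table under disorder d: the 2848 band shifts up and the
    asymmetric 2890-region band loses weight and broadens."""
    out = []
    for center, amp, sigma in _LIPID_BANDS:
        if center == 2848.0:
            out.append((center + 4.0 * d, amp, sigma))
        elif center == 2882.0:
            out.append((center + 9.0 * d, amp * (1.0 - 0.30 * d), sigma + 4.0 * d))
        else:
            out.append((center, amp, sigma))
    return out


def gen_raman(config: SynthConfig, composition: MembraneComposition,
              grid: np.ndarray | None = None, seed: int | None = None,
              noise_sd: float | None = None
              ) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Generate (mixture, pure-ASA reference, pure-lipid truth) spectra.

    mixture = lipid(disorder) + chi_ASA·scale·ASA + noise. The lipid truth
    has no 1606 cm⁻¹ band, so anchor-scaled subtraction is exact up to
    noise; disorder grows with chi_ASA, faster at pH 3 than pH 7.
    """
    if grid is None:
        grid = np.arange(1200.0, 3100.0 + 1e-9, 1.0)
    if grid[0] > 1200.0 or grid[-1] < 3100.0:
        raise ValueError("Raman grid must cover 1200–3100 cm⁻¹")
    if noise_sd is None:
        noise_sd = config.noise["raman"]
    d = disorder_parameter(config, composition)
    lipid_y = _bands(grid, _lipid_bands_disordered(d))
    asa_y = _bands(grid, _ASA_BANDS)
    mix_y = lipid_y + composition.chi_asa * config.asa_scale * asa_y
    if noise_sd > 0:
        rng = config.rng("raman", seed if seed is not None else 0)
        mix_y = np.clip(mix_y + noise_sd * rng.standard_normal(grid.shape), 0, None)
    label = composition.key()
    mixture = Spectrum(grid.copy(), mix_y, label=label,
                       meta={"disorder": d, "chi_asa": composition.chi_asa})
    reference = Spectrum(grid.copy(), asa_y, label="ASA reference")
    truth = Spectrum(grid.copy(), lipid_y, label=f"{label}|lipid-truth",
                     meta={"disorder": d})
    return mixture, reference, truth


def gen_study(config: SynthConfig, outdir: str | Path) -> pd.DataFrame:
    """Write a full synthetic study fixture tree and return its manifest.

    Layout: ``shrinkage/*.csv``, ``dsc/*.csv``, ``raman/*.txt`` plus
    ``manifest.csv`` (one row per file with composition and truth columns).
    Byte-identical for a fixed config seed.
    """
    outdir = Path(outdir)
    for sub in ("shrinkage", "dsc", "raman"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    rows = []

    for i, ((lipid, chol, pH), resp) in enumerate(sorted(config.pf_response.items())):
        for chi in (0.0, 0.5):
            comp = MembraneComposition(lipid, chol, chi, pH)
            series, truth = gen_shrinkage(config, comp, seed=i * 10 + int(chi * 2))
            name = f"shrinkage/{lipid}_{chol.replace(':', '-')}_pH{pH}_chi{chi:g}.csv"
            dio.write_series(outdir / name, series)
            rows.append({"file": name, "modality": "shrinkage", "lipid": lipid,
                         "chol_ratio": chol, "chi_asa": chi, "pH": pH,
                         "truth_pf_um_s": truth["pf_true"]})

    for i, ((lipid, chol, chi), (Tm, dH, sigma)) in enumerate(
            sorted(config.dsc_response.items(), key=str)):
        comp = MembraneComposition(lipid, chol, chi, 3)
        thermo, truth = gen_thermogram(config, comp, seed=i)
        name = f"dsc/{lipid}_{chol.replace(':', '-')}_chi{chi:g}.csv"
        dio.write_thermogram(outdir / name, thermo)
        rows.append({"file": name, "modality": "dsc", "lipid": lipid,
                     "chol_ratio": chol, "chi_asa": chi, "pH": 3,
                     "truth_Tm_C": Tm, "truth_dH_kcal_mol": dH})

    ref_written = False
    i = 0
    for chol in ("1:0", "10:1"):
        for pH in (3, 7):
            for chi in (0.0, 0.1, 0.3, 0.5):
                comp = MembraneComposition("POPC", chol, chi, pH)
                mix, ref, truth_spec = gen_raman(config, comp, seed=i)
                i += 1
                name = (f"raman/POPC_{chol.replace(':', '-')}_pH{pH}"
                        f"_chi{chi:g}.txt")
                dio.write_spectrum(outdir / name, mix)
                if not ref_written:
                    dio.write_spectrum(outdir / "raman/ASA_reference.txt", ref)
                    ref_written = True
                rows.append({"file": name, "modality": "raman", "lipid": "POPC",
                             "chol_ratio": chol, "chi_asa": chi, "pH": pH,
                             "truth_disorder": mix.meta["disorder"]})

    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
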