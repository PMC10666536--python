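"""File formats and run configuration.

All tabular formats are headed CSV with ``#``-prefixed metadata comment
lines; spectra are two-column text. Column names carry explicit units
(``t_s``, ``R1_um``, ``T_C``, ``heat_flow_mW`` …). Write-then-read is the
identity up to float formatting.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dsc import Thermogram
from .errors import ParseError
from .osmotic import ShrinkageSeries
from .raman import Spectrum
from .types import MembraneComposition

__all__ = [
    "RunConfig",
    "read_series", "write_series",
    "read_thermogram", "write_thermogram",
    "read_spectrum", "write_spectrum",
]

_FLOAT_FMT = "%.6f"


class RunConfig(BaseModel):
    """Validated run configuration (YAML).

    Unknown keys are rejected so typos fail loudly before any computation.
    """

    model_config = ConfigDict(extra="forbid")

    temperature_C: float = 30.0
    seed: int = 0
    geometry_mode: str = Field("sphere", pattern="^(sphere|truncated)$")
    endothermic_up: bool = True
    dsc_pre_window: tuple[float, float] = (-40.0, -30.0)
    dsc_post_window: tuple[float, float] = (-8.0, 0.0)
    raman_anchor_cm1: float = 1606.0
    raman_window_cm1: float = 10.0
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _split_comments(path: Path) -> tuple[dict[str, str], str]:
    """Separate leading ``# key: value`` comments from the CSV body."""
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    k, v = stripped.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}; "
                         f"found {list(df.columns)}")


def _meta_composition(meta: dict[str, str]) -> MembraneComposition | None:
    if "lipid" not in meta:
        return None
    return MembraneComposition(
        lipid=meta["lipid"], chol_ratio=meta.get("chol_ratio", "1:0"),
        chi_asa=float(meta.get("chi_asa", 0.0)), pH=int(meta.get("pH", 3)))


def write_series(path: str | Path, series: ShrinkageSeries) -> None:
    """Write a shrinkage series: metadata comments + t_s,R1_um,R2_um,r_um."""
    path = Path(path)
    comp = series.meta.get("composition")
    with open(path, "w") as fh:
        fh.write(f"# osmolality1_mOsm_kg: {series.osmolality1:g}\n")
        fh.write(f"# osmolality2_mOsm_kg: {series.osmolality2:g}\n")
        if comp is not None:
            fh.write(f"# lipid: {comp.lipid}\n# chol_ratio: {comp.chol_ratio}\n")
            fh.write(f"# chi_asa: {comp.chi_asa:g}\n# pH: {comp.pH}\n")
        for key in ("truth_pf", "noise_sd", "seed"):
            if series.meta.get(key) is not None:
                fh.write(f"# {key}: {series.meta[key]:g}\n")
        fh.write("t_s,R1_um,R2_um,r_um\n")
        for i in range(len(series)):
            fh.write(",".join(_FLOAT_FMT % v for v in
                              (series.t[i], series.R1[i], series.R2[i],
                               series.r[i])) + "\n")


def read_series(path: str | Path) -> ShrinkageSeries:
    """Read a shrinkage series CSV; validates monotone time and radii."""
    path = Path(path)
    meta, body = _split_comments(path)
    df = pd.read_csv(_io.StringIO(body))
    _require_columns(df, ["t_s", "R1_um", "R2_um", "r_um"], path)
    t = df["t_s"].to_numpy()
    if len(t) >= 2:
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise ParseError(f"{path}: time axis not strictly increasing at "
                             f"data row {bad[0] + 2}")
    for col in ("R1_um", "R2_um"):
        neg = np.where(df[col].to_numpy() <= 0)[0]
        if neg.size:
            raise ParseError(f"{path}: nonpositive {col} at data row {neg[0] + 2}")
    smeta: dict[str, Any] = dict(meta)
    comp = _meta_composition(meta)
    if comp is not None:
        smeta["composition"] = comp
    if "truth_pf" in meta:
        smeta["truth_pf"] = float(meta["truth_pf"])
    try:
        return ShrinkageSeries(
            t=t, R1=df["R1_um"].to_numpy(), R2=df["R2_um"].to_numpy(),
            r=df["r_um"].to_numpy(),
            osmolality1=float(meta.get("osmolality1_mOsm_kg", 0.0)),
            osmolality2=float(meta.get("osmolality2_mOsm_kg", 0.0)),
            meta=smeta)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_thermogram(path: str | Path, thermo: Thermogram) -> None:
    """Write a thermogram: metadata comments + T_C,heat_flow_mW."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# scan_rate_C_min: {thermo.scan_rate:g}\n")
        fh.write(f"# n_lipid_mol: {thermo.n_lipid:g}\n")
        comp = thermo.composition
        if comp is not None:
            fh.write(f"# lipid: {comp.lipid}\n# chol_ratio: {comp.chol_ratio}\n")
            fh.write(f"# chi_asa: {comp.chi_asa:g}\n# pH: {comp.pH}\n")
        for key in ("truth_Tm", "truth_dH"):
            if thermo.meta.get(key) is not None:
                fh.write(f"# {key}: {thermo.meta[key]:g}\n")
        fh.write("T_C,heat_flow_mW\n")
        for T, hf in zip(thermo.T, thermo.heat_flow):
            fh.write(f"{_FLOAT_FMT % T},{hf:.9g}\n")


def read_thermogram(path: str | Path,
                    endothermic_up: bool = True) -> Thermogram:
    """Read a thermogram CSV; flips sign when recorded endothermic-down."""
    path = Path(path)
    meta, body = _split_comments(path)
    df = pd.read_csv(_io.StringIO(body))
    _require_columns(df, ["T_C", "heat_flow_mW"], path)
    T = df["T_C"].to_numpy()
    bad = np.where(np.diff(T) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: temperature axis not strictly increasing "
                         f"at data row {bad[0] + 2}")
    hf = df["heat_flow_mW"].to_numpy()
    if not endothermic_up:
        hf = -hf
    if "scan_rate_C_min" not in meta or "n_lipid_mol" not in meta:
        raise ParseError(f"{path}: missing '# scan_rate_C_min' or "
                         "'# n_lipid_mol' metadata")
    tmeta: dict[str, Any] = dict(meta)
    for key in ("truth_Tm", "truth_dH"):
        if key in meta:
            tmeta[key] = float(meta[key])
    try:
        return Thermogram(T=T, heat_flow=hf,
                          scan_rate=float(meta["scan_rate_C_min"]),
                          n_lipid=float(meta["n_lipid_mol"]),
                          composition=_meta_composition(meta), meta=tmeta)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_spectrum(path: str | Path, spec: Spectrum) -> None:
    """Write a spectrum as two-column text (wavenumber_cm1, intensity)."""
    path = Path(path)
    with open(path, "w") as fh:
        if spec.label:
            fh.write(f"# label: {spec.label}\n")
        if "disorder" in spec.meta:
            fh.write(f"# disorder: {spec.meta['disorder']:g}\n")
        fh.write("wavenumber_cm1 intensity\n")
        for w, y in zip(spec.wavenumber, spec.intensity):
            fh.write(f"{_FLOAT_FMT % w} {_FLOAT_FMT % y}\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (whitespace or comma delimited) spectrum file."""
    path = Path(path)
    meta, body = _split_comments(path)
    first = body.splitlines()[0] if body else ""
    sep = "," if "," in first else r"\s+"
    df = pd.read_csv(_io.StringIO(body), sep=sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns, got {df.shape[1]}")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    bad = np.where(np.diff(w) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: wavenumber axis not strictly increasing "
                         f"at data row {bad[0] + 2}")
    smeta: dict[str, Any] = dict(meta)
    if "disorder" in meta:
        smeta["disorder"] = float(meta["disorder"])
    return Spectrum(wavenumber=w, intensity=y, label=meta.get("label", ""),
                    meta=smeta)
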