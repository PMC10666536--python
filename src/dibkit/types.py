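"""Shared domain records: membrane composition labels.

A :class:`MembraneComposition` tags every measurement (shrinkage series,
thermogram, spectrum) with the bilayer it came from: base lipid, the
lipid:cholesterol mole ratio, the aspirin mole fraction chi_ASA, and the
pH label that fixes aspirin's charge state (pH 3: protonated/uncharged,
pH 7: deprotonated/charged).
"""

from __future__ import annotations

from dataclasses import dataclass

LIPIDS = ("POPC", "DOPC")


@dataclass(frozen=True)
class MembraneComposition:
    """Covariate record for one membrane condition.

    Parameters
    ----------
    lipid:
        Base phosphatidylcholine, ``"POPC"`` or ``"DOPC"``.
    chol_ratio:
        Lipid:cholesterol mole ratio as a string label (``"1:0"``,
        ``"10:1"``, ``"4:1"``, ``"1:1"``); ``"1:0"`` means cholesterol-free.
    chi_asa:
        Aspirin mole fraction relative to total lipid, in ``[0, 1)``.
    pH:
        pH label, 3 or 7.
    """

    lipid: str
    chol_ratio: str = "1:0"
    chi_asa: float = 0.0
    pH: int = 3

    def __post_init__(self) -> None:
        if self.lipid not in LIPIDS:
            raise ValueError(f"unknown lipid {self.lipid!r}; expected one of {LIPIDS}")
        parts = self.chol_ratio.split(":")
        if len(parts) != 2:
            raise ValueError(f"chol_ratio must look like 'a:b', got {self.chol_ratio!r}")
        a, b = (float(p) for p in parts)
        if a <= 0 or b < 0:
            raise ValueError(f"chol ratio parts must be positive, got {self.chol_ratio!r}")
        if not 0.0 <= self.chi_asa < 1.0:
            raise ValueError(f"chi_asa must lie in [0, 1), got {self.chi_asa}")
        if self.pH not in (3, 7):
            raise ValueError(f"pH label must be 3 or 7, got {self.pH}")

    @property
    def chol_mole_fraction(self) -> float:
        """Cholesterol mole fraction relative to lipid + cholesterol."""
        a, b = (float(p) for p in self.chol_ratio.split(":"))
        return b / (a + b)

    def key(self) -> str:
        """Stable string key used by response tables and manifests."""
        return f"{self.lipid}|{self.chol_ratio}|{self.chi_asa:g}|pH{self.pH}"
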