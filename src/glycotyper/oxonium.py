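"""Oxonium-ion detection and the 9 normalized intensity features.

HCD fragmentation of a glycopeptide releases mono-/disaccharide oxonium ions.
Ten diagnostic ions are tracked (nominal m/z 138, 145, 163, 168, 186, 204,
274, 292, 325, 366); a spectrum qualifies as oxonium-ion containing when at
least ``min_ions`` of them fall among the top intensity fraction of its peaks,
with the HexNAc ion at 204 mandatory. The classifier features are the
intensities of the other 9 ions, each normalized by the intensity at 204 —
ratios are dimensionless, which makes them transferable across instruments
with different intensity units.

Exact ion m/z values are computed from elemental cation formulas (e.g.
HexNAc+ = C8H14NO5+), not the nominal integer labels; matching uses a ppm
window appropriate for high-resolution spectra.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .masses import formula_cation_mz
from .spectra import Ms2Spectrum, top_fraction_peaks

__all__ = [
    "OxoniumIon",
    "OxoniumFeatures",
    "FEATURE_IONS",
    "oxonium_ion_table",
    "ion_intensity",
    "is_oxonium_spectrum",
    "extract_features",
]


@dataclass(frozen=True)
class OxoniumIon:
    name: str
    nominal_mz: int
    exact_mz: float
    parent_sugar: str


# nominal label -> (name, cation formula, parent sugar class)
_ION_DEFS: dict[int, tuple[str, str, str]] = {
    138: ("HexNAc fragment", "C7H8NO2", "HexNAc"),
    145: ("Hex - H2O", "C6H9O4", "Hex"),
    163: ("Hex", "C6H11O5", "Hex"),
    168: ("HexNAc - 2 H2O", "C8H10NO3", "HexNAc"),
    186: ("HexNAc - H2O", "C8H12NO4", "HexNAc"),
    204: ("HexNAc", "C8H14NO5", "HexNAc"),
    274: ("Neu5Ac - H2O", "C11H16NO7", "Neu5Ac"),
    292: ("Neu5Ac", "C11H18NO8", "Neu5Ac"),
    325: ("Hex2", "C12H21O10", "Hex"),
    366: ("HexHexNAc", "C14H24NO10", "HexHexNAc"),
}

#: The 9 feature ions (all table ions except the 204 reference), ascending.
FEATURE_IONS: tuple[int, ...] = (138, 145, 163, 168, 186, 274, 292, 325, 366)

_TABLE: list[OxoniumIon] = [
    OxoniumIon(name, label, formula_cation_mz(formula), sugar)
    for label, (name, formula, sugar) in sorted(_ION_DEFS.items())
]
_EXACT_MZ: dict[int, float] = {ion.nominal_mz: ion.exact_mz for ion in _TABLE}


def oxonium_ion_table() -> list[OxoniumIon]:
    """The 10 diagnostic oxonium ions with exact monoisotopic m/z."""
    return list(_TABLE)


def oxonium_mz(label: int) -> float:
    """Exact m/z of a table ion by its nominal integer label."""
    return _EXACT_MZ[label]


@dataclass(frozen=True)
class OxoniumFeatures:
    """The 9 ion/204 intensity ratios plus the raw 204 intensity."""

    ratios: Mapping[int, float]
    intensity_204: float

    def __post_init__(self) -> None:
        if set(self.ratios) != set(FEATURE_IONS):
            raise ValueError("feature vector must contain exactly the 9 non-204 ion ratios")
        if self.intensity_204 <= 0:
            raise ValueError("reference 204 intensity must be positive")
        vals = np.array([self.ratios[k] for k in FEATURE_IONS], dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("ratios must be finite and nonnegative")

    def vector(self, feature_order: tuple[int, ...] | list[int] = FEATURE_IONS) -> np.ndarray:
        return np.array([self.ratios[k] for k in feature_order], dtype=float)


def ion_intensity(spectrum: Ms2Spectrum, exact_mz: float, tol_ppm: float = 20.0) -> float:
    """Intensity of the most intense peak within +-tol_ppm of exact_mz (0 if none).

    Taking the maximum within the window is robust to small noise splinters
    next to a real centroid.
    """
    delta = exact_mz * tol_ppm * 1e-6
    lo = np.searchsorted(spectrum.mz, exact_mz - delta, side="left")
    hi = np.searchsorted(spectrum.mz, exact_mz + delta, side="right")
    if hi <= lo:
        return 0.0
    return float(spectrum.intensity[lo:hi].max())


def is_oxonium_spectrum(
    spectrum: Ms2Spectrum,
    top_fraction: float = 0.05,
    min_ions: int = 2,
    require_204: bool = True,
    tol_ppm: float = 20.0,
) -> bool:
    """Oxonium-ion filter: >= min_ions table ions among the top intensity
    fraction of peaks, the 204 ion mandatory when require_204 is set."""
    top = top_fraction_peaks(spectrum, top_fraction)
    top_mz = np.array(sorted(p.mz for p in top))
    n_found = 0
    found_204 = False
    for ion in _TABLE:
        delta = ion.exact_mz * tol_ppm * 1e-6
        lo = np.searchsorted(top_mz, ion.exact_mz - delta, side="left")
        hi = np.searchsorted(top_mz, ion.exact_mz + delta, side="right")
        if hi > lo:
            n_found += 1
            if ion.nominal_mz == 204:
                found_204 = True
    if require_204 and not found_204:
        return False
    return n_found >= min_ions


def extract_features(spectrum: Ms2Spectrum, tol_ppm: float = 20.0) -> OxoniumFeatures:
    """The 9 normalized oxonium features of a spectrum.

    Raises ValueError when the reference 204 ion is absent — such a spectrum
    cannot be normalized and is unclassifiable. Ions absent from the spectrum
    contribute a ratio of 0.
    """
    i204 = ion_intensity(spectrum, _EXACT_MZ[204], tol_ppm)
    if i204 <= 0:
        raise ValueError(
            f"spectrum {spectrum.scan_id!r} has no peak at the 204 reference ion; "
            "oxonium features are undefined"
        )
    ratios = {
        label: ion_intensity(spectrum, _EXACT_MZ[label], tol_ppm) / i204
        for label in FEATURE_IONS
    }
    return OxoniumFeatures(ratios=ratios, intensity_204=i204)
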