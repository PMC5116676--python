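"""Reading and rank-based preprocessing of centroided MS/MS spectra.

Supports mzML, mzXML and MGF input via pyteomics. Spectra are screened for
precursor charge at read time (reject unassigned, singly and more-than-eight
protonated precursors, mirroring a typical acquisition charge-state screen) and
carry their peak lists as m/z-sorted numpy arrays.

Intensity-rank operations (bottom-fraction removal, top-fraction selection) use
a single deterministic tie-break: peaks are ranked by (intensity, then m/z)
ascending, so among equal intensities the lowest-m/z peak ranks lowest and is
dropped first from the bottom and admitted last into the top set.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import base64
import struct
import zlib

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .masses import PROTON

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Ms2Spectrum",
    "ReadStats",
    "read_spectra",
    "load_spectra",
    "remove_bottom_fraction",
    "top_fraction_peaks",
    "precursor_neutral_mass",
    "write_mgf",
]


@dataclass(frozen=True)
class Peak:
    """A single centroided peak."""

    mz: float
    intensity: float


class Ms2Spectrum:
    """A centroided MS2 scan: precursor info plus an m/z-sorted peak list."""

    __slots__ = ("scan_id", "precursor_mz", "precursor_charge", "retention_time", "mz", "intensity")

    def __init__(
        self,
        scan_id: str,
        precursor_mz: float,
        precursor_charge: int,
        mz: Sequence[float],
        intensity: Sequence[float],
        retention_time: float | None = None,
    ) -> None:
        mz_arr = np.asarray(mz, dtype=float)
        int_arr = np.asarray(intensity, dtype=float)
        if mz_arr.ndim != 1 or mz_arr.shape != int_arr.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz_arr.size < 1:
            raise ValueError("spectrum must contain at least one peak")
        if np.any(mz_arr <= 0):
            raise ValueError("all m/z values must be positive")
        if np.any(int_arr < 0):
            raise ValueError("intensities must be nonnegative")
        order = np.argsort(mz_arr, kind="stable")
        self.scan_id = str(scan_id)
        self.precursor_mz = float(precursor_mz)
        self.precursor_charge = int(precursor_charge)
        self.retention_time = None if retention_time is None else float(retention_time)
        self.mz = mz_arr[order]
        self.intensity = int_arr[order]

    # -- convenience views ------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @property
    def peaks(self) -> tuple[Peak, ...]:
        return tuple(Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity))

    @classmethod
    def from_peaks(
        cls,
        scan_id: str,
        precursor_mz: float,
        precursor_charge: int,
        peaks: Iterable[Peak | tuple[float, float]],
        retention_time: float | None = None,
    ) -> "Ms2Spectrum":
        pk = [(p.mz, p.intensity) if isinstance(p, Peak) else tuple(p) for p in peaks]
        mz = [p[0] for p in pk]
        inten = [p[1] for p in pk]
        return cls(scan_id, precursor_mz, precursor_charge, mz, inten, retention_time)

    def replace_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Ms2Spectrum":
        return Ms2Spectrum(
            self.scan_id, self.precursor_mz, self.precursor_charge, mz, intensity, self.retention_time
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Ms2Spectrum({self.scan_id!r}, mz={self.precursor_mz:.4f}, "
            f"z={self.precursor_charge}, peaks={self.n_peaks})"
        )


@dataclass
class ReadStats:
    """Bookkeeping for a read pass: how many scans were kept or dropped."""

    n_ms2: int = 0
    n_kept: int = 0
    n_charge_rejected: int = 0
    n_empty: int = 0


def _rank_order(spectrum: Ms2Spectrum) -> np.ndarray:
    """Indices of peaks from lowest to highest rank: (intensity, mz) ascending."""
    return np.lexsort((spectrum.mz, spectrum.intensity))


def remove_bottom_fraction(spectrum: Ms2Spectrum, fraction: float = 0.10) -> Ms2Spectrum:
    """Drop the floor(fraction * n) lowest-intensity peaks (low-quality peaks).

    Ties in intensity are broken by m/z: the lowest-m/z tied peak is dropped
    first. Returns a new spectrum; m/z ordering is preserved.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    k = math.floor(fraction * spectrum.n_peaks)
    if k == 0:
        return spectrum
    keep = np.sort(_rank_order(spectrum)[k:])
    return spectrum.replace_peaks(spectrum.mz[keep], spectrum.intensity[keep])


def top_fraction_peaks(spectrum: Ms2Spectrum, fraction: float) -> list[Peak]:
    """The ceil(fraction * n) highest-intensity peaks, as Peak records.

    A nonzero fraction on a nonempty spectrum always yields at least one peak.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * spectrum.n_peaks)
    top = np.sort(_rank_order(spectrum)[spectrum.n_peaks - k :])
    return [Peak(float(spectrum.mz[i]), float(spectrum.intensity[i])) for i in top]


def precursor_neutral_mass(spectrum: Ms2Spectrum) -> float:
    """Neutral (uncharged, deprotonated) precursor mass in Da."""
    if spectrum.precursor_charge < 1:
        raise ValueError("precursor charge is required to compute neutral mass")
    return (spectrum.precursor_mz - PROTON) * spectrum.precursor_charge


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_FORMATS = ("mgf", "mzml", "mzxml")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in _FORMATS:
        return ext
    raise ValueError(f"cannot infer spectrum format from extension {ext!r}; pass format=")


def _iter_mgf(path: str):
    with _mgf.read(path, convert_arrays=1, use_index=False) as reader:
        for idx, spec in enumerate(reader):
            params = spec.get("params", {})
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 0
            pepmass = params.get("pepmass", (0.0,))[0]
            rt = params.get("rtinseconds")
            title = params.get("title", f"index={idx}")
            yield title, float(pepmass or 0.0), charge, (None if rt is None else float(rt)), spec[
                "m/z array"
            ], spec["intensity array"]


# mzML/mzXML parsing is implemented directly on lxml: only the MS2 essentials
# are extracted (precursor m/z and charge, retention time, uncompressed or
# zlib base64 peak arrays). Tag matching ignores XML namespaces.


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _decode_binary(text: str, precision: int, compressed: bool, big_endian: bool = False) -> np.ndarray:
    raw = base64.b64decode(text.strip()) if text else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    dtype = ("<f4", "<f8") if not big_endian else (">f4", ">f8")
    return np.frombuffer(raw, dtype=dtype[0] if precision == 32 else dtype[1]).astype(float)


def _parse_mzml_spectrum(elem):
    ms_level = None
    pmz = 0.0
    charge = 0
    rt = None
    arrays: dict[str, np.ndarray] = {}
    for cv in elem.iter():
        if _local(cv.tag) != "cvParam":
            continue
        name = cv.get("name", "")
        if name == "ms level":
            ms_level = int(cv.get("value", 0))
        elif name == "selected ion m/z":
            pmz = float(cv.get("value", 0.0))
        elif name == "charge state":
            charge = int(float(cv.get("value", 0)))
        elif name == "scan start time":
            rt = float(cv.get("value", 0.0))
            if cv.get("unitName", "minute") == "minute":
                rt *= 60.0
    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        precision = 64
        compressed = False
        kind = None
        text = ""
        for child in bda.iter():
            tag = _local(child.tag)
            if tag == "cvParam":
                name = child.get("name", "")
                if name == "32-bit float":
                    precision = 32
                elif name == "64-bit float":
                    precision = 64
                elif name == "zlib compression":
                    compressed = True
                elif name in ("m/z array", "intensity array"):
                    kind = name
            elif tag == "binary":
                text = child.text or ""
        if kind:
            arrays[kind] = _decode_binary(text, precision, compressed)
    return (
        ms_level,
        elem.get("id", ""),
        pmz,
        charge,
        rt,
        arrays.get("m/z array", np.empty(0)),
        arrays.get("intensity array", np.empty(0)),
    )


def _iter_mzml(path: str):
    for _event, elem in etree.iterparse(path, events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level, scan_id, pmz, charge, rt, mz, inten = _parse_mzml_spectrum(elem)
        elem.clear()
        if ms_level != 2:
            continue
        yield scan_id, pmz, charge, rt, mz, inten


def _parse_mzxml_rt(text: str | None) -> float | None:
    if not text:
        return None
    # ISO-8601 duration as written by converters, e.g. "PT750.5S"
    t = text.strip().lstrip("PT").rstrip("S")
    try:
        return float(t)
    except ValueError:
        return None


def _iter_mzxml(path: str):
    for _event, elem in etree.iterparse(path, events=("end",)):
        if _local(elem.tag) != "scan":
            continue
        if int(elem.get("msLevel", 0)) != 2:
            elem.clear()
            continue
        scan_id = elem.get("num", "")
        rt = _parse_mzxml_rt(elem.get("retentionTime"))
        pmz = 0.0
        charge = 0
        mz = np.empty(0)
        inten = np.empty(0)
        for child in elem:
            tag = _local(child.tag)
            if tag == "precursorMz":
                pmz = float(child.text or 0.0)
                charge = int(child.get("precursorCharge", 0) or 0)
            elif tag == "peaks":
                precision = int(child.get("precision", 32))
                compressed = child.get("compressionType", "none") == "zlib"
                big_endian = child.get("byteOrder", "network") == "network"
                pairs = _decode_binary(child.text or "", precision, compressed, big_endian)
                mz = pairs[0::2]
                inten = pairs[1::2]
        elem.clear()
        yield scan_id, pmz, charge, rt, mz, inten


def read_spectra(
    path: str,
    format: str | None = None,
    charge_range: tuple[int, int] | None = (2, 8),
    stats: ReadStats | None = None,
) -> Iterator[Ms2Spectrum]:
    """Stream MS2 scans from an mzML/mzXML/MGF file.

    MS1 scans are skipped. Scans whose precursor charge is unassigned or
    outside ``charge_range`` are dropped (pass ``charge_range=None`` to keep
    everything). Scans with empty peak lists are dropped with a warning.
    Dropped counts accumulate on ``stats`` when provided.
    """
    fmt = (format or _infer_format(path)).lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {_FORMATS}")
    iterator = {"mgf": _iter_mgf, "mzml": _iter_mzml, "mzxml": _iter_mzxml}[fmt](path)
    stats = stats if stats is not None else ReadStats()
    for scan_id, pmz, charge, rt, mz, inten in iterator:
        stats.n_ms2 += 1
        if len(mz) == 0:
            stats.n_empty += 1
            logger.warning("scan %s has an empty peak list; dropped", scan_id)
            continue
        if charge_range is not None and not (charge_range[0] <= charge <= charge_range[1]):
            stats.n_charge_rejected += 1
            continue
        stats.n_kept += 1
        yield Ms2Spectrum(scan_id, pmz, charge, mz, inten, rt)


def load_spectra(
    path: str,
    format: str | None = None,
    charge_range: tuple[int, int] | None = (2, 8),
) -> tuple[list[Ms2Spectrum], ReadStats]:
    """Read a whole file into memory; returns (spectra, read statistics)."""
    stats = ReadStats()
    spectra = list(read_spectra(path, format=format, charge_range=charge_range, stats=stats))
    if stats.n_charge_rejected:
        logger.info(
            "%d of %d MS2 scans rejected by charge screening", stats.n_charge_rejected, stats.n_ms2
        )
    return spectra, stats


def write_mgf(spectra: Iterable[Ms2Spectrum], path: str) -> None:
    """Write spectra to an MGF file (PEPMASS/CHARGE/TITLE/RTINSECONDS dialect)."""

    def entries():
        for s in spectra:
            params = {
                "title": s.scan_id,
                "pepmass": s.precursor_mz,
                "charge": [s.precursor_charge],
            }
            if s.retention_time is not None:
                params["rtinseconds"] = s.retention_time
            yield {"params": params, "m/z array": s.mz, "intensity array": s.intensity}

    _mgf.write(entries(), output=path, file_mode="w")
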