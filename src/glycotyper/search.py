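"""Intact glycopeptide identification by precursor-mass matching.

Candidates are (peptide, glycan composition) pairs whose summed monoisotopic
mass matches the precursor neutral mass within the MS1 ppm tolerance; N-glycan
pairings require an N-sequon in the peptide and O-glycan pairings require an
S/T. Each candidate is scored against the spectrum with a modified Morpheus
score: the integer part counts matched singly charged b/y fragment ions plus
Y-series ions (the intact peptide carrying any sub-composition of the glycan,
Y0 = bare peptide), and the fractional part is the share of spectrum intensity
explained by those matches after oxonium-ion intensity is excluded from the
denominator — oxonium ions are disproportionately abundant in N-glycopeptide
spectra and would otherwise distort the score.

Error control uses a shuffle-decoy database searched alongside the targets;
a descending score sweep accepts the largest target set whose estimated FDR
(#decoy / #target above threshold) stays at or below the requested level.

Two orchestration modes: *conventional* searches every oxonium-ion spectrum
against both the N- and O-glycan spaces; *preclassify* first calls the
logistic N/O classifier on the spectrum's oxonium features and searches only
the assigned space, roughly halving the searched candidate volume.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import LogisticModel, predict
from .glycodb import GlycanComposition, GlycoDatabases, PeptideEntry
from .masses import CARBAMIDOMETHYL, OXIDATION, PROTON, RESIDUE_MASSES, WATER
from .oxonium import extract_features, is_oxonium_spectrum, oxonium_ion_table
from .spectra import Ms2Spectrum, precursor_neutral_mass, remove_bottom_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "TheoreticalIon",
    "Gpsm",
    "SearchConfig",
    "SearchReport",
    "generate_candidates",
    "theoretical_ions",
    "score_gpsm",
    "passes_intact_ion_rule",
    "fdr_filter",
    "curate_training_gpsms",
    "run_search",
]

#: Defensive cap on the Y-series enumeration per candidate.
MAX_Y_SUBCOMPOSITIONS = 400


@dataclass(frozen=True)
class TheoreticalIon:
    """A singly protonated fragment: b/y backbone ion or Y (peptide + partial
    glycan; ``glycan_counts`` is the retained (HexNAc, Hex, Fuc, NeuAc))."""

    kind: str  # 'b', 'y' or 'Y'
    index: int = 0
    glycan_counts: tuple[int, int, int, int] | None = None
    mz: float = 0.0


@dataclass
class Gpsm:
    """A glycopeptide-spectral match and its score components."""

    scan_id: str
    peptide: PeptideEntry
    glycan: GlycanComposition
    glyco_type: str
    is_decoy: bool
    n_matched_ions: int
    intensity_fraction: float
    total_spectrum_intensity: float
    y_series_matched: bool

    @property
    def score(self) -> float:
        return self.n_matched_ions + self.intensity_fraction

    @property
    def intensity_coverage(self) -> float:
        # the curation filter's "intensity coverage" is the matched fraction
        return self.intensity_fraction


@dataclass
class SearchConfig:
    """Tolerances, filters and mode for a glycopeptide search."""

    ms1_tol_ppm: float = 10.0
    ms2_tol_ppm: float = 20.0
    fdr: float = 0.01
    top_fraction: float = 0.05
    min_oxonium_ions: int = 2
    require_204: bool = True
    bottom_fraction: float = 0.10
    require_intact_rule: bool = True
    min_len_requiring_intact_ion: int = 11
    mode: str = "conventional"  # or "preclassify"

    def __post_init__(self) -> None:
        if self.ms1_tol_ppm <= 0 or self.ms2_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")
        if self.mode not in ("conventional", "preclassify"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def serum(cls, **overrides) -> "SearchConfig":
        """Complex-sample relaxations: oxonium filter over the top 10% of
        peaks and no intact-peptide-ion requirement."""
        params = dict(top_fraction=0.10, require_intact_rule=False)
        params.update(overrides)
        return cls(**params)


# ---------------------------------------------------------------------------
# Theoretical ions and scoring
# ---------------------------------------------------------------------------

_residue_cache: dict[tuple[str, int], np.ndarray] = {}


def _residue_masses(sequence: str, n_oxidations: int) -> np.ndarray:
    """Per-residue masses with fixed carbamidomethyl-C; variable oxidation is
    placed on the first n_oxidations Met residues (deterministic convention,
    since only the oxidation count is tracked)."""
    key = (sequence, n_oxidations)
    cached = _residue_cache.get(key)
    if cached is not None:
        return cached
    masses = np.array([RESIDUE_MASSES[aa] for aa in sequence])
    for i, aa in enumerate(sequence):
        if aa == "C":
            masses[i] += CARBAMIDOMETHYL
    remaining = n_oxidations
    for i, aa in enumerate(sequence):
        if remaining == 0:
            break
        if aa == "M":
            masses[i] += OXIDATION
            remaining -= 1
    _residue_cache[key] = masses
    return masses


_subcomp_cache: dict[GlycanComposition, list[tuple[tuple[int, int, int, int], float]]] = {}


def _sub_compositions(glycan: GlycanComposition) -> list[tuple[tuple[int, int, int, int], float]]:
    """All (counts, mass) sub-compositions of a glycan, empty one included,
    capped at MAX_Y_SUBCOMPOSITIONS."""
    cached = _subcomp_cache.get(glycan)
    if cached is not None:
        return cached
    from .masses import FUC, HEX, HEXNAC, NEUAC

    subs: list[tuple[tuple[int, int, int, int], float]] = []
    for kn in range(glycan.n_hexnac + 1):
        for kh in range(glycan.n_hex + 1):
            for kf in range(glycan.n_fuc + 1):
                for ks in range(glycan.n_neuac + 1):
                    subs.append(
                        ((kn, kh, kf, ks), kn * HEXNAC + kh * HEX + kf * FUC + ks * NEUAC)
                    )
                    if len(subs) >= MAX_Y_SUBCOMPOSITIONS:
                        _subcomp_cache[glycan] = subs
                        return subs
    _subcomp_cache[glycan] = subs
    return subs


def theoretical_ions(peptide: PeptideEntry, glycan: GlycanComposition) -> list[TheoreticalIon]:
    """Singly charged b_i / y_i (i = 1..len-1) and the Y series (peptide plus
    every sub-composition of the glycan, Y0 included)."""
    masses = _residue_masses(peptide.sequence, peptide.n_oxidations)
    n = len(masses)
    prefix = np.cumsum(masses)
    pep_mass = prefix[-1] + WATER
    ions: list[TheoreticalIon] = []
    for i in range(1, n):
        ions.append(TheoreticalIon("b", index=i, mz=prefix[i - 1] + PROTON))
        ions.append(TheoreticalIon("y", index=i, mz=pep_mass - prefix[n - i - 1] + PROTON))
    for counts, gmass in _sub_compositions(glycan):
        ions.append(TheoreticalIon("Y", glycan_counts=counts, mz=pep_mass + gmass + PROTON))
    return ions


def oxonium_peak_mask(spectrum: Ms2Spectrum, tol_ppm: float = 20.0) -> np.ndarray:
    """Boolean mask over peaks lying within tol_ppm of any table oxonium ion."""
    mask = np.zeros(spectrum.n_peaks, dtype=bool)
    for ion in oxonium_ion_table():
        delta = ion.exact_mz * tol_ppm * 1e-6
        lo = np.searchsorted(spectrum.mz, ion.exact_mz - delta, side="left")
        hi = np.searchsorted(spectrum.mz, ion.exact_mz + delta, side="right")
        mask[lo:hi] = True
    return mask


def score_gpsm(
    spectrum: Ms2Spectrum,
    peptide: PeptideEntry,
    glycan: GlycanComposition,
    glyco_type: str,
    is_decoy: bool = False,
    ms2_tol_ppm: float = 20.0,
    _oxonium_mask: np.ndarray | None = None,
) -> Gpsm:
    """Modified Morpheus score for one candidate against one spectrum.

    Each theoretical ion matches its nearest peak if that peak lies within the
    ppm tolerance; a peak's intensity counts once toward the explained
    fraction even when several ions hit it, and oxonium-peak intensity is
    excluded from both numerator and denominator.
    """
    ions = theoretical_ions(peptide, glycan)
    ion_mz = np.array([ion.mz for ion in ions])
    npk = spectrum.n_peaks
    idx = np.searchsorted(spectrum.mz, ion_mz)
    left = np.clip(idx - 1, 0, npk - 1)
    right = np.clip(idx, 0, npk - 1)
    d_left = np.abs(spectrum.mz[left] - ion_mz)
    d_right = np.abs(spectrum.mz[right] - ion_mz)
    nearest = np.where(d_left <= d_right, left, right)
    matched = np.abs(spectrum.mz[nearest] - ion_mz) <= ion_mz * ms2_tol_ppm * 1e-6

    n_matched = int(matched.sum())
    y_matched = bool(any(matched[i] for i, ion in enumerate(ions) if ion.kind == "Y"))

    oxo = _oxonium_mask if _oxonium_mask is not None else oxonium_peak_mask(spectrum, ms2_tol_ppm)
    matched_peaks = np.unique(nearest[matched])
    numerator = float(spectrum.intensity[matched_peaks[~oxo[matched_peaks]]].sum()) if n_matched else 0.0
    total = spectrum.total_intensity
    denominator = total - float(spectrum.intensity[oxo].sum())
    if denominator <= 0:
        if n_matched:
            logger.warning(
                "scan %s: spectrum intensity is entirely oxonium; fraction set to 0",
                spectrum.scan_id,
            )
        fraction = 0.0
    else:
        # keep the fractional part strictly below 1 so that floor(score)
        # always recovers the matched-ion count, even at full coverage
        fraction = min(numerator / denominator, 1.0 - 1e-10)
    return Gpsm(
        scan_id=spectrum.scan_id,
        peptide=peptide,
        glycan=glycan,
        glyco_type=glyco_type,
        is_decoy=is_decoy,
        n_matched_ions=n_matched,
        intensity_fraction=fraction,
        total_spectrum_intensity=total,
        y_series_matched=y_matched,
    )


def passes_intact_ion_rule(gpsm: Gpsm, min_len: int = 11) -> bool:
    """Peptides shorter than ``min_len`` residues must be supported by an
    intact peptide ion (a matched Y-series ion, bare or with partial glycan)."""
    return len(gpsm.peptide.sequence) >= min_len or gpsm.y_series_matched


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

class CandidateIndex:
    """Mass-sorted peptide pools for fast precursor-window lookups."""

    def __init__(self, dbs: GlycoDatabases) -> None:
        self.dbs = dbs
        self._target_masses, self._target_order = self._sorted(dbs.peptides)
        self._decoy_masses, self._decoy_order = self._sorted(dbs.decoy_peptides)

    @staticmethod
    def _sorted(entries: Sequence[PeptideEntry]) -> tuple[np.ndarray, np.ndarray]:
        masses = np.array([e.monoisotopic_mass for e in entries]) if entries else np.empty(0)
        order = np.argsort(masses, kind="stable")
        return masses[order], order

    def _window(
        self, pool: Sequence[PeptideEntry], masses: np.ndarray, order: np.ndarray,
        lo: float, hi: float,
    ) -> list[PeptideEntry]:
        a = np.searchsorted(masses, lo, side="left")
        b = np.searchsorted(masses, hi, side="right")
        return [pool[order[i]] for i in range(a, b)]

    def query(
        self, neutral_mass: float, glyco_type: str, ms1_tol_ppm: float, decoys: bool
    ) -> list[tuple[PeptideEntry, GlycanComposition, str, bool]]:
        tol = neutral_mass * ms1_tol_ppm * 1e-6
        glycans = self.dbs.n_glycans if glyco_type == "N" else self.dbs.o_glycans
        if decoys:
            pool, masses, order = self.dbs.decoy_peptides, self._decoy_masses, self._decoy_order
        else:
            pool, masses, order = self.dbs.peptides, self._target_masses, self._target_order
        out: list[tuple[PeptideEntry, GlycanComposition, str, bool]] = []
        for glycan in glycans:
            want = neutral_mass - glycan.mass
            for pep in self._window(pool, masses, order, want - tol, want + tol):
                if not decoys:
                    # motif gates apply to targets only; decoys estimate error
                    if glyco_type == "N" and not pep.has_n_motif:
                        continue
                    if glyco_type == "O" and not pep.has_st:
                        continue
                out.append((pep, glycan, glyco_type, decoys))
        return out


def generate_candidates(
    neutral_mass: float,
    dbs: GlycoDatabases,
    glyco_type_filter: str = "both",
    ms1_tol_ppm: float = 10.0,
    include_decoys: bool = True,
    _index: CandidateIndex | None = None,
) -> list[tuple[PeptideEntry, GlycanComposition, str, bool]]:
    """All (peptide, glycan, type, is_decoy) pairs matching the neutral mass
    within the MS1 tolerance. N pairings require an N-sequon, O pairings an
    S/T in the (target) peptide."""
    if glyco_type_filter not in ("N", "O", "both"):
        raise ValueError("glyco_type_filter must be 'N', 'O' or 'both'")
    index = _index if _index is not None else CandidateIndex(dbs)
    spaces = ["N", "O"] if glyco_type_filter == "both" else [glyco_type_filter]
    out = []
    for space in spaces:
        out.extend(index.query(neutral_mass, space, ms1_tol_ppm, decoys=False))
        if include_decoys:
            out.extend(index.query(neutral_mass, space, ms1_tol_ppm, decoys=True))
    return out


# ---------------------------------------------------------------------------
# FDR and curation
# ---------------------------------------------------------------------------

def _tie_key(g: Gpsm):
    # ties: decoy preferred (conservative), then smaller glycan, then peptide
    return (-g.score, 0 if g.is_decoy else 1, g.glycan.n_residues, g.peptide.sequence, str(g.glycan))


def fdr_filter(gpsms: Sequence[Gpsm], fdr: float = 0.01) -> tuple[list[Gpsm], float]:
    """Descending-score sweep; returns (accepted target GPSMs, score threshold).

    At each candidate threshold FDR is estimated as #decoy / max(#target, 1);
    the largest target set with estimated FDR <= ``fdr`` is accepted. Decoys
    sort before targets at equal score, which keeps the estimate conservative.
    """
    ranked = sorted(gpsms, key=_tie_key)
    best_cut = -1
    n_targets_best = 0
    n_decoy = n_target = 0
    for i, g in enumerate(ranked):
        if g.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
        if n_decoy / max(n_target, 1) <= fdr and n_target > n_targets_best:
            best_cut = i
            n_targets_best = n_target
    if best_cut < 0:
        return [], float("inf")
    accepted = [g for g in ranked[: best_cut + 1] if not g.is_decoy]
    return accepted, ranked[best_cut].score


def curate_training_gpsms(
    gpsms: Sequence[Gpsm],
    known_glycosites: Mapping[str, Iterable[int]],
    min_coverage: float = 0.10,
    min_total_intensity: float = 5e5,
) -> list[Gpsm]:
    """Training-set curation: keep GPSMs whose peptide overlaps a known
    glycosite (0-based protein positions), with intensity coverage >=
    min_coverage and total spectrum intensity >= min_total_intensity; O-linked
    GPSMs must lie on peptides with no N-sequon."""
    site_map = {prot: set(pos) for prot, pos in known_glycosites.items()}
    kept = []
    for g in gpsms:
        pep = g.peptide
        sites = site_map.get(pep.protein_id, set())
        if pep.start < 0:
            continue
        span = range(pep.start, pep.start + len(pep.sequence))
        if not any(s in sites for s in span):
            continue
        if g.intensity_coverage < min_coverage:
            continue
        if g.total_spectrum_intensity < min_total_intensity:
            continue
        if g.glyco_type == "O" and pep.has_n_motif:
            continue
        kept.append(g)
    return kept


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SearchReport:
    """Accepted identifications plus the summary counters of a search run."""

    gpsms: list[Gpsm]
    score_threshold: float
    mode: str
    n_spectra: int
    n_oxonium_spectra: int
    n_candidates_scored: int
    unclassifiable_scans: list[str] = field(default_factory=list)

    @property
    def n_assigned_spectra(self) -> int:
        return len(self.gpsms)

    @property
    def unique_glycopeptides(self) -> set[tuple[str, str]]:
        return {(g.peptide.sequence, str(g.glycan)) for g in self.gpsms}

    @property
    def peptide_backbones(self) -> set[str]:
        return {g.peptide.sequence for g in self.gpsms}

    @property
    def glycan_compositions(self) -> set[str]:
        return {str(g.glycan) for g in self.gpsms}

    def summary(self) -> dict[str, object]:
        return {
            "mode": self.mode,
            "n_spectra": self.n_spectra,
            "n_oxonium_spectra": self.n_oxonium_spectra,
            "assigned_spectra": self.n_assigned_spectra,
            "unique_glycopeptides": len(self.unique_glycopeptides),
            "peptide_backbones": len(self.peptide_backbones),
            "glycan_compositions": len(self.glycan_compositions),
            "score_threshold": self.score_threshold,
            "candidates_scored": self.n_candidates_scored,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scan_id": g.scan_id,
                "peptide": g.peptide.sequence,
                "protein": g.peptide.protein_id,
                "glycan": str(g.glycan),
                "glyco_type": g.glyco_type,
                "score": g.score,
                "n_matched_ions": g.n_matched_ions,
                "intensity_fraction": g.intensity_fraction,
                "is_decoy": g.is_decoy,
            }
            for g in self.gpsms
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "scan_id", "peptide", "protein", "glycan", "glyco_type",
                "score", "n_matched_ions", "intensity_fraction", "is_decoy",
            ],
        )


def run_search(
    spectra: Iterable[Ms2Spectrum],
    dbs: GlycoDatabases,
    config: SearchConfig | None = None,
    model: LogisticModel | None = None,
) -> SearchReport:
    """Search spectra for intact glycopeptides.

    Spectra are preprocessed (bottom-fraction removal), screened by the
    oxonium-ion filter, matched to candidates by precursor neutral mass,
    scored, reduced to their best GPSM, and filtered at the configured FDR.
    In preclassify mode each spectrum is first typed N or O from its oxonium
    features and only the assigned glycan space is searched.
    """
    config = config or SearchConfig()
    if config.mode == "preclassify" and model is None:
        raise ValueError("preclassify mode requires a fitted classifier model")
    index = CandidateIndex(dbs)
    best_gpsms: list[Gpsm] = []
    n_spectra = 0
    n_oxonium = 0
    n_scored = 0
    unclassifiable: list[str] = []
    for raw in spectra:
        n_spectra += 1
        spec = remove_bottom_fraction(raw, config.bottom_fraction)
        if not is_oxonium_spectrum(
            spec,
            top_fraction=config.top_fraction,
            min_ions=config.min_oxonium_ions,
            require_204=config.require_204,
            tol_ppm=config.ms2_tol_ppm,
        ):
            continue
        n_oxonium += 1
        if config.mode == "preclassify":
            try:
                label, _prob = predict(model, extract_features(spec, config.ms2_tol_ppm))
            except ValueError:
                unclassifiable.append(spec.scan_id)
                continue
            spaces = label
        else:
            spaces = "both"
        neutral = precursor_neutral_mass(spec)
        candidates = generate_candidates(
            neutral, dbs, spaces, config.ms1_tol_ppm, include_decoys=True, _index=index
        )
        if not candidates:
            continue
        oxo_mask = oxonium_peak_mask(spec, config.ms2_tol_ppm)
        scored = [
            score_gpsm(spec, pep, glycan, gtype, is_decoy, config.ms2_tol_ppm, _oxonium_mask=oxo_mask)
            for pep, glycan, gtype, is_decoy in candidates
        ]
        n_scored += len(scored)
        if config.require_intact_rule:
            scored = [
                g for g in scored
                if passes_intact_ion_rule(g, config.min_len_requiring_intact_ion)
            ]
        if not scored:
            continue
        best_gpsms.append(min(scored, key=_tie_key))
    accepted, threshold = fdr_filter(best_gpsms, config.fdr)
    return SearchReport(
        gpsms=accepted,
        score_threshold=threshold,
        mode=config.mode,
        n_spectra=n_spectra,
        n_oxonium_spectra=n_oxonium,
        n_candidates_scored=n_scored,
        unclassifiable_scans=unclassifiable,
    )
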