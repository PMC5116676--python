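"""Ground-truth synthetic glycopeptide HCD spectra.

Emulates the features of glycopeptide HCD spectra that the rest of the
package consumes: singly charged b/y backbone ions, a Y-ion ladder (peptide
retaining a nested sub-glycan), the 10 diagnostic oxonium ions with
class-conditional intensity ratios, ppm-scale m/z jitter and random noise
peaks. The class-conditional ratio medians follow the qualitative contrast
between glycosylation types — O-linked spectra carry a high 186/204 ratio and
abundant Neu5Ac ions, N-linked spectra carry higher Hex-derived ions and a
high HexHexNAc (366) ion — with log-normal spread around each median. The
medians are plausible synthetic settings expressing that ordering, not
measured values.

Every emitted spectrum is paired with a planted-truth record (peptide, glycan,
type, drawn ratios), so classifier and search results can be checked against
known ground truth. Identical configuration yields byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glycodb import (
    GlycanComposition,
    GlycoDatabases,
    PeptideEntry,
    build_databases,
    tryptic_digest,
)
from .masses import PROTON
from .oxonium import FEATURE_IONS, OxoniumFeatures, extract_features, oxonium_ion_table
from .spectra import Ms2Spectrum, write_mgf

__all__ = [
    "GeneratorConfig",
    "SynthDataset",
    "default_n_glycans",
    "default_o_glycans",
    "make_default_databases",
    "generate_spectrum",
    "generate_dataset",
]

#: Class-conditional medians of the 9 ion/204 ratios. O-linked: 186/204 high,
#: Neu5Ac ions (274/292) abundant; N-linked: Hex ions (145/163/325) and the
#: HexHexNAc 366 ion high, 186/204 low.
O_RATIO_MEDIANS: dict[int, float] = {
    138: 0.40, 145: 0.02, 163: 0.02, 168: 0.15, 186: 0.90,
    274: 0.50, 292: 0.60, 325: 0.02, 366: 0.15,
}
N_RATIO_MEDIANS: dict[int, float] = {
    138: 1.00, 145: 0.20, 163: 0.20, 168: 0.40, 186: 0.12,
    274: 0.10, 292: 0.10, 325: 0.20, 366: 0.50,
}

# non-oxonium peaks are kept out of a guard band around every table ion so
# that planted oxonium intensities stay unambiguous
_OXONIUM_GUARD_PPM = 30.0
_OXONIUM_MZ = np.array([ion.exact_mz for ion in oxonium_ion_table()])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a curated two-class training set of 872 N-linked and 527
    O-linked spectra with instrument-like 5 ppm MS2 (2 ppm MS1) mass jitter
    and a base-peak intensity scale of 1e6 counts.
    """

    seed: int = 1
    n_n: int = 872
    n_o: int = 527
    o_ratio_medians: Mapping[int, float] = field(default_factory=lambda: dict(O_RATIO_MEDIANS))
    n_ratio_medians: Mapping[int, float] = field(default_factory=lambda: dict(N_RATIO_MEDIANS))
    ratio_dispersion: float = 0.4  # sigma of log-normal spread around medians
    i204_dispersion: float = 0.3
    frag_efficiency_by: float = 0.7  # inclusion probability per b/y ion
    frag_efficiency_y: float = 0.8  # inclusion probability per Y-ladder ion
    n_noise_peaks: int = 30
    noise_intensity_scale: float = 2e3
    by_intensity_scale: float = 5e4
    y_intensity_scale: float = 1e5
    jitter_ppm: float = 5.0
    ms1_jitter_ppm: float = 2.0
    base_intensity: float = 1e6

    def __post_init__(self) -> None:
        for med in (*self.o_ratio_medians.values(), *self.n_ratio_medians.values()):
            if med <= 0:
                raise ValueError("ratio medians must be positive")
        if self.ratio_dispersion < 0 or self.jitter_ppm < 0:
            raise ValueError("dispersions and jitter must be nonnegative")


def default_n_glycans() -> list[GlycanComposition]:
    """Small synthetic N-glycan composition list: high-mannose series plus
    sialylated/fucosylated complex compositions (includes the N/O-ambiguous
    N3H3F0S0)."""
    return [GlycanComposition.parse(s) for s in (
        "N2H5F0S0", "N2H6F0S0", "N2H7F0S0", "N2H8F0S0", "N2H9F0S0",
        "N3H3F0S0", "N3H4F0S1", "N4H5F0S0", "N4H5F0S1", "N4H5F0S2",
        "N4H5F1S1", "N5H6F0S3",
    )]


def default_o_glycans() -> list[GlycanComposition]:
    """Small synthetic O-glycan composition list: mucin-type core-1/2 style
    compositions (includes the N/O-ambiguous N3H3F0S0)."""
    return [GlycanComposition.parse(s) for s in (
        "N1H1F0S0", "N1H1F0S1", "N1H1F0S2", "N1H1F1S1", "N2H1F0S0",
        "N2H2F0S0", "N2H2F0S1", "N2H2F0S2", "N3H3F0S0", "N3H3F0S1",
    )]


_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# residue draw weights: K/R enriched for tryptic peptides of realistic length,
# N/S/T enriched so sequons and O-sites occur at useful rates
_AA_WEIGHTS = np.array([
    0.05, 0.02, 0.05, 0.06, 0.03, 0.06, 0.02, 0.05, 0.06, 0.08,
    0.03, 0.07, 0.04, 0.04, 0.06, 0.09, 0.08, 0.06, 0.01, 0.04,
])
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def make_default_databases(
    seed: int,
    n_proteins: int = 10,
    protein_length: int = 250,
    decoy_seed: int | None = None,
) -> GlycoDatabases:
    """Synthetic protein pool digested into target peptides, with shuffle
    decoys and the default glycan lists."""
    rng = np.random.default_rng(seed)
    peptides: list[PeptideEntry] = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(_AA_ALPHABET, size=protein_length, p=_AA_WEIGHTS))
        peptides.extend(tryptic_digest(seq, protein_id=f"SYN{i:03d}"))
    return build_databases(
        peptides,
        default_n_glycans(),
        default_o_glycans(),
        decoy_seed=seed if decoy_seed is None else decoy_seed,
    )


def _jitter(mz: np.ndarray | float, ppm: float, rng: np.random.Generator):
    # gaussian mass error truncated at 3 sigma: centroided high-resolution
    # peaks do not stray arbitrarily far from their true m/z
    if ppm == 0:
        return mz
    scale = np.asarray(mz) * ppm * 1e-6
    draw = np.clip(rng.normal(0.0, 1.0, size=np.shape(mz)), -3.0, 3.0)
    return mz + draw * scale


def _in_guard_band(mz: float) -> bool:
    return bool(np.any(np.abs(_OXONIUM_MZ - mz) <= _OXONIUM_MZ * _OXONIUM_GUARD_PPM * 1e-6))


def _y_ladder(glycan: GlycanComposition) -> list[tuple[int, int, int, int]]:
    """Nested sub-compositions from the full glycan down to Y0, stripping
    NeuAc, then Fuc, then Hex, then HexNAc one residue at a time."""
    counts = [glycan.n_hexnac, glycan.n_hex, glycan.n_fuc, glycan.n_neuac]
    ladder = [tuple(counts)]
    for slot in (3, 2, 1, 0):
        while counts[slot] > 0:
            counts[slot] -= 1
            ladder.append(tuple(counts))
    return ladder  # ends at (0, 0, 0, 0) = Y0


def generate_spectrum(
    peptide: PeptideEntry,
    glycan: GlycanComposition,
    glyco_type: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    scan_id: str = "synth_0",
) -> tuple[Ms2Spectrum, dict]:
    """One synthetic HCD spectrum plus its planted-truth record."""
    from .search import _residue_masses  # shared residue-mass convention
    from .masses import WATER

    medians = config.o_ratio_medians if glyco_type == "O" else config.n_ratio_medians
    i204 = config.base_intensity * float(
        np.exp(rng.normal(0.0, config.i204_dispersion))
    )
    ratios = {
        ion: float(medians[ion] * np.exp(rng.normal(0.0, config.ratio_dispersion)))
        for ion in FEATURE_IONS
    }

    mzs: list[float] = []
    intens: list[float] = []
    for ion in oxonium_ion_table():
        inten = i204 if ion.nominal_mz == 204 else ratios[ion.nominal_mz] * i204
        mzs.append(float(_jitter(ion.exact_mz, config.jitter_ppm, rng)))
        intens.append(inten)

    res = _residue_masses(peptide.sequence, peptide.n_oxidations)
    prefix = np.cumsum(res)
    pep_mass = float(prefix[-1]) + WATER
    n = len(res)
    for i in range(1, n):
        for frag_mz in (float(prefix[i - 1]) + PROTON, pep_mass - float(prefix[n - i - 1]) + PROTON):
            if rng.random() >= config.frag_efficiency_by or _in_guard_band(frag_mz):
                continue
            mzs.append(float(_jitter(frag_mz, config.jitter_ppm, rng)))
            intens.append(config.by_intensity_scale * float(rng.exponential()))

    from .masses import FUC, HEX, HEXNAC, NEUAC

    for kn, kh, kf, ks in _y_ladder(glycan):
        y_mz = pep_mass + kn * HEXNAC + kh * HEX + kf * FUC + ks * NEUAC + PROTON
        if rng.random() >= config.frag_efficiency_y or _in_guard_band(y_mz):
            continue
        mzs.append(float(_jitter(y_mz, config.jitter_ppm, rng)))
        intens.append(config.y_intensity_scale * float(rng.exponential()))

    charge = int(rng.choice((2, 3)))
    neutral = pep_mass + glycan.mass
    precursor_mz = (neutral + charge * PROTON) / charge
    precursor_mz = float(_jitter(precursor_mz, config.ms1_jitter_ppm, rng))

    for _ in range(config.n_noise_peaks):
        noise_mz = float(rng.uniform(120.0, max(precursor_mz, 130.0)))
        if _in_guard_band(noise_mz):
            continue
        mzs.append(noise_mz)
        intens.append(config.noise_intensity_scale * float(rng.exponential()))

    spectrum = Ms2Spectrum(scan_id, precursor_mz, charge, mzs, intens)
    truth = {
        "scan_id": scan_id,
        "peptide": peptide.sequence,
        "protein": peptide.protein_id,
        "n_oxidations": peptide.n_oxidations,
        "glycan": str(glycan),
        "glyco_type": glyco_type,
        "charge": charge,
        "i204": i204,
        **{f"r{ion}": ratios[ion] for ion in FEATURE_IONS},
    }
    return spectrum, truth


@dataclass
class SynthDataset:
    """A generated spectrum collection with planted truth and features."""

    spectra: list[Ms2Spectrum]
    truth: pd.DataFrame
    features: list[OxoniumFeatures]
    labels: list[str]
    databases: GlycoDatabases
    config: GeneratorConfig

    def write(self, out_dir: str) -> dict[str, str]:
        """Write spectra.mgf plus truth/feature/label TSVs; returns paths."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "spectra": os.path.join(out_dir, "spectra.mgf"),
            "truth": os.path.join(out_dir, "truth.tsv"),
            "features": os.path.join(out_dir, "features.tsv"),
            "labels": os.path.join(out_dir, "labels.tsv"),
        }
        write_mgf(self.spectra, paths["spectra"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        feat_rows = []
        for spec, feat in zip(self.spectra, self.features):
            row = {"scan_id": spec.scan_id}
            row.update({f"r{k}": feat.ratios[k] for k in FEATURE_IONS})
            row["i204"] = feat.intensity_204
            feat_rows.append(row)
        pd.DataFrame(feat_rows).to_csv(paths["features"], sep="\t", index=False)
        pd.DataFrame(
            {"scan_id": [s.scan_id for s in self.spectra], "label": self.labels}
        ).to_csv(paths["labels"], sep="\t", index=False)
        return paths


def generate_dataset(
    config: GeneratorConfig | None = None,
    databases: GlycoDatabases | None = None,
    out_dir: str | None = None,
) -> SynthDataset:
    """Generate the configured N/O spectrum collection.

    Peptides are drawn from the sequon-bearing (N) or S/T-bearing,
    sequon-free (O) pools of the database; glycans from the matching
    composition list. Reproducible from ``config.seed``; pass ``out_dir`` to
    also write MGF and TSV files.
    """
    config = config or GeneratorConfig()
    dbs = databases if databases is not None else make_default_databases(config.seed)
    rng = np.random.default_rng(config.seed)
    n_pool = [p for p in dbs.peptides if p.has_n_motif]
    o_pool = [p for p in dbs.peptides if p.has_st and not p.has_n_motif]
    if config.n_n > 0 and not n_pool:
        raise ValueError("database has no sequon-bearing peptides for N spectra")
    if config.n_o > 0 and not o_pool:
        raise ValueError("database has no sequon-free S/T peptides for O spectra")

    spectra: list[Ms2Spectrum] = []
    truth_rows: list[dict] = []
    labels: list[str] = []
    plan = [("N", n_pool, dbs.n_glycans, config.n_n), ("O", o_pool, dbs.o_glycans, config.n_o)]
    for gtype, pool, glycans, count in plan:
        for i in range(count):
            pep = pool[int(rng.integers(len(pool)))]
            glycan = glycans[int(rng.integers(len(glycans)))]
            scan_id = f"synth_{gtype}_{i:05d}"
            spec, rec = generate_spectrum(pep, glycan, gtype, config, rng, scan_id)
            spectra.append(spec)
            truth_rows.append(rec)
            labels.append(gtype)
    features = [extract_features(s) for s in spectra]
    truth = pd.DataFrame(truth_rows)
    dataset = SynthDataset(
        spectra=spectra,
        truth=truth,
        features=features,
        labels=labels,
        databases=dbs,
        config=config,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
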