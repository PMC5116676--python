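"""Candidate generation, modified Morpheus scoring, FDR and search modes."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from glycotyper import (
    GlycanComposition,
    PeptideEntry,
    SearchConfig,
    build_databases,
    curate_training_gpsms,
    fdr_filter,
    generate_candidates,
    parse_composition,
    passes_intact_ion_rule,
    peptide_monoisotopic_mass,
    run_search,
    score_gpsm,
    theoretical_ions,
    train,
)
from glycotyper.glycodb import find_n_motifs
from glycotyper.masses import PROTON, RESIDUE_MASSES, WATER
from glycotyper.search import Gpsm

from .conftest import make_spectrum


def entry(seq: str, protein="P1", n_ox=0, start=0) -> PeptideEntry:
    return PeptideEntry(
        sequence=seq,
        protein_id=protein,
        n_oxidations=n_ox,
        monoisotopic_mass=peptide_monoisotopic_mass(seq, n_ox),
        n_motif_positions=tuple(find_n_motifs(seq)),
        start=start,
    )


# ---------------------------------------------------------------------------
# Theoretical ions
# ---------------------------------------------------------------------------

def test_dipeptide_ion_list():
    ions = theoretical_ions(entry("GK"), GlycanComposition(1, 0, 0, 0))
    kinds = [(ion.kind, ion.index, ion.glycan_counts) for ion in ions]
    assert ("b", 1, None) in kinds and ("y", 1, None) in kinds
    assert ("Y", 0, (0, 0, 0, 0)) in kinds  # bare peptide Y0
    assert ("Y", 0, (1, 0, 0, 0)) in kinds  # peptide + HexNAc
    assert not any(k == "y" and i >= 2 for k, i, _ in kinds)  # y_len excluded
    by_key = {(ion.kind, ion.index, ion.glycan_counts): ion.mz for ion in ions}
    assert by_key[("b", 1, None)] == pytest.approx(RESIDUE_MASSES["G"] + PROTON, abs=1e-6)
    assert by_key[("y", 1, None)] == pytest.approx(
        RESIDUE_MASSES["K"] + WATER + PROTON, abs=1e-6
    )
    assert by_key[("Y", 0, (0, 0, 0, 0))] == pytest.approx(
        peptide_monoisotopic_mass("GK") + PROTON, abs=1e-6
    )


def test_y_series_counts_subcompositions():
    ions = theoretical_ions(entry("GK"), GlycanComposition(2, 1, 0, 0))
    y_ions = [ion for ion in ions if ion.kind == "Y"]
    assert len(y_ions) == 6  # (2+1) x (1+1)


def test_oxidation_shifts_first_met():
    plain = theoretical_ions(entry("MAMK"), GlycanComposition(1, 0, 0, 0))
    oxidized = theoretical_ions(entry("MAMK", n_ox=1), GlycanComposition(1, 0, 0, 0))
    b1 = {tuple((i.kind, i.index)): i.mz for i in plain}[("b", 1)]
    b1_ox = {tuple((i.kind, i.index)): i.mz for i in oxidized}[("b", 1)]
    assert b1_ox - b1 == pytest.approx(15.994915, abs=1e-6)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _ion_mz(ions, kind, index):
    return next(i.mz for i in ions if i.kind == kind and i.index == index)


def test_score_full_coverage():
    pep = entry("AGGDLK")
    glycan = GlycanComposition(1, 1, 0, 0)
    ions = theoretical_ions(pep, glycan)
    spec = make_spectrum([(_ion_mz(ions, "b", 2), 100.0), (_ion_mz(ions, "y", 3), 100.0)])
    g = score_gpsm(spec, pep, glycan, "O")
    assert g.n_matched_ions == 2
    assert g.score == pytest.approx(3.0)


def test_score_with_unmatched_noise():
    pep = entry("AGGDLK")
    glycan = GlycanComposition(1, 1, 0, 0)
    ions = theoretical_ions(pep, glycan)
    spec = make_spectrum(
        [(_ion_mz(ions, "b", 2), 100.0), (_ion_mz(ions, "y", 3), 100.0), (900.0, 200.0)]
    )
    g = score_gpsm(spec, pep, glycan, "O")
    assert g.score == pytest.approx(2.5)


def test_score_only_oxonium_spectrum_is_zero():
    from glycotyper.oxonium import oxonium_mz

    pep = entry("AGGDLK")
    spec = make_spectrum([(oxonium_mz(204), 1e5), (oxonium_mz(186), 5e4)])
    g = score_gpsm(spec, pep, GlycanComposition(1, 1, 0, 0), "O")
    assert g.score == 0.0


def test_score_floor_is_matched_count(noiseless_dataset):
    ds = noiseless_dataset
    dbs = ds.databases
    by_key = {(p.sequence, p.n_oxidations): p for p in dbs.peptides}
    for spec, (_, row) in zip(ds.spectra[:30], ds.truth.iterrows()):
        pep = by_key[(row["peptide"], row["n_oxidations"])]
        g = score_gpsm(spec, pep, parse_composition(row["glycan"]), row["glyco_type"])
        assert int(g.score) == g.n_matched_ions
        assert 0.0 <= g.intensity_fraction < 1.0 + 1e-12


# Independent brute-force oracle: all-pairs peak-vs-ion matching with plain
# Python loops, assigning each ion its nearest in-tolerance peak.

_OXONIUM_MZ = [138.0550, 145.0495, 163.0601, 168.0655, 186.0761,
               204.0867, 274.0921, 292.1027, 325.1129, 366.1395]
_SUGARS = {"HexNAc": 203.079373, "Hex": 162.052824, "Fuc": 146.057909, "NeuAc": 291.095417}


def brute_force_score(spectrum, sequence, n_ox, glycan, tol_ppm=20.0):
    res = []
    for aa in sequence:
        m = RESIDUE_MASSES[aa] + (57.021464 if aa == "C" else 0.0)
        res.append(m)
    left = n_ox
    for i, aa in enumerate(sequence):
        if left and aa == "M":
            res[i] += 15.994915
            left -= 1
    pep_mass = sum(res) + WATER
    ion_mzs = []
    for i in range(1, len(sequence)):
        ion_mzs.append(sum(res[:i]) + PROTON)
        ion_mzs.append(sum(res[len(sequence) - i:]) + WATER + PROTON)
    for kn, kh, kf, ks in itertools.product(
        range(glycan.n_hexnac + 1), range(glycan.n_hex + 1),
        range(glycan.n_fuc + 1), range(glycan.n_neuac + 1),
    ):
        ion_mzs.append(
            pep_mass + kn * _SUGARS["HexNAc"] + kh * _SUGARS["Hex"]
            + kf * _SUGARS["Fuc"] + ks * _SUGARS["NeuAc"] + PROTON
        )
    peaks = list(zip(spectrum.mz, spectrum.intensity))
    oxo_idx = {
        i for i, (mz, _) in enumerate(peaks)
        if any(abs(mz - o) <= o * tol_ppm * 1e-6 for o in _OXONIUM_MZ)
    }
    n_matched = 0
    matched_idx = set()
    for ion_mz in ion_mzs:
        in_tol = [i for i, (mz, _) in enumerate(peaks) if abs(mz - ion_mz) <= ion_mz * tol_ppm * 1e-6]
        if in_tol:
            n_matched += 1
            # nearest in-tolerance peak, lower m/z on exact distance ties
            matched_idx.add(min(in_tol, key=lambda i: (abs(peaks[i][0] - ion_mz), peaks[i][0])))
    numerator = sum(peaks[i][1] for i in matched_idx - oxo_idx)
    denominator = sum(inten for _, inten in peaks) - sum(peaks[i][1] for i in oxo_idx)
    fraction = numerator / denominator if denominator > 0 else 0.0
    return n_matched + fraction


def test_scoring_matches_bruteforce_on_synthetic_candidates(noiseless_dataset):
    ds = noiseless_dataset
    by_key = {(p.sequence, p.n_oxidations): p for p in ds.databases.peptides}
    for spec, (_, row) in zip(ds.spectra[:20], ds.truth.iterrows()):
        pep = by_key[(row["peptide"], row["n_oxidations"])]
        glycan = parse_composition(row["glycan"])
        g = score_gpsm(spec, pep, glycan, row["glyco_type"])
        oracle = brute_force_score(spec, pep.sequence, pep.n_oxidations, glycan)
        assert g.score == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

@pytest.fixture()
def small_dbs():
    peptides = [
        entry("LCPDCPLLAPLNDSR"),  # sequon-bearing
        entry("TVAAPSVFIFPPSDEK"),  # S/T, no sequon
        entry("GGGGLGLGK"),  # neither S/T nor sequon
    ]
    return build_databases(
        peptides,
        [parse_composition("N4H5F0S1"), parse_composition("N2H5F0S0")],
        [parse_composition("N1H1F0S1")],
        decoy_seed=1,
    )


def test_candidates_contain_exact_pair(small_dbs):
    pep_mass = peptide_monoisotopic_mass("LCPDCPLLAPLNDSR")
    neutral = pep_mass + parse_composition("N4H5F0S1").mass
    cands = generate_candidates(neutral, small_dbs, "N", include_decoys=False)
    assert any(
        p.sequence == "LCPDCPLLAPLNDSR" and str(g) == "N4H5F0S1" for p, g, t, d in cands
    )


def test_candidates_respect_tolerance(small_dbs):
    pep_mass = peptide_monoisotopic_mass("LCPDCPLLAPLNDSR")
    neutral = (pep_mass + parse_composition("N4H5F0S1").mass) * (1 + 50e-6)  # 50 ppm off
    assert generate_candidates(neutral, small_dbs, "N", include_decoys=False) == []


def test_motif_gates(small_dbs):
    # a peptide with neither S/T nor a sequon is never paired as a target
    neutral_n = peptide_monoisotopic_mass("GGGGLGLGK") + parse_composition("N2H5F0S0").mass
    neutral_o = peptide_monoisotopic_mass("GGGGLGLGK") + parse_composition("N1H1F0S1").mass
    for neutral, space in [(neutral_n, "N"), (neutral_o, "O")]:
        cands = generate_candidates(neutral, small_dbs, space, include_decoys=False)
        assert not any(p.sequence == "GGGGLGLGK" for p, *_ in cands)
    # O pairings exclude sequon-free requirement does not bar S/T peptides
    neutral = peptide_monoisotopic_mass("TVAAPSVFIFPPSDEK") + parse_composition("N1H1F0S1").mass
    cands = generate_candidates(neutral, small_dbs, "O", include_decoys=False)
    assert any(p.sequence == "TVAAPSVFIFPPSDEK" for p, *_ in cands)


# ---------------------------------------------------------------------------
# Intact-ion rule
# ---------------------------------------------------------------------------

def test_intact_ion_rule():
    pep9 = entry("AGGDLKGGR")  # 9 residues
    glycan = GlycanComposition(1, 0, 0, 0)
    ions = theoretical_ions(pep9, glycan)
    y1_mz = next(i.mz for i in ions if i.kind == "Y" and i.glycan_counts == (1, 0, 0, 0))
    with_y = make_spectrum([(y1_mz, 500.0)])
    g = score_gpsm(with_y, pep9, glycan, "O")
    assert passes_intact_ion_rule(g)

    b2_mz = _ion_mz(ions, "b", 2)
    only_by = make_spectrum([(b2_mz, 500.0)])
    g2 = score_gpsm(only_by, pep9, glycan, "O")
    assert not passes_intact_ion_rule(g2)

    pep15 = entry("AGGDLKGGAGGDLKR")
    g3 = score_gpsm(only_by, pep15, glycan, "O")
    assert not g3.y_series_matched
    assert passes_intact_ion_rule(g3)  # length gate: rule not triggered


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def _gpsm(score: float, is_decoy: bool, scan="s") -> Gpsm:
    return Gpsm(
        scan_id=scan,
        peptide=entry("AGGDLK"),
        glycan=GlycanComposition(1, 0, 0, 0),
        glyco_type="O",
        is_decoy=is_decoy,
        n_matched_ions=int(score),
        intensity_fraction=score - int(score),
        total_spectrum_intensity=1e6,
        y_series_matched=True,
    )


def test_fdr_sweep_accepts_targets_above_single_decoy():
    targets = [_gpsm(100.0 - i * 0.5, False, f"t{i}") for i in range(99)]
    decoy = [_gpsm(10.0, True, "d0")]  # below every target
    accepted, threshold = fdr_filter(targets + decoy, fdr=0.01)
    assert len(accepted) == 99
    assert threshold <= min(t.score for t in targets)


def test_fdr_all_decoys_on_top_rejects_everything():
    decoys = [_gpsm(50.0 + i, True, f"d{i}") for i in range(5)]
    targets = [_gpsm(10.0 - i, False, f"t{i}") for i in range(5)]
    accepted, _ = fdr_filter(decoys + targets, fdr=0.01)
    assert accepted == []


def test_fdr_zero_decoys_accepts_all():
    targets = [_gpsm(5.0 + i, False, f"t{i}") for i in range(10)]
    accepted, threshold = fdr_filter(targets, fdr=0.01)
    assert len(accepted) == 10
    assert threshold == pytest.approx(5.0)


def test_fdr_monotone_in_strictness():
    rng = np.random.default_rng(0)
    gpsms = [_gpsm(float(rng.uniform(0, 30)), bool(rng.random() < 0.3), f"g{i}") for i in range(200)]
    sizes = [len(fdr_filter(gpsms, f)[0]) for f in (0.001, 0.01, 0.05, 0.2)]
    assert sizes == sorted(sizes)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def test_curation_filters():
    sites = {"P1": [12]}
    base = dict(
        scan_id="s",
        glycan=GlycanComposition(1, 1, 0, 0),
        is_decoy=False,
        n_matched_ions=5,
        y_series_matched=True,
    )
    good = Gpsm(
        peptide=entry("TVAAPSVFIFPPK", start=5), glyco_type="O",
        intensity_fraction=0.5, total_spectrum_intensity=1e6, **base,
    )
    low_cov = Gpsm(
        peptide=entry("TVAAPSVFIFPPK", start=5), glyco_type="O",
        intensity_fraction=0.09, total_spectrum_intensity=1e6, **base,
    )
    low_int = Gpsm(
        peptide=entry("TVAAPSVFIFPPK", start=5), glyco_type="O",
        intensity_fraction=0.5, total_spectrum_intensity=4.9e5, **base,
    )
    o_with_sequon = Gpsm(
        peptide=entry("TVNDSVFIFPPK", start=5), glyco_type="O",
        intensity_fraction=0.5, total_spectrum_intensity=1e6, **base,
    )
    off_site = Gpsm(
        peptide=entry("TVAAPSVFIFPPK", start=100), glyco_type="O",
        intensity_fraction=0.5, total_spectrum_intensity=1e6, **base,
    )
    kept = curate_training_gpsms([good, low_cov, low_int, o_with_sequon, off_site], sites)
    assert kept == [good]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def test_serum_config_relaxations():
    cfg = SearchConfig.serum(mode="conventional")
    assert cfg.top_fraction == 0.10
    assert not cfg.require_intact_rule
    assert cfg.ms1_tol_ppm == 10.0 and cfg.ms2_tol_ppm == 20.0


def test_preclassify_requires_model(noiseless_dataset):
    with pytest.raises(ValueError):
        run_search(noiseless_dataset.spectra[:2], noiseless_dataset.databases,
                   SearchConfig(mode="preclassify"), model=None)


def test_search_modes_agree_on_planted_truth(noiseless_dataset):
    ds = noiseless_dataset
    model = train(ds.features, ds.labels, seed=0)
    conv = run_search(ds.spectra, ds.databases, SearchConfig(mode="conventional"))
    pre = run_search(ds.spectra, ds.databases, SearchConfig(mode="preclassify"), model)

    # preclassify touches at most the candidate volume of conventional
    assert pre.n_candidates_scored <= conv.n_candidates_scored
    truth = {r["scan_id"]: (r["peptide"], r["glycan"], r["glyco_type"]) for _, r in ds.truth.iterrows()}
    for report in (conv, pre):
        correct = sum(
            1 for g in report.gpsms
            if truth[g.scan_id] == (g.peptide.sequence, str(g.glycan), g.glyco_type)
        )
        assert correct / len(ds.spectra) >= 0.95
        assert not any(g.is_decoy for g in report.gpsms)
    # every preclassify identification sits in the classifier-assigned space
    from glycotyper import extract_features, predict, remove_bottom_fraction

    for g in pre.gpsms:
        spec = next(s for s in ds.spectra if s.scan_id == g.scan_id)
        label, _ = predict(model, extract_features(remove_bottom_fraction(spec, 0.10)))
        assert g.glyco_type == label


def test_report_summary_and_frame(noiseless_dataset):
    ds = noiseless_dataset
    report = run_search(ds.spectra, ds.databases, SearchConfig(mode="conventional"))
    summary = report.summary()
    assert summary["assigned_spectra"] == len(report.gpsms)
    assert summary["unique_glycopeptides"] == len(report.unique_glycopeptides)
    frame = report.to_frame()
    assert len(frame) == len(report.gpsms)
    assert set(frame.columns) >= {"scan_id", "peptide", "glycan", "glyco_type", "score"}
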