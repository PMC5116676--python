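"""Monoisotopic mass constants shared across the package.

Amino-acid residue masses come from pyteomics; glycan residue and small-molecule
constants are the standard monoisotopic values used throughout glycoproteomics.
All masses in Da, all m/z in Th.
"""
from __future__ import annotations

from pyteomics import mass as _pmass

#: Mass of a proton (charge carrier for [M+nH]^n+ ions).
PROTON = 1.007276

#: Mass of an electron; subtracted when converting a cation formula mass to m/z.
ELECTRON = 0.000548579909

#: Monoisotopic mass of water (peptide termini).
WATER = 18.010565

#: Variable modification: oxidation (Met).
OXIDATION = 15.994915

#: Fixed modification: carbamidomethylation of Cys (iodoacetamide alkylation).
CARBAMIDOMETHYL = 57.021464

#: Monoisotopic residue masses of glycan building blocks (dehydrated, i.e. as
#: incorporated in a glycan chain).
HEXNAC = 203.079373
HEX = 162.052824
FUC = 146.057909
NEUAC = 291.095417

#: Standard amino-acid residue monoisotopic masses, one-letter codes.
RESIDUE_MASSES: dict[str, float] = dict(_pmass.std_aa_mass)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


def formula_cation_mz(formula: str) -> float:
    """m/z of a singly charged cation whose elemental formula (protons included)
    is given, i.e. the formula mass minus one electron."""
    return _pmass.calculate_mass(formula=formula) - ELECTRON
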