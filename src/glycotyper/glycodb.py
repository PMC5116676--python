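"""Peptide and glycan composition databases.

In-silico tryptic digestion (cleavage C-terminal to K/R unless followed by P),
variable Met oxidation, N-glycosylation sequon scanning (N-X-[S/T/C/V], X not
proline), glycan composition parsing with monoisotopic masses, and shuffle
decoy generation: the decoy pool is built by concatenating every target
sequence, shuffling the pooled residues with a seeded RNG, and re-cutting the
shuffled string into pieces whose lengths are exactly the multiset of target
lengths — so the decoy database conserves the target amino-acid composition
exactly while destroying all sequence structure.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from pyteomics import fasta as _fasta

from .masses import CARBAMIDOMETHYL, FUC, HEX, HEXNAC, NEUAC, OXIDATION, RESIDUE_MASSES, STANDARD_RESIDUES, WATER

logger = logging.getLogger(__name__)

__all__ = [
    "GlycanComposition",
    "PeptideEntry",
    "GlycoDatabases",
    "tryptic_digest",
    "peptide_monoisotopic_mass",
    "find_n_motifs",
    "glycan_mass",
    "parse_composition",
    "generate_decoy_peptides",
    "read_fasta",
    "read_glycan_db",
    "write_glycan_db",
    "read_peptide_list",
    "write_peptides_tsv",
    "digest_fasta",
    "build_databases",
]

_COMPOSITION_RE = re.compile(r"^N(\d+)H(\d+)F(\d+)S(\d+)$")
_MOTIF_RE = re.compile(r"N(?=[^P][STCV])")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """A glycan as counts of the four residue classes (no topology)."""

    n_hexnac: int = 0
    n_hex: int = 0
    n_fuc: int = 0
    n_neuac: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_hexnac, self.n_hex, self.n_fuc, self.n_neuac)
        if any(not isinstance(c, (int, np.integer)) or c < 0 for c in counts):
            raise ValueError("glycan residue counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("glycan composition must contain at least one residue")

    @property
    def mass(self) -> float:
        return (
            self.n_hexnac * HEXNAC + self.n_hex * HEX + self.n_fuc * FUC + self.n_neuac * NEUAC
        )

    @property
    def n_residues(self) -> int:
        return self.n_hexnac + self.n_hex + self.n_fuc + self.n_neuac

    def __str__(self) -> str:
        return f"N{self.n_hexnac}H{self.n_hex}F{self.n_fuc}S{self.n_neuac}"

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        m = _COMPOSITION_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed glycan composition string: {text!r}")
        return cls(*(int(g) for g in m.groups()))


def parse_composition(text: str) -> GlycanComposition:
    """Parse the canonical ``N#H#F#S#`` composition string."""
    return GlycanComposition.parse(text)


def glycan_mass(comp: GlycanComposition) -> float:
    """Monoisotopic mass of a glycan composition (Da)."""
    return comp.mass


@dataclass(frozen=True)
class PeptideEntry:
    """A (possibly modified) peptide from in-silico digestion.

    ``n_oxidations`` counts variable Met oxidations; Cys residues always carry
    the fixed carbamidomethyl group. ``start`` is the 0-based offset of the
    peptide in its parent protein (-1 if unknown, e.g. decoys).
    """

    sequence: str
    protein_id: str = ""
    missed_cleavages: int = 0
    n_oxidations: int = 0
    monoisotopic_mass: float = 0.0
    n_motif_positions: tuple[int, ...] = ()
    start: int = -1

    @property
    def has_n_motif(self) -> bool:
        return len(self.n_motif_positions) > 0

    @property
    def has_st(self) -> bool:
        return ("S" in self.sequence) or ("T" in self.sequence)


@dataclass
class GlycoDatabases:
    """Target and decoy peptide pools plus N- and O-glycan composition lists."""

    peptides: list[PeptideEntry]
    decoy_peptides: list[PeptideEntry]
    n_glycans: list[GlycanComposition]
    o_glycans: list[GlycanComposition]


def peptide_monoisotopic_mass(sequence: str, n_oxidations: int = 0) -> float:
    """Monoisotopic mass (Da) of a peptide with fixed carbamidomethyl-Cys and
    ``n_oxidations`` variable Met oxidations."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = WATER + OXIDATION * n_oxidations
    for aa in sequence:
        try:
            mass += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in peptide {sequence!r}") from None
        if aa == "C":
            mass += CARBAMIDOMETHYL
    return mass


def find_n_motifs(sequence: str) -> list[int]:
    """0-based positions of N in N-glycosylation sequons N-X-[S/T/C/V], X != P."""
    return [m.start() for m in _MOTIF_RE.finditer(sequence)]


def _cleavage_points(sequence: str) -> list[int]:
    """Boundaries of tryptic fragments: 0, every K/R not followed by P, end."""
    points = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            points.append(i + 1)
    points.append(len(sequence))
    return points


def tryptic_digest(
    protein_sequence: str,
    protein_id: str = "",
    max_missed: int = 2,
    max_ox: int = 2,
    min_len: int = 5,
    max_len: int = 70,
) -> list[PeptideEntry]:
    """In-silico tryptic digest with missed cleavages and Met-oxidation variants.

    Cleaves C-terminal to K/R except before P. Emits every peptide carrying
    0..max_missed internal missed cleavage sites within [min_len, max_len],
    each expanded into 0..min(max_ox, #Met) oxidation variants. Peptides
    containing non-standard residues are skipped with a warning.
    """
    seq = protein_sequence.strip().upper()
    points = _cleavage_points(seq)
    entries: list[PeptideEntry] = []
    for i in range(len(points) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(points))):
            pep = seq[points[i] : points[j]]
            if not (min_len <= len(pep) <= max_len):
                continue
            if not set(pep) <= STANDARD_RESIDUES:
                logger.warning(
                    "peptide %s from %s contains non-standard residues; skipped", pep, protein_id
                )
                continue
            missed = j - i - 1
            motifs = tuple(find_n_motifs(pep))
            for n_ox in range(0, min(max_ox, pep.count("M")) + 1):
                entries.append(
                    PeptideEntry(
                        sequence=pep,
                        protein_id=protein_id,
                        missed_cleavages=missed,
                        n_oxidations=n_ox,
                        monoisotopic_mass=peptide_monoisotopic_mass(pep, n_ox),
                        n_motif_positions=motifs,
                        start=points[i],
                    )
                )
    return entries


def generate_decoy_peptides(targets: Sequence[PeptideEntry], seed: int) -> list[PeptideEntry]:
    """Shuffle-decoy pool: concatenate target residues, shuffle, re-cut to the
    exact target length multiset. Decoys carry no motif annotation."""
    if not targets:
        raise ValueError("target peptide list is empty")
    pooled = np.array(list("".join(t.sequence for t in targets)))
    rng = np.random.default_rng(seed)
    rng.shuffle(pooled)
    shuffled = "".join(pooled)
    decoys: list[PeptideEntry] = []
    offset = 0
    for i, t in enumerate(targets):
        piece = shuffled[offset : offset + len(t.sequence)]
        offset += len(t.sequence)
        decoys.append(
            PeptideEntry(
                sequence=piece,
                protein_id="DECOY",
                missed_cleavages=0,
                n_oxidations=0,
                monoisotopic_mass=peptide_monoisotopic_mass(piece, 0),
                n_motif_positions=(),
                start=-1,
            )
        )
    return decoys


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> list[tuple[str, str]]:
    """(protein_id, sequence) pairs from FASTA. For UniProt-style headers
    (``sp|P12763|FETUA_BOVIN ...``) the accession is the second pipe field."""
    out = []
    with _fasta.read(path) as reader:
        for header, seq in reader:
            first = header.split()[0]
            fields = first.split("|")
            protein_id = fields[1] if len(fields) >= 2 and fields[1] else first
            out.append((protein_id, seq.upper()))
    return out


def digest_fasta(
    path: str,
    max_missed: int = 2,
    max_ox: int = 2,
    min_len: int = 5,
    max_len: int = 70,
) -> list[PeptideEntry]:
    """Digest every protein in a FASTA file; see :func:`tryptic_digest`."""
    entries: list[PeptideEntry] = []
    for protein_id, seq in read_fasta(path):
        entries.extend(tryptic_digest(seq, protein_id, max_missed, max_ox, min_len, max_len))
    return entries


def read_glycan_db(path: str) -> list[GlycanComposition]:
    """Glycan DB file: TSV with header ``N H F S`` (one row of counts per
    glycan) or one canonical ``N#H#F#S#`` string per line."""
    comps: list[GlycanComposition] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return comps
    header = lines[0].split()
    if [h.upper() for h in header] == ["N", "H", "F", "S"]:
        for ln in lines[1:]:
            n, h, f, s = (int(x) for x in ln.split())
            comps.append(GlycanComposition(n, h, f, s))
    else:
        for ln in lines:
            comps.append(GlycanComposition.parse(ln.split()[0]))
    return comps


def write_glycan_db(comps: Iterable[GlycanComposition], path: str) -> None:
    with open(path, "w") as fh:
        for c in comps:
            fh.write(f"{c}\n")


def write_peptides_tsv(entries: Iterable[PeptideEntry], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tprotein_id\tmissed_cleavages\tn_oxidations\tmonoisotopic_mass\tn_motif_positions\tstart\n")
        for e in entries:
            motifs = ",".join(str(p) for p in e.n_motif_positions)
            fh.write(
                f"{e.sequence}\t{e.protein_id}\t{e.missed_cleavages}\t{e.n_oxidations}\t"
                f"{e.monoisotopic_mass!r}\t{motifs}\t{e.start}\n"
            )


def read_peptide_list(path: str) -> list[PeptideEntry]:
    """Read a peptide list: either the full TSV written by
    :func:`write_peptides_tsv` or a plain text file with one
    ``PEPTIDE [protein_id]`` per line (masses and sequons recomputed)."""
    entries: list[PeptideEntry] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return entries
    if lines[0].split("\t")[0] == "sequence":
        for ln in lines[1:]:
            seq, prot, missed, n_ox, mass, motifs, start = ln.split("\t")
            entries.append(
                PeptideEntry(
                    sequence=seq,
                    protein_id=prot,
                    missed_cleavages=int(missed),
                    n_oxidations=int(n_ox),
                    monoisotopic_mass=float(mass),
                    n_motif_positions=tuple(int(p) for p in motifs.split(",") if p != ""),
                    start=int(start),
                )
            )
    else:
        for ln in lines:
            fields = ln.split()
            seq = fields[0].upper()
            prot = fields[1] if len(fields) > 1 else ""
            entries.append(
                PeptideEntry(
                    sequence=seq,
                    protein_id=prot,
                    monoisotopic_mass=peptide_monoisotopic_mass(seq),
                    n_motif_positions=tuple(find_n_motifs(seq)),
                )
            )
    return entries


def build_databases(
    peptides: Sequence[PeptideEntry],
    n_glycans: Sequence[GlycanComposition],
    o_glycans: Sequence[GlycanComposition],
    decoy_seed: int = 0,
) -> GlycoDatabases:
    """Assemble target+decoy peptide pools and glycan lists into one object."""
    return GlycoDatabases(
        peptides=list(peptides),
        decoy_peptides=generate_decoy_peptides(peptides, decoy_seed),
        n_glycans=list(n_glycans),
        o_glycans=list(o_glycans),
    )
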