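"""Peptide sequences, average masses, m/z and in-silico tryptic digestion.

Peptides are plain sequences over the 20 standard one-letter codes.  Masses
are computed on the *average* (not monoisotopic) scale, which is the scale
an ion-trap operator reads off a low-resolution MS1 peak; the residue-mass
table is shipped as an editable plain-text file so a different scale can be
substituted.  Digestion follows the trypsin rule "cleave C-terminal of K or
R" with no proline exception (see the methods note for why the bundled
calibration data force that choice).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

__all__ = [
    "AMINO_ACIDS",
    "Peptide",
    "AminoAcidMassTable",
    "DigestResult",
    "parse_peptide",
    "average_mass",
    "mz",
    "tryptic_digest",
    "count_missed_cleavages",
    "read_fasta",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CLEAVAGE_RESIDUES = frozenset("KR")


class PeptideError(ValueError):
    """Raised for sequences containing non-standard residues."""


@dataclass(frozen=True)
class Peptide:
    """A validated peptide sequence (upper-case, standard residues only)."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("peptide sequence is empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ACIDS:
                raise PeptideError(
                    f"invalid residue {ch!r} at position {pos} "
                    f"in {self.sequence!r}: not a standard amino-acid code"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def parse_peptide(text: str) -> Peptide:
    """Validate ``text`` as a peptide sequence.

    Input is case-insensitive and surrounding whitespace is ignored; the
    returned :class:`Peptide` stores the upper-case sequence.  The first
    offending character is reported on failure.
    """
    return Peptide(text.strip().upper())


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Per-residue average masses plus the water and proton masses.

    A peptide's neutral average mass is the sum of its residue masses plus
    ``water_mass``; ``proton_mass`` converts neutral mass to m/z.
    """

    residue_mass: dict[str, float]
    water_mass: float
    proton_mass: float

    def __post_init__(self) -> None:
        missing = AMINO_ACIDS - set(self.residue_mass)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")
        bad = [a for a, m in self.residue_mass.items() if m <= 0]
        if bad or self.water_mass <= 0 or self.proton_mass <= 0:
            raise ValueError("all masses must be strictly positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AminoAcidMassTable":
        """Read a two-column (key, mass) table; '#' lines are comments."""
        residues: dict[str, float] = {}
        water = proton = None
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, value = re.split(r"[\t ,]+", line, maxsplit=1)
            if key == "water":
                water = float(value)
            elif key == "proton":
                proton = float(value)
            else:
                residues[key.upper()] = float(value)
        if water is None or proton is None:
            raise ValueError(f"{path}: 'water' and 'proton' entries required")
        return cls(residue_mass=residues, water_mass=water, proton_mass=proton)

    @classmethod
    def default(cls) -> "AminoAcidMassTable":
        """The bundled standard average-mass table."""
        with resources.as_file(
            resources.files("peprt.data") / "average_masses.tsv"
        ) as path:
            return cls.from_file(path)


def average_mass(p: Peptide, masses: AminoAcidMassTable | None = None) -> float:
    """Neutral average mass of ``p`` in Da."""
    masses = masses or AminoAcidMassTable.default()
    return sum(masses.residue_mass[a] for a in p) + masses.water_mass


def mz(p: Peptide, charge: int, masses: AminoAcidMassTable | None = None) -> float:
    """m/z (Th) of ``p`` at the given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    masses = masses or AminoAcidMassTable.default()
    return (average_mass(p, masses) + charge * masses.proton_mass) / charge


def count_missed_cleavages(p: Peptide) -> int:
    """Number of internal tryptic sites (K/R before the last residue)."""
    return sum(1 for ch in p.sequence[:-1] if ch in _CLEAVAGE_RESIDUES)


@dataclass(frozen=True)
class DigestResult:
    """Fragments of a tryptic digest with per-fragment missed-cleavage counts.

    Fragments are ordered by start position, then end position; the subset
    with zero missed cleavages partitions the parent sequence in order.
    """

    fragments: tuple[Peptide, ...]
    missed_cleavages_per_fragment: tuple[int, ...] = field(default=())

    def fully_cleaved(self) -> tuple[Peptide, ...]:
        return tuple(
            f
            for f, m in zip(self.fragments, self.missed_cleavages_per_fragment)
            if m == 0
        )


def tryptic_digest(protein: Peptide, max_missed: int = 0) -> DigestResult:
    """In-silico trypsin digest of ``protein``.

    Cleaves after every K and R (including K/R followed by proline) and
    returns every fragment spanning 0..``max_missed`` internal sites.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    # cut points after each K/R, except a C-terminal one (no cut needed)
    cuts = [0] + [i + 1 for i, ch in enumerate(seq[:-1]) if ch in _CLEAVAGE_RESIDUES]
    cuts.append(len(seq))
    pieces = [seq[a:b] for a, b in zip(cuts, cuts[1:])]
    fragments: list[Peptide] = []
    missed: list[int] = []
    for start in range(len(pieces)):
        for nm in range(min(max_missed, len(pieces) - start - 1) + 1):
            fragments.append(Peptide("".join(pieces[start : start + nm + 1])))
            missed.append(nm)
    return DigestResult(
        fragments=tuple(fragments), missed_cleavages_per_fragment=tuple(missed)
    )


def read_fasta(path: str | Path) -> list[tuple[str, Peptide]]:
    """Read protein sequences from FASTA as (description, Peptide) pairs."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, parse_peptide(str(rec.seq))))
    return records
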