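"""Shared domain types.

Coordinates are 1-based, inclusive residue indices on the protein sequence as
supplied by the user (matching the D208E-style position notation used for
mature proteins throughout the mistranslation literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

MISMATCH_CLASSES = ("1st", "2nd", "3rd", "non-cognate")


@dataclass(frozen=True)
class Substitution:
    """One amino-acid substitution at a defined protein position.

    ``parent_codon`` is the codon actually decoded at that position (RNA
    alphabet); ``mismatch_class`` records which codon position a single
    nucleotide misreading must occur at to produce ``to_aa`` (with the
    3rd > 1st > 2nd priority when several positions can), or
    ``"non-cognate"`` when no single mismatch can.
    """

    protein_id: str
    position: int  # 1-based residue index
    from_aa: str
    to_aa: str
    parent_codon: Optional[str] = None
    mismatch_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mismatch_class is not None and self.mismatch_class not in MISMATCH_CLASSES:
            raise ValueError(f"unknown mismatch class {self.mismatch_class!r}")

    @property
    def label(self) -> str:
        """Conventional notation, e.g. ``D208E``."""
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein and, optionally, its coding sequence.

    If a CDS is given it must translate exactly to the amino-acid sequence
    (no stop codon included).
    """

    id: str
    sequence: str
    cds: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        if self.cds is not None:
            from .misreading import translate_cds  # local import, avoids cycle

            if len(self.cds) != 3 * len(self.sequence):
                raise ValueError(
                    f"CDS length {len(self.cds)} does not match protein "
                    f"length {len(self.sequence)}"
                )
            aa = translate_cds(self.cds)
            if aa != self.sequence:
                raise ValueError("CDS does not translate to the protein sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def codon_at(self, position: int) -> Optional[str]:
        """Codon decoded at 1-based residue ``position`` (None without CDS)."""
        if self.cds is None:
            return None
        return self.cds[3 * (position - 1) : 3 * position]


@dataclass(frozen=True)
class PeptideSpan:
    """A (possibly mutated) tryptic peptide located on its parent protein."""

    protein_id: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    sequence: str
    substitutions: tuple[Substitution, ...] = ()
    cleavage_altered: bool = False
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ErrorPattern:
    """An ordered set of substitutions made during one ribosome traversal."""

    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        pos = [s.position for s in self.substitutions]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("substitution positions must be strictly increasing")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    @property
    def d_list(self) -> tuple[int, ...]:
        """Counts of correct intervening residues between consecutive errors.

        Adjacent substitutions have d = 0.
        """
        p = self.positions
        return tuple(p[i + 1] - p[i] - 1 for i in range(len(p) - 1))

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "correct"
        return "+".join(s.label for s in self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)


#: Columns of the long-format intensity table.
INTENSITY_COLUMNS = [
    "species",
    "protein_id",
    "peptide_start",
    "peptide_end",
    "n_errors",
    "parent_species",
    "aga",
    "concentration_um",
    "time_min",
    "fraction",
    "replicate",
    "intensity",
]


@dataclass
class IntensityTable:
    """Peptide-species x sample table of MS-like intensities (long format).

    One row per (species, sample). ``species`` is the pattern label
    ("correct@start-end" for the correct peptide, "D208E+F211L" etc. for
    missense species); ``parent_species`` points each missense species at its
    correct parental peptide. Missing intensities are NaN.
    """

    frame: pd.DataFrame
    detection_floor: float = 0.0
    patterns: dict[str, ErrorPattern] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in INTENSITY_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"intensity table missing columns: {missing}")

    def species(self) -> list[str]:
        return list(self.frame["species"].unique())

    def subset(self, **conditions) -> pd.DataFrame:
        """Rows matching the given column == value conditions."""
        df = self.frame
        for key, value in conditions.items():
            df = df[df[key] == value]
        return df

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# agaclust intensity table v1\n")
            fh.write(f"# detection_floor={self.detection_floor}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "IntensityTable":
        floor = 0.0
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if "detection_floor=" in line:
                    floor = float(line.split("detection_floor=")[1])
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh, sep="\t")
        return cls(frame=frame, detection_floor=floor)
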