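"""Genetic-code level model of near-cognate misreading.

Aminoglycosides promote near-cognate decoding errors: the incorporated amino
acid differs from the cognate one by a single codon-anticodon mismatch,
preferentially at the third codon position. This module enumerates the
single-mismatch neighbourhood of a codon, classifies observed substitutions
by mismatch position (3rd > 1st > 2nd priority when several positions can
produce the same amino acid), and provides deterministic reverse translation
for synthetic coding sequences.

Codons use the RNA alphabet (ACGU); DNA input (T) is accepted and
normalised. The code table is the standard genetic code (NCBI table 1).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import NamedTuple, Optional

from Bio.Data import CodonTable

_BASES = "ACGU"

_TABLE = CodonTable.unambiguous_rna_by_id[1]

#: codon -> amino acid for all 64 codons; stop codons map to "*".
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: I and L are isobaric; standard MS workflows cannot distinguish them.
MASS_DEGENERATE = {"I": "J", "L": "J"}


def normalize_codon(codon: str) -> str:
    """Uppercase, DNA->RNA; raises on anything but a 3-letter ACGU codon."""
    c = codon.upper().replace("T", "U")
    if len(c) != 3 or any(b not in _BASES for b in c):
        raise ValueError(f"malformed codon {codon!r}")
    return c


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) or '*' for the given codon."""
    return GENETIC_CODE[normalize_codon(codon)]


def translate_cds(cds: str) -> str:
    cds = cds.upper().replace("T", "U")
    if len(cds) % 3:
        raise ValueError("CDS length is not a multiple of 3")
    out = []
    for i in range(0, len(cds), 3):
        aa = translate_codon(cds[i : i + 3])
        if aa == "*":
            raise ValueError(f"internal stop codon at nt {i + 1}")
        out.append(aa)
    return "".join(out)


class NearCognateVariant(NamedTuple):
    mismatch_position: int  # 1, 2 or 3 (codon position of the mismatch)
    alternative_base: str
    codon: str
    amino_acid: str  # '*' for stop-codon outcomes
    is_stop: bool


def enumerate_near_cognate(parent_codon: str) -> list[NearCognateVariant]:
    """All 9 single-nucleotide variants of a sense codon with translations.

    Stop-codon outcomes are flagged (``is_stop``); they are enumerated for
    completeness but never treated as amino-acid substitutions (misreading
    of a sense codon into a stop signal does not yield a full-length
    protein species).
    """
    codon = normalize_codon(parent_codon)
    if codon in STOP_CODONS:
        raise ValueError(f"{parent_codon!r} is a stop codon, not a sense codon")
    variants = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutated = codon[:pos] + base + codon[pos + 1 :]
            aa = GENETIC_CODE[mutated]
            variants.append(
                NearCognateVariant(pos + 1, base, mutated, aa, mutated in STOP_CODONS)
            )
    return variants


#: classification priority: third-position mismatches dominate under
#: aminoglycoside treatment, then first, then second.
_PRIORITY = (3, 1, 2)


@lru_cache(maxsize=None)
def classify_substitution(parent_codon: str, to_aa: str) -> str:
    """Mismatch-position class of a substitution, or ``"non-cognate"``.

    If ``to_aa`` is reachable from the parent codon by single mismatches at
    several codon positions, the class is resolved by the 3rd > 1st > 2nd
    priority. Substitutions requiring two or more nucleotide changes are
    classified ``"non-cognate"`` (these are excluded from error statistics
    by default).
    """
    codon = normalize_codon(parent_codon)
    to_aa = to_aa.upper()
    if to_aa == GENETIC_CODE[codon]:
        raise ValueError(f"{to_aa} is the cognate amino acid of {parent_codon}")
    if to_aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {to_aa!r}")
    reachable = {
        v.mismatch_position
        for v in enumerate_near_cognate(codon)
        if v.amino_acid == to_aa
    }
    for pos in _PRIORITY:
        if pos in reachable:
            return f"{pos}{'st' if pos == 1 else 'nd' if pos == 2 else 'rd'}"
    return "non-cognate"


@lru_cache(maxsize=1)
def default_codon_preferences() -> dict[str, str]:
    """Preferred codon per amino acid (shipped JSON config)."""
    text = resources.files("agaclust.data").joinpath("codon_preferences.json").read_text()
    return json.loads(text)["preferred_codons"]


def reverse_translate(
    protein_sequence: str, codon_preferences: Optional[dict[str, str]] = None
) -> str:
    """Deterministic CDS from a protein sequence.

    Uses a single preferred codon per amino acid; translation round-trips to
    the input. Raises on non-standard residues.
    """
    prefs = codon_preferences or default_codon_preferences()
    out = []
    for i, aa in enumerate(protein_sequence.upper()):
        if aa not in prefs:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
        codon = normalize_codon(prefs[aa])
        if GENETIC_CODE[codon] != aa:
            raise ValueError(f"preference table maps {aa} to non-synonymous codon {codon}")
        out.append(codon)
    return "".join(out)


def mass_degenerate(sequence_or_label: str) -> str:
    """Collapse Ile and Leu into the joint symbol J for MS-facing reports.

    Standard proteomics workflows cannot distinguish the isobaric residues
    I and L; internal representations keep them distinct, and this optional
    reporting mode merges them (e.g. ``"F211L" -> "F211J"``).
    """
    return "".join(MASS_DEGENERATE.get(ch, ch) for ch in sequence_or_label)


def substitution_from_codon(
    protein_id: str, position: int, parent_codon: str, to_aa: str
):
    """Build a classified :class:`~agaclust.types.Substitution`."""
    from .types import Substitution

    codon = normalize_codon(parent_codon)
    return Substitution(
        protein_id=protein_id,
        position=position,
        from_aa=GENETIC_CODE[codon],
        to_aa=to_aa.upper(),
        parent_codon=codon,
        mismatch_class=classify_substitution(codon, to_aa),
    )
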