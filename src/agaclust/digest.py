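"""In-silico tryptic digestion and substitution-aware peptide mapping.

Trypsin cleaves C-terminal to K or R unless the next residue is P. Amino
acid substitutions that create or destroy K/R (or a following P) change the
local cleavage pattern; the affected missense peptides are flagged, because
their intensities are not directly comparable to those of the wild-type
parental peptide.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from pyteomics import parser as _pt_parser

from .types import PeptideSpan, ProteinRecord, Substitution

#: cleave after K/R, not before P
TRYPSIN_RULE = r"[KR](?!P)"


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 0,
    protein_id: str = "",
    substitutions: Sequence[Substitution] = (),
) -> list[PeptideSpan]:
    """Tryptic peptides of ``sequence`` as located spans.

    With ``missed_cleavages = k`` every union of up to k+1 adjacent fully
    cleaved peptides is also emitted. Spans are ordered by start, then
    length; the fully cleaved (0-missed) peptides concatenate to the input.
    ``substitutions`` (positions on the same coordinate system) are attached
    to the spans that contain them.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seen = set()
    spans = []
    for start0, pep in _pt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages
    ):
        key = (start0, len(pep))
        if key in seen:
            continue
        seen.add(key)
        start, end = start0 + 1, start0 + len(pep)
        subs = tuple(s for s in substitutions if start <= s.position <= end)
        n_cleaved = len(
            [
                (s0, p)
                for s0, p in _pt_parser.icleave(pep, TRYPSIN_RULE, missed_cleavages=0)
            ]
        )
        spans.append(
            PeptideSpan(
                protein_id=protein_id,
                start=start,
                end=end,
                sequence=pep,
                substitutions=subs,
                missed_cleavages=n_cleaved - 1,
            )
        )
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


def apply_substitutions(sequence: str, substitutions: Iterable[Substitution]) -> str:
    """Mutated sequence; validates the wild-type residue at each position."""
    seq = list(sequence)
    for sub in substitutions:
        if sub.position > len(seq):
            raise ValueError(f"{sub.label}: position beyond sequence end")
        if seq[sub.position - 1] != sub.from_aa:
            raise ValueError(
                f"{sub.label}: sequence has {seq[sub.position - 1]} at "
                f"position {sub.position}, not {sub.from_aa}"
            )
        seq[sub.position - 1] = sub.to_aa
    return "".join(seq)


def peptide_for_substitutions(
    protein: ProteinRecord, substitutions: Sequence[Substitution]
) -> list[PeptideSpan]:
    """Tryptic peptide(s) of the mutated protein carrying the substitutions.

    The *mutated* sequence is digested; returned are the fully cleaved
    peptides containing at least one substituted position (one span when all
    substitutions fall in the same peptide, several otherwise — such
    multi-span sets are excluded from intensity-ratio estimators upstream).
    ``cleavage_altered`` is set on a span whose boundaries do not occur in
    the wild-type digest, i.e. the substitutions created or removed a
    cleavage site locally.
    """
    if not substitutions:
        raise ValueError("no substitutions given")
    ids = {s.protein_id for s in substitutions}
    if len(ids) > 1 or (protein.id not in ids):
        raise ValueError("all substitutions must be on the supplied protein")
    mutated = apply_substitutions(protein.sequence, substitutions)
    wt_bounds = {
        (p.start, p.end) for p in tryptic_digest(protein.sequence, protein_id=protein.id)
    }
    out = []
    for span in tryptic_digest(mutated, protein_id=protein.id, substitutions=substitutions):
        if not span.substitutions:
            continue
        altered = (span.start, span.end) not in wt_bounds
        out.append(
            PeptideSpan(
                protein_id=span.protein_id,
                start=span.start,
                end=span.end,
                sequence=span.sequence,
                substitutions=span.substitutions,
                cleavage_altered=altered,
                missed_cleavages=span.missed_cleavages,
            )
        )
    return out


def same_peptide(protein: ProteinRecord, positions: Sequence[int]) -> bool:
    """Do all positions fall into one fully cleaved wild-type peptide?"""
    for span in tryptic_digest(protein.sequence, protein_id=protein.id):
        if all(span.contains(p) for p in positions):
            return True
    return False


def containing_peptide(protein: ProteinRecord, position: int) -> PeptideSpan:
    """Fully cleaved wild-type peptide containing the given position."""
    for span in tryptic_digest(protein.sequence, protein_id=protein.id):
        if span.contains(position):
            return span
    raise ValueError(f"position {position} outside protein {protein.id}")
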