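"""Prediction of candidate error clusters from single-error frequencies.

Targeted MS cannot survey every conceivable multi-substitution peptide, so
candidate clusters are predicted from the measured single-substitution
frequencies: substitutions that co-occur within one tryptic peptide, closely
spaced, are ranked by the frequency expected if the drug stays bound between
the errors (first-error frequency times a conditional next-error prior per
following error), alongside the much smaller expectation under independent
errors (plain product of singles).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .digest import tryptic_digest
from .types import ErrorPattern, ProteinRecord, Substitution


@dataclass(frozen=True)
class ClusterCandidate:
    pattern: ErrorPattern
    stochastic_expectation: float  # product of single E_f values
    aga_expectation: float  # E_f(first) * efnext_prior^(n_errors - 1)

    @property
    def label(self) -> str:
        return self.pattern.label


def predict_cluster_candidates(
    single_ef_table: Mapping[Substitution, float],
    protein: ProteinRecord,
    efnext_prior: float,
    max_intervening: int,
    max_cluster_size: int = 4,
) -> list[ClusterCandidate]:
    """Ranked candidate clusters (descending drug-bound expectation).

    Only combinations whose substitutions fall in the same fully cleaved
    tryptic peptide, with at most ``max_intervening`` correct residues
    between consecutive errors and one substitution per position, are
    considered. Empty input yields an empty list.
    """
    if not (0.0 <= efnext_prior <= 1.0):
        raise ValueError("efnext_prior must be a probability")
    subs = [s for s in single_ef_table if s.protein_id == protein.id]
    if not subs:
        return []
    by_peptide: dict[tuple[int, int], list[Substitution]] = {}
    for span in tryptic_digest(protein.sequence, protein_id=protein.id):
        members = [s for s in subs if span.contains(s.position)]
        if len(members) >= 2:
            by_peptide[(span.start, span.end)] = sorted(
                members, key=lambda s: s.position
            )
    out: list[ClusterCandidate] = []
    for members in by_peptide.values():
        for k in range(2, min(max_cluster_size, len(members)) + 1):
            for combo in itertools.combinations(members, k):
                positions = [s.position for s in combo]
                if len(set(positions)) != k:
                    continue  # two alternative substitutions at one position
                gaps = [
                    positions[i + 1] - positions[i] - 1 for i in range(k - 1)
                ]
                if any(g > max_intervening for g in gaps):
                    continue
                stochastic = 1.0
                for s in combo:
                    stochastic *= single_ef_table[s]
                aga = single_ef_table[combo[0]] * efnext_prior ** (k - 1)
                out.append(
                    ClusterCandidate(
                        pattern=ErrorPattern(substitutions=tuple(combo)),
                        stochastic_expectation=stochastic,
                        aga_expectation=aga,
                    )
                )
    out.sort(key=lambda c: c.aga_expectation, reverse=True)
    return out
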