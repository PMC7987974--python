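"""Generative two-state model of ribosome elongation under an aminoglycoside.

One ribosome traverses the coding sequence codon by codon. Before decoding
each codon a free drug molecule may bind the ribosome (probability ``beta``
per codon, rebinding after drop-off allowed). While the drug is bound, the
codon is misread with probability ``m * w`` (site- and outcome-specific
weight ``w``); without the drug, a small background error probability
``epsilon0`` applies. At each translocation a bound drug is retained with
probability ``q``. Retention over the d + 1 translocations separating two
decoding events is what couples consecutive errors into clusters: the
conditional next-error frequency decays as ``m * w * q**(d + 1)``.

Pattern probabilities are computed exactly by a forward recursion over the
bound/unbound state (a plain two-state hidden Markov chain); synthetic MS
intensity tables are emitted by drawing Poisson counts for each peptide
species at ``N`` effective traversals and applying log-normal detection
noise. An explicit per-ribosome Monte Carlo mode exists for cross-checks.

Background errors are only modelled at codons that carry designated
substitution weights; the enumerable outcome space at those sites is closed
(probabilities sum to one), and codons outside the designated sites never
err. The error-prone *ram* regime (drug-independent misreading) is obtained
with ``beta = 0`` and a raised ``ram_rate``, which makes errors at the
designated sites independent of each other.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .digest import containing_peptide
from .misreading import reverse_translate, substitution_from_codon
from .presets import AGAPreset
from .types import (
    INTENSITY_COLUMNS,
    ErrorPattern,
    IntensityTable,
    PeptideSpan,
    ProteinRecord,
    Substitution,
)

#: per-codon binding probability per µM of nominal drug concentration
BETA_PER_UM = 5e-5

#: default titration (µM), spanning sub-lethal to maximum-misreading doses
DEFAULT_CONCENTRATIONS = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class AGAParams:
    """Generative parameters of one drug at one nominal concentration.

    ``weights`` maps (1-based position, substituted amino acid) to the
    relative misreading weight of that outcome; the effective bound-state
    misreading probability of the outcome is ``m * w``.
    """

    name: str
    beta: float
    q: float
    m: float = 1.0
    weights: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, value in (("beta", self.beta), ("q", self.q), ("m", self.m)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must be in [0, 1], got {value}")
        totals: dict[int, float] = {}
        for (pos, _aa), w in self.weights.items():
            if w < 0:
                raise ValueError("weights must be non-negative")
            totals[pos] = totals.get(pos, 0.0) + w
        for pos, total in totals.items():
            if self.m * total > 1.0 + 1e-12:
                raise ValueError(
                    f"effective misreading probability m*w = {self.m * total:.3g} "
                    f"> 1 at position {pos}"
                )

    def site_weights(self) -> dict[int, dict[str, float]]:
        out: dict[int, dict[str, float]] = {}
        for (pos, aa), w in self.weights.items():
            out.setdefault(pos, {})[aa] = w
        return out


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment."""

    n_ribosomes: float = 1e8  # effective traversals N per condition
    seed: Optional[int] = None
    epsilon0: float = 1e-7  # background per-codon error probability
    ram_rate: float = 0.0  # extra drug-independent error probability (ram mode)
    noise_cv: float = 0.05  # log-normal intensity CV per measurement (targeted-MS grade)
    detection_floor: float = 1e3  # intensities below this are missing
    global_scale: float = 1e3  # intensity units per molecule count
    n_replicates: int = 3  # technical replicates per condition

    def __post_init__(self) -> None:
        if self.n_ribosomes <= 0:
            raise ValueError("n_ribosomes must be positive")
        for label, value in (("epsilon0", self.epsilon0), ("ram_rate", self.ram_rate)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{label} must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def unbound_error_rate(self) -> float:
        return min(1.0, self.epsilon0 + self.ram_rate)

    def rng(self, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
        if rng is not None:
            return rng
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# pattern probabilities
# ---------------------------------------------------------------------------


def _emissions(
    site_w: dict[int, dict[str, float]],
    prescribed: dict[int, Optional[str]],
    m: float,
    epsilon0: float,
    length: int,
) -> list[tuple[float, float]]:
    """(unbound, bound) emission factors per codon for one pattern.

    ``prescribed[pos]`` is the required substitution at ``pos`` (None for
    "decoded correctly"); positions absent from ``prescribed`` are
    marginalised (factor one in both states).
    """
    out = []
    for pos in range(1, length + 1):
        if pos not in prescribed:
            out.append((1.0, 1.0))
            continue
        weights = site_w.get(pos, {})
        total = sum(weights.values())
        eps = epsilon0 if total > 0 else 0.0
        want = prescribed[pos]
        if want is None:
            out.append((1.0 - eps, 1.0 - m * total))
        else:
            if want not in weights:
                raise ValueError(
                    f"pattern prescribes {want} at position {pos}, which has "
                    "no misreading weight"
                )
            frac = weights[want] / total
            out.append((eps * frac, m * weights[want]))
    return out


def _forward(
    emissions: Sequence[tuple[float, float]], beta: float, q: float
) -> float:
    """Forward recursion over the bound/unbound chain; exact probability."""
    a_u, a_b = 1.0, 0.0
    for e_u, e_b in emissions:
        b_in = a_b + a_u * beta
        u_in = a_u * (1.0 - beta)
        fb = b_in * e_b
        a_b = fb * q
        a_u = u_in * e_u + fb * (1.0 - q)
    return a_u + a_b


def pattern_probability(
    pattern: ErrorPattern,
    protein: ProteinRecord,
    params: AGAParams,
    epsilon0: float = 0.0,
    scope: Optional[Iterable[int]] = None,
) -> float:
    """Exact probability that one traversal emits exactly this pattern.

    ``scope`` is the set of positions whose outcome the pattern constrains
    (default: every position carrying a misreading weight). Scope positions
    not in the pattern must be decoded correctly; positions outside the
    scope are marginalised over, so restricting the scope to one tryptic
    peptide yields the marginal species probability that an MS measurement
    of that peptide sees.
    """
    site_w = params.site_weights()
    scope_set = set(scope) if scope is not None else set(site_w)
    prescribed: dict[int, Optional[str]] = {pos: None for pos in scope_set}
    for sub in pattern.substitutions:
        if sub.position < 1 or sub.position > len(protein):
            raise ValueError(f"{sub.label}: position outside protein")
        if sub.position not in scope_set:
            raise ValueError(f"{sub.label}: position outside pattern scope")
        prescribed[sub.position] = sub.to_aa
    emissions = _emissions(site_w, prescribed, params.m, epsilon0, len(protein))
    return _forward(emissions, params.beta, params.q)


def pattern_space(
    protein: ProteinRecord, params: AGAParams, scope: Optional[Iterable[int]] = None
) -> list[ErrorPattern]:
    """Every pattern over the scope positions (correct or any weighted outcome).

    Exponential in the number of sites; intended for small designs and for
    completeness checks (the probabilities of all returned patterns sum to
    one for any parameter set).
    """
    site_w = params.site_weights()
    positions = sorted(set(scope) if scope is not None else set(site_w))
    per_site = []
    for pos in positions:
        options: list[Optional[str]] = [None] + sorted(site_w.get(pos, {}))
        per_site.append(options)
    patterns = []
    for combo in itertools.product(*per_site):
        subs = tuple(
            _site_substitution(protein, pos, aa)
            for pos, aa in zip(positions, combo)
            if aa is not None
        )
        patterns.append(ErrorPattern(substitutions=subs))
    return patterns


def _site_substitution(protein: ProteinRecord, position: int, to_aa: str) -> Substitution:
    codon = protein.codon_at(position)
    if codon is not None:
        return substitution_from_codon(protein.id, position, codon, to_aa)
    return Substitution(
        protein_id=protein.id,
        position=position,
        from_aa=protein.sequence[position - 1],
        to_aa=to_aa,
    )


# ---------------------------------------------------------------------------
# species and counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesDef:
    """One peptide species to quantify: a pattern within a peptide scope."""

    pattern: ErrorPattern
    peptide: PeptideSpan
    scope: tuple[int, ...]

    @property
    def label(self) -> str:
        if not self.pattern.substitutions:
            return f"correct@{self.peptide.start}-{self.peptide.end}"
        return self.pattern.label

    @property
    def parent_label(self) -> Optional[str]:
        if not self.pattern.substitutions:
            return None
        return f"correct@{self.peptide.start}-{self.peptide.end}"


def cluster_species(
    protein: ProteinRecord,
    cluster: ErrorPattern,
    include_subclusters: bool = True,
) -> list[SpeciesDef]:
    """Species set for one cluster: correct parent, singles, (sub)clusters.

    All cluster positions must fall into one fully cleaved tryptic peptide.
    For clusters of three or more errors the N-terminal-anchored
    sub-clusters are included (they are the denominators of the stepwise
    next-error frequencies).
    """
    positions = cluster.positions
    peptide = containing_peptide(protein, positions[0])
    if not all(peptide.contains(p) for p in positions):
        raise ValueError(
            f"cluster {cluster.label} spans several tryptic peptides; "
            "not a quantifiable single-peptide species set"
        )
    scope = positions
    species = [SpeciesDef(ErrorPattern(()), peptide, scope)]
    for sub in cluster.substitutions:
        species.append(SpeciesDef(ErrorPattern((sub,)), peptide, scope))
    if include_subclusters and len(cluster) > 2:
        for k in range(2, len(cluster)):
            species.append(
                SpeciesDef(ErrorPattern(cluster.substitutions[:k]), peptide, scope)
            )
    species.append(SpeciesDef(cluster, peptide, scope))
    return species


def sample_counts(
    protein: ProteinRecord,
    params: AGAParams,
    config: SimConfig,
    species: Sequence[SpeciesDef],
    rng: Optional[np.random.Generator] = None,
    mode: str = "poisson",
) -> dict[str, int]:
    """Molecule counts per species from N effective traversals.

    ``mode="poisson"`` (default) draws each species count from a Poisson
    law with mean ``N * P(species)`` — fast and accurate for rare species.
    ``mode="explicit"`` runs a per-ribosome Monte Carlo of the same chain
    and tallies species; it is exact but O(N * L) and intended for
    cross-validation at small N.
    """
    rng = config.rng(rng)
    n = int(config.n_ribosomes)
    if mode == "poisson":
        counts = {}
        for sp in species:
            p = pattern_probability(
                sp.pattern, protein, params, config.unbound_error_rate, scope=sp.scope
            )
            counts[sp.label] = int(rng.poisson(n * p)) if p > 0 else 0
        return counts
    if mode == "explicit":
        return _explicit_counts(protein, params, config, species, n, rng)
    raise ValueError(f"unknown mode {mode!r}")


def _explicit_counts(
    protein: ProteinRecord,
    params: AGAParams,
    config: SimConfig,
    species: Sequence[SpeciesDef],
    n: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    site_w = params.site_weights()
    positions = sorted(site_w)
    aa_order = {pos: sorted(site_w[pos]) for pos in positions}
    eps = config.unbound_error_rate
    bound = np.zeros(n, dtype=bool)
    outcomes: dict[int, np.ndarray] = {}
    for pos in range(1, len(protein) + 1):
        if params.beta > 0:
            bind = (~bound) & (rng.random(n) < params.beta)
            bound |= bind
        if pos in site_w:
            weights = np.array([site_w[pos][aa] for aa in aa_order[pos]])
            total = weights.sum()
            p_err = np.where(bound, params.m * total, eps if total > 0 else 0.0)
            err = rng.random(n) < p_err
            out = np.zeros(n, dtype=np.int64)  # 0 = correct
            n_err = int(err.sum())
            if n_err and total > 0:
                out[err] = rng.choice(
                    np.arange(1, len(weights) + 1), size=n_err, p=weights / total
                )
            outcomes[pos] = out
        if params.q < 1.0:
            bound &= rng.random(n) < params.q
    counts = {}
    for sp in species:
        want = {pos: 0 for pos in sp.scope}
        for sub in sp.pattern.substitutions:
            want[sub.position] = aa_order[sub.position].index(sub.to_aa) + 1
        match = np.ones(n, dtype=bool)
        for pos, idx in want.items():
            match &= outcomes[pos] == idx
        counts[sp.label] = int(match.sum())
    return counts


# ---------------------------------------------------------------------------
# intensity emission
# ---------------------------------------------------------------------------


def emit_intensity_table(
    counts: Mapping[str, int],
    species: Sequence[SpeciesDef],
    config: SimConfig,
    sample_meta: Mapping[str, object],
    rng: Optional[np.random.Generator] = None,
    ionization: Optional[Mapping[str, float]] = None,
) -> IntensityTable:
    """MS-like intensities for one condition (all replicates).

    intensity = count x global scale x ionization x log-normal noise
    (unit-mean, CV from the config). All species share ionization factor 1
    by default — the label-free assumption of identical ionization and
    fragmentation — with an optional per-species multiplier to stress-test
    the estimators. Values below the detection floor become missing.
    """
    rng = config.rng(rng)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    rows = []
    for rep in range(1, config.n_replicates + 1):
        for sp in species:
            count = counts.get(sp.label, 0)
            ion = ionization.get(sp.label, 1.0) if ionization else 1.0
            base = count * config.global_scale * ion
            if sigma > 0 and base > 0:
                base *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            value = base if base >= config.detection_floor else np.nan
            rows.append(
                {
                    "species": sp.label,
                    "protein_id": sp.peptide.protein_id,
                    "peptide_start": sp.peptide.start,
                    "peptide_end": sp.peptide.end,
                    "n_errors": len(sp.pattern),
                    "parent_species": sp.parent_label or "",
                    "aga": sample_meta.get("aga", ""),
                    "concentration_um": sample_meta.get("concentration_um", np.nan),
                    "time_min": sample_meta.get("time_min", 120.0),
                    "fraction": sample_meta.get("fraction", "total"),
                    "replicate": rep,
                    "intensity": value,
                }
            )
    frame = pd.DataFrame(rows, columns=INTENSITY_COLUMNS)
    patterns = {sp.label: sp.pattern for sp in species}
    return IntensityTable(frame=frame, detection_floor=config.detection_floor, patterns=patterns)


def concat_tables(tables: Sequence[IntensityTable]) -> IntensityTable:
    frame = pd.concat([t.frame for t in tables], ignore_index=True)
    patterns: dict[str, ErrorPattern] = {}
    for t in tables:
        patterns.update(t.patterns)
    return IntensityTable(
        frame=frame, detection_floor=tables[0].detection_floor, patterns=patterns
    )


def simulate_titration(
    protein: ProteinRecord,
    preset: AGAPreset,
    species: Sequence[SpeciesDef],
    config: SimConfig,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    rng: Optional[np.random.Generator] = None,
    beta_per_um: float = BETA_PER_UM,
    weights: Optional[Mapping[tuple[int, str], float]] = None,
) -> list[IntensityTable]:
    """One intensity table per drug concentration.

    Binding scales linearly with the nominal concentration
    (``beta = beta_per_um * c``, capped at one), so single-error frequencies
    rise with dose while the conditional next-error frequency — a property
    of the bound ribosome only — stays put.
    """
    rng = config.rng(rng)
    if weights is None:
        weights = _species_weights(species, preset)
    tables = []
    for conc in concentrations:
        params = AGAParams(
            name=preset.name,
            beta=min(1.0, beta_per_um * conc),
            q=preset.q,
            weights=weights,
        )
        counts = sample_counts(protein, params, config, species, rng=rng)
        tables.append(
            emit_intensity_table(
                counts,
                species,
                config,
                {"aga": preset.name, "concentration_um": conc},
                rng=rng,
            )
        )
    return tables


def _species_weights(
    species: Sequence[SpeciesDef], preset: AGAPreset
) -> dict[tuple[int, str], float]:
    """Back-solved site weights for the clusters present in a species set.

    The following-error weight comes from the preset anchored at the
    cluster's inter-error distance; the first-error site uses the same
    weight (the misreading preference of a site is conserved between single
    and in-cluster errors).
    """
    weights: dict[tuple[int, str], float] = {}
    for sp in species:
        subs = sp.pattern.substitutions
        if len(subs) < 2:
            continue
        for i, sub in enumerate(subs):
            d = subs[i].position - subs[i - 1].position - 1 if i > 0 else None
            if i == 0:
                d = subs[1].position - subs[0].position - 1
            weights[(sub.position, sub.to_aa)] = preset.bound_misreading(d)
    if not weights:
        raise ValueError("species set contains no multi-error cluster")
    return weights


def titrate_cluster(
    protein: ProteinRecord,
    cluster: ErrorPattern,
    preset: AGAPreset,
    config: SimConfig,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    rng: Optional[np.random.Generator] = None,
    beta_per_um: float = BETA_PER_UM,
) -> IntensityTable:
    """Convenience: titration of one cluster, returned as a combined table."""
    species = cluster_species(protein, cluster)
    tables = simulate_titration(
        protein, preset, species, config, concentrations, rng=rng, beta_per_um=beta_per_um
    )
    return concat_tables(tables)


def profile_weights(
    clusters: Sequence[ErrorPattern], preset: AGAPreset
) -> dict[tuple[int, str], float]:
    """Uniform back-solved site weights for a distance-profile experiment.

    Every cluster site gets the same bound-state misreading probability
    (anchored at the preset's own anchor distance), so the observable
    E_f^next across clusters decays purely through retention, as
    m*w*q^(d+1).
    """
    mw = preset.bound_misreading()
    weights: dict[tuple[int, str], float] = {}
    for cluster in clusters:
        for sub in cluster.substitutions:
            weights[(sub.position, sub.to_aa)] = mw
    return weights


def simulate_profile_table(
    protein: ProteinRecord,
    clusters: Sequence[ErrorPattern],
    preset: AGAPreset,
    config: SimConfig,
    concentration: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    beta_per_um: float = BETA_PER_UM,
) -> IntensityTable:
    """Single-condition intensity table covering many clusters at once.

    Used for distance-dependence experiments: each cluster lives in its own
    tryptic peptide; species probabilities are the per-peptide marginals.
    The concentration defaults to the preset's maximum-misreading dose.
    """
    rng = config.rng(rng)
    if concentration is None:
        concentration = preset.max_misreading_conc_um or 8.0
    weights = profile_weights(clusters, preset)
    params = AGAParams(
        name=preset.name,
        beta=min(1.0, beta_per_um * concentration),
        q=preset.q,
        weights=weights,
    )
    species: list[SpeciesDef] = []
    for cluster in clusters:
        species.extend(cluster_species(protein, cluster))
    counts = sample_counts(protein, params, config, species, rng=rng)
    return emit_intensity_table(
        counts,
        species,
        config,
        {"aga": preset.name, "concentration_um": concentration},
        rng=rng,
    )


def fraction_split(
    counts: Mapping[str, int],
    destabilization_map: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, int], dict[str, int]]:
    """Binomially partition species counts into soluble/insoluble fractions.

    ``destabilization_map`` gives each species an aggregation propensity in
    [0, 1] (the insoluble-fraction probability; default 0).
    """
    soluble, insoluble = {}, {}
    for label, count in counts.items():
        p = destabilization_map.get(label, 0.0)
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"aggregation propensity for {label} not in [0, 1]")
        ins = int(rng.binomial(count, p)) if count > 0 else 0
        insoluble[label] = ins
        soluble[label] = count - ins
    return soluble, insoluble


# ---------------------------------------------------------------------------
# synthetic model proteins
# ---------------------------------------------------------------------------

_BACKGROUND = "ASTVGLINQH"  # no K/R (cleavage), P (KP rule), or D/E/F (cluster sites)


def _scaffold(length: int, boundary_every: int = 20) -> list[str]:
    seq = [_BACKGROUND[i % len(_BACKGROUND)] for i in range(length)]
    for pos in range(boundary_every, length + 1, boundary_every):
        seq[pos - 1] = "K"
    return seq


def make_model_protein(protein_id: str = "modelP") -> ProteinRecord:
    """Synthetic 300-residue model protein with the benchmark cluster sites.

    Tryptic boundaries every 20 residues; D208/F211 sit in one peptide
    (d = 2 geometry) and E241/E242/E244 in another (d = 0 and d = 1
    geometries), mirroring the D208E-F211L, E241D-E242D and E242D-E244D
    cluster layouts studied on elongation factor Tu. The coding sequence is
    the deterministic reverse translation, so every benchmark substitution
    is a third-position near-cognate misreading.
    """
    seq = _scaffold(300)
    for pos, aa in ((208, "D"), (211, "F"), (241, "E"), (242, "E"), (244, "E")):
        seq[pos - 1] = aa
    sequence = "".join(seq)
    return ProteinRecord(id=protein_id, sequence=sequence, cds=reverse_translate(sequence))


#: benchmark cluster geometries on the model protein: label -> ((pos, to_aa), ...)
MODEL_CLUSTERS: dict[str, tuple[tuple[int, str], ...]] = {
    "D208E-F211L": ((208, "E"), (211, "L")),
    "E242D-E244D": ((242, "D"), (244, "D")),
    "E241D-E242D": ((241, "D"), (242, "D")),
}


def cluster_from_positions(
    protein: ProteinRecord, sites: Sequence[tuple[int, str]]
) -> ErrorPattern:
    """Classified error pattern from (position, substituted amino acid) pairs."""
    subs = tuple(_site_substitution(protein, pos, aa) for pos, aa in sites)
    return ErrorPattern(substitutions=subs)


def model_cluster(protein: ProteinRecord, label: str) -> ErrorPattern:
    return cluster_from_positions(protein, MODEL_CLUSTERS[label])


def make_profile_protein(
    d_values: Sequence[int] = tuple(range(7)),
    clusters_per_d: int = 3,
    protein_id: str = "profileP",
) -> tuple[ProteinRecord, list[ErrorPattern]]:
    """Synthetic protein hosting E->D cluster pairs at each requested distance.

    Each tryptic peptide (20 residues) carries one pair of glutamates
    separated by d correct residues; ``clusters_per_d`` peptides are laid
    out per distance. Returns the protein and the list of cluster patterns.
    """
    n_peptides = len(d_values) * clusters_per_d
    length = 20 * n_peptides
    seq = _scaffold(length)
    layouts = []
    for j in range(n_peptides):
        d = d_values[j % len(d_values)]
        first = 20 * j + 5
        second = first + d + 1
        seq[first - 1] = "E"
        seq[second - 1] = "E"
        layouts.append((first, second))
    sequence = "".join(seq)
    protein = ProteinRecord(id=protein_id, sequence=sequence, cds=reverse_translate(sequence))
    clusters = [
        cluster_from_positions(protein, ((a, "D"), (b, "D"))) for a, b in layouts
    ]
    return protein, clusters
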