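"""Proteotoxicity-side normalizations.

Secondary readouts of mistranslation stress: enrichment of missense species
in the insoluble (aggregate) fraction, thermostability curves of missense
versus parental peptides, and the standard preprocessing of label-free
proteome tables (presence filter, down-shifted normal imputation, 0-1
interval scaling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats


@dataclass(frozen=True)
class FractionPair:
    """Per-replicate intensities of one species in both solubility fractions."""

    insoluble: tuple[float, ...]
    soluble: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.insoluble) != len(self.soluble):
            raise ValueError("fraction replicate counts differ")
        if any(v < 0 for v in self.insoluble + self.soluble):
            raise ValueError("intensities must be >= 0")

    def ratios(self) -> np.ndarray:
        sol = np.asarray(self.soluble, dtype=float)
        ins = np.asarray(self.insoluble, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return ins / sol


@dataclass
class EnrichmentResult:
    enrichment: float
    p_value: float
    upper_limit: bool = False  # zero soluble intensity somewhere
    log_ratios: tuple[float, ...] = ()


def aggregation_enrichment(
    pair: FractionPair,
    correct_reference: Sequence[FractionPair],
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Aggregation enrichment of a species over the correct-peptide cohort.

    Per replicate, the species' insoluble/soluble ratio is divided by the
    median ratio of the correct peptides; the reported enrichment is the
    mean over replicates and the p value a one-sample t test of the log
    ratios against zero (``alternative`` may be "greater" to mirror a
    one-tailed aggregation test). Requires >= 2 replicates.
    """
    n_rep = len(pair.soluble)
    if n_rep < 2:
        raise ValueError("need >= 2 replicates for significance")
    species_ratio = pair.ratios()
    upper = bool(np.any(~np.isfinite(species_ratio)))
    ref = np.array([p.ratios() for p in correct_reference], dtype=float)
    ref_median = np.nanmedian(np.where(np.isfinite(ref), ref, np.nan), axis=0)
    rel = species_ratio / ref_median
    finite = rel[np.isfinite(rel) & (rel > 0)]
    if finite.size < 2:
        return EnrichmentResult(
            enrichment=math.inf if upper else math.nan,
            p_value=math.nan,
            upper_limit=upper,
        )
    logs = np.log(finite)
    t = sp_stats.ttest_1samp(logs, 0.0, alternative=alternative)
    return EnrichmentResult(
        enrichment=float(finite.mean()),
        p_value=float(t.pvalue),
        upper_limit=upper,
        log_ratios=tuple(logs),
    )


@dataclass
class StabilityCurve:
    temperatures: tuple[float, ...]  # deg C, ascending
    values: tuple[float, ...]  # missense/parent signal, anchor == 1
    anchor: float = 41.0


def thermostability_normalize(
    raw: Mapping[float, float],
    parent: Mapping[float, float],
    anchor: float = 41.0,
) -> StabilityCurve:
    """Relative thermostability of a missense species.

    Per temperature, the missense signal is divided by the parental signal;
    the curve is rescaled so the anchor temperature (41 degC by default)
    equals one. Raises when the anchor is missing from either series.
    """
    temps = sorted(set(raw) & set(parent))
    if anchor not in raw or anchor not in parent:
        raise ValueError(f"anchor temperature {anchor} missing")
    if parent[anchor] <= 0 or raw[anchor] <= 0:
        raise ValueError("anchor signals must be positive")
    anchor_ratio = raw[anchor] / parent[anchor]
    values = tuple((raw[t] / parent[t]) / anchor_ratio for t in temps)
    return StabilityCurve(temperatures=tuple(temps), values=values, anchor=anchor)


def presence_filter(matrix: pd.DataFrame, min_fraction: float = 0.6) -> pd.DataFrame:
    """Keep rows (proteins) observed in at least ``min_fraction`` of samples."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    frac = matrix.notna().mean(axis=1)
    return matrix.loc[frac >= min_fraction]


def impute_missing(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Down-shifted normal imputation of missing log-intensities, per sample.

    Each missing value in a sample (column) is drawn from a normal law with
    mean = sample mean - downshift * sample SD and SD = width * sample SD
    (the Perseus-style defaults are width 0.3, downshift 1.8). Observed
    values are never altered. A sample with fewer than two observed values
    has no defined distribution and is rejected.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has < 2 observed values")
        mu = observed.mean() - downshift * observed.std(ddof=1)
        sigma = width * observed.std(ddof=1)
        draws = rng.normal(mu, sigma, size=n_missing)
        out.loc[out[col].isna(), col] = draws
    return out


def scale_to_interval(vector: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Min-max scaling of a per-protein profile to [0, 1].

    Returns (scaled values, degenerate flag); a constant vector maps to all
    zeros with the flag set.
    """
    x = np.asarray(vector, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False
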