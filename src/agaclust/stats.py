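"""Error-frequency statistics for peptide-level intensity tables.

The basic observable is the error frequency E_f: the intensity ratio of a
missense peptide to its correct parental peptide. On top of it sit the
cluster statistics: the stochastic expectation (product of singles), the
amplification A = E_f^cluster / (E_f^1st * E_f^2nd), the conditional
next-error frequency E_f^next (with E_f^1st * E_f^next = E_f^cluster) by
three estimators — a through-origin titration slope, a frequency ratio, and
a direct intensity (LFQ) ratio — and the distance profile of E_f^next with
its exponential retention fit N(d) = c * q^d.

E_f^1st in the cluster pipeline is the *marginal* frequency of the first
misreading event, i.e. the summed intensity of every species carrying that
substitution (the single-error peptide plus the cluster peptides) over the
parent. With that convention E_f^next is exactly the conditional
probability of the next error given the first, which is what the retention
model predicts as m*w*q^(d+1).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .types import ErrorPattern, IntensityTable, Substitution


class EstimatorExclusion(ValueError):
    """A species fails the physico-chemical comparability requirements."""


# ---------------------------------------------------------------------------
# error frequencies
# ---------------------------------------------------------------------------


@dataclass
class ErrorFrequencyRecord:
    species: str
    condition: dict
    ef: float
    parent_source: str = "measured"  # or "median-fallback"
    upper_limit: bool = False
    replicate_efs: tuple[float, ...] = ()
    intensities: tuple[float, ...] = ()  # missense intensity per replicate
    parent_intensities: tuple[float, ...] = ()


def compute_ef(
    table: IntensityTable,
    species: str,
    condition: Optional[Mapping[str, object]] = None,
) -> Optional[ErrorFrequencyRecord]:
    """E_f of one missense species under one condition.

    Per replicate, E_f = missense intensity / parent intensity; when the
    parent peptide was never detected, the median intensity of all correct
    peptides in that sample stands in (flagged ``median-fallback``).
    Missing missense intensities are imputed at the detection floor and the
    record is flagged as an upper limit. Replicates are aggregated by the
    median. Returns None when the species has no rows at all under the
    condition (absent is missing, not zero).
    """
    condition = dict(condition or {})
    rows = table.subset(species=species, **condition)
    if rows.empty:
        return None
    parent_label = str(rows["parent_species"].iloc[0])
    upper = False
    source = "measured"
    efs, missense_is, parent_is = [], [], []
    for rep in sorted(rows["replicate"].unique()):
        i_m = rows.loc[rows["replicate"] == rep, "intensity"].sum(min_count=1)
        if np.isnan(i_m):
            i_m = table.detection_floor
            upper = True
        i_p = np.nan
        if parent_label:
            prows = table.subset(species=parent_label, replicate=rep, **condition)
            if not prows.empty:
                i_p = prows["intensity"].sum(min_count=1)
        if np.isnan(i_p):
            sample = table.subset(replicate=rep, **condition)
            correct = sample.loc[sample["n_errors"] == 0, "intensity"].dropna()
            if correct.empty:
                continue
            i_p = float(correct.median())
            source = "median-fallback"
        efs.append(i_m / i_p)
        missense_is.append(float(i_m))
        parent_is.append(float(i_p))
    if not efs:
        return None
    return ErrorFrequencyRecord(
        species=species,
        condition=condition,
        ef=float(np.median(efs)),
        parent_source=source,
        upper_limit=upper,
        replicate_efs=tuple(efs),
        intensities=tuple(missense_is),
        parent_intensities=tuple(parent_is),
    )


def induction_filter(
    treated: ErrorFrequencyRecord,
    untreated: ErrorFrequencyRecord,
    fold: float = 2.0,
) -> bool:
    """Keep a species only if its signal is consistently induced > fold.

    Chemical-background features (isobaric oxidations, deamidations) sit at
    the same intensity with and without drug; requiring a consistent
    greater-than-``fold`` induction in every replicate removes them.
    """
    if treated.species != untreated.species:
        raise ValueError("records must describe the same species")
    t = np.asarray(treated.intensities, dtype=float)
    u = np.asarray(untreated.intensities, dtype=float)
    if t.size == 0 or u.size == 0:
        return False
    n = min(t.size, u.size)
    return bool(np.all(t[:n] > fold * u[:n]))


def stochastic_expectation(singles: Sequence[ErrorFrequencyRecord | float]) -> float:
    """Expected cluster frequency under independent errors: product of singles."""
    product = 1.0
    for s in singles:
        product *= s.ef if isinstance(s, ErrorFrequencyRecord) else float(s)
    return product


def amplification(ef_cluster: float, ef_first: float, ef_second: float) -> float:
    """Fold excess of the cluster over its stochastic expectation.

    Equals one for independent errors. A zero denominator yields +inf (the
    measured value is then only a lower limit).
    """
    denom = ef_first * ef_second
    if denom == 0:
        return math.inf
    return ef_cluster / denom


# ---------------------------------------------------------------------------
# E_f^next estimators
# ---------------------------------------------------------------------------


def efnext_slope(series: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """E_f^next as the through-origin slope of E_f^cluster on E_f^1st.

    ``series`` holds (ef_first, ef_cluster) pairs from a titration or time
    course; at E_f^1st = 0 no cluster can exist (translation is vectorial),
    so the intercept is fixed at zero. Returns (slope, standard error);
    requires at least three points.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (ef_first, ef_cluster) points")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(x @ x)
    if sxx == 0:
        return 0.0, 0.0
    slope = float(x @ y) / sxx
    resid = y - slope * x
    se = math.sqrt(float(resid @ resid) / (len(x) - 1) / sxx)
    return slope, se


def efnext_ratio(ef_cluster: float, ef_first: float) -> float:
    """E_f^next as the ratio of cluster and first-error frequencies.

    For a three-error cluster the third-step value is the frequency of the
    triple over that of its leading double.
    """
    if ef_first <= 0:
        raise ValueError("ef_first must be positive")
    return ef_cluster / ef_first


def physicochemical_exclusion(sub: Substitution) -> Optional[str]:
    """Reason a substitution disqualifies direct intensity comparison, if any.

    Histidine gain or loss shifts the charge-state distribution; lysine or
    arginine gain or loss changes the tryptic cleavage pattern. Either way
    the missense and parent species no longer ionise comparably.
    """
    if "H" in (sub.from_aa, sub.to_aa):
        return f"{sub.label}: charge-state change (His gain/loss)"
    if sub.from_aa in "KR" or sub.to_aa in "KR":
        return f"{sub.label}: tryptic cleavage change (K/R gain/loss)"
    return None


def efnext_lfq(
    cluster_intensity: float,
    first_error_intensity: float,
    following: Sequence[Substitution] = (),
    cleavage_altered: bool = False,
) -> float:
    """E_f^next as a direct label-free intensity ratio (same sample).

    Valid only when the cluster and single-first-error peptides share the
    backbone and the *following* substitutions neither change the charge
    state nor the cleavage pattern; otherwise an
    :class:`EstimatorExclusion` is raised with the reason.
    """
    if cleavage_altered:
        raise EstimatorExclusion("cleavage pattern altered; intensities not comparable")
    for sub in following:
        reason = physicochemical_exclusion(sub)
        if reason:
            raise EstimatorExclusion(reason)
    if first_error_intensity <= 0:
        raise ValueError("first-error intensity must be positive")
    return cluster_intensity / first_error_intensity


# ---------------------------------------------------------------------------
# cluster statistics pipeline
# ---------------------------------------------------------------------------


@dataclass
class ClusterStat:
    pattern_label: str
    condition: dict
    ef_first: float  # marginal frequency of the first misreading event
    ef_second: float
    ef_cluster: float
    amplification: float
    efnext: float
    estimator_used: str = "ratio_absolute"
    d_list: tuple[int, ...] = ()
    upper_limit: bool = False


_SUB_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")


def parse_pattern_label(label: str, protein_id: str = "") -> ErrorPattern:
    """Pattern from a species label like ``"D208E+F211L"``."""
    subs = []
    for token in label.split("+"):
        m = _SUB_RE.match(token)
        if not m:
            raise ValueError(f"cannot parse substitution {token!r}")
        subs.append(
            Substitution(
                protein_id=protein_id,
                position=int(m.group(2)),
                from_aa=m.group(1),
                to_aa=m.group(3),
            )
        )
    return ErrorPattern(substitutions=tuple(subs))


def _pattern_of(table: IntensityTable, label: str) -> ErrorPattern:
    if label in table.patterns:
        return table.patterns[label]
    return parse_pattern_label(label)


def marginal_first_ef(
    table: IntensityTable,
    first: Substitution,
    condition: Optional[Mapping[str, object]] = None,
) -> Optional[ErrorFrequencyRecord]:
    """Marginal E_f of a misreading event: all species carrying it, summed."""
    condition = dict(condition or {})
    carriers = []
    for label in table.species():
        if label.startswith("correct"):
            continue
        try:
            pattern = _pattern_of(table, label)
        except ValueError:
            continue
        if any(
            s.position == first.position and s.to_aa == first.to_aa
            for s in pattern.substitutions
        ):
            carriers.append(label)
    if not carriers:
        return None
    records = [compute_ef(table, label, condition) for label in carriers]
    records = [r for r in records if r is not None]
    if not records:
        return None
    n_rep = max(len(r.replicate_efs) for r in records)
    efs = []
    for i in range(n_rep):
        total = sum(r.replicate_efs[i] for r in records if len(r.replicate_efs) > i)
        efs.append(total)
    return ErrorFrequencyRecord(
        species=f"marginal:{first.label}",
        condition=condition,
        ef=float(np.median(efs)),
        upper_limit=any(r.upper_limit for r in records),
        replicate_efs=tuple(efs),
    )


def cluster_stat(
    table: IntensityTable,
    cluster_label: str,
    condition: Optional[Mapping[str, object]] = None,
) -> Optional[ClusterStat]:
    """Per-condition cluster statistics from an intensity table.

    The first error of a cluster is its N-terminal-most substitution
    (translation proceeds N to C). Its frequency is the marginal over all
    carrier species; the second error enters the amplification as the
    exclusive single-substitution species.
    """
    condition = dict(condition or {})
    pattern = _pattern_of(table, cluster_label)
    if len(pattern) < 2:
        raise ValueError(f"{cluster_label} is not a cluster")
    first, second = pattern.substitutions[0], pattern.substitutions[1]
    rec_cluster = compute_ef(table, cluster_label, condition)
    rec_first = marginal_first_ef(table, first, condition)
    rec_second = compute_ef(table, second.label, condition)
    if rec_cluster is None or rec_first is None:
        return None
    ef_second = rec_second.ef if rec_second is not None else math.nan
    return ClusterStat(
        pattern_label=cluster_label,
        condition=condition,
        ef_first=rec_first.ef,
        ef_second=ef_second,
        ef_cluster=rec_cluster.ef,
        amplification=amplification(rec_cluster.ef, rec_first.ef, ef_second)
        if np.isfinite(ef_second)
        else math.nan,
        efnext=efnext_ratio(rec_cluster.ef, rec_first.ef),
        estimator_used="ratio_absolute",
        d_list=pattern.d_list,
        upper_limit=rec_cluster.upper_limit or rec_first.upper_limit,
    )


def efnext_from_titration(
    table: IntensityTable,
    cluster_label: str,
    estimator: str = "ratio",
    condition_key: str = "concentration_um",
) -> tuple[float, list[ClusterStat]]:
    """E_f^next across the conditions of a titration (or time course).

    ``estimator="ratio"`` reports the median per-condition ratio
    E_f^cluster / E_f^1st; ``estimator="slope"`` fits the through-origin
    regression of E_f^cluster on E_f^1st over the conditions.
    """
    values = sorted(table.frame[condition_key].dropna().unique())
    stats = []
    for v in values:
        st = cluster_stat(table, cluster_label, {condition_key: v})
        if st is not None:
            stats.append(st)
    if not stats:
        raise ValueError(f"no quantifiable conditions for {cluster_label}")
    if estimator == "ratio":
        return float(np.median([s.efnext for s in stats])), stats
    if estimator == "slope":
        slope, _se = efnext_slope([(s.ef_first, s.ef_cluster) for s in stats])
        return slope, stats
    raise ValueError(f"unknown estimator {estimator!r}")


# ---------------------------------------------------------------------------
# distance profiles and retention fitting
# ---------------------------------------------------------------------------


@dataclass
class DistanceProfile:
    aga: str
    reference: str
    points: pd.DataFrame  # columns: d, value, sd, n
    anchor: str = "reference"
    fit: Optional["RetentionFit"] = None


@dataclass
class RetentionFit:
    q: float
    q_ci: tuple[float, float]
    c: float
    n_boot: int
    degenerate: bool = False
    residual_ss: float = math.nan


def build_distance_profile(
    records: Iterable[tuple[str, int, float]] | pd.DataFrame,
    reference: str = "Str",
    anchor: str = "reference",
) -> dict[str, DistanceProfile]:
    """Normalized E_f^next versus inter-error distance, per drug.

    Each record is (drug, d, efnext) for one cluster. Per distance, values
    are divided by the reference drug's mean at the same distance (the
    reference has nearly no distance dependence, so it provides a
    cluster-by-cluster ionization/normalization control); multiple clusters
    at one distance aggregate as mean +- SD. ``anchor="reference"`` leaves
    the reference profile at one everywhere; ``anchor="d0"`` additionally
    rescales every drug to one at its smallest measured distance.
    Distances without a reference measurement are dropped with a warning.
    """
    if isinstance(records, pd.DataFrame):
        df = records.rename(columns=dict(zip(records.columns, ["aga", "d", "efnext"])))
    else:
        df = pd.DataFrame(list(records), columns=["aga", "d", "efnext"])
    if reference not in set(df["aga"]):
        raise ValueError(f"reference drug {reference!r} not in records")
    ref_mean = df[df["aga"] == reference].groupby("d")["efnext"].mean()
    profiles = {}
    for aga, group in df.groupby("aga"):
        rows = []
        for d, vals in group.groupby("d")["efnext"]:
            if d not in ref_mean.index:
                warnings.warn(
                    f"{aga}: no {reference} reference at d={d}; point dropped"
                )
                continue
            norm = vals / ref_mean.loc[d]
            rows.append(
                {
                    "d": int(d),
                    "value": float(norm.mean()),
                    "sd": float(norm.std(ddof=1)) if len(norm) > 1 else 0.0,
                    "n": int(len(norm)),
                }
            )
        pts = pd.DataFrame(rows, columns=["d", "value", "sd", "n"]).sort_values("d")
        pts = pts.reset_index(drop=True)
        if anchor == "d0" and not pts.empty:
            scale = pts["value"].iloc[0]
            if scale > 0:
                pts["value"] /= scale
                pts["sd"] /= scale
        profiles[str(aga)] = DistanceProfile(
            aga=str(aga), reference=reference, points=pts, anchor=anchor
        )
    return profiles


def _exp_model(d, c, q):
    return c * np.power(q, d)


def fit_retention(
    profile: DistanceProfile,
    n_boot: int = 200,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> RetentionFit:
    """Per-translocation retention probability from the distance profile.

    Nonlinear least squares of N(d) = c * q^d with q constrained to [0, 1];
    the exponent is d (not d + 1) because the profile is a ratio to the
    reference at matched d, which cancels the shared offset. The confidence
    interval is a parametric bootstrap over the point uncertainties
    (points with a single cluster get a 10% nominal uncertainty).
    """
    pts = profile.points
    if len(pts) < 3:
        raise ValueError("need >= 3 distinct distances to fit retention")
    d = pts["d"].to_numpy(dtype=float)
    y = pts["value"].to_numpy(dtype=float)
    sd = pts["sd"].to_numpy(dtype=float).copy()
    sd[sd <= 0] = 0.1 * np.abs(y[sd <= 0])
    rng = rng if rng is not None else np.random.default_rng(seed)

    if np.ptp(y) < 1e-12:
        fit = RetentionFit(
            q=1.0, q_ci=(1.0, 1.0), c=float(y.mean()), n_boot=0, degenerate=True
        )
        profile.fit = fit
        return fit

    def _fit_once(yy):
        popt, _ = optimize.curve_fit(
            _exp_model,
            d,
            yy,
            p0=(max(yy[0], 1e-6), 0.5),
            bounds=([0.0, 0.0], [np.inf, 1.0]),
            maxfev=10000,
        )
        return popt

    c_hat, q_hat = _fit_once(y)
    resid = y - _exp_model(d, c_hat, q_hat)
    qs = []
    for _ in range(n_boot):
        perturbed = y + rng.normal(0.0, sd)
        try:
            qs.append(_fit_once(perturbed)[1])
        except RuntimeError:
            continue
    if qs:
        lo, hi = np.percentile(qs, [2.5, 97.5])
    else:
        lo = hi = q_hat
    fit = RetentionFit(
        q=float(q_hat),
        q_ci=(float(lo), float(hi)),
        c=float(c_hat),
        n_boot=len(qs),
        residual_ss=float(resid @ resid),
    )
    profile.fit = fit
    return fit


# ---------------------------------------------------------------------------
# drug grouping
# ---------------------------------------------------------------------------


def classify_aga(
    median_single_ef: Optional[float],
    efnext_adjacent: Optional[float],
    efnext_cutoff: float = 0.2,
    single_ef_cutoff: float = 1e-5,
) -> str:
    """Two-group classification of a bactericidal aminoglycoside.

    Group I: potent single-error induction with moderate, distance-flat
    clustering (streptomycin-like). Group II: moderate single errors but a
    high adjacent next-error frequency with steep distance decay
    (apramycin-like). The rule is a simple 2-D threshold; drugs with
    missing or negligible statistics stay unclassified.
    """
    if median_single_ef is None or efnext_adjacent is None:
        return "unclassified"
    if not (np.isfinite(median_single_ef) and np.isfinite(efnext_adjacent)):
        return "unclassified"
    if efnext_adjacent >= efnext_cutoff:
        return "II"
    if median_single_ef >= single_ef_cutoff:
        return "I"
    return "unclassified"
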