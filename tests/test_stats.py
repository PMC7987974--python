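"""Error-frequency estimators, cluster statistics, distance-profile fitting."""

import math

import numpy as np
import pandas as pd
import pytest

import agaclust as ag
from agaclust.simulate import AGAParams, SimConfig, sample_counts
from agaclust.stats import (
    EstimatorExclusion,
    RetentionFit,
    efnext_lfq,
    efnext_ratio,
    efnext_slope,
    parse_pattern_label,
)
from agaclust.types import INTENSITY_COLUMNS, IntensityTable, Substitution


def _table(rows, floor=1e2):
    base = {
        "protein_id": "P",
        "peptide_start": 1,
        "peptide_end": 10,
        "n_errors": 1,
        "parent_species": "correct@1-10",
        "aga": "Str",
        "concentration_um": 8.0,
        "time_min": 120.0,
        "fraction": "total",
        "replicate": 1,
    }
    full = []
    for row in rows:
        r = dict(base)
        r.update(row)
        full.append(r)
    return IntensityTable(
        frame=pd.DataFrame(full, columns=INTENSITY_COLUMNS), detection_floor=floor
    )


class TestComputeEf:
    def test_simple_ratio(self):
        t = _table(
            [
                {"species": "correct@1-10", "n_errors": 0, "parent_species": "", "intensity": 1.5e6},
                {"species": "D2E", "intensity": 150.0},
            ]
        )
        rec = ag.compute_ef(t, "D2E")
        assert rec.ef == pytest.approx(1e-4)
        assert rec.parent_source == "measured"
        assert not rec.upper_limit

    def test_median_fallback_when_parent_absent(self):
        t = _table(
            [
                {"species": "correct@20-30", "n_errors": 0, "parent_species": "", "intensity": 1e6},
                {"species": "correct@31-44", "n_errors": 0, "parent_species": "", "intensity": 2e6},
                {"species": "correct@45-60", "n_errors": 0, "parent_species": "", "intensity": 4e6},
                {"species": "N2K", "intensity": 100.0},
            ]
        )
        rec = ag.compute_ef(t, "N2K")
        assert rec.parent_source == "median-fallback"
        assert rec.ef == pytest.approx(100.0 / 2e6)

    def test_absent_species_is_missing_not_zero(self):
        t = _table([{"species": "correct@1-10", "n_errors": 0, "parent_species": "", "intensity": 1e6}])
        assert ag.compute_ef(t, "D2E") is None

    def test_missing_intensity_imputed_as_upper_limit(self):
        t = _table(
            [
                {"species": "correct@1-10", "n_errors": 0, "parent_species": "", "intensity": 1e6},
                {"species": "D2E", "intensity": np.nan},
            ],
            floor=50.0,
        )
        rec = ag.compute_ef(t, "D2E")
        assert rec.upper_limit
        assert rec.ef == pytest.approx(50.0 / 1e6)

    def test_replicates_aggregate_by_median(self):
        rows = [
            {"species": "correct@1-10", "n_errors": 0, "parent_species": "", "replicate": r, "intensity": 1e6}
            for r in (1, 2, 3)
        ] + [
            {"species": "D2E", "replicate": 1, "intensity": 90.0},
            {"species": "D2E", "replicate": 2, "intensity": 100.0},
            {"species": "D2E", "replicate": 3, "intensity": 260.0},
        ]
        rec = ag.compute_ef(_table(rows), "D2E")
        assert rec.ef == pytest.approx(1e-4)
        assert rec.replicate_efs == pytest.approx((9e-5, 1e-4, 2.6e-4))


class TestInductionFilter:
    def _rec(self, intensities):
        from agaclust.stats import ErrorFrequencyRecord

        return ErrorFrequencyRecord(
            species="D2E", condition={}, ef=1e-4, intensities=tuple(intensities)
        )

    def test_consistently_induced_kept(self):
        assert ag.induction_filter(self._rec([300, 330, 290]), self._rec([100, 100, 100]))

    def test_weak_induction_dropped(self):
        assert not ag.induction_filter(self._rec([150, 160, 140]), self._rec([100, 100, 100]))

    def test_inconsistent_induction_dropped(self):
        assert not ag.induction_filter(self._rec([300, 150, 290]), self._rec([100, 100, 100]))

    def test_constant_background_dropped_in_simulation(self, model_protein):
        """A spiked species with drug-independent intensity fails the filter."""
        rng = np.random.default_rng(4)
        cluster = ag.model_cluster(model_protein, "E242D-E244D")
        species = ag.cluster_species(model_protein, cluster)
        config = SimConfig(n_ribosomes=1e8, noise_cv=0.2)
        kept = 0
        n_trials = 40
        for _ in range(n_trials):
            tables = []
            for conc, beta in ((0.0, 0.0), (8.0, 4e-4)):
                params = AGAParams(
                    name="Str", beta=beta, q=0.97,
                    weights={(242, "D"): 0.05, (244, "D"): 0.05},
                )
                counts = sample_counts(model_protein, params, config, species, rng=rng)
                counts["background"] = 5000  # chemical background, drug-blind
                bg = ag.SpeciesDef(
                    pattern=ag.ErrorPattern(()), peptide=species[0].peptide, scope=()
                )
                table = ag.emit_intensity_table(
                    counts, species, config, {"aga": "Str", "concentration_um": conc}, rng=rng
                )
                extra = table.frame[table.frame["species"] == species[0].label].copy()
                extra["species"] = "background"
                extra["n_errors"] = 1
                noise = np.exp(rng.normal(-0.02, 0.2, size=len(extra)))
                extra["intensity"] = 5000 * config.global_scale * noise
                table.frame = pd.concat([table.frame, extra], ignore_index=True)
                tables.append(table)
            untreated, treated = tables
            rec_t = ag.compute_ef(treated, "background", {"concentration_um": 8.0})
            rec_u = ag.compute_ef(untreated, "background", {"concentration_um": 0.0})
            if ag.induction_filter(rec_t, rec_u):
                kept += 1
        assert kept / n_trials <= 0.05


def test_stochastic_expectation_is_product():
    assert ag.stochastic_expectation([1e-4, 1e-3]) == pytest.approx(1e-7)
    assert ag.stochastic_expectation([1e-4, 1e-4, 1e-3]) == pytest.approx(1e-11)


def test_amplification_ratio_and_identity():
    a = ag.amplification(8e-6, 1e-4, 1e-3)
    assert a == pytest.approx(80.0)
    # identity A = efnext / ef_second
    assert a == pytest.approx(efnext_ratio(8e-6, 1e-4) / 1e-3)
    assert math.isinf(ag.amplification(1e-6, 0.0, 1e-3))


class TestEfnextEstimators:
    def test_slope_on_proportional_points(self):
        pts = [(1e-4, 8e-6), (2e-4, 1.6e-5), (4e-4, 3.2e-5)]
        slope, se = efnext_slope(pts)
        assert slope == pytest.approx(0.08, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_slope_zero_when_no_clusters(self):
        slope, _ = efnext_slope([(1e-4, 0.0), (2e-4, 0.0), (4e-4, 0.0)])
        assert slope == 0.0

    def test_slope_needs_three_points(self):
        with pytest.raises(ValueError):
            efnext_slope([(1e-4, 8e-6), (2e-4, 1.6e-5)])

    def test_ratio(self):
        assert efnext_ratio(8e-6, 1e-4) == pytest.approx(0.08)
        # third error of a triple over its leading double
        assert efnext_ratio(2e-7, 8e-7) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            efnext_ratio(1e-6, 0.0)

    def test_lfq_ratio_and_exclusions(self):
        assert efnext_lfq(400.0, 8000.0) == pytest.approx(0.05)
        with pytest.raises(EstimatorExclusion, match="cleavage pattern"):
            efnext_lfq(400.0, 8000.0, cleavage_altered=True)
        y310h = Substitution(protein_id="P", position=310, from_aa="Y", to_aa="H")
        with pytest.raises(EstimatorExclusion, match="charge-state"):
            efnext_lfq(400.0, 8000.0, following=[y310h])
        n2k = Substitution(protein_id="P", position=2, from_aa="N", to_aa="K")
        with pytest.raises(EstimatorExclusion, match="cleavage"):
            efnext_lfq(400.0, 8000.0, following=[n2k])

    def test_lfq_equals_ratio_with_shared_parent_and_unit_ionization(self):
        # same parent intensity cancels: I_cluster/I_first == ef_cluster/ef_first
        parent = 2e6
        assert efnext_lfq(400.0, 8000.0) == pytest.approx(
            efnext_ratio(400.0 / parent, 8000.0 / parent)
        )

    def test_estimators_agree_on_noiseless_titration(self, model_protein):
        cluster = ag.model_cluster(model_protein, "E242D-E244D")
        config = SimConfig(n_ribosomes=1e9, seed=9, noise_cv=0.0)
        table = ag.titrate_cluster(model_protein, cluster, ag.get_preset("Apr"), config)
        ratio, stats = ag.efnext_from_titration(table, cluster.label, estimator="ratio")
        slope, _ = ag.efnext_from_titration(table, cluster.label, estimator="slope")
        assert ratio == pytest.approx(slope, rel=0.05)
        # LFQ estimator on one condition: intensities directly
        st = stats[2]
        cond = st.condition
        df = table.subset(**cond)
        med = df.groupby("species")["intensity"].median()
        lfq = efnext_lfq(
            med[cluster.label],
            med[cluster.label] + med["E242D"],  # marginal first-event intensity
        )
        assert lfq == pytest.approx(st.efnext, rel=0.05)


def test_cluster_stat_identities(model_protein, config):
    """A = E_f^cluster/(E_f^1st*E_f^2nd) and E_f^cluster = E_f^1st*E_f^next."""
    cluster = ag.model_cluster(model_protein, "E242D-E244D")
    table = ag.titrate_cluster(model_protein, cluster, ag.get_preset("Apr"), config)
    for conc in (2.0, 8.0):
        st = ag.cluster_stat(table, cluster.label, {"concentration_um": conc})
        assert st.ef_cluster == pytest.approx(st.ef_first * st.efnext, rel=1e-12)
        assert st.amplification == pytest.approx(
            st.efnext / st.ef_second, rel=1e-12
        )
        assert st.d_list == (1,)


def test_concentration_invariance_of_efnext(model_protein, config):
    """E_f^1st spans >= 10-fold over the titration; E_f^next stays flat."""
    from scipy.stats import linregress

    cluster = ag.model_cluster(model_protein, "E242D-E244D")
    table = ag.titrate_cluster(model_protein, cluster, ag.get_preset("Apr"), config)
    _, stats = ag.efnext_from_titration(table, cluster.label)
    firsts = [s.ef_first for s in stats]
    assert max(firsts) / min(firsts) >= 10
    res = linregress(np.log([s.condition["concentration_um"] for s in stats]),
                     [s.efnext for s in stats])
    assert abs(res.slope) < 2 * res.stderr + 1e-3


def test_parse_pattern_label_round_trip():
    pat = parse_pattern_label("D208E+F211L")
    assert pat.positions == (208, 211)
    assert pat.d_list == (2,)
    assert pat.label == "D208E+F211L"
    with pytest.raises(ValueError):
        parse_pattern_label("notalabel")


class TestDistanceProfile:
    def test_identical_drug_gives_flat_unit_profile(self):
        records = [("Str", d, 0.05) for d in range(3)] + [("X", d, 0.05) for d in range(3)]
        profiles = ag.build_distance_profile(records)
        assert profiles["X"].points["value"].tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_halving_per_distance_against_flat_reference(self):
        records = [("Str", d, 0.05) for d in range(3)]
        records += [("X", d, 0.05 * 0.5**d) for d in range(3)]
        profiles = ag.build_distance_profile(records)
        assert profiles["X"].points["value"].tolist() == pytest.approx([1.0, 0.5, 0.25])

    def test_missing_reference_distance_dropped_with_warning(self):
        records = [("Str", 0, 0.05), ("Str", 1, 0.05), ("X", 0, 0.1), ("X", 2, 0.1)]
        with pytest.warns(UserWarning, match="point dropped"):
            profiles = ag.build_distance_profile(records)
        assert profiles["X"].points["d"].tolist() == [0]

    def test_d0_anchor_rescales_to_one(self):
        records = [("Str", d, 0.05) for d in range(3)]
        records += [("X", d, 0.4 * 0.5**d) for d in range(3)]
        profiles = ag.build_distance_profile(records, anchor="d0")
        assert profiles["X"].points["value"].iloc[0] == pytest.approx(1.0)

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            ag.build_distance_profile([("X", 0, 0.1)], reference="Str")


class TestFitRetention:
    def _profile(self, values, sds=None):
        pts = pd.DataFrame(
            {
                "d": range(len(values)),
                "value": values,
                "sd": sds if sds is not None else [0.0] * len(values),
                "n": [3] * len(values),
            }
        )
        return ag.DistanceProfile(aga="X", reference="Str", points=pts)

    def test_exact_geometric_profile(self):
        fit = ag.fit_retention(self._profile([1.0, 0.5, 0.25]), n_boot=50, seed=0)
        assert fit.q == pytest.approx(0.5, abs=1e-6)
        assert fit.c == pytest.approx(1.0, abs=1e-6)

    def test_flat_profile_is_degenerate_q_one(self):
        fit = ag.fit_retention(self._profile([1.0, 1.0, 1.0, 1.0]), seed=0)
        assert fit.degenerate and fit.q == 1.0

    def test_needs_three_distances(self):
        with pytest.raises(ValueError):
            ag.fit_retention(self._profile([1.0, 0.5]))

    @pytest.mark.parametrize("q_true", [0.3, 0.5, 0.7])
    def test_recovers_q_within_ci_on_noisy_profiles(self, q_true):
        rng = np.random.default_rng(int(q_true * 100))
        hits = 0
        n_runs = 20
        for _ in range(n_runs):
            values = q_true ** np.arange(7) * np.exp(rng.normal(0, 0.05, 7))
            sds = 0.05 * values
            fit = ag.fit_retention(self._profile(values, sds), n_boot=100, rng=rng)
            if fit.q_ci[0] <= q_true <= fit.q_ci[1]:
                hits += 1
        assert hits >= 0.8 * n_runs

    def test_flat_truth_recovered_at_boundary(self):
        rng = np.random.default_rng(1)
        values = np.exp(rng.normal(0, 0.02, 7))
        fit = ag.fit_retention(self._profile(values, 0.02 * values), n_boot=100, rng=rng)
        assert fit.q > 0.9


class TestClassifyAga:
    def test_group_i_drug(self, model_protein, config):
        cluster = ag.model_cluster(model_protein, "E241D-E242D")
        preset = ag.get_preset("Str")
        table = ag.titrate_cluster(
            model_protein, cluster, preset, config, concentrations=[8.0]
        )
        st = ag.cluster_stat(table, cluster.label, {"concentration_um": 8.0})
        assert ag.classify_aga(st.ef_first, st.efnext) == "I"

    def test_group_ii_drug(self, model_protein, config):
        cluster = ag.model_cluster(model_protein, "E241D-E242D")
        preset = ag.get_preset("Sis")
        table = ag.titrate_cluster(
            model_protein, cluster, preset, config, concentrations=[8.0]
        )
        st = ag.cluster_stat(table, cluster.label, {"concentration_um": 8.0})
        assert ag.classify_aga(st.ef_first, st.efnext) == "II"

    def test_degenerate_inputs_unclassified(self):
        assert ag.classify_aga(0.0, 0.0) == "unclassified"
        assert ag.classify_aga(None, 0.3) == "unclassified"
        assert ag.classify_aga(math.nan, 0.3) == "unclassified"


def test_ram_mode_amplification_near_one(model_protein):
    """Independent (ram-strain) errors show no cluster amplification."""
    cluster = ag.model_cluster(model_protein, "E242D-E244D")
    species = ag.cluster_species(model_protein, cluster)
    config = SimConfig(n_ribosomes=1e9, seed=6, ram_rate=2e-3, noise_cv=0.0)
    params = AGAParams(
        name="ram", beta=0.0, q=0.5, weights={(242, "D"): 1.0, (244, "D"): 1.0}
    )
    counts = sample_counts(model_protein, params, config, species)
    table = ag.emit_intensity_table(counts, species, config, {"aga": "ram"})
    st = ag.cluster_stat(table, cluster.label, {})
    assert st.amplification == pytest.approx(1.0, rel=0.15)
    # observed cluster frequency matches the stochastic product
    product = ag.stochastic_expectation([st.ef_first, st.ef_second])
    assert st.ef_cluster == pytest.approx(product, rel=0.15)
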