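import numpy as np
import pandas as pd
import pytest

from aggregome.io import FRACTION_AGGREGATE
from aggregome.simulate import (
    SimulationConfig,
    evaluate_recovery,
    null_config,
    planted_config,
    simulate_annotations,
    simulate_counts,
    simulate_dataset,
    simulate_lfq,
    simulate_proteome,
    treatment_gainers,
)


class TestProteome:
    def test_equal_thresholds_symmetric_counts(self):
        cfg = null_config(seed=1, n_proteins=4000)
        truth = simulate_proteome(cfg)
        # identical thresholds and a shared latent uniform: flags coincide
        assert (truth["aggregates_control"] == truth["aggregates_treated"]).all()

    def test_steep_limit_is_hard_threshold(self):
        cfg = SimulationConfig(seed=2, n_proteins=500, aggregation_steepness=1e-9, n_gainers=None)
        truth = simulate_proteome(cfg)
        expected = truth["sigma"] > cfg.tau_control
        assert (truth["aggregates_control"] == expected).all()

    def test_lower_threshold_creates_gainers(self):
        base = SimulationConfig(seed=3, n_proteins=3000, n_gainers=None)
        lowered = SimulationConfig(
            seed=3, n_proteins=3000, n_gainers=None, tau_treated=base.tau_control - 1.0
        )
        n_base = len(treatment_gainers(simulate_proteome(base)))
        n_lower = len(treatment_gainers(simulate_proteome(lowered)))
        assert n_lower > n_base

    def test_exact_planting(self):
        truth = simulate_proteome(planted_config(seed=4, n_gainers=150))
        assert len(treatment_gainers(truth)) == 150
        # gainers never aggregate in the control condition
        gain = truth.loc[sorted(treatment_gainers(truth))]
        assert not gain["aggregates_control"].any()

    def test_sigma_consistency(self):
        truth = simulate_proteome(SimulationConfig(seed=5, n_proteins=200))
        np.testing.assert_allclose(
            truth["sigma"], np.log10(truth["abundance"] + 1) + truth["propensity_z"]
        )


class TestLfq:
    def test_null_effect_sides_match_in_distribution(self):
        cfg = null_config(seed=6, n_proteins=3000)
        table, design = simulate_lfq(simulate_proteome(cfg), cfg)
        agg = design.subset(FRACTION_AGGREGATE)
        case = table.intensities[agg.case_labels]
        ctrl = table.intensities[agg.control_labels]
        # same detection rate and intensity scale on both sides
        assert abs(case.notna().mean().mean() - ctrl.notna().mean().mean()) < 0.02
        assert abs(np.nanmean(np.log2(case)) - np.nanmean(np.log2(ctrl))) < 0.05

    def test_detection_monotone_in_intensity(self):
        cfg = SimulationConfig(seed=7, n_proteins=4000)
        truth = simulate_proteome(cfg)
        table, design = simulate_lfq(truth, cfg)
        # bin proteins by true abundance; detection frequency must not decrease
        wcl_cols = [s.label for s in design if s.fraction == "wcl"]
        det = table.intensities[wcl_cols].notna().mean(axis=1)
        bins = pd.qcut(np.log10(truth["abundance"]), 6, labels=False)
        rates = det.groupby(bins.to_numpy()).mean()
        assert (rates.diff().dropna() >= -0.02).all()

    def test_seed_reproducibility(self):
        cfg = planted_config(seed=8, n_proteins=300, n_gainers=20)
        t1, _ = simulate_lfq(simulate_proteome(cfg), cfg)
        t2, _ = simulate_lfq(simulate_proteome(cfg), cfg)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)

    def test_nonaggregators_mostly_missing_in_aggregate_fraction(self):
        cfg = SimulationConfig(seed=9, n_proteins=3000)
        truth = simulate_proteome(cfg)
        table, design = simulate_lfq(truth, cfg)
        agg_cols = design.subset(FRACTION_AGGREGATE).labels
        det = table.intensities[agg_cols].notna().mean(axis=1)
        non_agg = ~truth["aggregates_control"] & ~truth["aggregates_treated"]
        # the majority of non-aggregator cells fall below the detection limit
        assert det[non_agg.to_numpy()].mean() < 0.5


class TestCounts:
    def test_zero_dispersion_is_poisson_like(self):
        cfg = SimulationConfig(seed=10, n_proteins=2000, nb_dispersion=0.0)
        truth = simulate_proteome(cfg)
        counts = simulate_counts(truth, cfg, n_samples=40)
        mean = counts.mean(axis=1)
        var = counts.var(axis=1)
        big = mean > 50
        ratio = (var[big] / mean[big]).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_library_size_scales_totals(self):
        cfg = SimulationConfig(seed=11, n_proteins=2000)
        truth = simulate_proteome(cfg)
        small = simulate_counts(truth, cfg).to_numpy().mean()
        big_cfg = SimulationConfig(seed=11, n_proteins=2000, library_size=cfg.library_size * 2)
        big = simulate_counts(truth, big_cfg).to_numpy().mean()
        assert big / small == pytest.approx(2.0, rel=0.05)

    def test_seeded_reproducibility(self):
        cfg = SimulationConfig(seed=12, n_proteins=100)
        truth = simulate_proteome(cfg)
        pd.testing.assert_frame_equal(simulate_counts(truth, cfg), simulate_counts(truth, cfg))


class TestAnnotations:
    def test_null_odds_near_one(self):
        cfg = planted_config(seed=13, n_proteins=4000, n_gainers=300)
        truth = simulate_proteome(cfg)
        ors = [
            simulate_annotations(truth, 1.0, 400, seed=s)[1] for s in range(20)
        ]
        assert np.mean(ors) == pytest.approx(1.0, abs=0.15)

    def test_planted_odds_detected(self):
        from aggregome.enrichment import ContingencyTable2x2, chi_square

        cfg = planted_config(seed=14, n_proteins=4000, n_gainers=300)
        truth = simulate_proteome(cfg)
        sets, realized = simulate_annotations(truth, 5.0, 400, seed=0)
        members = sets.members("planted_set")
        gainers = treatment_gainers(truth)
        rest = set(truth.index) - gainers
        table = ContingencyTable2x2(
            len(gainers & members),
            len(gainers - members),
            len(rest & members),
            len(rest - members),
        )
        assert realized > 2.0
        assert chi_square(table)["p"] < 1e-4

    def test_set_size_respected_and_bounded(self):
        cfg = planted_config(seed=15, n_proteins=200, n_gainers=20)
        truth = simulate_proteome(cfg)
        sets, _ = simulate_annotations(truth, 2.0, 50, seed=0)
        assert len(sets.members("planted_set")) == 50
        with pytest.raises(ValueError):
            simulate_annotations(truth, 2.0, 500, seed=0)


class TestRecovery:
    def _truth(self):
        return pd.DataFrame(
            {
                "aggregates_control": [False, False, False, True],
                "aggregates_treated": [True, True, False, True],
            },
            index=["P1", "P2", "P3", "P4"],
        )

    def test_perfect_caller(self):
        calls = pd.DataFrame({"call": ["up", "up", "ns", "ns"]}, index=["P1", "P2", "P3", "P4"])
        res = evaluate_recovery(calls, self._truth())
        assert res["sensitivity"] == 1.0 and res["empirical_fdr"] == 0.0

    def test_no_calls_convention(self):
        calls = pd.DataFrame({"call": ["ns"] * 4}, index=["P1", "P2", "P3", "P4"])
        res = evaluate_recovery(calls, self._truth())
        assert res["sensitivity"] == 0.0 and res["empirical_fdr"] == 0.0

    def test_false_calls_counted(self):
        calls = pd.DataFrame({"call": ["up", "ns", "up", "up"]}, index=["P1", "P2", "P3", "P4"])
        res = evaluate_recovery(calls, self._truth())
        assert res["sensitivity"] == pytest.approx(0.5)
        assert res["empirical_fdr"] == pytest.approx(2 / 3)


def test_dataset_writer_round_trips(tmp_path):
    from aggregome.io import read_count_matrix, read_protein_groups, read_sample_design

    cfg = planted_config(seed=16, n_proteins=120, n_gainers=10)
    paths = simulate_dataset(cfg, tmp_path)
    design = read_sample_design(paths["design"])
    table = read_protein_groups(paths["protein_groups"], design)
    assert len(table) == 120
    counts = read_count_matrix(paths["counts"])
    assert counts.shape == (120, cfg.n_replicates)
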