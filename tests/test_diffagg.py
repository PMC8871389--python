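import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from aggregome.diffagg import (
    DifferentialCallConfig,
    ImputationConfig,
    adjust_bh,
    call_differential,
    differential_test,
    impute_missing,
    log2_transform,
    prefilter_identified,
    run_differential,
)
from aggregome.errors import InternalError
from aggregome.io import ProteinGroupTable, SampleDesign, SampleInfo
from conftest import make_log_matrix


def _table(values, design):
    n = len(values)
    meta = pd.DataFrame(
        {
            "gene_symbols": [()] * n,
            "is_contaminant": False,
            "is_reverse": False,
            "razor_unique_peptides": 2,
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="group_id"),
    )
    intensities = pd.DataFrame(
        np.asarray(values, dtype=float), index=meta.index, columns=design.labels
    )
    return ProteinGroupTable(meta=meta, intensities=intensities)


class TestLog2Transform:
    def test_values_and_detection_counts(self, small_design):
        table = _table([[8] * 8, [np.nan] * 8, [4, 4, np.nan, np.nan, 2, np.nan, np.nan, np.nan]], small_design)
        matrix = log2_transform(table, small_design)
        assert matrix.values.loc["P0", "case_1"] == 3.0
        counts = matrix.detection_counts()
        # the all-missing protein is retained with 0/0
        assert counts.loc["P1"].tolist() == [0, 0]
        assert counts.loc["P2"].tolist() == [2, 1]
        assert (counts.sum(axis=1) <= 8).all()

    def test_zero_is_internal_error(self, small_design):
        table = _table([[8] * 8], small_design)
        table.intensities.iloc[0, 0] = 0.0  # bypass the constructor check
        with pytest.raises(InternalError):
            log2_transform(table, small_design)


class TestPrefilter:
    @pytest.mark.parametrize(
        "case_n, ctrl_n, min_repeats, kept",
        [
            (1, 1, 2, False),  # one replicate per side is not enough
            (2, 0, 2, True),   # two on either side suffices (OR rule)
            (0, 2, 2, True),
            (0, 0, 0, True),   # min 0 keeps everything
        ],
    )
    def test_or_rule(self, small_design, case_n, ctrl_n, min_repeats, kept):
        row = [10.0 if i < case_n else np.nan for i in range(4)] + [
            10.0 if i < ctrl_n else np.nan for i in range(4)
        ]
        matrix = make_log_matrix([row], small_design)
        out = prefilter_identified(matrix, min_repeats)
        assert (len(out.values) == 1) is kept


class TestImputation:
    def test_complete_matrix_unchanged_for_any_seed(self, small_design, rng):
        matrix = make_log_matrix(rng.normal(20, 2, (30, 8)), small_design)
        for seed in (0, 99):
            out = impute_missing(matrix, ImputationConfig(seed=seed))
            pd.testing.assert_frame_equal(out.values, matrix.values)

    def test_single_cell_concentrates_at_downshifted_mean(self, small_design, rng):
        # Monte-Carlo oracle: the average of 100 draws from
        # N(mu - 1.8 sd, (0.3 sd)^2) lies within 3*(0.3 sd)/10 of its mean.
        values = rng.normal(25, 2, (200, 8))
        values[0, 0] = np.nan
        matrix = make_log_matrix(values, small_design)
        col = matrix.values["case_1"]
        mu, sd = col.mean(), col.std(ddof=1)
        out = impute_missing(matrix, ImputationConfig(seed=1))
        imputed = out.values.iloc[0, 0]
        assert abs(imputed - (mu - 1.8 * sd)) < 3 * (0.3 * sd) / np.sqrt(100)

    def test_seed_determinism(self, small_design, rng):
        values = rng.normal(20, 3, (50, 8))
        values[rng.uniform(size=values.shape) < 0.3] = np.nan
        matrix = make_log_matrix(values, small_design)
        a = impute_missing(matrix, ImputationConfig(seed=7))
        b = impute_missing(matrix, ImputationConfig(seed=7))
        assert a.values.equals(b.values)  # bit-identical

    def test_sparse_sample_falls_back_to_global(self, small_design, rng):
        values = rng.normal(20, 3, (5, 8))
        values[:4, 0] = np.nan  # one observed value in case_1
        values[4, 1] = np.nan
        matrix = make_log_matrix(values, small_design)
        with pytest.warns(UserWarning, match="global"):
            out = impute_missing(matrix, ImputationConfig(seed=0))
        assert out.mask.all().all()


class TestDifferentialTest:
    def test_identical_groups(self, small_design):
        matrix = make_log_matrix([[5.0] * 8], small_design)
        res = differential_test(matrix)
        assert res.loc["P0", "t"] == 0.0
        assert res.loc["P0", "p"] == 1.0
        assert res.loc["P0", "log2fc"] == 0.0

    def test_label_swap_antisymmetry(self, small_design, rng):
        values = rng.normal(20, 2, (40, 8))
        matrix = make_log_matrix(values, small_design)
        res = differential_test(matrix)
        swapped = SampleDesign(
            [
                SampleInfo(
                    label=s.label,
                    condition="control" if s.condition == "case" else "case",
                    replicate=s.replicate,
                )
                for s in small_design
            ]
        )
        res_sw = differential_test(make_log_matrix(values, swapped), swapped)
        np.testing.assert_allclose(res["log2fc"], -res_sw["log2fc"])
        np.testing.assert_allclose(res["t"], -res_sw["t"])
        np.testing.assert_allclose(res["p"], res_sw["p"])

    def test_two_unit_shift(self, small_design, rng):
        jitter = rng.normal(0, 1e-3, 8)
        matrix = make_log_matrix([np.r_[np.full(4, 5.0), np.full(4, 3.0)] + jitter], small_design)
        res = differential_test(matrix)
        assert res.loc["P0", "log2fc"] == pytest.approx(2.0, abs=0.01)
        assert res.loc["P0", "p"] < 1e-6


def _bh_bruteforce(p):
    """Independent step-up oracle: sort, scale by m/rank, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_known_values(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @given(
        p=arrays(
            float,
            st.integers(1, 200),
            elements=st.floats(0, 1, allow_nan=False, allow_subnormal=False),
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_bruteforce(self, p):
        np.testing.assert_allclose(adjust_bh(p), _bh_bruteforce(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=500)
        assert (adjust_bh(p) >= p - 1e-15).all()


class TestCallRules:
    @pytest.mark.parametrize(
        "p_adj, log2fc, n_case, n_ctrl, expected",
        [
            (0.04, 1.5, 3, 4, "up"),
            (0.04, 1.5, 1, 4, "ns"),   # too few detected case replicates
            (0.2, 3.0, 4, 4, "ns"),    # not significant
            (0.04, -1.5, 0, 3, "down"),
            (0.04, -1.5, 4, 1, "ns"),  # down needs detected control replicates
            (0.05, 1.0, 2, 2, "up"),   # boundaries are inclusive
        ],
    )
    def test_gates(self, p_adj, log2fc, n_case, n_ctrl, expected):
        results = pd.DataFrame({"log2fc": [log2fc], "p_adj": [p_adj]}, index=["P0"])
        detection = pd.DataFrame(
            {"n_detected_case": [n_case], "n_detected_control": [n_ctrl]}, index=["P0"]
        )
        out = call_differential(results, detection, DifferentialCallConfig())
        assert out.loc["P0", "call"] == expected


class TestPipelineInvariants:
    def test_complete_data_is_seed_independent(self, small_design, rng):
        table = _table(2.0 ** rng.normal(20, 2, (60, 8)), small_design)
        a = run_differential(table, small_design, ImputationConfig(seed=1, n_draws=5))
        b = run_differential(table, small_design, ImputationConfig(seed=2, n_draws=100))
        pd.testing.assert_frame_equal(a, b)

    def test_label_swap_swaps_calls(self, small_design, rng):
        values = 2.0 ** rng.normal(20, 2, (300, 8))
        shift = rng.uniform(size=300) < 0.1
        values[shift, :4] *= 2.0 ** rng.uniform(1.5, 3, shift.sum())[:, None]
        table = _table(values, small_design)
        res = run_differential(table, small_design, ImputationConfig(seed=0))
        swapped = SampleDesign(
            [
                SampleInfo(
                    label=s.label,
                    condition="control" if s.condition == "case" else "case",
                    replicate=s.replicate,
                )
                for s in small_design
            ]
        )
        res_sw = run_differential(table, swapped, ImputationConfig(seed=0))
        assert set(res.index[res["call"] == "up"]) == set(res_sw.index[res_sw["call"] == "down"])
        assert set(res.index[res["call"] == "down"]) == set(res_sw.index[res_sw["call"] == "up"])
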