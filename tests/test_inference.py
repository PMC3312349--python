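"""Permutation tests, Holm adjustment, envelopes, diversity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfbiomass import (
    BiomassField,
    CascadeSpec,
    analyze_field,
    generate_cascade,
    holm_adjust,
    kendall_correlation,
    pairwise_week_tests,
    permutation_test_dq,
    quantile_regression_dh,
    randomization_envelope,
    shannon_index,
)


SKEW = (0.4, 0.3, 0.2, 0.1)
STEEP = (0.55, 0.25, 0.15, 0.05)
UNIFORM = (0.25, 0.25, 0.25, 0.25)


def cascade_spectra(weights, n, levels=6, seed0=0):
    return [analyze_field(generate_cascade(
        CascadeSpec(weights, levels=levels, mode="microcanonical", seed=seed0 + i)))
        for i in range(n)]


class TestShannon:
    @pytest.mark.parametrize("abund,expected", [
        ((1, 1, 1, 1), 2.0),
        ((5,), 0.0),
        ((8, 4, 2, 2), 1.75),
    ])
    def test_hand_values(self, abund, expected):
        assert shannon_index(abund) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0, 0])


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(0)
        group = [rng.normal(1.8, 0.05, 21) for _ in range(4)]
        res = permutation_test_dq(group, [g.copy() for g in group],
                                  n_perm=500, seed=1)
        assert res.observed_stat == 0.0
        assert res.p_value == 1.0

    def test_zero_variance_everywhere_rejected(self):
        flat = [np.full(21, 2.0) for _ in range(3)]
        with pytest.raises(ValueError, match="zero variance"):
            permutation_test_dq(flat, [f.copy() for f in flat], n_perm=10, seed=0)

    def test_separated_ensembles_detected(self):
        a = cascade_spectra(UNIFORM, 5, levels=8, seed0=0)
        b = cascade_spectra(STEEP, 5, levels=8, seed0=100)
        res = permutation_test_dq(a, b, n_perm=10_000, seed=3)
        assert res.p_value <= 0.01

    def test_null_p_values_super_uniform(self):
        # same-ensemble groups: rejection at 0.05 should stay near 0.05
        rej = 0
        n_sims = 60
        for i, ss in enumerate(np.random.SeedSequence(7).spawn(n_sims)):
            seeds = ss.generate_state(11)
            specs = [analyze_field(generate_cascade(
                CascadeSpec(SKEW, levels=5, mode="microcanonical",
                            seed=int(s % 2**31))))
                for s in seeds[:10]]
            res = permutation_test_dq(specs[:5], specs[5:], n_perm=199,
                                      seed=int(seeds[10] % 2**31))
            rej += res.p_value <= 0.05
        assert rej / n_sims <= 0.09 + 2.5 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_p_value_floor(self):
        a = cascade_spectra(UNIFORM, 2, levels=5, seed0=0)
        b = cascade_spectra(STEEP, 2, levels=5, seed0=50)
        res = permutation_test_dq(a, b, n_perm=100, seed=0)
        assert res.p_value >= 1 / 101


class TestHolm:
    def test_hand_examples(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.03, 0.04]),
                                   [0.03, 0.06, 0.06])
        np.testing.assert_allclose(holm_adjust([0.5, 0.9]), [1.0, 1.0])
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_dominates_raw_and_orders_consistently(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([])


class TestPairwise:
    def test_row_count_and_adjustment(self):
        groups = [(f"w{i}", cascade_spectra(SKEW, 2, levels=5, seed0=10 * i))
                  for i in range(3)]
        table = pairwise_week_tests(groups, n_perm=99, seed=1)
        assert len(table) == 3
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)

    def test_separated_extremes_significant_with_enough_plates(self):
        groups = [("early", cascade_spectra(STEEP, 8, levels=6, seed0=0)),
                  ("mid", cascade_spectra(SKEW, 8, levels=6, seed0=100)),
                  ("late", cascade_spectra(UNIFORM, 8, levels=6, seed0=200))]
        table = pairwise_week_tests(groups, n_perm=9999, seed=5)
        row = table[(table.label_a == "early") & (table.label_b == "late")]
        assert float(row["p_adj"].iloc[0]) <= 0.01


class TestEnvelope:
    def test_structured_cascade_flagged_nonrandom(self):
        field = generate_cascade(CascadeSpec(STEEP, levels=6,
                                             mode="microcanonical", seed=2))
        env = randomization_envelope(field, n_rep=99, alpha=0.01, seed=4,
                                     gradient="never")
        # the multiplicative correlation structure is destroyed by
        # shuffling, so the observed curve escapes the band over most q
        assert env.any_outside
        assert env.outside.sum() >= len(env.q_grid) // 2

    def test_iid_field_not_flagged(self):
        field = BiomassField(np.random.default_rng(3).uniform(0.5, 1.5, (64, 64)))
        env = randomization_envelope(field, n_rep=199, alpha=0.01, seed=5)
        assert not env.any_outside

    def test_constant_field_degenerate_band(self):
        env = randomization_envelope(BiomassField(np.full((64, 64), 2.0)),
                                     n_rep=5, alpha=0.01, seed=0)
        assert not env.any_outside
        np.testing.assert_allclose(env.lower, env.observed)
        np.testing.assert_allclose(env.upper, env.observed)

    def test_bounds_ordered(self):
        field = generate_cascade(CascadeSpec(SKEW, levels=5,
                                             mode="microcanonical", seed=9))
        env = randomization_envelope(field, n_rep=49, seed=1)
        assert np.all(env.lower <= env.upper)


class TestKendall:
    def test_perfect_discordance(self):
        tau, _ = kendall_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert tau == pytest.approx(-1.0)

    def test_weekly_table_example(self):
        # brute-force concordant/discordant count over the 15 pairs gives -0.6
        x = [1.780, 1.881, 1.897, 1.943, 1.957, 1.985]
        y = [3.57, 2.69, 2.26, 2.11, 2.77, 1.62]
        tau, _ = kendall_correlation(x, y)
        assert tau == pytest.approx(-0.6)

    def test_independent_data_rarely_significant(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            tau, p = kendall_correlation(rng.normal(size=50), rng.normal(size=50))
            hits += p <= 0.05
        assert hits <= 4

    def test_all_tied_rejected(self):
        with pytest.raises(ValueError):
            kendall_correlation([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestQuantileRegression:
    def test_exact_line_recovered_at_every_level(self):
        d1 = np.linspace(1.6, 2.0, 12)
        qfit = quantile_regression_dh(d1, -3.0 * d1 + 8.0)
        np.testing.assert_allclose(qfit.slopes, -3.0, atol=1e-6)

    def test_median_fit_recovers_negative_slope_under_noise(self):
        rng = np.random.default_rng(6)
        d1 = rng.uniform(1.6, 2.0, 80)
        h = -4.0 * d1 + 10.0 + rng.normal(0, 0.3, 80)
        qfit = quantile_regression_dh(d1, h, tau_levels=[0.5],
                                      se="bootstrap", n_boot=100, seed=1)
        assert abs(qfit.slopes[0] + 4.0) < 3 * qfit.slope_ses[0] + 0.5

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            quantile_regression_dh(np.full(10, 1.8), np.arange(10.0))

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            quantile_regression_dh(np.linspace(1, 2, 10), np.arange(10.0),
                                   tau_levels=[0.0, 0.5])
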