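"""Generators: cascades, fBm surfaces, shuffles, succession series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfbiomass import (
    BiomassField,
    CascadeSpec,
    generate_cascade,
    generate_community,
    generate_fbm_surface,
    generate_succession_series,
    power_spectrum,
    shuffle_field,
    theoretical_dq,
)


SKEW = (0.4, 0.3, 0.2, 0.1)
STEEP = (0.55, 0.25, 0.15, 0.05)
UNIFORM = (0.25, 0.25, 0.25, 0.25)


class TestCascade:
    def test_uniform_weights_give_flat_field(self):
        f = generate_cascade(CascadeSpec(UNIFORM, levels=4, mode="deterministic"))
        assert f.shape == (16, 16)
        np.testing.assert_allclose(f.values, 1.0 / 256)

    def test_two_level_deterministic_extremes(self):
        # cell values are two-factor products of the weights
        f = generate_cascade(CascadeSpec(SKEW, levels=2, mode="deterministic"))
        products = np.multiply.outer(np.array(SKEW), np.array(SKEW))
        assert f.values.max() == pytest.approx(0.16)
        assert f.values.min() == pytest.approx(0.01)
        np.testing.assert_allclose(np.sort(f.values.ravel()), np.sort(products.ravel()))

    def test_deterministic_reading_order(self):
        f = generate_cascade(CascadeSpec(SKEW, levels=1, mode="deterministic"))
        np.testing.assert_allclose(f.values, [[0.4, 0.3], [0.2, 0.1]])

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_microcanonical_preserves_value_multiset(self, seed):
        det = generate_cascade(CascadeSpec(SKEW, levels=8, mode="deterministic"))
        mic = generate_cascade(CascadeSpec(SKEW, levels=8, mode="microcanonical", seed=seed))
        np.testing.assert_allclose(
            np.sort(mic.values.ravel()), np.sort(det.values.ravel()), rtol=1e-12)

    @pytest.mark.parametrize("mode,seed", [
        ("deterministic", None), ("microcanonical", 7), ("canonical", 7)])
    def test_mass_conservation(self, mode, seed):
        f = generate_cascade(CascadeSpec(SKEW, levels=10, mode=mode, seed=seed))
        assert abs(f.total_mass() - 1.0) < 1e-9

    def test_canonical_all_positive(self):
        f = generate_cascade(CascadeSpec(SKEW, levels=7, mode="canonical", seed=3))
        assert f.values.min() > 0

    def test_dyadic_aggregation_recovers_coarser_cascade(self, det_cascade_l6):
        # box masses at size 2^(6-k) equal the level-k cascade exactly
        coarse = generate_cascade(CascadeSpec(SKEW, levels=3, mode="deterministic"))
        eps = 2 ** 3
        agg = det_cascade_l6.values.reshape(8, eps, 8, eps).sum(axis=(1, 3))
        np.testing.assert_allclose(agg, coarse.values, rtol=1e-12)

    def test_seeded_reproducibility(self):
        spec = CascadeSpec(SKEW, levels=6, mode="canonical", seed=11)
        np.testing.assert_array_equal(
            generate_cascade(spec).values, generate_cascade(spec).values)

    @pytest.mark.parametrize("bad", [
        dict(weights=(0.5, 0.3, 0.3, 0.1), levels=3),
        dict(weights=(0.5, 0.5, 0.1, -0.1), levels=3),
        dict(weights=SKEW, levels=0),
        dict(weights=SKEW, levels=3, mode="grandcanonical"),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            CascadeSpec(**bad)


class TestTheoreticalDq:
    def test_uniform_weights_all_q(self):
        for q in (-5, -1, 0, 1, 2, 5):
            assert theoretical_dq(UNIFORM, q) == pytest.approx(2.0)

    @pytest.mark.parametrize("q,expected", [
        (2.0, -np.log2(0.30)),        # 1.73697
        (1.0, 1.8464393446710154),    # base-2 entropy of the weights
        (5.0, 1.5663361416302486),
        (-1.0, 2.1904108919704655),
    ])
    def test_skew_weights_closed_form(self, q, expected):
        assert theoretical_dq(SKEW, q) == pytest.approx(expected, abs=1e-9)

    def test_zero_weight_negative_q_rejected(self):
        with pytest.raises(ValueError):
            theoretical_dq((0.5, 0.3, 0.2, 0.0), -1.0)

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_nonincreasing_in_q(self, raw):
        w = np.array(raw) / np.sum(raw)
        qs = np.arange(-5, 5.5, 0.5)
        dq = np.array([theoretical_dq(w, q) for q in qs])
        assert np.all(np.diff(dq) <= 1e-12)


class TestFbmSurface:
    def test_deterministic_for_fixed_seed(self):
        a = generate_fbm_surface(2.0, 64, seed=5)
        b = generate_fbm_surface(2.0, 64, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonnegative_and_sized(self):
        f = generate_fbm_surface(1.5, 128, seed=0)
        assert f.shape == (128, 128)
        assert f.values.min() == 0.0

    @pytest.mark.parametrize("beta", [0.0, 2.5])
    def test_spectral_exponent_recovery(self, beta):
        errs = [power_spectrum(generate_fbm_surface(beta, 256, seed=s)).beta_hat - beta
                for s in range(10)]
        assert abs(np.median(errs)) < 0.3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_fbm_surface(-0.5, 64, seed=0)
        with pytest.raises(ValueError):
            generate_fbm_surface(1.0, 100, seed=0)


class TestShuffle:
    def test_value_multiset_and_mass_conserved(self, iid_field):
        out = shuffle_field(iid_field, seed=1)
        np.testing.assert_array_equal(
            np.sort(out.values.ravel()), np.sort(iid_field.values.ravel()))

    def test_constant_field_unchanged(self):
        f = BiomassField(np.full((8, 8), 3.0))
        np.testing.assert_array_equal(shuffle_field(f, seed=0).values, f.values)

    def test_seeded_reproducibility(self, iid_field):
        a = shuffle_field(iid_field, seed=9)
        b = shuffle_field(iid_field, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestCommunityAndSuccession:
    def test_community_richness_and_h_bounds(self):
        c = generate_community(20, evenness=0.8, seed=0)
        assert 1 <= c.richness <= 20
        assert 0.0 <= c.shannon_h <= np.log2(c.richness)

    def test_series_structure_and_reproducibility(self):
        s1 = generate_succession_series(n_weeks=3, plates_per_week=2, levels=5, seed=4)
        s2 = generate_succession_series(n_weeks=3, plates_per_week=2, levels=5, seed=4)
        assert s1.n_weeks == 3
        assert all(len(p) == 2 for p in s1.plates)
        np.testing.assert_array_equal(s1.plates[1][0].values, s2.plates[1][0].values)

    def test_theoretical_d1_endpoints_and_monotonicity(self):
        s = generate_succession_series(n_weeks=6, start_weights=STEEP,
                                       plates_per_week=1, levels=4, seed=0)
        d1 = s.theoretical_d1()
        assert d1[0] == pytest.approx(1.601, abs=5e-4)
        assert d1[-1] == pytest.approx(2.0, abs=1e-12)
        assert np.all(np.diff(d1) >= -1e-12)

    def test_shannon_h_trends_down(self):
        s = generate_succession_series(n_weeks=6, plates_per_week=1, levels=4, seed=1)
        h = [c.shannon_h for c in s.communities]
        tau = np.polyfit(range(6), h, 1)[0]
        assert tau < 0

    def test_too_few_weeks_rejected(self):
        with pytest.raises(ValueError):
            generate_succession_series(n_weeks=1, plates_per_week=1, levels=4, seed=0)
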