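"""Estimator correctness: micro-examples, brute-force oracle equivalence
at p=1, channel-permutation and amplitude invariance, entropy bounds."""

import math

import numpy as np
import pytest

from mventropy import (
    CoarseSeries,
    MultichannelSeries,
    coarse_grain,
    fuzzy_similarity,
    gen_wgn,
    mv_dispersion_entropy,
    mv_fuzzy_entropy,
    mv_increment_entropy,
    mv_permutation_entropy,
    mv_rc_fuzzy_entropy,
    mv_sample_entropy,
    multiscale_curve,
    rc_fuzzy_similarity,
    zscore_channels,
)
from mventropy.containers import DegenerateInputError, default_params
from mventropy.estimators import (
    dispersion_digitize,
    increment_series,
    increment_word,
    ncdf_map,
    pattern_distribution,
)

import oracles


def coarse(values):
    return CoarseSeries(np.asarray(values, dtype=float), scale=1)


class TestFuzzySimilarity:
    def test_boundary_is_one(self):
        assert fuzzy_similarity(0.15, 0.15) == 1.0

    def test_double_tolerance_is_half(self):
        assert fuzzy_similarity(0.30, 0.15) == pytest.approx(0.5, abs=1e-15)

    def test_zero_distance(self):
        assert fuzzy_similarity(0.0, 0.15) == 1.0

    def test_lambda_one_reduces_to_plain(self):
        for dist in (0.0, 0.1, 0.15, 0.2, 1.0):
            assert rc_fuzzy_similarity(dist, 0.15, 1.0) == fuzzy_similarity(dist, 0.15)

    def test_relaxed_threshold(self):
        r, lam = 0.15, 0.8
        assert rc_fuzzy_similarity(lam * r, r, lam) == 1.0
        assert rc_fuzzy_similarity(lam * r + r, r, lam) == pytest.approx(0.5, abs=1e-15)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            rc_fuzzy_similarity(-0.1, 0.15, 1.0)


class TestOracleEquivalence:
    """p=1 reduction must agree with naive univariate implementations."""

    def test_sample_entropy(self):
        x = gen_wgn(1, 200, 3).values[0]
        ours = mv_sample_entropy(coarse(x), default_params("mvmse"))
        ref = oracles.univariate_sample_entropy(x, 2, 1, 0.15)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_fuzzy_entropy(self):
        x = gen_wgn(1, 200, 4).values[0]
        ours = mv_fuzzy_entropy(coarse(x), default_params("mvmfe"))
        ref = oracles.univariate_fuzzy_entropy(x, 2, 1, 0.15)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_rc_fuzzy_entropy_scale_one(self):
        x = gen_wgn(1, 200, 5).values[0]
        ours = mv_rc_fuzzy_entropy(
            MultichannelSeries(x), 1, default_params("rcmvmfe")
        )
        ref = oracles.univariate_fuzzy_entropy(x, 2, 1, 0.15, lam=0.8)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_permutation_entropy(self):
        x = gen_wgn(1, 500, 6).values[0]
        ours = mv_permutation_entropy(coarse(x), default_params("mvmpe"))
        ref = oracles.univariate_permutation_entropy(x, 3, 1)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_dispersion_entropy(self):
        x = gen_wgn(1, 500, 7).values[0]
        ours = mv_dispersion_entropy(coarse(x), default_params("mvmde"))
        ref = oracles.univariate_dispersion_entropy(x, 3, 1, 3)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_increment_entropy(self):
        x = gen_wgn(1, 300, 8).values[0]
        ours = mv_increment_entropy(coarse(x), default_params("mvmie"))
        ref = oracles.univariate_increment_entropy(x, 3, 1, 4)
        assert ours == pytest.approx(ref, abs=1e-10)


class TestSampleEntropy:
    def test_undefined_on_zero_matches(self):
        # widely spaced ramp: no two templates within r
        x = np.arange(0.0, 20.0)
        out = mv_sample_entropy(coarse(x), default_params("mvmse"))
        assert math.isnan(out)

    def test_fuzzy_finite_where_sample_undefined(self):
        x = np.arange(0.0, 20.0)
        assert math.isfinite(mv_fuzzy_entropy(coarse(x), default_params("mvmfe")))

    def test_too_few_vectors(self):
        with pytest.raises(DegenerateInputError):
            mv_sample_entropy(coarse([1.0, 2.0, 3.0, 4.0]), default_params("mvmse"))


class TestRCmvMFE:
    def test_collapses_to_mvmfe_at_scale_one_lambda_one(self, wgn_pair):
        params = default_params("rcmvmfe", lambda_adj=1.0)
        z = zscore_channels(wgn_pair)
        a = mv_rc_fuzzy_entropy(z, 1, params)
        b = mv_fuzzy_entropy(coarse_grain(z, 1), params)
        assert a == pytest.approx(b, abs=1e-12)

    def test_uses_all_offsets(self, wgn_pair):
        # at s=2 the value must differ from the single-offset computation
        params = default_params("rcmvmfe")
        z = zscore_channels(wgn_pair)
        rc = mv_rc_fuzzy_entropy(z, 2, params)
        single = mv_fuzzy_entropy(coarse_grain(z, 2), default_params("mvmfe", lambda_adj=0.8))
        assert rc != pytest.approx(single, abs=1e-12)


class TestPermutationEntropy:
    def test_hand_enumeration(self):
        # windows (3,1,2),(1,2,5),(2,5,4): three distinct patterns
        out = mv_permutation_entropy(
            coarse([3.0, 1.0, 2.0, 5.0, 4.0]), default_params("mvmpe")
        )
        assert out == pytest.approx(math.log(3), abs=1e-12)

    def test_monotone_series_zero(self):
        out = mv_permutation_entropy(coarse(np.arange(50.0)), default_params("mvmpe"))
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_upper_bound(self, tri_series):
        params = default_params("mvmpe")
        out = mv_permutation_entropy(coarse_grain(tri_series, 1), params)
        assert out <= math.log(math.factorial(params.embed_m)) + 1e-12


class TestNCDFAndDigitize:
    def test_mean_maps_to_half(self):
        x = coarse([1.0, 2.0, 3.0, 4.0, 5.0])
        y = ncdf_map(x)
        assert y[0, 2] == pytest.approx(0.5, abs=1e-12)

    def test_one_sd_above_mean(self):
        vals = np.array([0.0, 1.0, -1.0, 2.0, -2.0])
        y = ncdf_map(coarse(vals))
        from scipy.stats import norm

        sd = vals.std(ddof=1)
        assert y[0, 3] == pytest.approx(norm.cdf(2.0 / sd), abs=1e-12)

    def test_outputs_in_open_interval(self, rng):
        y = ncdf_map(coarse(rng.standard_normal(1000)))
        assert np.all((y > 0) & (y < 1))

    @pytest.mark.parametrize("y,expected", [(0.4, 2), (0.999, 3), (0.01, 1)])
    def test_digitize_examples(self, y, expected):
        assert dispersion_digitize(y, 3) == expected

    def test_digitize_rejects_outside(self):
        with pytest.raises(ValueError):
            dispersion_digitize(1.0, 3)

    def test_constant_channel_rejected(self):
        with pytest.raises(DegenerateInputError):
            ncdf_map(coarse(np.ones(10)))


class TestDispersionEntropy:
    def test_upper_bound(self, tri_series):
        params = default_params("mvmde")
        out = mv_dispersion_entropy(coarse_grain(tri_series, 1), params)
        assert out <= params.embed_m * math.log(params.classes_c) + 1e-12

    def test_combination_cap(self):
        big = CoarseSeries(np.random.default_rng(0).standard_normal((40, 50)), 1)
        with pytest.raises(ValueError, match="cap"):
            mv_dispersion_entropy(big, default_params("mvmde"))


class TestIncrementEntropy:
    def test_increment_series(self):
        out = increment_series(coarse([1.0, 3.0, 2.0, 2.0]))
        assert np.allclose(out.values, [[2.0, -1.0, 0.0]])

    def test_zero_window_word(self):
        assert increment_word(np.zeros(2), 4) == ((0, 0), (0, 0))

    def test_signs(self):
        word = increment_word(np.array([2.0, -1.0, 0.0]), 4)
        assert tuple(s for s, _ in word) == (1, -1, 0)

    def test_word_matches_oracle(self):
        window = np.array([2.0, -1.0, 0.0])
        assert increment_word(window, 4) == oracles.increment_word(window, 4)

    def test_constant_series_zero_entropy(self):
        # constant increments: a linear ramp gives a single word
        out = mv_increment_entropy(coarse(np.arange(50.0)), default_params("mvmie"))
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_upper_bound(self, tri_series):
        params = default_params("mvmie")
        out = mv_increment_entropy(coarse_grain(tri_series, 1), params)
        bound = params.embed_m * math.log(2 * (params.resolution_R + 1) + 1)
        assert out <= bound + 1e-12


class TestSharedInvariants:
    """Channel-permutation behavior.

    Pattern-counting estimators pool per-channel counts, so reordering
    channels is an exact no-op. The composite-vector family is exactly
    symmetric at dimension m, but the pooled (m+1)-extension compares
    vectors from different channel-extension families positionally, so the
    full entropy is only approximately permutation invariant; the
    approximate checks below use tolerances far above float noise but far
    below any entropy difference the estimators are used to detect.
    """

    @pytest.mark.parametrize("name,fn", [("mvmpe", mv_permutation_entropy), ("mvmie", mv_increment_entropy)])
    def test_pattern_counters_exactly_invariant(self, tri_series, name, fn):
        params = default_params(name)
        z = zscore_channels(tri_series)
        a = fn(coarse_grain(z, 1), params)
        b = fn(coarse_grain(MultichannelSeries(z.values[[2, 0, 1]]), 1), params)
        assert a == pytest.approx(b, abs=1e-12)

    def test_phi_m_exactly_invariant(self):
        from mventropy._kernels import phi_fuzzy, phi_hard
        from mventropy.core import embed_composite

        z = zscore_channels(gen_wgn(3, 400, 2))
        zp = MultichannelSeries(z.values[[2, 0, 1]])
        a = embed_composite(coarse_grain(z, 1), 2, 1)
        b = embed_composite(coarse_grain(zp, 1), 2, 1)
        assert phi_hard(a, 0.15) == pytest.approx(phi_hard(b, 0.15), abs=1e-12)
        assert phi_fuzzy(a, 0.15, 0.8) == pytest.approx(phi_fuzzy(b, 0.15, 0.8), abs=1e-12)

    @pytest.mark.parametrize(
        "name,tol",
        [("mvmfe", 0.15), ("mvmde", 0.05)],
    )
    def test_composite_family_approximately_invariant(self, name, tol):
        fn = {"mvmfe": mv_fuzzy_entropy, "mvmde": mv_dispersion_entropy}[name]
        params = default_params(name)
        for seed in range(3):
            z = zscore_channels(gen_wgn(2, 1000, seed))
            a = fn(coarse_grain(z, 1), params)
            b = fn(coarse_grain(MultichannelSeries(z.values[[1, 0]]), 1), params)
            assert a == pytest.approx(b, abs=tol)

    def test_rcmvmfe_approximately_invariant(self):
        params = default_params("rcmvmfe")
        for seed in range(3):
            z = zscore_channels(gen_wgn(2, 1000, seed))
            a = mv_rc_fuzzy_entropy(z, 2, params)
            b = mv_rc_fuzzy_entropy(MultichannelSeries(z.values[[1, 0]]), 2, params)
            assert a == pytest.approx(b, abs=0.1)

    @pytest.mark.parametrize("name", ["mvmse", "mvmfe", "rcmvmfe", "mvmpe", "mvmde", "mvmie"])
    def test_amplitude_invariance(self, tri_series, name):
        params = default_params(name, max_scale=3)
        scaled = MultichannelSeries(tri_series.values * np.array([[5.0], [0.2], [1.0]]))
        a = multiscale_curve(tri_series, name, params).values
        b = multiscale_curve(scaled, name, params).values
        assert np.allclose(a, b, atol=1e-9, equal_nan=True)

    @pytest.mark.parametrize("name", ["mvmpe", "mvmde", "mvmie"])
    def test_pattern_distribution_normalizes(self, tri_series, name):
        params = default_params(name)
        freqs = pattern_distribution(coarse_grain(tri_series, 2), name, params)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(freqs > 0)


class TestMultiscaleCurve:
    def test_single_scale_matches_direct(self, wgn_pair):
        params = default_params("mvmfe", max_scale=1)
        curve = multiscale_curve(wgn_pair, "mvmfe", params)
        direct = mv_fuzzy_entropy(coarse_grain(zscore_channels(wgn_pair), 1), params)
        assert curve[1] == pytest.approx(direct, abs=1e-12)

    def test_degenerate_scales_marked_not_raised(self):
        s = gen_wgn(2, 40, 0)
        curve = multiscale_curve(s, "mvmse", default_params("mvmse", max_scale=20))
        assert curve.values.size == 20
        assert not curve.defined[-1]  # scale 20 leaves 2 samples: undefined

    def test_unknown_algorithm(self, wgn_pair):
        with pytest.raises(ValueError):
            multiscale_curve(wgn_pair, "nope", default_params("mvmse"))
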