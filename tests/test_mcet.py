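import math

import numpy as np
import pytest

import oracles
from hetmcet import (
    DegenerateInputError,
    EstimatorSpec,
    Histogram,
    MCETConfig,
    apply_threshold,
    classical_config,
    compute_histogram,
    confusion,
    cross_entropy_objective,
    enumerate_heterogeneous_configs,
    enumerate_homogeneous_configs,
    find_threshold,
    jaccard,
    sweep,
)
from hetmcet.histogram_io import BinaryMask, GrayImage


def delta_histogram(**level_counts) -> Histogram:
    counts = np.zeros(256, dtype=np.int64)
    for level, count in level_counts.items():
        counts[int(level.lstrip("g"))] = count
    return Histogram(counts)


TWO_DELTA = delta_histogram(g50=100, g200=100)


def spec_tuple(spec: EstimatorSpec):
    return (spec.approach, spec.q, spec.d_half)


class TestObjective:
    def test_unit_means_give_zero(self, rng, histogram_factory):
        hist = histogram_factory(rng)
        assert cross_entropy_objective(hist, 100, 1.0, 1.0) == 0.0

    def test_single_occupied_level_closed_form(self):
        hist = delta_histogram(g29=7)  # internal level 30
        # all mass in the lower mode: n(t) = -i0 * n * log(mu1)
        assert cross_entropy_objective(hist, 40, 3.0, 2.0) == pytest.approx(
            -30 * 7 * math.log(3.0)
        )

    def test_two_delta_direct_summation(self):
        hist = delta_histogram(g50=100, g200=100)  # internal 51, 201
        expected = -51 * 100 * math.log(51) - 201 * 100 * math.log(201)
        assert cross_entropy_objective(hist, 51, 51.0, 201.0) == pytest.approx(expected)

    def test_matches_bruteforce_on_random_histograms(self, rng, histogram_factory):
        for _ in range(20):
            hist = histogram_factory(rng)
            t = int(rng.integers(1, 256))
            mu1, mu2 = rng.uniform(1, 256, size=2)
            assert cross_entropy_objective(hist, t, mu1, mu2) == pytest.approx(
                oracles.brute_objective(hist.counts, t, mu1, mu2), rel=1e-12
            )

    def test_nonpositive_mean_is_invalid_candidate(self, rng, histogram_factory):
        hist = histogram_factory(rng)
        assert cross_entropy_objective(hist, 100, 0.0, 5.0) == math.inf
        assert cross_entropy_objective(hist, 100, 5.0, -1.0) == math.inf


class TestFindThreshold:
    def test_two_delta_classical_smallest_plateau_minimizer(self):
        result = find_threshold(TWO_DELTA, classical_config())
        assert result.t_star == 50
        assert result.mu1 == pytest.approx(51.0)
        assert result.mu2 == pytest.approx(201.0)

    def test_two_delta_mask_isolates_upper_delta(self):
        img = GrayImage(np.array([[50] * 10, [200] * 10]))
        result = find_threshold(compute_histogram(img), classical_config())
        mask = apply_threshold(img, result.t_star)
        gt = BinaryMask(np.array([[0] * 10, [1] * 10]))
        assert jaccard(confusion(mask, gt)) == 1.0

    def test_two_delta_heterogeneous_separates_the_deltas(self):
        for config in enumerate_heterogeneous_configs():
            t = find_threshold(TWO_DELTA, config).t_star
            assert 50 <= t <= 199, config.label

    def test_histogram_sufficiency_under_pixel_permutation(self, rng):
        pixels = rng.integers(0, 256, size=144)
        a = GrayImage(pixels.reshape(12, 12))
        b = GrayImage(rng.permutation(pixels).reshape(12, 12))
        ra = find_threshold(compute_histogram(a))
        rb = find_threshold(compute_histogram(b))
        assert ra.t_star == rb.t_star

    def test_count_scaling_leaves_objective_shape_unchanged(self, rng, histogram_factory):
        """Scaling every count by a positive integer scales the
        objective linearly, so the set of minimizers is preserved (the
        reported argmin may hop within a flat plateau only through
        last-ulp rounding, so the check is on objective values)."""
        for _ in range(10):
            hist = histogram_factory(rng)
            scaled = Histogram(hist.counts * 7)
            for config in (classical_config(), enumerate_heterogeneous_configs()[24]):
                a = find_threshold(hist, config)
                b = find_threshold(scaled, config)
                finite = np.isfinite(a.objective_curve)
                assert np.array_equal(finite, np.isfinite(b.objective_curve))
                np.testing.assert_allclose(
                    b.objective_curve[finite], 7.0 * a.objective_curve[finite], rtol=1e-10
                )
                # each reported optimum minimizes the other curve too
                assert a.objective_curve[b.t_star] == pytest.approx(a.objective, rel=1e-10)
                assert b.objective_curve[a.t_star] == pytest.approx(b.objective, rel=1e-10)

    def test_single_level_histogram_is_degenerate(self):
        with pytest.raises(DegenerateInputError, match="93"):
            find_threshold(delta_histogram(g93=10))

    def test_matches_bruteforce_oracle_small(self, rng, histogram_factory):
        """Spot equivalence vs the expanded-pixel-list scan (the full
        50-histogram x 33-config sweep runs in the acceptance suite)."""
        configs = [classical_config()] + enumerate_heterogeneous_configs()[:6]
        pairs = [(spec_tuple(c.mu1_spec), spec_tuple(c.mu2_spec)) for c in configs]
        for _ in range(8):
            hist = histogram_factory(rng, n_levels=8, max_count=9)
            expected = oracles.brute_find_threshold(hist.counts, pairs)
            got = [find_threshold(hist, c).t_star for c in configs]
            assert got == expected


class TestEnumeration:
    def test_heterogeneous_table(self):
        configs = enumerate_heterogeneous_configs()
        assert len(configs) == 32
        assert [c.config_id for c in configs] == list(range(1, 33))
        # fixed rows
        assert configs[0].label == "classical/geometric"
        assert str(configs[24].mu1_spec) == "c-harmonic:+0.5"
        assert str(configs[24].mu2_spec) == "c-harmonic:-1.5"
        assert configs[-1].label == "alpha-trim:55/c-harmonic:-0.5"
        # heterogeneity rule: approaches differ except sign-opposed
        # contra-harmonic pairs
        for c in configs:
            if c.mu1_spec.approach == c.mu2_spec.approach:
                assert c.mu1_spec.approach == "c-harmonic"
                assert c.mu1_spec.q in (+0.5, +1.5)
                assert c.mu2_spec.q in (-0.5, -1.5)
        # positive orders only on the lower mode, negative on the upper
        for c in configs:
            if c.mu1_spec.approach == "c-harmonic":
                assert c.mu1_spec.q > 0
            if c.mu2_spec.approach == "c-harmonic":
                assert c.mu2_spec.q < 0
        assert len({(str(c.mu1_spec), str(c.mu2_spec)) for c in configs}) == 32

    def test_homogeneous_table(self):
        configs = enumerate_homogeneous_configs()
        assert len(configs) == 21
        assert all(c.mu1_spec == c.mu2_spec for c in configs)
        assert configs[0].label == "classical/classical"
        ch_orders = [c.mu1_spec.q for c in configs if c.mu1_spec.approach == "c-harmonic"]
        assert ch_orders == [-3.0, -1.5, -0.5, 0.5, 1.5]
        trims = [c.mu1_spec.d_half for c in configs if c.mu1_spec.approach == "alpha-trim"]
        assert trims == [10, 20, 30, 40, 50, 55, 60, 65, 70, 80, 90, 100, 110]

    def test_classical_config_is_row_zero(self):
        c = classical_config()
        assert c.config_id == 0
        assert c.mu1_spec == c.mu2_spec == EstimatorSpec("classical")


class TestSweep:
    def test_worker_count_does_not_change_results(self, rng, histogram_factory):
        hist = histogram_factory(rng)
        configs = enumerate_heterogeneous_configs()
        serial = sweep(hist, configs, workers=1)
        parallel = sweep(hist, configs, workers=4)
        assert [r.t_star for r in serial] == [r.t_star for r in parallel]
        assert [r.objective for r in serial] == [r.objective for r in parallel]

    def test_sweep_over_full_table_yields_32_results(self):
        results = sweep(TWO_DELTA, enumerate_heterogeneous_configs())
        assert len(results) == 32

    def test_singleton_sweep_equals_find_threshold(self):
        config = MCETConfig(EstimatorSpec("harmonic"), EstimatorSpec("alpha-trim", d_half=55))
        assert sweep(TWO_DELTA, [config])[0].t_star == find_threshold(TWO_DELTA, config).t_star

    def test_empty_config_list_rejected(self):
        with pytest.raises(ValueError):
            sweep(TWO_DELTA, [])
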