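"""Granger-causality estimator tests: AR fits, the GCI, order selection,
and the segment-averaged GC matrix, checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from braingc.granger import (
    fit_ar_univariate,
    fit_var_bivariate,
    gc_matrix,
    gci_pair,
    select_order,
)
from braingc.preprocessing import SegmentSet
from braingc.recording import Recording
from braingc.synthetic import generate_mvar

from _oracles import gci_pair_bruteforce
from conftest import two_node_spec


def ar1(n, a, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    e = rng.normal(0, sd, n)
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = a * x[t - 1] + e[t]
    return x


class TestUnivariateFit:
    def test_white_noise_coefficient_near_zero(self):
        x = np.random.default_rng(0).normal(0, 1, 100_000)
        fit = fit_ar_univariate(x, 1)
        assert abs(fit.coefficients[0]) < 0.02
        assert abs(fit.residual_variance - 1.0) < 0.05

    def test_ar1_coefficient_recovered(self):
        fit = fit_ar_univariate(ar1(100_000, 0.8, seed=1), 1)
        assert abs(fit.coefficients[0] - 0.8) < 0.02

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_ar_univariate(np.ones(1000), 2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fit_ar_univariate(np.random.default_rng(0).normal(size=20), 3)


class TestBivariateFit:
    def test_lagged_dependence_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100_000)
        e = rng.normal(0, 1, 100_000)
        y = np.empty_like(x)
        y[0] = e[0]
        y[1:] = 0.5 * x[:-1] + e[1:]
        fit_x, fit_y = fit_var_bivariate(x, y, 1)
        # y-equation coefficients are [x lags, y lags]
        assert abs(fit_y.coefficients[0] - 0.5) < 0.02
        assert abs(fit_y.coefficients[1]) < 0.02

    def test_independent_pair_cross_coefficients_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, (2, 50_000))
        fit_x, _ = fit_var_bivariate(x, y, 2)
        assert np.all(np.abs(fit_x.coefficients[2:]) < 0.03)

    def test_duplicate_series_is_degenerate(self):
        x = ar1(5000, 0.6, seed=4)
        with pytest.raises(ValueError, match="degenerate"):
            fit_var_bivariate(x, x, 2)

    def test_unequal_lengths_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="equal length"):
            fit_var_bivariate(rng.normal(size=1000), rng.normal(size=999), 1)


class TestGciPair:
    def test_independent_pair_both_directions_small(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, (2, 20_000))
        a, b = gci_pair(x, y, 2)
        assert a < 0.01 and b < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_bruteforce_normal_equations(self, seed, p):
        rec = generate_mvar(two_node_spec(0.5, seed=seed), 8000)
        ours = gci_pair(rec.data[0], rec.data[1], p)
        oracle = gci_pair_bruteforce(rec.data[0], rec.data[1], p)
        assert ours == pytest.approx(oracle, abs=1e-8)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(1e-3, 1e3))
    def test_invariant_to_channel_rescaling(self, scale):
        rec = generate_mvar(two_node_spec(0.5, seed=77), 4000)
        base = gci_pair(rec.data[0], rec.data[1], 1)
        scaled = gci_pair(rec.data[0] * scale, rec.data[1], 1)
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_estimate_variance_shrinks_with_sample_size(self):
        def spread(n):
            vals = [
                gci_pair(*generate_mvar(two_node_spec(0.5, seed=900 + k), n).data, 1)[0]
                for k in range(8)
            ]
            return np.var(vals)

        assert spread(50_000) < spread(2_000)


class TestSelectOrder:
    def test_var3_order_recovered(self):
        """BIC should identify the generating order of a VAR(3) system."""
        from braingc.synthetic import CouplingGraph, MVARSpec

        hits = 0
        for k in range(50):
            g = CouplingGraph(2, ((0, 1),), (0.4,), ("a", "b"))
            spec = MVARSpec(
                coupling=g,
                self_dynamics=((0.4, 0.0, 0.3), (0.3, 0.0, 0.35)),
                noise_sd=(1.0, 1.0),
                sample_rate=1000.0,
                seed=5000 + k,
            )
            rec = generate_mvar(spec, 10_000)
            if select_order(rec.data[0], rec.data[1], p_max=8) == 3:
                hits += 1
        assert hits >= 45

    def test_pmax_one_returns_one(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, (2, 2000))
        assert select_order(x, y, p_max=1) == 1

    def test_pmax_too_large_for_series_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            select_order(rng.normal(size=50), rng.normal(size=50), p_max=40)


def make_segments(arrays, fs=1000.0, labels=("a", "b")):
    segs = [Recording(a, fs, labels) for a in arrays]
    return SegmentSet(segments=segs, band=None, source_state="test", seed=0,
                      window_starts=tuple(range(len(segs))))


class TestGcMatrix:
    def test_single_segment_matches_gci_pair_convention(self):
        rec = generate_mvar(two_node_spec(0.5, seed=11), 6000)
        segs = make_segments([rec.data])
        m = gc_matrix(segs, p=2)
        x_to_y, y_to_x = gci_pair(rec.data[0], rec.data[1], 2)
        assert m.values[0, 1] == pytest.approx(x_to_y, abs=1e-8)
        assert m.values[1, 0] == pytest.approx(y_to_x, abs=1e-8)
        assert m.values[0, 0] == m.values[1, 1] == 0.0

    def test_identical_segments_average_to_single_value(self):
        rec = generate_mvar(two_node_spec(0.5, seed=12), 6000)
        one = gc_matrix(make_segments([rec.data]), p=2)
        five = gc_matrix(make_segments([rec.data] * 5), p=2)
        assert np.allclose(one.values, five.values)
        assert five.n_segments_averaged == 5

    def test_failing_channel_reported_with_context(self):
        rec = generate_mvar(two_node_spec(0.5, seed=13), 6000)
        data = rec.data.copy()
        data[1] = 0.0
        with pytest.raises(ValueError, match="test"):
            gc_matrix(make_segments([data]), p=2)

    def test_auto_order_is_recorded_and_bounded(self):
        rec = generate_mvar(two_node_spec(0.5, seed=14), 8000)
        m = gc_matrix(make_segments([rec.data]), p="auto", p_max=6)
        assert 1 <= m.order_used <= 6

    def test_true_edges_rank_above_non_edges_in_scenario(self):
        """On raw (unfiltered) scenario data, the known coupling edges carry
        higher GCI than non-edges, median over seeds."""
        from braingc.synthetic import default_scenario, generate_scenario

        ratios = []
        for seed in range(5):
            sc = default_scenario(duration_s=15.0, seed=seed)
            _, rec = generate_scenario(sc)[0]
            segs = make_segments([rec.data], labels=rec.channel_labels)
            m = gc_matrix(segs, p=5)
            emask = np.zeros(m.values.shape, bool)
            for s, t in sc.base.coupling.edges:
                emask[s, t] = True
            off = ~np.eye(len(rec.channel_labels), dtype=bool)
            ratios.append(
                np.median(m.values[emask]) / np.median(m.values[off & ~emask])
            )
        assert np.median(ratios) > 1.5
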