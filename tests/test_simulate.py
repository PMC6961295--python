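"""Synthetic-chromosome generator, read sampling, splitting, SSE."""

import numpy as np
import pytest

from finehic import (
    ReadCountMatrix,
    SimulationParams,
    cross_validate,
    distance_normalize,
    sample_read_counts,
    simulate_true_if,
    split_read_counts,
    sse_eval,
)
from finehic.simulate import downsample_read_counts, expected_rates


class TestGenerator:
    def test_same_seed_bit_identical(self):
        p = SimulationParams(n_fragments=80, seed=5)
        a, b = simulate_true_if(p), simulate_true_if(p)
        assert np.array_equal(a.if_true.values, b.if_true.values)
        assert np.array_equal(a.fragment_map.ends, b.fragment_map.ends)
        assert np.array_equal(a.bias.bias, b.bias.bias)
        assert np.array_equal(a.loop_anchors, b.loop_anchors)

    def test_decay_only_field_is_distance_pure(self):
        p = SimulationParams(
            n_fragments=100, n_tads=1, n_subtads=0, n_loops=0,
            decay_gamma=1.0, bias_log_sd=0.0, seed=3,
        )
        sim = simulate_true_if(p)
        out = distance_normalize(sim.if_true, sim.fragment_map, stratum_bp=500)
        ok = np.isfinite(out.values)
        # IF depends only on distance, so stratified normalization is ~1
        # everywhere; residuals remain because the decay varies continuously
        # within each finite-width stratum (up to ~stratum/scale relative)
        assert np.allclose(out.values[ok], 1.0, atol=0.15)

    def test_bias_mean_one_and_positive(self):
        sim = simulate_true_if(SimulationParams(n_fragments=200, seed=9))
        assert sim.bias.bias.mean() == pytest.approx(1.0)
        assert np.all(sim.bias.bias > 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(n_fragments=3)
        with pytest.raises(ValueError):
            SimulationParams(decay_gamma=-1.0)


class TestReadSampling:
    def test_zero_depth_all_zero(self, small_sim):
        rc = sample_read_counts(small_sim.if_true, small_sim.bias, 0, seed=0)
        assert rc.total() == 0

    def test_poisson_expectation_monte_carlo(self):
        sim = simulate_true_if(SimulationParams(n_fragments=30, seed=2))
        depth = 500
        lam = expected_rates(sim.if_true, sim.bias, depth)
        n_rep = 200
        acc = np.zeros_like(lam)
        for s in range(n_rep):
            acc += sample_read_counts(sim.if_true, sim.bias, depth, seed=s).values
        mean = acc / n_rep
        iu, ju = np.triu_indices(30)
        se = np.sqrt(lam[iu, ju] / n_rep)
        sel = lam[iu, ju] > 1e-4
        dev = np.abs(mean[iu, ju][sel] - lam[iu, ju][sel])
        # cell-wise 5-sigma guard plus an aggregate 3-sigma check
        assert np.all(dev <= 5 * np.maximum(se[sel], 1e-3))
        agg = (mean[iu, ju][sel] - lam[iu, ju][sel]).sum()
        agg_se = np.sqrt(lam[iu, ju][sel].sum() / n_rep)
        assert abs(agg) <= 3 * agg_se

    def test_constant_field_variance_matches_mean(self):
        n = 40
        from finehic import BiasVector, IFMatrix

        ifm = IFMatrix(np.ones((n, n)))
        bias = BiasVector.unit(n)
        depth = 4 * n * (n + 1) // 2  # rate 4 per sampled cell
        counts = []
        for s in range(60):
            rc = sample_read_counts(ifm, bias, depth, seed=s)
            iu, ju = np.triu_indices(n)
            counts.append(rc.values[iu, ju])
        allc = np.concatenate(counts)
        assert allc.mean() == pytest.approx(4.0, rel=0.05)
        assert allc.var() == pytest.approx(allc.mean(), rel=0.1)


class TestSplit:
    def test_conservation_exact_cellwise(self, small_sim):
        rc = sample_read_counts(small_sim.if_true, small_sim.bias, 5000, seed=1)
        inp, test = split_read_counts(rc, 0.8, seed=2)
        assert np.array_equal(inp.values + test.values, rc.values)

    def test_expected_fraction(self, small_sim):
        rc = sample_read_counts(small_sim.if_true, small_sim.bias, 20_000, seed=1)
        totals = []
        for s in range(50):
            inp, _ = split_read_counts(rc, 0.8, seed=s)
            totals.append(inp.n_read_pairs())
        m = np.mean(totals)
        npairs = rc.n_read_pairs()
        se = np.sqrt(npairs * 0.8 * 0.2 / 50)
        assert abs(m - 0.8 * npairs) <= 3 * se

    def test_bad_fraction(self, small_sim):
        rc = sample_read_counts(small_sim.if_true, small_sim.bias, 100, seed=1)
        with pytest.raises(ValueError):
            split_read_counts(rc, 1.0)

    def test_downsample_full_fraction_is_identity(self, small_sim):
        rc = sample_read_counts(small_sim.if_true, small_sim.bias, 100, seed=1)
        assert downsample_read_counts(rc, 1.0) is rc


class TestSSE:
    def test_identical_matrices_zero(self):
        v = np.ones((6, 6))
        rc = ReadCountMatrix(np.ones((6, 6), dtype=int))
        assert sse_eval(v, rc, scale=1.0) == 0.0

    def test_single_cell_difference(self):
        v = np.ones((6, 6))
        w = np.ones((6, 6), dtype=int)
        w[1, 4] += 1
        w[4, 1] += 1
        assert sse_eval(v, ReadCountMatrix(w), scale=1.0) == 1.0

    def test_matches_brute_force(self, rng):
        n = 15
        pred = rng.random((n, n))
        pred = (pred + pred.T) / 2
        upper = rng.poisson(2.0, (n, n))
        rc = ReadCountMatrix(np.triu(upper) + np.triu(upper, 1).T)
        brute = sum(
            (pred[i, j] - rc.values[i, j]) ** 2
            for i in range(n)
            for j in range(i + 1, n)
        )
        assert sse_eval(pred, rc, scale=1.0) == pytest.approx(brute)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            sse_eval(np.ones((4, 4)), ReadCountMatrix(np.zeros((5, 5), int)))


class TestCrossValidate:
    def test_smoke_and_row_count(self):
        params = SimulationParams(n_fragments=100, seed=0)
        table = cross_validate(
            params, {"fixed:2": "fixed:2", "akde": "akde"},
            depth_fractions=[1.0, 0.5], seeds=[0],
        )
        assert len(table) == 4  # 2 methods x 2 depths x 1 seed
        assert table.sse.notna().all()
        # deeper input should not give a (much) worse fixed-binning fit
        f = table[table.method == "fixed:2"].set_index("depth_fraction").sse
        assert f[1.0] <= f[0.5] * 1.5

    def test_estimator_failure_recorded_not_raised(self):
        params = SimulationParams(n_fragments=100, seed=0)
        table = cross_validate(
            params, {"bad": "fixed:0", "ok": "fixed:2"}, seeds=[0]
        )
        bad = table[table.method == "bad"]
        assert bad.sse.isna().all()
        assert (table[table.method == "ok"].sse.notna()).all()
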