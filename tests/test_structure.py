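"""Directionality index, domain boundaries, distance normalization, loops."""

import numpy as np
import pytest

from finehic import (
    FragmentMap,
    IFMatrix,
    SimulationParams,
    call_domain_boundaries,
    call_loops,
    directionality_profile,
    distance_normalize,
    score_candidate_peaks,
    simulate_true_if,
)
from finehic.structure import DEFAULT_DELTA_BP, DEFAULT_DI_WINDOW


def _uniform_fmap(n, size=1000):
    ends = np.arange(1, n + 1) * size
    return FragmentMap("chrT", ends - size, ends)


class TestDirectionalityIndex:
    def test_uniform_matrix_gives_zero(self):
        n = 30
        ifm = IFMatrix(np.ones((n, n)))
        prof = directionality_profile(ifm, _uniform_fmap(n), delta=5000)
        inner = prof.di_prime[6:-6]
        assert np.allclose(inner, 0.0)

    def test_worked_value(self):
        # A = 10, B = 30 -> E = 20, DI = +10, DI' = +0.5
        n = 5
        v = np.zeros((n, n))
        v[1, 2] = v[2, 1] = 10.0  # upstream of fragment 2
        v[2, 3] = v[3, 2] = 30.0  # downstream
        prof = directionality_profile(IFMatrix(v), _uniform_fmap(n), delta=1000)
        assert prof.upstream[2] == 10.0
        assert prof.downstream[2] == 30.0
        assert prof.di[2] == pytest.approx(10.0)
        assert prof.di_prime[2] == pytest.approx(0.5)

    def test_default_delta_is_500kb(self):
        assert DEFAULT_DELTA_BP == 500_000
        assert DEFAULT_DI_WINDOW == 21

    def test_zero_flank_masked(self):
        n = 6
        prof = directionality_profile(
            IFMatrix(np.zeros((n, n))), _uniform_fmap(n), delta=2000
        )
        assert prof.mask.all()

    def test_antisymmetry_under_reversal(self, rng):
        n = 40
        v = rng.random((n, n))
        v = v + v.T
        fmap = _uniform_fmap(n)
        prof = directionality_profile(IFMatrix(v), fmap, delta=7000)
        rev = directionality_profile(IFMatrix(v[::-1, ::-1].copy()), fmap, delta=7000)
        ok = ~np.isnan(prof.di_prime)
        assert np.allclose(
            prof.di_prime[ok], -rev.di_prime[::-1][ok], rtol=1e-9
        )

    def test_di_prime_bounded_by_two(self, rng):
        n = 50
        v = rng.random((n, n)) * 5
        v = v + v.T
        prof = directionality_profile(IFMatrix(v), _uniform_fmap(n), delta=9000)
        ok = ~np.isnan(prof.di_prime)
        assert np.all(np.abs(prof.di_prime[ok]) <= 2.0 + 1e-12)


class TestDomainBoundaries:
    def test_flat_profile_no_boundaries(self):
        n = 40
        prof = directionality_profile(
            IFMatrix(np.ones((n, n))), _uniform_fmap(n), delta=5000
        )
        bset = call_domain_boundaries(prof, window=7, exclusion_bp=0)
        assert len(bset) == 0

    def test_even_window_rejected(self):
        n = 20
        prof = directionality_profile(
            IFMatrix(np.ones((n, n))), _uniform_fmap(n), delta=5000
        )
        with pytest.raises(ValueError, match="odd"):
            call_domain_boundaries(prof, window=8)

    def test_planted_tad_junction_recovered(self):
        sim = simulate_true_if(
            SimulationParams(
                n_fragments=200, n_tads=2, n_subtads=0, n_loops=0,
                bias_log_sd=0.0, seed=11,
            )
        )
        junction = int(sim.tad_boundaries[0])
        prof = directionality_profile(sim.if_true, sim.fragment_map)
        bset = call_domain_boundaries(
            prof, sim.fragment_map, window=21, exclusion_bp=0
        )
        assert len(bset) >= 1
        # the top-ranked extremum flanks the planted junction (weaker
        # secondary extrema appear where the +-delta window edge crosses it)
        assert abs(int(bset.indices[0]) - junction) <= 1

    def test_end_exclusion_removes_terminal_fragments(self):
        sim = simulate_true_if(
            SimulationParams(n_fragments=200, n_tads=2, n_subtads=0,
                             n_loops=0, bias_log_sd=0.0, seed=11)
        )
        prof = directionality_profile(sim.if_true, sim.fragment_map)
        bset = call_domain_boundaries(
            prof, sim.fragment_map, window=21, exclusion_bp=10**9
        )
        assert len(bset) == 0


class TestDistanceNormalize:
    def test_pure_distance_function_normalizes_to_one(self):
        n = 40
        fmap = _uniform_fmap(n)
        d = np.abs(fmap.pos[None, :] - fmap.pos[:, None]).astype(float)
        ifm = IFMatrix(1.0 / (d + 1000))
        out = distance_normalize(ifm, fmap, stratum_bp=1000)
        ok = np.isfinite(out.values)
        assert np.allclose(out.values[ok], 1.0)

    def test_single_enriched_cell(self):
        n = 40
        fmap = _uniform_fmap(n)
        v = np.ones((n, n))
        v[10, 20] = v[20, 10] = 2.0  # 2x its stratum mean (others 1)
        out = distance_normalize(IFMatrix(v), fmap, stratum_bp=1000)
        # stratum holds 2(n-10) cells, two of value 2: mean = 1 + 1/(n-10)
        stratum_mean = 1.0 + 1.0 / (n - 10)
        assert out.values[10, 20] == pytest.approx(2.0 / stratum_mean)

    def test_stratum_means_are_one(self, rng):
        n = 50
        fmap = _uniform_fmap(n)
        v = rng.random((n, n)) + 0.1
        out = distance_normalize(IFMatrix((v + v.T) / 2), fmap, stratum_bp=3000)
        d = np.abs(fmap.pos[None, :] - fmap.pos[:, None]) // 3000
        for s in np.unique(d):
            vals = out.values[d == s]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                assert vals.mean() == pytest.approx(1.0, abs=1e-9)


class TestPeakScores:
    def test_flat_field_scores_one(self):
        n = 60
        fmap = _uniform_fmap(n)
        ps = score_candidate_peaks(IFMatrix(np.ones((n, n))), fmap, 3000, 6000)
        ok = np.isfinite(ps.score)
        assert ok.any()
        assert np.allclose(ps.score[ok], 1.0)

    def test_planted_square_scores_its_enrichment(self):
        n = 80
        fmap = _uniform_fmap(n)
        v = np.ones((n, n))
        ci, cj = 30, 60
        v[ci - 1 : ci + 2, cj - 1 : cj + 2] = 5.0
        v[cj - 1 : cj + 2, ci - 1 : ci + 2] = 5.0
        ps = score_candidate_peaks(IFMatrix(v), fmap, 1000, 9000)
        # peak square (+-1000 bp = 3 fragments) exactly covers the planted
        # block; all flanks are clean background 1
        assert ps.score[ci, cj] == pytest.approx(5.0)

    def test_p_must_be_smaller_than_w(self):
        fmap = _uniform_fmap(10)
        with pytest.raises(ValueError):
            score_candidate_peaks(IFMatrix(np.ones((10, 10))), fmap, 5000, 5000)


class TestLoopCalling:
    def test_flat_matrix_yields_no_confident_calls(self):
        n = 120
        fmap = _uniform_fmap(n, size=2000)
        calls = call_loops(
            IFMatrix(np.ones((n, n))), fmap,
            scales=[(4000, 10_000)], seed=0,
        )
        confident = [c for c in calls if c.fdr is not None and c.fdr < 0.1]
        assert confident == []
        if calls:
            assert min(c.fdr for c in calls if c.fdr is not None) > 0.5

    def test_planted_loop_recovered_across_seeds(self):
        hits = 0
        for seed in range(5):
            sim = simulate_true_if(
                SimulationParams(
                    n_fragments=500, n_tads=1, n_subtads=0, n_loops=1,
                    loop_fold=10.0, bias_log_sd=0.0, seed=100 + seed,
                )
            )
            ai, aj = map(int, sim.loop_anchors[0])
            calls = call_loops(sim.if_true, sim.fragment_map, seed=seed)
            assert calls, "no candidate loops found"
            top = calls[0]
            if abs(top.anchor[0] - ai) <= 1 and abs(top.anchor[1] - aj) <= 1:
                hits += 1
        assert hits >= 4

    def test_retained_calls_respect_min_dist(self, rng):
        n = 150
        fmap = _uniform_fmap(n, size=2000)
        v = rng.random((n, n)) + 0.5
        v = (v + v.T) / 2
        calls = call_loops(
            IFMatrix(v), fmap, scales=[(4000, 10_000)],
            min_dist=20_000, seed=1,
        )
        pos = fmap.pos
        same_scale = [c for c in calls if c.scale == (4000, 10_000)]
        for a in range(len(same_scale)):
            for b in range(a + 1, len(same_scale)):
                ca, cb = same_scale[a], same_scale[b]
                d = max(
                    abs(int(pos[ca.cell[0]]) - int(pos[cb.cell[0]])),
                    abs(int(pos[ca.cell[1]]) - int(pos[cb.cell[1]])),
                )
                assert d > 20_000

    def test_fdr_monotone_in_score_within_bin(self):
        sim = simulate_true_if(
            SimulationParams(n_fragments=300, n_loops=3, seed=21)
        )
        calls = call_loops(sim.if_true, sim.fragment_map, seed=2)
        by_bin: dict = {}
        for c in calls:
            if c.fdr is not None:
                by_bin.setdefault((c.scale, c.distance_bp // 10_000), []).append(c)
        checked = 0
        for group in by_bin.values():
            group.sort(key=lambda c: c.score)
            for lo, hi in zip(group, group[1:]):
                assert hi.fdr <= lo.fdr + 1e-12
                checked += 1
        assert checked > 0

    def test_loop_defaults(self):
        from finehic.structure import (
            DEFAULT_MIN_DIST_BP,
            DEFAULT_MIN_SCORE,
            DEFAULT_SCALES,
        )

        assert DEFAULT_MIN_SCORE == 1.0
        assert DEFAULT_MIN_DIST_BP == 20_000
        assert DEFAULT_SCALES == ((30_000, 60_000), (50_000, 100_000))
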