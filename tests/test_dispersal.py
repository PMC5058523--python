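import numpy as np
import pytest
from scipy.ndimage import label

from snailrisk import DispersalParams, suitability_to_1000
from snailrisk.dispersal import _kernel_footprint, init_state, run, step

from conftest import make_grid


def grid_of(values, **kw):
    return make_grid(values, **kw)


def full_suit(shape, value=1000.0):
    return make_grid(np.full(shape, value))


class TestParams:
    def test_published_ldd_bounds_disable_ldd_with_warning(self):
        p = DispersalParams(ldd_min_dist=2, ldd_max_dist=0, ldd_freq=0.05)
        assert not p.ldd_enabled
        with pytest.warns(UserWarning, match="long-distance"):
            p.warn_if_ldd_disabled()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            DispersalParams(propagule_prod=1.5)

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            DispersalParams(rc_threshold=1500)


class TestKernelFootprint:
    def test_default_kernel_reaches_eight_neighbors(self):
        fp = _kernel_footprint((1.0,))
        # distance 1 and sqrt(2)~1.41 both round to 1; center excluded
        assert fp.sum() == 8.0 and fp[1, 1] == 0.0 and fp[0, 0] == 1.0

    def test_two_ring_kernel_indexed_by_rounded_distance(self):
        fp = _kernel_footprint((0.5, 0.1))
        assert fp[2, 3] == 0.5   # offset (0,1): distance 1
        assert fp[2, 0] == 0.1   # offset (0,-2): distance 2
        assert fp[1, 1] == 0.5   # offset (-1,-1): 1.41 rounds to 1
        assert fp[0, 0] == 0.0   # offset (-2,-2): 2.83 rounds to 3 -> out

    def test_center_is_zero(self):
        fp = _kernel_footprint((1.0, 1.0))
        k = len(fp) // 2
        assert fp[k, k] == 0.0


class TestInitState:
    def test_barrier_takes_precedence(self):
        initial = grid_of([[1.0, 1.0]])
        barrier = grid_of([[1.0, 0.0]])
        st = init_state(initial, barrier, DispersalParams(ldd_freq=0))
        assert st.occupied.tolist() == [[0, 1]]
        assert st.age.tolist() == [[0, 1]]  # seeded mature (ini_mat_age=1)

    def test_empty_initial_state(self):
        st = init_state(grid_of([[0.0, 0.0]]), grid_of([[0.0, 0.0]]),
                        DispersalParams(ldd_freq=0))
        assert st.occupied.sum() == 0

    def test_counts_match_tally(self):
        rng = np.random.default_rng(0)
        ini = grid_of((rng.random((10, 10)) < 0.4).astype(float))
        bar = grid_of((rng.random((10, 10)) < 0.3).astype(float))
        st = init_state(ini, bar, DispersalParams(ldd_freq=0))
        expect = ((ini.values == 1) & (bar.values == 0)).sum()
        assert st.occupied.sum() == expect


class TestStep:
    def params(self, **kw):
        kw.setdefault("ldd_freq", 0.0)
        return DispersalParams(**kw)

    def test_no_colonization_channels_only_shrinks(self):
        rng = np.random.default_rng(1)
        ini = grid_of((rng.random((10, 10)) < 0.5).astype(float))
        bar = grid_of(np.zeros((10, 10)))
        p = self.params(kernel=(0.0,))
        st = init_state(ini, bar, p)
        suit = make_grid(
            np.where(rng.random((10, 10)) < 0.5, 1000.0, 0.0))
        prev = st.occupied.sum()
        for _ in range(5):
            step(st, suit, rng)
            assert st.occupied.sum() <= prev
            prev = st.occupied.sum()

    def test_certain_colonization_of_adjacent_suitable_cell(self):
        ini = grid_of([[1.0, 0.0]])
        bar = grid_of([[0.0, 0.0]])
        p = self.params(kernel=(1.0,), propagule_prod=1.0)
        st = init_state(ini, bar, p)
        step(st, full_suit((1, 2)), np.random.default_rng(0))
        assert st.occupied.tolist() == [[1, 1]]

    def test_decolonization_below_threshold(self):
        ini = grid_of([[1.0, 1.0]])
        bar = grid_of([[0.0, 0.0]])
        st = init_state(ini, bar, self.params(kernel=(0.0,)))
        suit = make_grid([[1000.0, 400.0]])
        step(st, suit, np.random.default_rng(0))
        assert st.occupied.tolist() == [[1, 0]]
        assert st.age[0, 1] == 0

    def test_barrier_never_occupied(self):
        rng = np.random.default_rng(2)
        ini = grid_of((rng.random((12, 12)) < 0.3).astype(float))
        bar = grid_of((rng.random((12, 12)) < 0.3).astype(float))
        st = init_state(ini, bar, self.params(kernel=(1.0,)))
        suit = full_suit((12, 12))
        for _ in range(10):
            step(st, suit, rng)
            assert not np.any((st.occupied == 1) & (st.barrier == 1))
            assert np.all((st.age > 0) == (st.occupied == 1))

    def test_colonization_rate_matches_analytic_probability(self):
        # single mature source with a sub-certain kernel: the adjacent
        # cell's per-step colonization probability has a closed form
        p_col = 0.3
        hits = 0
        trials = 400
        rng = np.random.default_rng(3)
        for _ in range(trials):
            st = init_state(grid_of([[1.0, 0.0]]), grid_of([[0.0, 0.0]]),
                            self.params(kernel=(p_col,)))
            step(st, full_suit((1, 2)), rng)
            hits += int(st.occupied[0, 1])
        se = np.sqrt(p_col * (1 - p_col) / trials)
        assert abs(hits / trials - p_col) < 3 * se

    def test_multiple_sources_compound_pressure(self):
        # two mature sources each reaching the middle cell with prob 0.5:
        # P(colonized) = 1 - 0.5^2 = 0.75
        hits = 0
        trials = 400
        rng = np.random.default_rng(4)
        for _ in range(trials):
            st = init_state(grid_of([[1.0, 0.0, 1.0]]),
                            grid_of([[0.0, 0.0, 0.0]]),
                            self.params(kernel=(0.5,)))
            step(st, full_suit((1, 3)), rng)
            hits += int(st.occupied[0, 1])
        se = np.sqrt(0.75 * 0.25 / trials)
        assert abs(hits / trials - 0.75) < 3 * se

    def test_out_of_range_suitability_rejected(self):
        st = init_state(grid_of([[1.0]]), grid_of([[0.0]]), self.params())
        with pytest.raises(ValueError):
            step(st, make_grid([[2000.0]]), np.random.default_rng(0))


class TestRun:
    def _series(self, shape, periods, value=1000.0):
        return [full_suit(shape, value) for _ in range(periods)]

    def test_unlimited_fills_all_suitable_cells(self):
        ini = grid_of([[1.0] + [0.0] * 8])
        bar = grid_of([[0.0] * 9])
        p = DispersalParams(enc_chg_steps=2, replicates=1, ldd_freq=0)
        occ, _ = run(ini, bar, self._series((1, 9), 2), p, "unlimited")
        assert all(np.all(g.values == 1) for g in occ)

    def test_none_scenario_tracks_suitability_collapse(self):
        ini = grid_of([[1.0, 1.0]])
        bar = grid_of([[0.0, 0.0]])
        series = [full_suit((1, 2)), full_suit((1, 2), 0.0)]
        p = DispersalParams(enc_chg_steps=2, replicates=1, ldd_freq=0)
        occ, _ = run(ini, bar, series, p, "none")
        assert occ[0].values.sum() == 2 and occ[1].values.sum() == 0

    def test_series_length_mismatch_rejected(self):
        p = DispersalParams(enc_chg_steps=4, ldd_freq=0)
        with pytest.raises(ValueError, match="enc_chg_steps"):
            run(grid_of([[1.0]]), grid_of([[0.0]]),
                self._series((1, 1), 2), p)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(5)
        ini_v = np.zeros((15, 15))
        ini_v[7, 7] = 1
        ini = grid_of(ini_v)
        bar = grid_of((rng.random((15, 15)) < 0.2).astype(float))
        suit = make_grid(
            np.where(rng.random((15, 15)) < 0.8, 1000.0, 0.0))
        p = DispersalParams(enc_chg_steps=2, disp_steps=5, replicates=3,
                            seed=11, ldd_freq=0)
        a, ha = run(ini, bar, [suit, suit], p)
        b, hb = run(ini, bar, [suit, suit], p)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.values, gb.values)
        assert ha.equals(hb)

    def test_barrier_ring_confines_to_reachable_set(self):
        # a closed barrier ring: spread must match 8-connected reachability
        n = 15
        bar_v = np.zeros((n, n))
        bar_v[4, 4:11] = bar_v[10, 4:11] = 1
        bar_v[4:11, 4] = bar_v[4:11, 10] = 1
        ini_v = np.zeros((n, n))
        ini_v[7, 7] = 1
        p = DispersalParams(enc_chg_steps=1, disp_steps=30, replicates=3,
                            seed=1, ldd_freq=0)
        occ, _ = run(grid_of(ini_v), grid_of(bar_v),
                     self._series((n, n), 1), p)
        # oracle: connected component of the start among non-barrier cells
        labels, _ = label(1 - bar_v, structure=np.ones((3, 3)))
        reach = labels == labels[7, 7]
        outside = ~reach
        assert np.all(occ[0].values[outside] == 0)
        assert np.all(occ[0].values[reach] == 1)  # certain kernel fills it

    def test_scenario_nesting_on_random_landscape(self):
        rng = np.random.default_rng(9)
        n = 20
        bar = grid_of((rng.random((n, n)) < 0.2).astype(float))
        free = np.argwhere(bar.values == 0)
        ini_v = np.zeros((n, n))
        for i in free[rng.permutation(len(free))[:5]]:
            ini_v[tuple(i)] = 1
        suit_v = np.where(rng.random((n, n)) < 0.7, 1000.0, 0.0)
        # keep initial cells suitable so the none scenario persists
        suit_v[ini_v == 1] = 1000.0
        series = [make_grid(suit_v)] * 2
        p = DispersalParams(enc_chg_steps=2, disp_steps=5, replicates=3,
                            seed=2, ldd_freq=0)
        occ_n, _ = run(grid_of(ini_v), bar, series, p, "none")
        occ_c, _ = run(grid_of(ini_v), bar, series, p, "constrained")
        occ_u, _ = run(grid_of(ini_v), bar, series, p, "unlimited")
        for gn, gc, gu in zip(occ_n, occ_c, occ_u):
            assert np.all(gc.values[gn.values == 1] == 1)   # none ⊆ every rep
            assert np.all(gu.values[gc.values > 0] == 1)    # any rep ⊆ unltd
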