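import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuvarp.inference import (
    PermutationDesign,
    enumerate_orbit,
    fdr_adjust,
    forward_select,
    generate_permutation,
    naive_orbit_size,
    permutation_test,
)
from cuvarp.ordination import rda_matrices

from conftest import quant_table


class TestGeneratePermutation:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=30), st.integers(min_value=0, max_value=2 ** 30))
    def test_free_always_a_bijection(self, n, seed):
        perm = generate_permutation(PermutationDesign(), n, np.random.default_rng(seed))
        assert sorted(perm) == list(range(n))

    def test_blocks_stay_within_blocks(self, rng):
        design = PermutationDesign("blocks", block_labels=["a"] * 3 + ["b"] * 4)
        for _ in range(50):
            perm = generate_permutation(design, 7, rng)
            assert sorted(perm[:3]) == [0, 1, 2]
            assert sorted(perm[3:]) == [3, 4, 5, 6]

    def test_series_single_block_hits_exactly_the_cyclic_orbit(self, rng):
        design = PermutationDesign("series")
        seen = {tuple(generate_permutation(design, 4, rng)) for _ in range(10_000)}
        expected = {tuple(np.roll(np.arange(4), -s)) for s in range(4)}
        assert seen == expected

    def test_series_mirror_doubles_the_orbit(self, rng):
        design = PermutationDesign("series", allow_mirror=True)
        seen = {tuple(generate_permutation(design, 4, rng)) for _ in range(10_000)}
        assert len(seen) == 8

    def test_split_plot_keeps_plots_adjacent_and_ordered(self, rng):
        design = PermutationDesign("split_plot", block_labels=["s1", "s1", "s2", "s2"])
        for _ in range(100):
            perm = generate_permutation(design, 4, rng)
            halves = [tuple(perm[:2]), tuple(perm[2:])]
            assert set(halves) <= {(0, 1), (2, 3)}

    def test_split_plot_unequal_blocks_rejected(self, rng):
        design = PermutationDesign("split_plot", block_labels=["a", "a", "b"])
        with pytest.raises(ValueError, match="equal-sized"):
            generate_permutation(design, 3, rng)

    def test_label_count_mismatch_rejected(self, rng):
        design = PermutationDesign("blocks", block_labels=["a", "b"])
        with pytest.raises(ValueError, match="labels"):
            generate_permutation(design, 3, rng)

    @pytest.mark.parametrize(
        "design",
        [
            PermutationDesign("blocks", block_labels=["a"] * 3 + ["b"] * 3),
            PermutationDesign("series", block_labels=["a"] * 3 + ["b"] * 3),
            PermutationDesign("series", allow_mirror=True, block_labels=["a"] * 4 + ["b"] * 4),
            PermutationDesign("split_plot", block_labels=["a"] * 2 + ["b"] * 2 + ["c"] * 2),
            PermutationDesign(
                "split_plot", shift_within=True, block_labels=["a"] * 2 + ["b"] * 2
            ),
        ],
    )
    def test_draws_stay_inside_the_enumerated_orbit(self, design, rng):
        n = len(design.block_labels)
        orbit = {tuple(p) for p in enumerate_orbit(design, n)}
        assert len(orbit) <= naive_orbit_size(design, n)
        for _ in range(200):
            assert tuple(generate_permutation(design, n, rng)) in orbit


class TestPermutationTest:
    def test_p_value_floor(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + 0.01 * rng.normal(size=30)
        tr = permutation_test(y, x, n_perm=999, seed=1)
        assert tr.p_value >= 1 / 1000

    def test_exhaustive_matches_manual_enumeration(self, rng):
        y = rng.normal(size=4)
        x = rng.normal(size=4)
        tr = permutation_test(y, x, n_perm=999, seed=0)
        assert tr.exhaustive and tr.n_perm == 24
        f_obs = rda_matrices(y, x).pseudo_f
        f_all = [
            rda_matrices(y[list(p)], x).pseudo_f
            for p in itertools.permutations(range(4))
        ]
        manual_p = np.mean([f >= f_obs - 1e-9 for f in f_all])
        assert tr.p_value == pytest.approx(manual_p)

    def test_deterministic_given_seed(self, rng):
        y = rng.normal(size=40)
        x = rng.normal(size=40)
        a = permutation_test(y, x, n_perm=199, seed=5)
        b = permutation_test(y, x, n_perm=199, seed=5)
        assert a == b

    def test_partial_test_detects_signal_beyond_covariate(self, rng):
        n = 60
        w = rng.normal(size=n)
        x = rng.normal(size=n)
        y = w + x + 0.3 * rng.normal(size=n)
        tr = permutation_test(y, x, w, n_perm=199, seed=2)
        assert tr.p_value <= 0.01

    def test_covariate_equal_to_predictor_gives_null_result(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        tr = permutation_test(y, x, x, n_perm=99, seed=0)
        assert tr.statistic == 0.0 and tr.p_value == 1.0

    def test_null_p_values_are_superuniform(self, rng):
        # Kolmogorov distance of the null p-value distribution from uniform,
        # 1000 replicates at 199 permutations
        pvals = []
        for i in range(1000):
            y = rng.normal(size=20)
            x = rng.normal(size=20)
            pvals.append(permutation_test(y, x, n_perm=199, seed=i).p_value)
        pvals = np.sort(pvals)
        grid = np.arange(1, 1001) / 1000
        ks = np.abs(pvals - grid).max()
        assert ks < 0.05


class TestFdrAdjust:
    def test_hand_stepup_computation(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_order_preserved(self, ps):
        adj = fdr_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestForwardSelect:
    def _cands(self, arrays, n):
        ids = [f"s{i}" for i in range(n)]
        return quant_table(np.column_stack(arrays), ids=ids,
                           columns=[f"c{j+1}" for j in range(len(arrays))])

    def test_orthogonal_response_selects_nothing(self, rng):
        n = 40
        y = rng.normal(size=n)
        cands = self._cands([rng.normal(size=n), rng.normal(size=n)], n)
        sel = forward_select(y, cands, alpha=0.01, n_perm=99, seed=3)
        assert sel.selected == []
        assert sel.stop_reason == "alpha_fail"

    def test_planted_signal_selected_first(self, rng):
        n = 100
        x1 = rng.normal(size=n)
        y = 2 * x1 + 0.5 * rng.normal(size=n)
        cands = self._cands([rng.normal(size=n), x1], n)
        sel = forward_select(y, cands, alpha=0.05, n_perm=199, seed=4)
        assert sel.selected[0] == "c2"

    def test_deterministic_given_seed(self, rng):
        n = 50
        y = rng.normal(size=n)
        cands = self._cands([rng.normal(size=n) for _ in range(3)], n)
        a = forward_select(y, cands, alpha=0.2, n_perm=99, seed=9)
        b = forward_select(y, cands, alpha=0.2, n_perm=99, seed=9)
        assert a == b

    def test_cumulative_adj_r2_nondecreasing(self, rng):
        n = 80
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = x1 + x2 + 0.5 * rng.normal(size=n)
        cands = self._cands([x1, x2, rng.normal(size=n)], n)
        sel = forward_select(y, cands, alpha=0.05, n_perm=199, seed=6)
        gains = [s.adj_r2_gain for s in sel.steps]
        assert all(g > 0 for g in gains)
        assert set(sel.selected) >= {"c1", "c2"}

    def test_all_noise_candidates_rarely_selected(self, rng):
        # FDR + double stopping keep the family-wise entry rate near alpha:
        # at most ~10% of null replicates admit any candidate
        false_runs = 0
        n_rep = 200
        for i in range(n_rep):
            n = 60
            y = rng.normal(size=n)
            cands = self._cands([rng.normal(size=n) for _ in range(3)], n)
            sel = forward_select(y, cands, alpha=0.05, n_perm=199, seed=7000 + i)
            false_runs += bool(sel.selected)
        assert false_runs / n_rep <= 0.10
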