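import itertools
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloshift import (blomberg_k, categorical_signal_test,
                        continuous_signal_test, fitch_min_transitions,
                        read_newick, simulate_bm_traits, write_newick)

from conftest import random_tree


def brute_force_min_transitions(tree, states):
    """Independent oracle: enumerate every internal-state assignment and count
    parent-child mismatches along branches."""
    codes = {tree.tip_index(lab): s for lab, s in states.items()}
    internals = [i for i in range(tree.n_nodes) if tree.children[i]]
    alphabet = sorted(set(states.values()))
    best = np.inf
    for combo in itertools.product(alphabet, repeat=len(internals)):
        full = dict(codes)
        full.update(zip(internals, combo))
        cost = sum(full[nd] != full[tree.parent[nd]]
                   for nd in range(tree.n_nodes) if tree.parent[nd] >= 0)
        best = min(best, cost)
    return int(best)


class TestFitch:
    def test_single_clade_boundary(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_min_transitions(t, {"A": 1, "B": 1, "C": 0, "D": 0}) == 1

    def test_constant_states(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_min_transitions(t, {"A": 1, "B": 1, "C": 1, "D": 1}) == 0

    def test_alternating_states(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fitch_min_transitions(t, {"A": 1, "B": 0, "C": 1, "D": 0}) == 2

    def test_missing_state_rejected(self):
        t = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(KeyError):
            fitch_min_transitions(t, {"A": 1, "B": 1, "C": 0})

    @pytest.mark.parametrize("n_states", [2, 3])
    def test_matches_exhaustive_oracle(self, n_states):
        rng = np.random.default_rng(7)
        for seed in range(30):
            tree = random_tree(seed, int(rng.integers(4, 9)))
            states = {lab: int(rng.integers(n_states)) for lab in tree.tip_labels}
            if len(set(states.values())) < 2:
                continue
            assert fitch_min_transitions(tree, states) == \
                brute_force_min_transitions(tree, states)


class TestCategoricalSignal:
    def test_clade_concordant_states_significant(self, balanced16):
        states = {lab: ("pos" if int(lab[1:]) < 8 else "neg")
                  for lab in balanced16.tip_labels}
        res = categorical_signal_test(balanced16, states, n_rand=1000, seed=0)
        assert res.observed_transitions == 1
        assert res.p_value <= 0.01
        assert res.null_median >= res.observed_transitions

    def test_constant_character(self, balanced16):
        states = {lab: "pos" for lab in balanced16.tip_labels}
        with pytest.warns(UserWarning, match="constant"):
            res = categorical_signal_test(balanced16, states, seed=0)
        assert res.observed_transitions == 0
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self, balanced16):
        states = {lab: ("a" if i % 2 else "b")
                  for i, lab in enumerate(balanced16.tip_labels)}
        r1 = categorical_signal_test(balanced16, states, n_rand=99, seed=5)
        r2 = categorical_signal_test(balanced16, states, n_rand=99, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_distribution, r2.null_distribution)
        assert r1.p_value > 0

    def test_type_one_error_rate(self, balanced16):
        """Random coin-flip characters should be rejected at roughly the
        nominal 5% rate."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_tests = 100
        for i in range(n_tests):
            states = {lab: int(rng.integers(2)) for lab in balanced16.tip_labels}
            if len(set(states.values())) < 2:
                continue
            res = categorical_signal_test(balanced16, states, n_rand=199, seed=i)
            rejections += res.p_value <= 0.05
        assert 0.0 <= rejections / n_tests <= 0.12


class TestBlombergK:
    def test_star_tree_exactly_one(self):
        t = read_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert blomberg_k(t, {"A": 0, "B": 1, "C": 3, "D": -2, "E": 0.5}) \
            == pytest.approx(1.0, abs=1e-12)

    def test_two_tips_exactly_one(self):
        t = read_newick("(A:2,B:2);")
        assert blomberg_k(t, {"A": 0.0, "B": 1.0}) == pytest.approx(1.0)

    def test_constant_trait_rejected(self, three_tip):
        with pytest.raises(ValueError):
            blomberg_k(three_tip, {"A": 1.0, "B": 1.0, "C": 1.0})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-100, 100, allow_nan=False),
           scale=st.floats(0.01, 100, allow_nan=False))
    def test_affine_invariance(self, shift, scale):
        tree = random_tree(3, 12)
        x = np.array(list(simulate_bm_traits(tree, 1.0, 0.0, seed=8).values()))
        x = {lab: v for lab, v in zip(tree.tip_labels, x)}
        k0 = blomberg_k(tree, x)
        k1 = blomberg_k(tree, {l: shift + scale * v for l, v in x.items()})
        assert k1 == pytest.approx(k0, rel=1e-9)

    def test_matches_picante_oracle(self):
        """Independent cross-check against the reference R implementation."""
        tree = random_tree(9, 12)
        x = simulate_bm_traits(tree, 1.0, 0.0, seed=4)
        nwk = write_newick(tree)
        vals = ",".join(repr(x[l]) for l in tree.tip_labels)
        names = ",".join(f'"{l}"' for l in tree.tip_labels)
        rcode = (
            'suppressMessages(library(picante));'
            f'phy <- read.tree(text="{nwk}");'
            f'x <- c({vals}); names(x) <- c({names});'
            'cat(sprintf("%.12f", Kcalc(x[phy$tip.label], phy)))'
        )
        proc = subprocess.run(["Rscript", "-e", rcode],
                              capture_output=True, text=True, timeout=300)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/picante unavailable: {proc.stderr[-200:]}")
        assert blomberg_k(tree, x) == pytest.approx(float(proc.stdout), rel=1e-9)


class TestContinuousSignal:
    def test_bm_trait_detected(self):
        """Phylogenetically structured traits should usually be significant."""
        pvals = []
        for seed in range(15):
            tree = random_tree(100 + seed, 31)
            x = simulate_bm_traits(tree, 1.0, 0.0, seed=seed)
            pvals.append(continuous_signal_test(tree, x, n_perm=199,
                                                seed=seed).p_value)
        assert np.median(pvals) < 0.05

    def test_shuffled_trait_type_one_error(self, yule50):
        rng = np.random.default_rng(3)
        base = simulate_bm_traits(yule50, 1.0, 0.0, seed=1)
        rejections, n_tests = 0, 60
        for i in range(n_tests):
            vals = rng.permutation(list(base.values()))
            x = dict(zip(yule50.tip_labels, vals))
            res = continuous_signal_test(yule50, x, n_perm=199, seed=i)
            rejections += res.p_value <= 0.05
        assert rejections / n_tests <= 0.13

    def test_deterministic_and_positive_p(self, yule50):
        x = simulate_bm_traits(yule50, 1.0, 0.0, seed=2)
        r1 = continuous_signal_test(yule50, x, n_perm=99, seed=9)
        r2 = continuous_signal_test(yule50, x, n_perm=99, seed=9)
        assert r1.K == r2.K and r1.p_value == r2.p_value
        assert r1.p_value >= 1 / 100
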