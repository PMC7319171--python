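"""Phylogenetic signal tests.

Categorical characters (e.g. Crabtree positive/negative) are tested with the
Fitch small-parsimony count — the minimum number of state transitions on the
tree — against a null built by shuffling the observed states across tips.
Continuous traits use Blomberg's K, whose expectation is 1 under Brownian
motion, with a permutation null built the same way.  Randomization p-values
use the add-one convention, so they are never exactly zero (the minimum
attainable p with 1,000 randomizations is about 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg

from .oushift import bm_covariance, _as_tip_vector
from .treeio import Phylogeny

__all__ = [
    "CategoricalSignalResult",
    "ContinuousSignalResult",
    "fitch_min_transitions",
    "categorical_signal_test",
    "blomberg_k",
    "continuous_signal_test",
    "phylogenetic_mean",
]


@dataclass(frozen=True)
class CategoricalSignalResult:
    observed_transitions: int
    null_distribution: np.ndarray  # int, size n_rand
    null_median: float
    p_value: float  # (1 + #{null <= observed}) / (1 + n_rand)


@dataclass(frozen=True)
class ContinuousSignalResult:
    K: float
    p_value: float  # (1 + #{K_perm >= K_obs}) / (1 + n_perm)
    n_perm: int
    seed: int | None


# ----------------------------------------------------------- Fitch parsimony

def _states_to_codes(tree: Phylogeny, states) -> tuple[np.ndarray, list]:
    if isinstance(states, Mapping):
        try:
            vals = [states[lab] for lab in tree.tip_labels]
        except KeyError as exc:
            raise KeyError(f"tip without a state: {exc.args[0]!r}") from None
    else:
        vals = list(states)
        if len(vals) != tree.n_tips:
            raise ValueError(f"expected {tree.n_tips} states, got {len(vals)}")
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        raise ValueError("tip without a state")
    cats = sorted(set(vals), key=str)
    code = {c: k for k, c in enumerate(cats)}
    return np.array([code[v] for v in vals], dtype=int), cats


def _fitch_count(tree: Phylogeny, codes: np.ndarray) -> int:
    """Postorder Fitch pass over a binary tree; state sets as bitmasks."""
    tips = tree.tip_indices
    masks = np.zeros(tree.n_nodes, dtype=np.int64)
    masks[tips] = np.int64(1) << codes
    count = 0
    for nd in tree.postorder:
        kids = tree.children[nd]
        if not kids:
            continue
        a, b = masks[kids[0]], masks[kids[1]]
        inter = a & b
        if inter:
            masks[nd] = inter
        else:
            masks[nd] = a | b
            count += 1
    return count


def fitch_min_transitions(tree: Phylogeny, states) -> int:
    """Minimum number of character-state transitions explaining the tip
    states (Fitch small parsimony).  The tree must be binary; multistate
    characters are supported through the set-intersection/union recursion."""
    if not tree.is_binary():
        raise ValueError("Fitch parsimony requires a binary tree; resolve polytomies first")
    codes, _ = _states_to_codes(tree, states)
    return _fitch_count(tree, codes)


def categorical_signal_test(tree: Phylogeny, states, n_rand: int = 1000,
                            seed: int | None = None) -> CategoricalSignalResult:
    """Parsimony-randomization test of phylogenetic signal in a categorical
    character.

    The observed minimum transition count is compared with counts obtained by
    shuffling the tip-state vector over the tips (preserving state
    frequencies), ``n_rand`` times; signal is inferred when the observed count
    falls in the lower 5% tail of the null.
    """
    if not tree.is_binary():
        raise ValueError("Fitch parsimony requires a binary tree; resolve polytomies first")
    codes, cats = _states_to_codes(tree, states)
    if len(cats) < 2:
        warnings.warn("constant character: no transitions possible, p set to 1")
        null = np.zeros(n_rand, dtype=int)
        return CategoricalSignalResult(0, null, 0.0, 1.0)
    observed = _fitch_count(tree, codes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_rand, dtype=int)
    work = codes.copy()
    for r in range(n_rand):
        rng.shuffle(work)
        null[r] = _fitch_count(tree, work)
    p = (1 + int(np.sum(null <= observed))) / (1 + n_rand)
    return CategoricalSignalResult(observed, null, float(np.median(null)), p)


# ------------------------------------------------------------- Blomberg's K

def phylogenetic_mean(C: np.ndarray, x: np.ndarray) -> float:
    """GLS/ML estimate of the root state under BM: (1' C^-1 x) / (1' C^-1 1)."""
    cf = linalg.cho_factor(C, lower=True)
    ones = np.ones(x.size)
    Ci1 = linalg.cho_solve(cf, ones)
    return float(Ci1 @ x / (Ci1 @ ones))


def _k_statistic(C, cf, x):
    n = x.size
    ones = np.ones(n)
    Ci1 = linalg.cho_solve(cf, ones)
    sum_Ci1 = float(Ci1 @ ones)
    a_hat = float(Ci1 @ x) / sum_Ci1
    dev = x - a_hat
    num = float(dev @ dev)
    den = float(dev @ linalg.cho_solve(cf, dev))
    if den <= 0 or num <= 0:
        raise ValueError("Blomberg's K undefined for a (near-)constant trait")
    expected = (np.trace(C) - n / sum_Ci1) / (n - 1)
    return (num / den) / expected


def blomberg_k(tree: Phylogeny, x) -> float:
    """Blomberg's K: observed over BM-expected ratio of trait variance to
    phylogenetically corrected variance.  K = 1 is the Brownian-motion
    expectation; K > 1 means closer relatives resemble each other more than
    BM predicts, K near 0 means less.  Invariant to shifting and positively
    scaling the trait."""
    x = _as_tip_vector(tree, x)
    if tree.n_tips < 3:
        # the estimator is well defined for n = 2 as well; allow it
        pass
    if np.ptp(x) == 0:
        raise ValueError("Blomberg's K undefined for a constant trait")
    C = bm_covariance(tree)
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        raise ValueError("singular BM covariance (duplicated zero-distance tips?)") from None
    return float(_k_statistic(C, cf, x))


def continuous_signal_test(tree: Phylogeny, x, n_perm: int = 1000,
                           seed: int | None = None) -> ContinuousSignalResult:
    """Permutation test of phylogenetic signal in a continuous trait.

    Trait values are shuffled across tips ``n_perm`` times; the p-value is the
    add-one-corrected fraction of permuted K values at least as large as the
    observed K.
    """
    x = _as_tip_vector(tree, x)
    if np.ptp(x) == 0:
        raise ValueError("Blomberg's K undefined for a constant trait")
    C = bm_covariance(tree)
    cf = linalg.cho_factor(C, lower=True)
    k_obs = _k_statistic(C, cf, x)
    rng = np.random.default_rng(seed)
    count = 0
    work = x.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _k_statistic(C, cf, work) >= k_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return ContinuousSignalResult(float(k_obs), p, n_perm, seed)
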