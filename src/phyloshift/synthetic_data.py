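"""Simulation of trees and trait data with the structure the analysis assumes.

Provides a seeded Yule (pure-birth) tree simulator, exact trait simulators for
Brownian motion and Ornstein-Uhlenbeck processes (with branch-anchored optimum
shifts inherited by descendant lineages), a symmetric two-state Markov
simulator for binary characters, and a bundled fixture emulating a
31-species yeast dataset: a 200-MY-deep tree containing a monophyletic
"WGD clade" (~1/3 of the tips, stem near 100 MY), three fermentation proxies
(Gly, RQ, EthY) evolving under OU with a positive optimum shift on the WGD
stem, a shift-free BM trait (DW), and a clade-concordant Crabtree character.

A single global seed expands into independent per-stage substreams (tree,
each trait, binary character), so adding a trait does not perturb earlier
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .oushift import OUParameters
from .treeio import Phylogeny, anchor_calibrate

__all__ = [
    "SimulationConfig",
    "YeastDataset",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_ou_traits",
    "simulate_binary_trait",
    "make_yeast_like_dataset",
]


def _stage_rng(seed, stage: int) -> np.random.Generator:
    """Independent, order-stable substream for one simulation stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stage,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Controls for a single simulated dataset."""

    seed: int
    n_tips: int = 31
    birth_rate: float = 1.0          # splits per lineage per MY (pre-scaling)
    model: str = "BM"                # "BM" or "OU"
    ou: OUParameters | None = None
    root_state: float = 0.0
    binary_rate: float = 0.0         # transitions per MY for the binary trait

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.model not in ("BM", "OU"):
            raise ValueError("model must be 'BM' or 'OU'")


# ------------------------------------------------------------------- trees

def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed=None) -> Phylogeny:
    """Pure-birth tree grown until ``n_tips`` extant lineages.

    Waiting times between splits are exponential with rate k * birth_rate at
    k lineages; after the last split all pending branches are extended by one
    further exponential waiting time, so the tree is exactly ultrametric.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    parent = [-1]
    starts = [0.0]          # branch start time per node (root: 0)
    labels: list = [None]
    end_time = [None]       # filled at close
    active = []             # node ids of open lineages
    for _ in range(2):
        parent.append(0)
        starts.append(0.0)
        labels.append(None)
        active.append(len(parent) - 1)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        nd = active.pop(idx)
        # nd becomes an internal node splitting at time t
        starts_nd = starts[nd]
        end = t
        for _ in range(2):
            parent.append(nd)
            starts.append(t)
            labels.append(None)
            active.append(len(parent) - 1)
        starts[nd] = (starts_nd, end)  # mark as closed internal
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    lengths = np.zeros(len(parent))
    tip_no = 0
    for nd in range(len(parent)):
        if isinstance(starts[nd], tuple):
            s, e = starts[nd]
            lengths[nd] = e - s
        elif nd in active:
            lengths[nd] = t - starts[nd]
            tip_no += 1
            labels[nd] = f"t{tip_no}"
        # root keeps length 0
    return Phylogeny(np.array(parent), lengths, tuple(labels))


# ------------------------------------------------------------------- traits

def simulate_bm_traits(tree: Phylogeny, sigma2: float, root_state: float = 0.0,
                       seed=None) -> dict:
    """Brownian motion along branches: child = parent + N(0, sigma2 * length)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    vals = np.zeros(tree.n_nodes)
    vals[tree.root] = root_state
    for nd in tree.preorder:
        p = tree.parent[nd]
        if p >= 0:
            vals[nd] = vals[p] + rng.normal(0.0, np.sqrt(sigma2 * tree.lengths[nd]))
    return {tree.labels[i]: float(vals[i]) for i in tree.tip_indices}


def simulate_ou_traits(tree: Phylogeny, params: OUParameters,
                       seed=None, root_state: float | None = None) -> dict:
    """Exact OU transition along each branch under its regime optimum.

    Over a branch of length t with optimum theta_b:
    child = parent * e^(-alpha t) + theta_b * (1 - e^(-alpha t))
            + N(0, sigma2 * (1 - e^(-2 alpha t)) / (2 alpha)).
    Regimes: the base optimum is theta0; each shift (branch, delta) adds delta
    on that branch and every branch below it.  The root state defaults to
    theta0.
    """
    if params.alpha <= 0:
        raise ValueError("simulate_ou_traits requires alpha > 0")
    rng = np.random.default_rng(seed)
    a, s2 = params.alpha, params.sigma2
    theta = np.full(tree.n_nodes, params.theta0)
    deltas = dict(params.shifts)
    for nd in tree.preorder:
        p = tree.parent[nd]
        if p >= 0:
            theta[nd] = theta[p] + deltas.get(int(nd), 0.0)
    vals = np.zeros(tree.n_nodes)
    vals[tree.root] = params.theta0 if root_state is None else root_state
    for nd in tree.preorder:
        p = tree.parent[nd]
        if p >= 0:
            t = tree.lengths[nd]
            decay = np.exp(-a * t)
            var = s2 * (1.0 - np.exp(-2.0 * a * t)) / (2.0 * a)
            vals[nd] = vals[p] * decay + theta[nd] * (1.0 - decay) \
                + rng.normal(0.0, np.sqrt(var))
    return {tree.labels[i]: float(vals[i]) for i in tree.tip_indices}


def simulate_binary_trait(tree: Phylogeny, rate: float,
                          root_state: str = "negative",
                          states: tuple = ("negative", "positive"),
                          seed=None) -> dict:
    """Symmetric two-state Markov chain: P(change over a branch of length t)
    = (1 - e^(-2 rate t)) / 2."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if root_state not in states:
        raise ValueError("root_state must be one of states")
    rng = np.random.default_rng(seed)
    other = {states[0]: states[1], states[1]: states[0]}
    val = [None] * tree.n_nodes
    val[tree.root] = root_state
    for nd in tree.preorder:
        p = tree.parent[nd]
        if p >= 0:
            p_change = 0.5 * (1.0 - np.exp(-2.0 * rate * tree.lengths[nd]))
            val[nd] = other[val[p]] if rng.random() < p_change else val[p]
    return {tree.labels[i]: val[i] for i in tree.tip_indices}


# ------------------------------------------------------------ yeast fixture

#: Generating parameters of the yeast-like fixture, per trait:
#: (model, theta0/root, stationary sd (OU) or tip sd at the root depth (BM)).
YEAST_TRAIT_PARAMS = {
    "DW": ("BM", 0.25, 0.08),
    "Gly": ("OU", 0.02, 0.005),
    "RQ": ("OU", 1.00, 0.15),
    "EthY": ("OU", 0.30, 0.05),
}
YEAST_HEIGHT = 200.0       # MY, the root calibration anchor
YEAST_WGD_AGE = 100.0      # MY, target age of the WGD stem
YEAST_ALPHA_T = 5.0        # alpha * tree height for the OU traits
YEAST_SHIFT_SD = 3.0       # optimum shift in units of stationary sd


@dataclass(frozen=True)
class YeastDataset:
    """A simulated stand-in for the 31-species yeast trait dataset."""

    tree: Phylogeny
    traits: pd.DataFrame          # species x (DW, Gly, RQ, EthY, crabtree)
    wgd_clade: tuple              # tip labels of the WGD clade
    wgd_branch: int               # branch id (child node) of the WGD stem
    truth: dict                   # every generating parameter


def _choose_wgd_branch(tree: Phylogeny, target_age: float,
                       target_frac: float = 1.0 / 3.0) -> int:
    """Internal branch whose clade size is nearest ~1/3 of the tips and whose
    node age is nearest the target, scored jointly."""
    n = tree.n_tips
    ages = tree.ages
    best, best_score = None, np.inf
    for nd in range(tree.n_nodes):
        if tree.parent[nd] < 0 or not tree.children[nd]:
            continue
        k = tree.clade_tips(nd).size
        if not 2 <= k <= n - 2:
            continue
        score = abs(k - target_frac * n) / (target_frac * n) \
            + abs(ages[nd] - target_age) / target_age
        if score < best_score:
            best, best_score = nd, score
    if best is None:
        raise RuntimeError("no eligible internal branch for the WGD clade")
    return int(best)


def make_yeast_like_dataset(seed, n_tips: int = 31,
                            n_extra_positive: int = 2) -> YeastDataset:
    """Simulated bundle mirroring a real comparative dataset: tree, four continuous
    traits, a Crabtree-like binary character, and the generating truth.

    Gly, RQ and EthY evolve under OU with a +3-stationary-sd optimum shift on
    the WGD stem; DW evolves under shift-free BM; the binary character is
    'positive' throughout the WGD clade plus ``n_extra_positive`` random
    outside tips (long-term Crabtree-positive lineages arising independently).
    """
    tree = simulate_yule_tree(n_tips, birth_rate=1.0, seed=_stage_rng(seed, 0))
    tree = anchor_calibrate(tree, "root", YEAST_HEIGHT)
    wgd_branch = _choose_wgd_branch(tree, YEAST_WGD_AGE)
    wgd_clade = tuple(tree.labels[i] for i in tree.clade_tips(wgd_branch))

    alpha = YEAST_ALPHA_T / YEAST_HEIGHT
    traits = {}
    truth_traits = {}
    for stage, (name, (model, base, sd)) in enumerate(YEAST_TRAIT_PARAMS.items(),
                                                      start=1):
        rng = _stage_rng(seed, stage)
        if model == "BM":
            sigma2 = sd ** 2 / YEAST_HEIGHT
            traits[name] = simulate_bm_traits(tree, sigma2, base, rng)
            truth_traits[name] = {"model": "BM", "sigma2": sigma2,
                                  "root_state": base, "shift_branch": None}
        else:
            sigma2 = 2.0 * alpha * sd ** 2
            delta = YEAST_SHIFT_SD * sd
            params = OUParameters(alpha=alpha, sigma2=sigma2, theta0=base,
                                  shifts=((wgd_branch, delta),))
            traits[name] = simulate_ou_traits(tree, params, rng)
            truth_traits[name] = {"model": "OU", "alpha": alpha,
                                  "sigma2": sigma2, "theta0": base,
                                  "shift_branch": wgd_branch,
                                  "delta_theta": delta,
                                  "stationary_sd": sd}

    rng = _stage_rng(seed, len(YEAST_TRAIT_PARAMS) + 1)
    outside = [lab for lab in tree.tip_labels if lab not in wgd_clade]
    extra = list(rng.choice(outside, size=min(n_extra_positive, len(outside)),
                            replace=False))
    positive = set(wgd_clade) | set(extra)
    crabtree = {lab: ("positive" if lab in positive else "negative")
                for lab in tree.tip_labels}

    table = pd.DataFrame({name: pd.Series(vals) for name, vals in traits.items()})
    table["crabtree"] = pd.Series(crabtree)
    table.index.name = "species"
    table = table.loc[list(tree.tip_labels)]

    truth = {
        "seed": seed,
        "n_tips": n_tips,
        "height": YEAST_HEIGHT,
        "wgd_branch": wgd_branch,
        "wgd_age": float(tree.ages[wgd_branch]),
        "wgd_clade": wgd_clade,
        "extra_positive": extra,
        "alpha": alpha,
        "traits": truth_traits,
    }
    return YeastDataset(tree=tree, traits=table, wgd_clade=wgd_clade,
                        wgd_branch=wgd_branch, truth=truth)
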