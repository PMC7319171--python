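"""Ancestral states under Brownian motion and phenogram/heat-map data.

A phenogram projects the phylogeny into (time, trait) space: each branch
becomes a line segment from (parent time, parent state) to (child time, child
state), with observed values at the tips and GLS/ML Brownian-motion estimates
at internal nodes.  Ancestral states are computed under BM even when an OU
model is preferred for inference — the phenogram is a descriptive device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .oushift import bm_covariance, _as_tip_vector
from .phylosignal import phylogenetic_mean
from .treeio import Phylogeny

__all__ = [
    "PhenogramData",
    "ancestral_states_bm",
    "phenogram_segments",
    "heatmap_matrix",
]


@dataclass(frozen=True)
class PhenogramData:
    """One line segment per non-root node plus tip group labels.

    ``segments`` columns: node, label, group, parent_time, parent_state,
    child_time, child_state.  Times run forward from the root (0) to the tree
    height."""

    segments: pd.DataFrame
    tree_height: float


def _node_tip_shared_times(tree: Phylogeny) -> np.ndarray:
    """S[u, i] = time from the root to MRCA(node u, tip i) — the shared-path
    covariance (unit rate) between a node's state and a tip's state under BM."""
    tips = tree.tip_indices
    S = np.zeros((tree.n_nodes, tips.size))
    for u in range(tree.n_nodes):
        covered = np.zeros(tips.size, dtype=bool)
        a = u
        while a >= 0:
            mask = tree.descendant_tip_mask(a) & ~covered
            S[u, mask] = tree.times[a]
            covered |= mask
            a = tree.parent[a]
    return S


def ancestral_states_bm(tree: Phylogeny, x) -> np.ndarray:
    """GLS/ML estimate of every node's state under Brownian motion.

    Returns a vector over all nodes (tips carry their observed values; the
    root carries the phylogenetic mean used by Blomberg's K).  Equivalent to
    the conditional expectation given the tips, i.e. the re-rooted
    phylogenetic weighted mean.
    """
    x = _as_tip_vector(tree, x)
    C = bm_covariance(tree)
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError:
        raise ValueError("singular BM covariance") from None
    a_hat = phylogenetic_mean(C, x)
    S = _node_tip_shared_times(tree)
    states = a_hat + S @ linalg.cho_solve(cf, x - a_hat)
    states[tree.tip_indices] = x  # exact by construction; enforce bitwise
    return states


def phenogram_segments(tree: Phylogeny, x, groups: "Mapping | Iterable[str] | None" = None,
                       group_names: tuple = ("WGD+", "WGD-")) -> PhenogramData:
    """Branch segments of the (time, trait) projection.

    ``groups`` may be a mapping {tip label: group} or an iterable of tip
    labels forming the focal clade (labelled ``group_names[0]``, the rest
    ``group_names[1]``); branches whose descendant tips span both groups are
    labelled ``"ancestral"``.
    """
    x = _as_tip_vector(tree, x)
    states = ancestral_states_bm(tree, x)
    times = tree.times

    if groups is None:
        tip_group = {lab: "" for lab in tree.tip_labels}
    elif isinstance(groups, Mapping):
        tip_group = dict(groups)
    else:
        focal = set(groups)
        tip_group = {lab: group_names[0] if lab in focal else group_names[1]
                     for lab in tree.tip_labels}

    rows = []
    for nd in range(tree.n_nodes):
        p = tree.parent[nd]
        if p < 0:
            continue
        below = {tip_group.get(tree.labels[t], "") for t in tree.clade_tips(nd)}
        group = below.pop() if len(below) == 1 else "ancestral"
        rows.append({
            "node": nd,
            "label": tree.labels[nd] or "",
            "group": group,
            "parent_time": float(times[p]),
            "parent_state": float(states[p]),
            "child_time": float(times[nd]),
            "child_state": float(states[nd]),
        })
    return PhenogramData(segments=pd.DataFrame(rows), tree_height=tree.height)


def heatmap_matrix(table: pd.DataFrame, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Per-trait z-scores (mean 0, sd 1 over non-missing species) for the
    descriptive heat map; rows follow the tree's tip order when a tree is
    given.  Constant columns become zeros with a warning; missing entries
    stay missing and are excluded from the moments."""
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("no numeric trait columns to standardize")
    out = pd.DataFrame(index=table.index)
    for c in num.columns:
        col = num[c]
        if col.notna().sum() < 2:
            raise ValueError(f"trait {c!r}: fewer than 2 species with data")
        sd = col.std()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"trait {c!r} is constant; z-scores set to 0")
            out[c] = np.where(col.notna(), 0.0, np.nan)
        else:
            out[c] = (col - col.mean()) / sd
    if tree is not None:
        order = [lab for lab in tree.tip_labels if lab in out.index]
        missing = sorted(set(out.index) - set(order))
        out = out.loc[order + missing]
    return out
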