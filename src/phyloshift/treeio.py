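"""Rooted time-calibrated phylogenies: Newick I/O, pruning, strain averaging, calibration.

The :class:`Phylogeny` container is an immutable array-backed rooted tree with
branch lengths in time units (forward from the root; node *age* is measured
backward from the tips).  Newick parsing is delegated to :mod:`dendropy`;
everything downstream (covariances, parsimony, shift designs) operates on the
integer-indexed arrays kept here.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "NewickParseError",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "average_strain_replicates",
    "anchor_calibrate",
    "read_trait_table",
    "validate_trait_table",
    "TRAIT_COLUMNS",
    "CATEGORICAL_COLUMN",
]

#: Continuous trait columns of a standard trait table, in canonical order:
#: dry-weight growth rate, glycerol production (g/gDW hr), respiratory
#: quotient (dimensionless) and ethanol yield (g ethanol / g glucose).
TRAIT_COLUMNS = ("DW", "Gly", "RQ", "EthY")

#: Binary character column (Crabtree-positive / Crabtree-negative).
CATEGORICAL_COLUMN = "crabtree"

#: Relative ultrametricity tolerance (fraction of tree height).
ULTRAMETRIC_RTOL = 1e-6


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be interpreted as a valid tree."""


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with branch lengths, indexed by node.

    Nodes are integers ``0 .. n_nodes-1`` in preorder (root first).  A branch
    is identified by the index of its *child* node; the root carries no
    branch.  ``labels[i]`` is the tip label for leaves and an optional
    internal-node label otherwise.
    """

    parent: np.ndarray          # int, -1 at the root
    lengths: np.ndarray         # float, 0.0 at the root
    labels: tuple               # str | None per node
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=int)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "lengths", lengths)
        if parent.shape != lengths.shape:
            raise ValueError("parent and lengths must have equal shape")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any(lengths[parent >= 0] < 0):
            raise ValueError("negative branch length")
        tips = self.tip_indices
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None for lab in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dups}")

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self) -> tuple:
        if "children" not in self._cache:
            kids = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    kids[p].append(i)
            self._cache["children"] = tuple(tuple(k) for k in kids)
        return self._cache["children"]

    @property
    def tip_indices(self) -> np.ndarray:
        if "tips" not in self._cache:
            is_parent = np.zeros(self.n_nodes, dtype=bool)
            is_parent[self.parent[self.parent >= 0]] = True
            self._cache["tips"] = np.flatnonzero(~is_parent)
        return self._cache["tips"]

    @property
    def n_tips(self) -> int:
        return self.tip_indices.size

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children always before parents."""
        if "postorder" not in self._cache:
            order, stack = [], [self.root]
            while stack:
                nd = stack.pop()
                order.append(nd)
                stack.extend(self.children[nd])
            self._cache["postorder"] = np.array(order[::-1], dtype=int)
        return self._cache["postorder"]

    @property
    def preorder(self) -> np.ndarray:
        return self.postorder[::-1]

    @property
    def times(self) -> np.ndarray:
        """Time of each node measured forward from the root (root at 0)."""
        if "times" not in self._cache:
            t = np.zeros(self.n_nodes)
            for nd in self.preorder:
                p = self.parent[nd]
                if p >= 0:
                    t[nd] = t[p] + self.lengths[nd]
            self._cache["times"] = t
        return self._cache["times"]

    @property
    def height(self) -> float:
        return float(self.times[self.tip_indices].max())

    @property
    def ages(self) -> np.ndarray:
        """Node ages measured backward from the tips (tips of an ultrametric
        tree at age 0)."""
        return self.height - self.times

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        depths = self.times[self.tip_indices]
        h = depths.max()
        if h == 0:
            return True
        return bool(depths.max() - depths.min() <= rtol * h)

    def is_binary(self) -> bool:
        return all(len(k) in (0, 2) for k in self.children)

    # ----------------------------------------------------------------- queries
    def tip_index(self, label: str) -> int:
        if "tipmap" not in self._cache:
            self._cache["tipmap"] = {self.labels[i]: int(i) for i in self.tip_indices}
        try:
            return self._cache["tipmap"][label]
        except KeyError:
            raise KeyError(f"unknown tip label: {label!r}") from None

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor of a set of tip labels."""
        nodes = [self.tip_index(l) for l in labels]
        if not nodes:
            raise ValueError("empty label set")
        paths = []
        for nd in nodes:
            path = []
            while nd >= 0:
                path.append(nd)
                nd = self.parent[nd]
            paths.append(set(path))
        common = set.intersection(*paths)
        # deepest common ancestor
        return int(max(common, key=lambda n: self.times[n]))

    def clade_tips(self, node: int) -> np.ndarray:
        """Tip indices descending from (and including) ``node``."""
        out, stack = [], [int(node)]
        while stack:
            nd = stack.pop()
            kids = self.children[nd]
            if kids:
                stack.extend(kids)
            else:
                out.append(nd)
        return np.array(sorted(out), dtype=int)

    def descendant_tip_mask(self, node: int) -> np.ndarray:
        """Boolean mask over ``tip_indices`` for membership in ``node``'s clade."""
        tips = self.tip_indices
        members = set(self.clade_tips(node).tolist())
        return np.array([t in members for t in tips])


# --------------------------------------------------------------------- Newick

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    labels: list = [None] * n
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                tok = nd.taxon.label if nd.taxon else (nd.label or "<internal>")
                raise NewickParseError(f"missing branch length on branch above {tok!r}")
            lengths[i] = float(nd.edge.length)
        if nd.taxon is not None:
            labels[i] = nd.taxon.label
        elif nd.label:
            labels[i] = nd.label
    return _rebuild(parent, lengths, labels, collapse_zero_internal=True)


def _rebuild(parent, lengths, labels, collapse_zero_internal=False) -> Phylogeny:
    """Renumber a parent-array tree to preorder, optionally collapsing
    zero-length internal branches (which would make shift placements
    unidentifiable)."""
    n = len(parent)
    children = [[] for _ in range(n)]
    root = -1
    for i, p in enumerate(parent):
        if p == -1:
            root = i
        elif p >= 0:
            children[p].append(i)  # nodes with parent == -2 are dropped
    if collapse_zero_internal:
        collapsed = False
        for i in range(n):
            if children[i] and parent[i] >= 0 and lengths[i] == 0.0:
                p = parent[i]
                for c in children[i]:
                    parent[c] = p
                    children[p].append(c)
                children[p].remove(i)
                children[i] = []
                parent[i] = -2  # dropped
                collapsed = True
        if collapsed:
            warnings.warn("collapsed zero-length internal branch(es)", stacklevel=3)
    # preorder renumber, skipping dropped nodes
    order, stack = [], [root]
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(reversed(children[nd]))
    new_id = {old: new for new, old in enumerate(order)}
    m = len(order)
    new_parent = np.full(m, -1, dtype=int)
    new_lengths = np.zeros(m)
    new_labels = [None] * m
    for old in order:
        i = new_id[old]
        if parent[old] >= 0:
            new_parent[i] = new_id[parent[old]]
            new_lengths[i] = lengths[old]
        new_labels[i] = labels[old]
    return Phylogeny(new_parent, new_lengths, tuple(new_labels))


def read_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick tree with branch lengths.

    Raises :class:`NewickParseError` on malformed input (unbalanced
    parentheses, duplicate tip labels, missing branch lengths).
    """
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    try:
        return _from_dendropy(dtree)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc


def write_newick(tree: Phylogeny, precision: int = 12) -> str:
    """Serialize to a Newick string (round-trips through :func:`read_newick`)."""
    fmt = f"%.{precision}g"

    def render(nd: int) -> str:
        kids = tree.children[nd]
        if kids:
            inner = ",".join(render(c) for c in kids)
            lab = tree.labels[nd] or ""
            body = f"({inner}){lab}"
        else:
            body = tree.labels[nd]
        if tree.parent[nd] >= 0:
            return f"{body}:{fmt % tree.lengths[nd]}"
        return body

    return render(tree.root) + ";"


# -------------------------------------------------------------------- pruning

def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict the tree to a subset of tips.

    Internal nodes left with a single child are spliced out (branch lengths
    summed), so root-to-tip depths and pairwise patristic distances among the
    kept tips are preserved exactly.  The root is retained even if it ends up
    with a single child, which keeps depths intact.
    """
    keep = set(keep)
    known = set(tree.tip_labels)
    unknown = sorted(keep - known)
    if unknown:
        raise KeyError(f"labels not in tree: {unknown}")
    if len(keep) < 2:
        raise ValueError("need at least two tips to keep")

    n = tree.n_nodes
    keep_node = np.zeros(n, dtype=bool)
    for lab in keep:
        nd = tree.tip_index(lab)
        while nd >= 0 and not keep_node[nd]:
            keep_node[nd] = True
            nd = tree.parent[nd]

    parent = tree.parent.copy()
    lengths = tree.lengths.copy()
    labels = list(tree.labels)
    children = [list(c) for c in tree.children]
    # drop unkept subtrees
    for i in range(n):
        if keep_node[i]:
            children[i] = [c for c in children[i] if keep_node[c]]
        else:
            parent[i] = -2
            children[i] = []
    # splice unary internal nodes (never the root)
    for nd in tree.postorder:
        if parent[nd] == -2 or nd == tree.root:
            continue
        if len(children[nd]) == 1:
            child = children[nd][0]
            p = parent[nd]
            lengths[child] += lengths[nd]
            parent[child] = p
            children[p][children[p].index(nd)] = child
            parent[nd] = -2
            children[nd] = []
    return _rebuild(parent, lengths, labels)


# ----------------------------------------------------- strain-level averaging

def average_strain_replicates(
    raw: pd.DataFrame,
    strain_to_species: Mapping[str, str],
) -> pd.DataFrame:
    """Collapse a strain-level trait table to one row per species.

    Continuous traits are averaged arithmetically over strains with
    non-missing values; the categorical character must be unanimous within a
    species (a conflict raises ``ValueError``).

    Parameters
    ----------
    raw:
        Strain-level table indexed by strain name (or with a ``strain``
        column), with continuous trait columns and optionally a categorical
        column.
    strain_to_species:
        Mapping from every strain name to its species.
    """
    tbl = raw.copy()
    if "strain" in tbl.columns:
        tbl = tbl.set_index("strain")
    missing = sorted(set(tbl.index) - set(strain_to_species))
    if missing:
        raise KeyError(f"strains without a species assignment: {missing}")
    species = tbl.index.map(lambda s: strain_to_species[s])
    tbl = tbl.assign(species=species)

    num_cols = [c for c in tbl.columns if c != "species"
                and pd.api.types.is_numeric_dtype(tbl[c])]
    cat_cols = [c for c in tbl.columns if c != "species" and c not in num_cols]

    grouped = tbl.groupby("species", sort=True)
    out = grouped[num_cols].mean() if num_cols else pd.DataFrame(index=grouped.size().index)
    for c in cat_cols:
        states = grouped[c].agg(lambda s: set(s.dropna()))
        conflicts = {sp: sorted(st) for sp, st in states.items() if len(st) > 1}
        if conflicts:
            raise ValueError(f"conflicting categorical states within species: {conflicts}")
        out[c] = states.map(lambda st: next(iter(st)) if st else np.nan)
    out.index.name = "species"
    return out


# ---------------------------------------------------------------- calibration

def anchor_calibrate(tree: Phylogeny, node: "int | str | Iterable[str]",
                     age: float) -> Phylogeny:
    """Rescale all branch lengths uniformly so a chosen node sits at ``age``
    (in MY, measured backward from the tips).

    ``node`` may be a node index, the string ``"root"``, or an iterable of tip
    labels whose MRCA is the anchor.  Uniform scaling preserves ultrametricity
    and every branch-length ratio; only one anchor can be honoured exactly.
    """
    if age <= 0:
        raise ValueError("anchor age must be positive")
    if isinstance(node, str) and node == "root":
        nd = tree.root
    elif isinstance(node, (int, np.integer)):
        nd = int(node)
    else:
        nd = tree.mrca(node)
    subtree_height = float(tree.times[tree.clade_tips(nd)].max() - tree.times[nd])
    if subtree_height <= 0:
        raise ValueError("anchor node has zero height (is it a tip?)")
    factor = age / subtree_height
    return Phylogeny(tree.parent.copy(), tree.lengths * factor, tree.labels)


# ---------------------------------------------------------------- trait table

def read_trait_table(path_or_buf, sep: str | None = None) -> pd.DataFrame:
    """Read a species x trait CSV/TSV with header
    ``species,DW,Gly,RQ,EthY,crabtree``; empty fields or ``NA`` are missing."""
    df = pd.read_csv(path_or_buf, sep=sep, engine="python" if sep is None else "c",
                     na_values=["NA", ""], index_col="species")
    validate_trait_table(df)
    return df


def validate_trait_table(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated species keys: {dups}")
    if "RQ" in df.columns:
        rq = pd.to_numeric(df["RQ"], errors="coerce")
        bad = df.index[(rq <= 0).fillna(False)]
        if len(bad):
            raise ValueError(f"RQ must be positive where present; offending species: {list(bad)}")


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index_label="species", na_rep="NA")
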