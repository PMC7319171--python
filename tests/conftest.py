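import numpy as np
import pytest

from phyloshift import anchor_calibrate, read_newick, simulate_yule_tree


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced16():
    """Balanced ultrametric 16-tip tree of height 4."""

    def clade(labels, depth):
        if len(labels) == 1:
            return f"{labels[0]}:{depth}"
        half = len(labels) // 2
        return f"({clade(labels[:half], depth - 1)},{clade(labels[half:], depth - 1)}):1"

    labels = [f"s{i}" for i in range(16)]
    return read_newick(f"({clade(labels[:8], 3)},{clade(labels[8:], 3)});")


@pytest.fixture(scope="session")
def yule50():
    """A fixed 50-tip Yule tree rescaled to unit height."""
    tree = simulate_yule_tree(50, 1.0, seed=42)
    return anchor_calibrate(tree, "root", 1.0)


def random_tree(seed, n_tips, height=1.0):
    tree = simulate_yule_tree(n_tips, 1.0, seed=seed)
    return anchor_calibrate(tree, "root", height)
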