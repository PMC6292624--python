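"""Shared fixtures: panel-bound trees, default model, small hand-built trees."""

import numpy as np
import pandas as pd
import pytest

from mitocline import bundled_tree, default_panel, denmark_model
from mitocline.tree import HaploNode, HaploTree, Variant


@pytest.fixture(scope="session")
def tree_and_panel():
    tree = bundled_tree()
    panel = default_panel(tree)
    tree.attach_panel(panel)
    return tree, panel


@pytest.fixture(scope="session")
def model():
    return denmark_model()


def make_tree(spec):
    """Build a panel-less tree from {(name, parent, level): [(pos, allele), ...]}."""
    nodes = [
        HaploNode(name, parent, level, tuple(Variant(p, a) for p, a in variants))
        for (name, parent, level), variants in spec.items()
    ]
    return HaploTree(nodes)


@pytest.fixture
def mini_tree():
    """root -> R(macro) -> H(hg) -> H1(subhg), plus U(hg) under R."""
    tree = make_tree(
        {
            ("mt-MRCA", None, "root"): [],
            ("R", "mt-MRCA", "macro"): [(10, "C"), (20, "T")],
            ("H", "R", "hg"): [(30, "A"), (40, "G")],
            ("U", "R", "hg"): [(50, "G")],
            ("H1", "H", "subhg"): [(60, "T")],
        }
    )
    panel = pd.DataFrame(
        {
            "position": [10, 20, 30, 40, 50, 60, 70, 80],
            "ref": ["T", "C", "G", "A", "A", "C", "C", "C"],
            "alt": ["C", "T", "A", "G", "G", "T", "T", "T"],
        }
    )
    tree.attach_panel(panel)
    return tree, panel


def genotype_for(tree, panel, hg):
    """Noise-free call vector implied by a root->hg path."""
    pos_to_idx = {int(p): i for i, p in enumerate(panel["position"])}
    vec = np.zeros(len(panel), dtype=np.int8)
    for v in tree.path_variants(hg):
        vec[pos_to_idx[v.position]] = 1
    return vec
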