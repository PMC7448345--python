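"""Shared fixtures: small hand-built hierarchies and random-tree helpers."""

import numpy as np
import pytest

from ontodist import Ontology


@pytest.fixture
def chain_ontology():
    """root -> a -> b -> c, a single chain of depth 3."""
    return Ontology({"a": "root", "b": "a", "c": "b"})


@pytest.fixture
def flat_ontology():
    """Five findings all children of the root."""
    return Ontology({f"f{i}": "root" for i in range(5)})


@pytest.fixture
def tremor_ontology():
    """Sibling findings at depth 4 under a shared parent at depth 3.

    root(0) -> x(1) -> y(2) -> tremor(3) -> {resting_tremor, postural_tremor}(4);
    the classic worked example: Wu-Palmer sibling distance 0.25, parent
    augmentation weight 0.5.
    """
    return Ontology({
        "x": "root", "y": "x", "tremor": "y",
        "resting_tremor": "tremor", "postural_tremor": "tremor",
    })


def make_random_tree(n_concepts: int, seed: int) -> Ontology:
    """Random mono-hierarchy: each new concept attaches to a random node."""
    rng = np.random.default_rng(seed)
    nodes = ["root"]
    parent_of = {}
    for i in range(n_concepts):
        cid = f"N{i:04d}"
        parent_of[cid] = nodes[rng.integers(len(nodes))]
        nodes.append(cid)
    return Ontology(parent_of)
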