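import numpy as np
import pytest

from perisynapse import synthetic
from perisynapse.morphology import (
    Compartment,
    DendriteNode,
    DendriteTree,
    classify_branches,
)


def make_tree(node_specs):
    """Build a tree from (id, parent, (x, y, z), radius, compartment) tuples."""
    nodes = {
        nid: DendriteNode(nid, parent, pos, radius, comp)
        for nid, parent, pos, radius, comp in node_specs
    }
    return DendriteTree(nodes=nodes)


@pytest.fixture
def straight_cable():
    """Soma at origin, 10 shaft nodes along +x at 2 μm spacing, radius 0.2."""
    specs = [(1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA)]
    for i in range(10):
        specs.append((i + 2, i + 1, (2.0 * (i + 1), 0.0, 0.0), 0.2, Compartment.SHAFT))
    return make_tree(specs)


@pytest.fixture
def bifurcating_tree():
    """Soma -> 3-node trunk -> two 3-node daughters."""
    specs = [(1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA)]
    nid = 2
    for i in range(3):
        specs.append((nid, nid - 1, (0.0, 2.0 * (i + 1), 0.0), 0.3, Compartment.SHAFT))
        nid += 1
    fork = nid - 1
    for side in (-1.0, 1.0):
        parent = fork
        for i in range(3):
            specs.append(
                (nid, parent, (side * 2.0 * (i + 1), 6.0 + 2.0 * (i + 1), 0.0), 0.3, Compartment.SHAFT)
            )
            parent = nid
            nid += 1
    return make_tree(specs)


@pytest.fixture(scope="session")
def synth_cell():
    """Default synthetic cell: tree + domain-labelled branches + truth."""
    return synthetic.generate_tree(synthetic.TreeConfig(), seed=42)


@pytest.fixture(scope="session")
def synth_puncta(synth_cell):
    tree, labels, _ = synth_cell
    puncta, truth = synthetic.place_puncta(tree, labels, synthetic.PunctaConfig(), seed=7)
    return puncta, truth


def brute_force_surface(point, tree, tol=1e-9):
    """Independent per-segment python-loop oracle for surface distance.

    Returns (distance, branch ids of all segments within ``tol`` of the min).
    """
    seg = tree.segments()
    p = np.asarray(point, float)
    dists = []
    for i in range(len(seg.a)):
        a, b = seg.a[i], seg.b[i]
        ab = b - a
        denom = float(ab @ ab)
        t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0)) if denom > 0 else 0.0
        closest = a + t * ab
        r = seg.ra[i] + t * (seg.rb[i] - seg.ra[i])
        dists.append(max(float(np.linalg.norm(p - closest)) - r, 0.0))
    dmin = min(dists)
    cands = {int(seg.branch_id[i]) for i, d in enumerate(dists) if d <= dmin + tol}
    return dmin, cands
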