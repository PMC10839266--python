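"""Morphology: SWC I/O, branch taxonomy, and point-to-surface geometry."""

import numpy as np
import pytest

from perisynapse.morphology import (
    Compartment,
    DendriteNode,
    DendriteTree,
    Domain,
    MorphologyError,
    Subdivision,
    assign_domains,
    classify_branches,
    read_morphology,
    surface_distance,
    surface_distances,
    total_cable_length,
    write_morphology,
)
from perisynapse import synthetic

from conftest import brute_force_surface, make_tree


class TestSwcIO:
    def test_minimal_tree_round_trip(self, tmp_path):
        p = tmp_path / "t.swc"
        p.write_text("1 1 0 0 0 1.0 -1\n2 3 2 0 0 0.3 1\n3 3 4 0 0 0.3 2\n")
        tree = read_morphology(p)
        assert len(tree.nodes) == 3
        assert len(classify_branches(tree)) == 1
        out = tmp_path / "out.swc"
        write_morphology(tree, out)
        tree2 = read_morphology(out, cell_id=tree.cell_id)
        assert tree.nodes == tree2.nodes

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1 -1\n1 3 1 0 0 0.3 1\n")
        with pytest.raises(MorphologyError, match="duplicate"):
            read_morphology(p)

    def test_multi_root_rejected(self):
        with pytest.raises(MorphologyError, match="root"):
            make_tree(
                [
                    (1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA),
                    (2, None, (1.0, 0.0, 0.0), 1.0, Compartment.SOMA),
                ]
            )

    def test_cycle_rejected(self):
        nodes = {
            1: DendriteNode(1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA),
            2: DendriteNode(2, 3, (1.0, 0.0, 0.0), 0.3, Compartment.SHAFT),
            3: DendriteNode(3, 2, (2.0, 0.0, 0.0), 0.3, Compartment.SHAFT),
        }
        with pytest.raises(MorphologyError, match="cycle"):
            DendriteTree(nodes=nodes)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(MorphologyError, match="radius"):
            DendriteNode(1, None, (0.0, 0.0, 0.0), 0.0, Compartment.SOMA)


class TestBranchTaxonomy:
    def test_unbranched_cable_is_single_primary(self, straight_cable):
        labels = classify_branches(straight_cable)
        assert len(labels) == 1
        (lbl,) = labels.values()
        assert lbl.branch_order == 1
        assert lbl.subdivision is Subdivision.PRIMARY

    def test_bifurcation_orders_and_subdivisions(self, bifurcating_tree):
        labels = classify_branches(bifurcating_tree)
        orders = sorted(l.branch_order for l in labels.values())
        assert orders == [1, 2, 2]
        subs = sorted(l.subdivision.value for l in labels.values())
        assert subs == ["primary", "terminal", "terminal"]

    def test_random_binary_tree_matches_exhaustive_traversal(self):
        # grow a random binary tree of 16 tips -> 31 branches, then label it
        rng = np.random.default_rng(5)
        specs = [(1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA)]
        nid = 2
        tips = []
        specs.append((nid, 1, (0.0, 1.0, 0.0), 0.3, Compartment.SHAFT))
        tips.append((nid, np.array([0.0, 1.0, 0.0])))
        nid += 1
        while len(specs) < 200 or len(tips) < 16:
            i = rng.integers(len(tips))
            parent, pos = tips[i]
            if rng.uniform() < 0.12 and len(tips) < 16:
                newtips = []
                for _ in range(2):
                    step = rng.normal(0, 1, 3)
                    step /= np.linalg.norm(step)
                    npos = pos + step
                    specs.append((nid, parent, tuple(npos), 0.3, Compartment.SHAFT))
                    newtips.append((nid, npos))
                    nid += 1
                tips.pop(i)
                tips.extend(newtips)
            else:
                step = rng.normal(0, 1, 3)
                step /= np.linalg.norm(step)
                npos = pos + step
                specs.append((nid, parent, tuple(npos), 0.3, Compartment.SHAFT))
                tips[i] = (nid, npos)
                nid += 1
        tree = make_tree(specs)
        labels = classify_branches(tree)
        assert len(labels) == 31  # 16 tips in a binary tree

        # oracle: enumerate root-to-node paths and count branch points
        children = tree.children()
        shaft = {n for n, nd in tree.nodes.items() if nd.compartment is Compartment.SHAFT}
        for lbl in labels.values():
            first, last = lbl.node_ids[0], lbl.node_ids[-1]
            # order = number of branch points strictly above, plus 1
            order = 1
            cur = tree.nodes[first].parent_id
            while cur is not None:
                kids = [c for c in children[cur] if c in shaft]
                if len(kids) > 1:
                    order += 1
                cur = tree.nodes[cur].parent_id
            assert order == lbl.branch_order
            is_tip = not any(c in shaft for c in children[last])
            soma_adjacent = tree.nodes[first].parent_id == 1
            if soma_adjacent:
                assert lbl.subdivision is Subdivision.PRIMARY
            elif is_tip:
                assert lbl.subdivision is Subdivision.TERMINAL
            else:
                assert lbl.subdivision is Subdivision.INTERMEDIATE

    def test_labels_invariant_to_reindexing_and_rigid_motion(self, bifurcating_tree):
        base = classify_branches(bifurcating_tree)
        # reindex ids (reverse order) and rotate+translate positions
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        ids = sorted(bifurcating_tree.nodes)
        remap = {old: new for old, new in zip(ids, reversed(ids))}
        specs = []
        for old in ids:
            n = bifurcating_tree.nodes[old]
            pos = tuple(rot @ np.asarray(n.position) + np.array([5.0, -3.0, 2.0]))
            specs.append(
                (remap[old], None if n.parent_id is None else remap[n.parent_id], pos, n.radius, n.compartment)
            )
        moved = make_tree(specs)
        other = classify_branches(moved)
        key = lambda labels: sorted(
            (l.branch_order, l.subdivision.value, round(l.length, 9), len(l.node_ids))
            for l in labels.values()
        )
        assert key(base) == key(other)

    def test_branch_lengths_conserve_total_cable(self, synth_cell):
        tree, labels, _ = synth_cell
        total = 0.0
        for n in tree.nodes.values():
            if n.parent_id is None or n.compartment is not Compartment.SHAFT:
                continue
            total += float(np.linalg.norm(np.subtract(n.position, tree.nodes[n.parent_id].position)))
        assert total_cable_length(labels) == pytest.approx(total, rel=1e-9)

    def test_no_shaft_warns_and_returns_empty(self):
        tree = make_tree([(1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA)])
        with pytest.warns(UserWarning, match="no shaft"):
            assert classify_branches(tree) == {}


class TestDomains:
    def test_explicit_annotation_copied_verbatim(self, bifurcating_tree):
        labels = classify_branches(bifurcating_tree)
        annot = {bid: Domain.BASAL for bid in labels}
        out = assign_domains(bifurcating_tree, labels, annot)
        assert all(l.domain is Domain.BASAL for l in out.values())

    def test_missing_annotation_warns_unassigned(self, bifurcating_tree):
        labels = classify_branches(bifurcating_tree)
        annot = {min(labels): Domain.BASAL}
        with pytest.warns(UserWarning, match="unassigned"):
            out = assign_domains(bifurcating_tree, labels, annot)
        assert out[min(labels)].domain is Domain.BASAL
        assert sum(l.domain is Domain.UNASSIGNED for l in out.values()) == len(labels) - 1

    def test_threshold_mode_matches_generator_truth(self, synth_cell):
        tree, labels, truth = synth_cell
        for lbl in labels.values():
            first = lbl.node_ids[0]
            side = truth.node_side[first]
            if side == "basal":
                assert lbl.domain is Domain.BASAL
            else:
                d = truth.node_path_dist[tree.nodes[first].parent_id]
                if d < 100:
                    assert lbl.domain is Domain.PROXIMAL_APICAL
                elif d < 250:
                    assert lbl.domain is Domain.DISTAL_APICAL
                else:
                    assert lbl.domain is Domain.APICAL_TUFT

    def test_basal_branch_is_basal_regardless_of_distance(self):
        cfg = synthetic.TreeConfig(basal_length=400.0)  # far beyond both cutoffs
        tree, labels, truth = synthetic.generate_tree(cfg, seed=0)
        basal = [l for l in labels.values() if truth.node_side[l.node_ids[0]] == "basal"]
        assert basal and all(l.domain is Domain.BASAL for l in basal)


class TestSurfaceDistance:
    def test_point_beside_cylinder(self, straight_cable):
        hit = surface_distance((10.0, 0.6, 0.0), straight_cable)
        assert hit.surface_distance == pytest.approx(0.4, abs=1e-12)
        assert hit.nearest_compartment is Compartment.SHAFT

    def test_point_on_centerline_is_zero(self, straight_cable):
        hit = surface_distance((10.0, 0.0, 0.0), straight_cable)
        assert hit.surface_distance == 0.0

    def test_matches_brute_force(self, synth_cell):
        # vectorised path vs an independent per-segment python loop; agreement
        # to 1e-9 um (different float summation orders preclude bit equality)
        tree, _, _ = synth_cell
        rng = np.random.default_rng(0)
        pts = rng.uniform(-50, 350, size=(100, 3))
        hits = surface_distances(pts, tree)
        for p, hit in zip(pts, hits):
            d, cands = brute_force_surface(p, tree)
            assert hit.surface_distance == pytest.approx(d, abs=1e-9)
            assert hit.nearest_branch_id in cands

    def test_lipschitz_in_query_point(self):
        # 1-Lipschitz holds exactly for uniform radii (no taper slope)
        specs = [(1, None, (0.0, 0.0, 0.0), 0.3, Compartment.SOMA)]
        nid = 2
        for i in range(3):
            specs.append((nid, nid - 1, (0.0, 2.0 * (i + 1), 0.0), 0.3, Compartment.SHAFT))
            nid += 1
        for side in (-1.0, 1.0):
            parent = 4
            for i in range(3):
                specs.append((nid, parent, (side * 2.0 * (i + 1), 6.0 + 2.0 * (i + 1), 0.0), 0.3, Compartment.SHAFT))
                parent = nid
                nid += 1
        tree = make_tree(specs)
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(-10, 15, 3)
            q = p + rng.normal(0, 0.5, 3)
            dp = surface_distance(p, tree).surface_distance
            dq = surface_distance(q, tree).surface_distance
            assert abs(dp - dq) <= np.linalg.norm(p - q) + 1e-9

    def test_shaft_spine_tie_resolves_to_spine(self):
        # spine neck along +y from the shaft node; query point equidistant
        specs = [
            (1, None, (0.0, 0.0, 0.0), 1.0, Compartment.SOMA),
            (2, 1, (2.0, 0.0, 0.0), 0.2, Compartment.SHAFT),
            (3, 2, (4.0, 0.0, 0.0), 0.2, Compartment.SHAFT),
            (4, 3, (4.0, 1.0, 0.0), 0.2, Compartment.SPINE),
        ]
        tree = make_tree(specs)
        # point on the shaft surface where the spine neck exits: distance 0 to both
        hit = surface_distance((4.0, 0.2, 0.0), tree)
        assert hit.nearest_compartment is Compartment.SPINE
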