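"""Dendrite reconstructions: data model, SWC I/O, branch taxonomy, surface geometry.

A reconstruction is a tree of nodes (soma, dendritic shaft, spine) with radii,
read from a standard 7-column SWC file (type code 1 = soma, 3 = dendrite shaft,
5 = spine).  Branches are maximal unbranched shaft paths between the soma,
branch points and tips; they carry a subdivision label (primary if attached to
the soma, terminal if ending at a tip, intermediate otherwise), a centripetal
branch order (1 at soma-adjacent branches, +1 per branch point) and a dendritic
domain (basal / proximal apical / distal apical / apical tuft).

The dendrite surface is modelled as a union of tapered frusta around skeleton
segments: the distance from a point to the surface is its distance to the
nearest segment's centerline minus the radius linearly interpolated at the
closest parameter, floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class Compartment(str, Enum):
    SOMA = "soma"
    SHAFT = "shaft"
    SPINE = "spine"


class Subdivision(str, Enum):
    PRIMARY = "primary"
    INTERMEDIATE = "intermediate"
    TERMINAL = "terminal"


class Domain(str, Enum):
    BASAL = "basal"
    PROXIMAL_APICAL = "proximal_apical"
    DISTAL_APICAL = "distal_apical"
    APICAL_TUFT = "apical_tuft"
    UNASSIGNED = "unassigned"


_SWC_TYPE_TO_COMPARTMENT = {1: Compartment.SOMA, 3: Compartment.SHAFT, 5: Compartment.SPINE}
_COMPARTMENT_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_COMPARTMENT.items()}


class MorphologyError(ValueError):
    """Structural or validation problem in a reconstruction."""


@dataclass(frozen=True)
class DendriteNode:
    """One skeleton sample point.

    Positions and radii are in micrometres; ``parent_id`` is ``None`` for the
    single root node (which must be somatic).
    """

    node_id: int
    parent_id: int | None
    position: tuple[float, float, float]
    radius: float
    compartment: Compartment

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise MorphologyError(f"node {self.node_id}: radius must be > 0, got {self.radius}")


@dataclass
class DendriteTree:
    """A validated dendritic reconstruction (connected, acyclic, single root)."""

    nodes: dict[int, DendriteNode]
    cell_id: str = "cell"
    cell_type: str = "other"

    # caches built on demand
    _segments: "SegmentArrays | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            ids = [n.node_id for n in roots]
            raise MorphologyError(f"tree must have exactly one root, found {len(roots)}: {ids}")
        if roots[0].compartment is not Compartment.SOMA:
            raise MorphologyError(f"root node {roots[0].node_id} must be soma")
        # every parent must exist; walking to root must terminate (acyclicity)
        for n in self.nodes.values():
            if n.parent_id is not None and n.parent_id not in self.nodes:
                raise MorphologyError(f"node {n.node_id} references missing parent {n.parent_id}")
        visited_ok: set[int] = set()
        for n in self.nodes.values():
            seen: set[int] = set()
            cur: DendriteNode | None = n
            while cur is not None and cur.node_id not in visited_ok:
                if cur.node_id in seen:
                    raise MorphologyError(f"cycle detected through node {cur.node_id}")
                seen.add(cur.node_id)
                cur = self.nodes.get(cur.parent_id) if cur.parent_id is not None else None
            visited_ok |= seen

    @property
    def root(self) -> DendriteNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id is not None:
                ch[n.parent_id].append(n.node_id)
        for lst in ch.values():
            lst.sort()
        return ch

    # -- geometry ----------------------------------------------------------
    def segments(self) -> "SegmentArrays":
        if self._segments is None:
            self._segments = _build_segments(self)
        return self._segments


@dataclass(frozen=True)
class BranchLabel:
    branch_id: int
    subdivision: Subdivision
    branch_order: int
    domain: Domain = Domain.UNASSIGNED
    node_ids: tuple[int, ...] = ()
    length: float = 0.0


@dataclass(frozen=True)
class SurfaceHit:
    """Nearest-surface query result for one point."""

    surface_distance: float
    nearest_compartment: Compartment
    nearest_branch_id: int


@dataclass
class SegmentArrays:
    """Flat frustum-segment arrays for vectorised distance queries.

    ``a``/``b`` are the proximal/distal endpoints (n, 3); radii interpolate
    linearly from ``ra`` to ``rb`` along each segment.  ``is_spine`` marks
    segments whose distal node is a spine; ``branch_id`` is the shaft branch
    the segment belongs to (spine segments carry their attachment branch).
    """

    a: np.ndarray
    b: np.ndarray
    ra: np.ndarray
    rb: np.ndarray
    is_spine: np.ndarray
    branch_id: np.ndarray


def _build_segments(tree: DendriteTree) -> SegmentArrays:
    # branch ids require taxonomy; compute node -> branch map lazily
    node_branch = _node_branch_map(tree)
    a, b, ra, rb, sp, bid = [], [], [], [], [], []
    for n in tree.nodes.values():
        if n.parent_id is None:
            continue
        p = tree.nodes[n.parent_id]
        if p.compartment is Compartment.SOMA and n.compartment is Compartment.SOMA:
            continue  # intra-soma segments are not dendritic surface
        start = np.asarray(p.position, float)
        start_r = p.radius
        if n.compartment is Compartment.SPINE and p.compartment is not Compartment.SPINE:
            # spine necks contribute only their portion outside the parent
            # surface, as a thin frustum of the spine's own radius — otherwise
            # the neck frustum would bulge through the shaft surface and claim
            # shaft-surface points as spine-associated
            axis = np.asarray(n.position, float) - start
            length = float(np.linalg.norm(axis))
            if length > 0:
                offset = min(p.radius, 0.9 * length)
                start = start + axis / length * offset
            start_r = n.radius
        a.append(tuple(start))
        b.append(n.position)
        ra.append(start_r)
        rb.append(n.radius)
        sp.append(n.compartment is Compartment.SPINE)
        bid.append(node_branch.get(n.node_id, node_branch.get(n.parent_id, -1)))
    if not a:
        return SegmentArrays(
            np.empty((0, 3)), np.empty((0, 3)), np.empty(0), np.empty(0),
            np.empty(0, bool), np.empty(0, int),
        )
    return SegmentArrays(
        np.asarray(a, float), np.asarray(b, float),
        np.asarray(ra, float), np.asarray(rb, float),
        np.asarray(sp, bool), np.asarray(bid, int),
    )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_morphology(path: str | Path, cell_id: str | None = None) -> DendriteTree:
    """Read a 7-column SWC file (μm, 1-based ids; types 1=soma, 3=shaft, 5=spine)."""
    path = Path(path)
    nodes: dict[int, DendriteNode] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        nid, ntype = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        if nid in nodes:
            raise MorphologyError(f"{path}:{lineno}: duplicate node id {nid}")
        if ntype not in _SWC_TYPE_TO_COMPARTMENT:
            raise MorphologyError(f"{path}:{lineno}: unsupported SWC type code {ntype}")
        nodes[nid] = DendriteNode(
            node_id=nid,
            parent_id=None if parent == -1 else parent,
            position=(x, y, z),
            radius=r,
            compartment=_SWC_TYPE_TO_COMPARTMENT[ntype],
        )
    return DendriteTree(nodes=nodes, cell_id=cell_id or path.stem)


def write_morphology(tree: DendriteTree, path: str | Path) -> None:
    """Write the tree back to SWC; round-trips bit-exactly via repr floats."""
    lines = ["# id type x y z radius parent"]
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        t = _COMPARTMENT_TO_SWC_TYPE[n.compartment]
        x, y, z = n.position
        parent = -1 if n.parent_id is None else n.parent_id
        lines.append(f"{n.node_id} {t} {x!r} {y!r} {z!r} {n.radius!r} {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_annotation(path: str | Path) -> dict[int, Domain]:
    """Read a ``<name>.domains.tsv`` sidecar (columns: branch_id, domain)."""
    out: dict[int, Domain] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("branch_id"):
            continue
        bid, dom = line.split("\t")[:2]
        out[int(bid)] = Domain(dom)
    return out


# ---------------------------------------------------------------------------
# Branch taxonomy
# ---------------------------------------------------------------------------

def _shaft_children(tree: DendriteTree) -> dict[int, list[int]]:
    """Children maps restricted to non-spine nodes (spines never break branches)."""
    ch: dict[int, list[int]] = {nid: [] for nid in tree.nodes}
    for n in tree.nodes.values():
        if n.parent_id is None or n.compartment is Compartment.SPINE:
            continue
        ch[n.parent_id].append(n.node_id)
    for lst in ch.values():
        lst.sort()
    return ch


def classify_branches(tree: DendriteTree) -> dict[int, BranchLabel]:
    """Decompose the shaft skeleton into branches and label them.

    A branch runs from a start node (the soma or a branch point) through
    unbranched shaft nodes to the next branch point or tip.  Soma-adjacent
    branches are order 1 and ``primary``; tip-ending branches ``terminal``
    (a branch that is both is labelled primary); orders increase by one at
    each branch point.  Spine nodes neither start, end nor extend branches.
    """
    shaft_ids = [nid for nid, n in tree.nodes.items() if n.compartment is Compartment.SHAFT]
    if not shaft_ids:
        warnings.warn("tree has no shaft nodes; no branches to classify", stacklevel=2)
        return {}

    ch = _shaft_children(tree)
    labels: dict[int, BranchLabel] = {}
    next_bid = 1
    # stack entries: (start node id, order, soma_adjacent)
    root = tree.root
    stack: list[tuple[int, int, bool]] = []
    # branches begin at each shaft child of the soma cluster
    soma_ids = {nid for nid, n in tree.nodes.items() if n.compartment is Compartment.SOMA}
    for sid in sorted(soma_ids):
        for c in ch[sid]:
            if tree.nodes[c].compartment is Compartment.SHAFT:
                stack.append((c, 1, True))
    stack.reverse()
    while stack:
        start, order, soma_adjacent = stack.pop()
        path = [start]
        cur = start
        while True:
            kids = [c for c in ch[cur] if tree.nodes[c].compartment is Compartment.SHAFT]
            if len(kids) == 1:
                cur = kids[0]
                path.append(cur)
            else:
                break
        kids = [c for c in ch[cur] if tree.nodes[c].compartment is Compartment.SHAFT]
        is_tip = len(kids) == 0
        if soma_adjacent:
            subdivision = Subdivision.PRIMARY  # soma attachment takes precedence over tip
        elif is_tip:
            subdivision = Subdivision.TERMINAL
        else:
            subdivision = Subdivision.INTERMEDIATE
        length = _path_length(tree, path)
        labels[next_bid] = BranchLabel(
            branch_id=next_bid,
            subdivision=subdivision,
            branch_order=order,
            node_ids=tuple(path),
            length=length,
        )
        next_bid += 1
        for c in reversed(kids):
            stack.append((c, order + 1, False))
    return labels


def _path_length(tree: DendriteTree, node_ids: Sequence[int]) -> float:
    total = 0.0
    for nid in node_ids:
        n = tree.nodes[nid]
        if n.parent_id is None:
            continue
        p = tree.nodes[n.parent_id]
        # the soma-to-first-shaft-node segment counts toward the primary branch
        total += float(np.linalg.norm(np.subtract(n.position, p.position)))
    return total


def _node_branch_map(tree: DendriteTree) -> dict[int, int]:
    labels = classify_branches(tree)
    node_branch: dict[int, int] = {}
    for lbl in labels.values():
        for nid in lbl.node_ids:
            node_branch[nid] = lbl.branch_id
    # spines inherit the branch of their shaft attachment (walk up to a shaft node)
    for nid, n in tree.nodes.items():
        if n.compartment is not Compartment.SPINE:
            continue
        cur = n
        while cur is not None and cur.compartment is Compartment.SPINE:
            cur = tree.nodes.get(cur.parent_id) if cur.parent_id is not None else None
        if cur is not None and cur.node_id in node_branch:
            node_branch[nid] = node_branch[cur.node_id]
    return node_branch


def path_distance_to_soma(tree: DendriteTree, labels: Mapping[int, BranchLabel]) -> dict[int, float]:
    """Path distance (μm) from the soma to the proximal end of each branch."""
    node_xyz = {nid: np.asarray(n.position) for nid, n in tree.nodes.items()}
    # cumulative distance to each shaft node by walking from root
    dist: dict[int, float] = {tree.root.node_id: 0.0}
    order_ids = sorted(tree.nodes, key=lambda nid: _depth(tree, nid))
    for nid in order_ids:
        n = tree.nodes[nid]
        if n.parent_id is None or nid in dist:
            continue
        d = dist[n.parent_id] + float(np.linalg.norm(node_xyz[nid] - node_xyz[n.parent_id]))
        dist[nid] = d
    out = {}
    for bid, lbl in labels.items():
        first = tree.nodes[lbl.node_ids[0]]
        out[bid] = dist[first.parent_id] if first.parent_id is not None else 0.0
    return out


def _depth(tree: DendriteTree, nid: int) -> int:
    d = 0
    cur = tree.nodes[nid]
    while cur.parent_id is not None:
        cur = tree.nodes[cur.parent_id]
        d += 1
    return d


def assign_domains(
    tree: DendriteTree,
    labels: Mapping[int, BranchLabel],
    domain_spec: Mapping[int, Domain] | Mapping[str, float] | None = None,
    *,
    apical_root_ids: Iterable[int] = (),
) -> dict[int, BranchLabel]:
    """Assign a dendritic domain to every branch.

    ``domain_spec`` is either an explicit branch→domain annotation map (real
    reconstructions, traced manually from overview stacks) or a threshold dict
    ``{"proximal_max": μm, "distal_max": μm}`` on path distance from the soma
    along the apical trunk (synthetic trees).  In threshold mode branches not
    descending from ``apical_root_ids`` are basal regardless of distance.
    """
    out: dict[int, BranchLabel] = {}
    if domain_spec and all(isinstance(k, (int, np.integer)) for k in domain_spec):
        for bid, lbl in labels.items():
            dom = domain_spec.get(bid)  # type: ignore[arg-type]
            if dom is None:
                warnings.warn(f"branch {bid} missing from annotation; left unassigned", stacklevel=2)
                dom = Domain.UNASSIGNED
            out[bid] = _with_domain(lbl, Domain(dom))
        return out
    if domain_spec:
        prox_max = float(domain_spec["proximal_max"])  # type: ignore[index]
        dist_max = float(domain_spec["distal_max"])  # type: ignore[index]
        apical_roots = set(apical_root_ids)
        apical_branches = _descendant_branches(tree, labels, apical_roots)
        pd = path_distance_to_soma(tree, labels)
        for bid, lbl in labels.items():
            if bid not in apical_branches:
                out[bid] = _with_domain(lbl, Domain.BASAL)
            elif pd[bid] < prox_max:
                out[bid] = _with_domain(lbl, Domain.PROXIMAL_APICAL)
            elif pd[bid] < dist_max:
                out[bid] = _with_domain(lbl, Domain.DISTAL_APICAL)
            else:
                out[bid] = _with_domain(lbl, Domain.APICAL_TUFT)
        return out
    warnings.warn("no domain annotation or thresholds; all branches unassigned", stacklevel=2)
    return {bid: _with_domain(lbl, Domain.UNASSIGNED) for bid, lbl in labels.items()}


def _with_domain(lbl: BranchLabel, dom: Domain) -> BranchLabel:
    return BranchLabel(lbl.branch_id, lbl.subdivision, lbl.branch_order, dom, lbl.node_ids, lbl.length)


def _descendant_branches(
    tree: DendriteTree, labels: Mapping[int, BranchLabel], root_node_ids: set[int]
) -> set[int]:
    """Branch ids whose first node descends from (or is) one of root_node_ids."""
    out = set()
    for bid, lbl in labels.items():
        cur: int | None = lbl.node_ids[0]
        while cur is not None:
            if cur in root_node_ids:
                out.add(bid)
                break
            cur = tree.nodes[cur].parent_id
    return out


# ---------------------------------------------------------------------------
# Surface distance
# ---------------------------------------------------------------------------

def _point_segment_distances(points: np.ndarray, seg: SegmentArrays) -> np.ndarray:
    """(n_points, n_segments) surface distances to each tapered frustum."""
    ab = seg.b - seg.a  # (s, 3)
    denom = np.einsum("ij,ij->i", ab, ab)  # |ab|^2, (s,)
    ap = points[:, None, :] - seg.a[None, :, :]  # (p, s, 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("psj,sj->ps", ap, ab) / denom[None, :]
    t = np.where(denom[None, :] > 0, t, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = seg.a[None, :, :] + t[:, :, None] * ab[None, :, :]
    center_d = np.linalg.norm(points[:, None, :] - closest, axis=2)
    radius = seg.ra[None, :] + t * (seg.rb - seg.ra)[None, :]
    return np.maximum(center_d - radius, 0.0)


def surface_distance(
    point: Sequence[float] | np.ndarray, tree: DendriteTree
) -> SurfaceHit:
    """Distance from a point to the dendrite surface, with compartment and branch.

    Ties between shaft and spine at exactly equal distance resolve to spine.
    """
    hits = surface_distances(np.asarray(point, float)[None, :], tree)
    return hits[0]


def surface_distances(points: np.ndarray, tree: DendriteTree, chunk: int = 2048) -> list[SurfaceHit]:
    """Vectorised surface query for many points (chunked over points)."""
    seg = tree.segments()
    if seg.a.shape[0] == 0:
        raise MorphologyError("tree has no dendritic segments")
    points = np.asarray(points, float)
    out: list[SurfaceHit] = []
    for lo in range(0, len(points), chunk):
        d = _point_segment_distances(points[lo : lo + chunk], seg)
        dmin = d.min(axis=1)
        for i, row in enumerate(d):
            m = row == dmin[i]
            # spine wins ties; among equals pick deterministically by segment index
            if np.any(m & seg.is_spine):
                j = int(np.flatnonzero(m & seg.is_spine)[0])
                comp = Compartment.SPINE
            else:
                j = int(np.flatnonzero(m)[0])
                comp = Compartment.SPINE if seg.is_spine[j] else Compartment.SHAFT
            out.append(SurfaceHit(float(dmin[i]), comp, int(seg.branch_id[j])))
    return out


def total_cable_length(labels: Mapping[int, BranchLabel]) -> float:
    return float(sum(lbl.length for lbl in labels.values()))
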