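"""Ground-truthed synthetic inputs for every analysis stage.

No imaging data ships with this package, so each pipeline stage is exercised
on simulated inputs with known ground truth: branched pyramidal-like dendritic
trees with spines; puncta placed on shafts, spines and background with
domain-dependent densities; pre/post/perisynaptic marker triplets with
configurable separations and jitter; rendered anisotropic image stacks; and
smFISH fields of nuclei with class-dependent transcript counts and occasional
merged-puncta clusters.

Default parameters copy the quantitative regimes the analyses are meant to
resolve — 0.666 μm pre/post separation with a perisynaptic marker at 0.69 μm,
a 65% spine-association probability, tuft-vs-proximal density ratio 3, and
transcript means of 13.2 (neurons) vs 2.8 (non-neuronal cells) — so recovery
tests are interpretable against published figure-scale values.  All
distributional choices (Poisson placements, Gaussian jitter) are modelling
choices of this generator, not measured properties.

Every generator is a pure function of (config, seed): the same seed gives a
bit-identical output, and each emitted object appears exactly once in the
returned ground-truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import (
    BranchLabel,
    Compartment,
    DendriteNode,
    DendriteTree,
    classify_branches,
    assign_domains,
)
from .spot_detection import ImageStack, PunctumSet, SR_VOXEL_SIZE


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TreeConfig:
    """Geometry of the synthetic pyramidal-like cell (lengths in μm)."""

    n_basal: int = 4
    basal_length: float = 80.0
    apical_trunk_length: float = 300.0
    n_oblique: int = 8
    oblique_length: float = 80.0
    n_tuft: int = 6
    tuft_length: float = 100.0
    step: float = 2.0
    soma_radius: float = 5.0
    shaft_radius: float = 0.4
    spine_radius: float = 0.15
    spine_neck_length: float = 1.0
    spine_density: float = 1.0  # spines per μm of shaft cable
    proximal_max: float = 100.0  # apical path-distance domain cutoffs
    distal_max: float = 250.0


@dataclass
class PunctaConfig:
    """Placement densities for the puncta generator (per μm of cable)."""

    domain_density: dict[str, float] = field(
        default_factory=lambda: {
            "basal": 0.4,
            "proximal_apical": 0.4,
            "distal_apical": 0.8,
            "apical_tuft": 1.2,
        }
    )
    spine_association_prob: float = 0.65
    background_rate: float = 5e-5  # spurious detections per μm^3 of bounding volume
    jitter_sigma: float = 0.05  # isotropic localization jitter, μm
    punctum_radius_xy: float = 0.15
    punctum_radius_z: float = 0.3


@dataclass
class TripletConfig:
    """Synaptic marker triplet geometry (μm)."""

    n: int = 500
    pre_post_separation: float = 0.666
    pre_post_sigma: float = 0.05
    peri_offset: float = 0.69
    peri_sigma: float = 0.05
    asymmetry: float = 0.0  # shift of the peri marker toward the pre marker
    spacing: float = 4.0  # grid spacing between triplet centers


@dataclass
class RenderConfig:
    voxel_size: tuple[float, float, float] = SR_VOXEL_SIZE  # (z, y, x) μm
    snr: float = 10.0
    peak_intensity: float = 100.0
    margin: float = 1.0  # μm of padding around the puncta bounding box
    max_bytes: int = 2 << 30


@dataclass
class FishConfig:
    """smFISH field structure per (region, layer) stratum."""

    n_cells: int = 200
    # fraction of probe-positive neurons per stratum; remaining cells split
    # among the other three classes in fixed proportions
    lphn2_neuron_frac: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("pSub", "deep"): 0.63,
            ("pSub", "superficial"): 0.50,
            ("iSub", "deep"): 0.56,
            ("iSub", "superficial"): 0.56,
            ("dSub", "deep"): 0.50,
            ("dSub", "superficial"): 0.33,
        }
    )
    other_class_split: tuple[float, float, float] = (0.55, 0.05, 0.40)  # N+/L2-, N-/L2+, N-/L2-
    transcripts_neuron: float = 13.2
    transcripts_non_neuronal: float = 2.8
    cluster_prob: float = 0.15
    cluster_k_max: int = 6
    mean_single_area: float = 0.3  # μm², isolated punctum footprint
    area_sigma: float = 0.02
    nucleus_radius: float = 4.0
    scatter_radius: float = 2.5  # transcripts placed within this radius of the nucleus
    min_cell_spacing: float = 7.0  # > 2 x scatter_radius: assignments stay unambiguous
    rect_width_px: int = 600
    rect_height_px: int = 2400
    pixel_size: float = 0.22


# ---------------------------------------------------------------------------
# Dendritic tree
# ---------------------------------------------------------------------------

@dataclass
class TreeTruth:
    """Construction-side record of the generated morphology."""

    node_side: dict[int, str]  # node -> "apical" | "basal"
    node_path_dist: dict[int, float]  # path distance from soma, μm
    spine_nodes: tuple[int, ...]


def generate_tree(config: TreeConfig, seed: int) -> tuple[DendriteTree, dict[int, BranchLabel], TreeTruth]:
    """Build a branched pyramidal-like tree with spines and labelled domains.

    The apical trunk runs along +y with oblique side branches and a terminal
    tuft; basal dendrites radiate into the −y hemisphere.  Spines are a
    Poisson process along all shaft cable at ``spine_density``.  Returned
    labels carry domains assigned by path-distance thresholds; the truth
    record holds the construction-side node annotations used to verify them.
    """
    if config.apical_trunk_length <= 0 or config.step <= 0:
        raise ValueError("degenerate tree config: lengths must be > 0")
    rng = np.random.default_rng(seed)
    nodes: dict[int, DendriteNode] = {}
    side: dict[int, str] = {}
    pdist: dict[int, float] = {}
    next_id = [1]

    def add(parent: int | None, pos, radius, comp, node_side, path_d) -> int:
        nid = next_id[0]
        next_id[0] += 1
        nodes[nid] = DendriteNode(nid, parent, tuple(float(v) for v in pos), radius, comp)
        side[nid] = node_side
        pdist[nid] = path_d
        return nid

    soma = add(None, (0.0, 0.0, 0.0), config.soma_radius, Compartment.SOMA, "soma", 0.0)

    def grow_cable(parent: int, start_pos, direction, length, node_side) -> list[int]:
        """Straight run of shaft nodes every ``step`` μm; returns node ids."""
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        n_steps = max(1, int(round(length / config.step)))
        ids = []
        pos = np.asarray(start_pos, float)
        d = pdist[parent]
        for _ in range(n_steps):
            pos = pos + direction * config.step
            d += config.step
            parent = add(parent, pos, config.shaft_radius, Compartment.SHAFT, node_side, d)
            ids.append(parent)
        return ids

    # apical trunk with obliques and tuft
    trunk = grow_cable(soma, (0.0, 0.0, 0.0), (0.0, 1.0, 0.0), config.apical_trunk_length, "apical")
    apical_root = trunk[0]
    if config.n_oblique > 0:
        # obliques concentrate on the lower trunk, as in stratum radiatum
        pick = np.linspace(4, int(0.6 * len(trunk)), config.n_oblique).astype(int)
        for i, ti in enumerate(pick):
            phi = 2 * math.pi * (i + rng.uniform(0, 0.5)) / config.n_oblique
            direction = (math.cos(phi), 0.35, math.sin(phi))
            grow_cable(trunk[ti], nodes[trunk[ti]].position, direction, config.oblique_length, "apical")
    tip = trunk[-1]
    for i in range(config.n_tuft):
        phi = 2 * math.pi * (i + rng.uniform(0, 0.5)) / max(1, config.n_tuft)
        direction = (0.6 * math.cos(phi), 1.0, 0.6 * math.sin(phi))
        grow_cable(tip, nodes[tip].position, direction, config.tuft_length, "apical")

    # basal dendrites, each bifurcating at half length
    for i in range(config.n_basal):
        phi = 2 * math.pi * (i + rng.uniform(0, 0.5)) / max(1, config.n_basal)
        direction = np.array([math.cos(phi), -1.0, math.sin(phi)])
        half = grow_cable(soma, (0.0, 0.0, 0.0), direction, config.basal_length / 2, "basal")
        for sgn in (-1.0, 1.0):
            perp = np.array([-math.sin(phi), -1.0, math.cos(phi)]) * sgn
            branch_dir = direction + 0.6 * perp
            grow_cable(half[-1], nodes[half[-1]].position, branch_dir, config.basal_length / 2, "basal")

    # spines: Poisson along every shaft segment
    spine_ids = []
    shaft_ids = sorted(nid for nid, n in nodes.items() if n.compartment is Compartment.SHAFT)
    for nid in shaft_ids:
        n_spines = rng.poisson(config.spine_density * config.step)
        base = np.asarray(nodes[nid].position)
        parent_node = nodes[nodes[nid].parent_id]
        axis = base - np.asarray(parent_node.position)
        axis = axis / max(np.linalg.norm(axis), 1e-12)
        for _ in range(n_spines):
            direction = rng.normal(size=3)
            direction = direction - axis * (direction @ axis)  # stick out sideways
            norm = np.linalg.norm(direction)
            if norm < 1e-9:
                continue
            direction /= norm
            head = base + direction * (config.shaft_radius + config.spine_neck_length)
            sid = add(nid, head, config.spine_radius, Compartment.SPINE, side[nid], pdist[nid])
            spine_ids.append(sid)

    tree = DendriteTree(nodes=nodes, cell_id=f"synth-{seed}")
    labels = classify_branches(tree)
    labels = assign_domains(
        tree,
        labels,
        {"proximal_max": config.proximal_max, "distal_max": config.distal_max},
        apical_root_ids=[apical_root],
    )
    truth = TreeTruth(node_side=side, node_path_dist=pdist, spine_nodes=tuple(spine_ids))
    return tree, labels, truth


# ---------------------------------------------------------------------------
# Puncta placement
# ---------------------------------------------------------------------------

def place_puncta(
    tree: DendriteTree,
    labels: dict[int, BranchLabel],
    config: PunctaConfig,
    seed: int,
    channel: str = "lphn2",
) -> tuple[PunctumSet, pd.DataFrame]:
    """Place puncta on shafts/spines/background with known per-domain densities.

    Shaft candidates arrive as a Poisson process along each branch's cable at
    the branch domain's density; each is reassigned to a random spine of the
    same branch with probability ``spine_association_prob`` (kept on the shaft
    when the branch has no spines).  All placements sit exactly on the frustum
    surface before isotropic Gaussian jitter.  Background puncta are uniform
    in the bounding volume.  The returned truth table records the intended
    placement class, branch, domain and exact pre-jitter position.
    """
    rng = np.random.default_rng(seed)
    spines_by_branch = _spines_by_branch(tree, labels)
    records: list[dict] = []
    truth_rows: list[dict] = []
    pid = 1
    for bid in sorted(labels):
        lbl = labels[bid]
        lam = config.domain_density.get(lbl.domain.value, 0.0)
        n_puncta = rng.poisson(lam * lbl.length)
        segs = _branch_segments(tree, lbl)
        seg_len = np.array([s["length"] for s in segs])
        cum = np.cumsum(seg_len)
        for _ in range(n_puncta):
            on_spine = rng.uniform() < config.spine_association_prob and spines_by_branch.get(bid)
            if on_spine:
                sid = spines_by_branch[bid][rng.integers(len(spines_by_branch[bid]))]
                spine = tree.nodes[sid]
                direction = _random_unit(rng)
                base_pos = np.asarray(spine.position) + direction * spine.radius
                placement = "spine"
            else:
                u = rng.uniform(0, cum[-1])
                si = int(np.searchsorted(cum, u))
                s = segs[si]
                t = (u - (cum[si] - seg_len[si])) / seg_len[si]
                center = s["a"] + t * (s["b"] - s["a"])
                radius_t = s["ra"] + t * (s["rb"] - s["ra"])
                axis = (s["b"] - s["a"]) / max(np.linalg.norm(s["b"] - s["a"]), 1e-12)
                direction = _random_perp(rng, axis)
                base_pos = center + direction * radius_t
                placement = "shaft"
            pos = base_pos + rng.normal(0, config.jitter_sigma, size=3) if config.jitter_sigma > 0 else base_pos
            records.append(_punctum(pid, pos, config, rng))
            truth_rows.append(
                {
                    "punctum_id": pid,
                    "placement": placement,
                    "branch_id": bid,
                    "domain": lbl.domain.value,
                    "subdivision": lbl.subdivision.value,
                    "x_true": base_pos[0],
                    "y_true": base_pos[1],
                    "z_true": base_pos[2],
                }
            )
            pid += 1

    # background puncta uniform in the bounding volume
    xyz = np.array([n.position for n in tree.nodes.values()])
    lo, hi = xyz.min(axis=0) - 5.0, xyz.max(axis=0) + 5.0
    volume = float(np.prod(hi - lo))
    for _ in range(rng.poisson(config.background_rate * volume)):
        pos = rng.uniform(lo, hi)
        records.append(_punctum(pid, pos, config, rng))
        truth_rows.append(
            {
                "punctum_id": pid,
                "placement": "background",
                "branch_id": -1,
                "domain": "",
                "subdivision": "",
                "x_true": pos[0],
                "y_true": pos[1],
                "z_true": pos[2],
            }
        )
        pid += 1

    puncta = PunctumSet.from_records(channel, records)
    truth = pd.DataFrame(truth_rows)
    return puncta, truth


def _punctum(pid: int, pos, config: PunctaConfig, rng) -> dict:
    return {
        "punctum_id": pid,
        "x_um": float(pos[0]),
        "y_um": float(pos[1]),
        "z_um": float(pos[2]),
        "r_xy_um": config.punctum_radius_xy,
        "r_z_um": config.punctum_radius_z,
        "intensity": float(rng.uniform(80, 120)),
    }


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_perp(rng, axis: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v = v - axis * (v @ axis)
    n = np.linalg.norm(v)
    if n < 1e-9:
        return _random_perp(rng, axis)
    return v / n


def _spines_by_branch(tree: DendriteTree, labels) -> dict[int, list[int]]:
    node_branch: dict[int, int] = {}
    for bid, lbl in labels.items():
        for nid in lbl.node_ids:
            node_branch[nid] = bid
    out: dict[int, list[int]] = {}
    for nid, n in sorted(tree.nodes.items()):
        if n.compartment is Compartment.SPINE and n.parent_id in node_branch:
            out.setdefault(node_branch[n.parent_id], []).append(nid)
    return out


def _branch_segments(tree: DendriteTree, lbl: BranchLabel) -> list[dict]:
    segs = []
    for nid in lbl.node_ids:
        n = tree.nodes[nid]
        p = tree.nodes[n.parent_id]
        a, b = np.asarray(p.position), np.asarray(n.position)
        length = float(np.linalg.norm(b - a))
        if length > 0:
            segs.append({"a": a, "b": b, "ra": p.radius, "rb": n.radius, "length": length})
    return segs


# ---------------------------------------------------------------------------
# Synaptic triplets
# ---------------------------------------------------------------------------

def generate_triplets(
    config: TripletConfig, seed: int, channels: tuple[str, str, str] = ("pre", "post", "peri")
) -> tuple[PunctumSet, PunctumSet, PunctumSet, pd.DataFrame]:
    """Generate isolated pre/post/perisynaptic marker triplets.

    Triplet centers sit on a cubic grid (spacing ``config.spacing`` μm) so
    nearest-neighbour queries always resolve within-triplet partners.  The
    synapse axis is uniformly oriented; pre and post markers sit ±sep/2 along
    it, and the peri marker on the perpendicular bisector at the height that
    realises the drawn peri distance, then shifted by ``asymmetry`` toward the
    pre marker.  Truth records exact positions and pairwise distances.
    """
    if config.n < 1:
        raise ValueError("need at least one triplet")
    rng = np.random.default_rng(seed)
    side = int(math.ceil(config.n ** (1.0 / 3.0)))
    centers = []
    for i in range(config.n):
        iz, rem = divmod(i, side * side)
        iy, ix = divmod(rem, side)
        centers.append(np.array([ix, iy, iz], float) * config.spacing)
    rec_a, rec_b, rec_c, truth_rows = [], [], [], []
    for i, center in enumerate(centers, start=1):
        axis = _random_unit(rng)
        sep = max(0.05, rng.normal(config.pre_post_separation, config.pre_post_sigma))
        a = center - axis * sep / 2
        b = center + axis * sep / 2
        target = max(sep / 2 + 1e-6, rng.normal(config.peri_offset, config.peri_sigma))
        h = math.sqrt(max(target**2 - (sep / 2) ** 2, 0.0))
        perp = _random_perp(rng, axis)
        c = center + perp * h - axis * config.asymmetry
        rec_a.append(_marker(i, a))
        rec_b.append(_marker(i, b))
        rec_c.append(_marker(i, c))
        truth_rows.append(
            {
                "triplet_id": i,
                "d_pre_post": float(np.linalg.norm(a - b)),
                "d_peri_pre": float(np.linalg.norm(c - a)),
                "d_peri_post": float(np.linalg.norm(c - b)),
            }
        )
    sets = tuple(
        PunctumSet.from_records(ch, rec) for ch, rec in zip(channels, (rec_a, rec_b, rec_c))
    )
    return (*sets, pd.DataFrame(truth_rows))


def _marker(pid: int, pos: np.ndarray) -> dict:
    return {
        "punctum_id": pid,
        "x_um": float(pos[0]),
        "y_um": float(pos[1]),
        "z_um": float(pos[2]),
        "r_xy_um": 0.15,
        "r_z_um": 0.3,
        "intensity": 100.0,
    }


# ---------------------------------------------------------------------------
# Stack rendering
# ---------------------------------------------------------------------------

def render_stack(
    puncta: PunctumSet, config: RenderConfig, seed: int, channel: str | None = None
) -> ImageStack:
    """Render puncta as anisotropic Gaussians on a calibrated voxel grid.

    Each punctum contributes a Gaussian with σ set from its radii (σ = r/√3,
    the scale at which a blob detector of matched size responds maximally);
    Gaussian read noise with σ = peak / SNR is added on top.
    """
    vz, vy, vx = config.voxel_size
    if len(puncta) == 0:
        shape = (16, 32, 32)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, config.peak_intensity / config.snr, size=shape)
        return ImageStack(voxels=noise.astype(np.float32), voxel_size=config.voxel_size, channel=channel or puncta.channel)
    xyz = puncta.centers()
    lo = xyz.min(axis=0) - config.margin
    hi = xyz.max(axis=0) + config.margin
    shape = (
        int(math.ceil((hi[2] - lo[2]) / vz)) + 1,
        int(math.ceil((hi[1] - lo[1]) / vy)) + 1,
        int(math.ceil((hi[0] - lo[0]) / vx)) + 1,
    )
    nbytes = 8 * shape[0] * shape[1] * shape[2]
    if nbytes > config.max_bytes:
        raise MemoryError(
            f"rendered volume would need {nbytes / 1e9:.1f} GB; tile the field instead"
        )
    img = np.zeros(shape, dtype=np.float64)
    vox = np.array([vz, vy, vx])
    for _, row in puncta.table.iterrows():
        center_um = np.array([row.z_um - lo[2], row.y_um - lo[1], row.x_um - lo[0]])
        sigma_um = np.array([row.r_z_um, row.r_xy_um, row.r_xy_um]) / math.sqrt(3.0)
        c_vox = center_um / vox
        s_vox = sigma_um / vox
        lo_i = np.maximum(np.floor(c_vox - 4 * s_vox).astype(int), 0)
        hi_i = np.minimum(np.ceil(c_vox + 4 * s_vox).astype(int) + 1, shape)
        if np.any(lo_i >= hi_i):
            continue
        grids = np.meshgrid(
            *[np.arange(l, h) for l, h in zip(lo_i, hi_i)], indexing="ij"
        )
        expo = sum(((g - c) / max(s, 1e-9)) ** 2 for g, c, s in zip(grids, c_vox, s_vox))
        img[tuple(slice(l, h) for l, h in zip(lo_i, hi_i))] += row.intensity * np.exp(-0.5 * expo)
    rng = np.random.default_rng(seed)
    img += rng.normal(0, config.peak_intensity / config.snr, size=shape)
    stack = ImageStack(voxels=img, voxel_size=config.voxel_size, channel=channel or puncta.channel)
    stack.origin_um = tuple(lo)  # type: ignore[attr-defined]
    return stack


# ---------------------------------------------------------------------------
# smFISH fields
# ---------------------------------------------------------------------------

def generate_fish_field(
    config: FishConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate nuclei and probe puncta for every (region, layer) stratum.

    Returns (cells, puncta, truth, rect_specs).  Cells carry their true
    class; probe-positive cells draw a zero-truncated Poisson transcript
    count (neuronal vs non-neuronal mean), transcripts scatter around the
    nucleus, and with probability ``cluster_prob`` a cell's co-located
    transcripts merge into a single large-area cluster punctum.
    """
    rng = np.random.default_rng(seed)
    w = config.rect_width_px * config.pixel_size
    h = config.rect_height_px * config.pixel_size
    regions = sorted({r for r, _ in config.lphn2_neuron_frac})
    rect_specs = [
        {
            "region": region,
            "origin": (i * (w + 20.0), 0.0),
            "width_px": config.rect_width_px,
            "height_px": config.rect_height_px,
        }
        for i, region in enumerate(regions)
    ]
    cells_rows, puncta_rows, truth_rows = [], [], []
    cell_id, punctum_id = 1, 1
    for i, region in enumerate(regions):
        x0 = i * (w + 20.0)
        for layer in ("deep", "superficial"):
            frac_pos_neuron = config.lphn2_neuron_frac[(region, layer)]
            rest = 1.0 - frac_pos_neuron
            probs = [frac_pos_neuron] + [rest * s for s in config.other_class_split]
            y_lo = 0.0 if layer == "deep" else h / 2
            centers = _poisson_disc(
                rng, config.n_cells, (x0, y_lo), (w, h / 2), config.min_cell_spacing
            )
            classes = rng.choice(4, size=len(centers), p=np.array(probs) / sum(probs))
            for (cx, cy), cls in zip(centers, classes):
                label = ("NeuN+/L2+", "NeuN+/L2-", "NeuN-/L2+", "NeuN-/L2-")[cls]
                neun = cls in (0, 1)
                positive = cls in (0, 2)
                if positive:
                    lam = config.transcripts_neuron if neun else config.transcripts_non_neuronal
                    count = 0
                    while count == 0:  # zero-truncated: positive cells show >= 1 transcript
                        count = int(rng.poisson(lam))
                else:
                    count = 0
                cells_rows.append(
                    {
                        "cell_id": cell_id,
                        "x_um": cx,
                        "y_um": cy,
                        "nucleus_radius": config.nucleus_radius,
                        "neun_positive": neun,
                        "region": region,
                        "layer": layer,
                    }
                )
                truth_rows.append(
                    {
                        "cell_id": cell_id,
                        "true_class": label,
                        "true_count": count,
                        "region": region,
                        "layer": layer,
                    }
                )
                punctum_id = _emit_transcripts(
                    rng, config, puncta_rows, punctum_id, cell_id, (cx, cy), count
                )
                cell_id += 1
    cells = pd.DataFrame(cells_rows)
    puncta = pd.DataFrame(
        puncta_rows,
        columns=["punctum_id", "x_um", "y_um", "area_um2", "true_cell_id", "true_k"],
    )
    truth = pd.DataFrame(truth_rows)
    return cells, puncta, truth, rect_specs


def _emit_transcripts(rng, config: FishConfig, rows, punctum_id, cell_id, center, count) -> int:
    cx, cy = center
    remaining = count
    while remaining > 0:
        if remaining >= 2 and rng.uniform() < config.cluster_prob:
            k = int(min(remaining, rng.integers(2, config.cluster_k_max + 1)))
        else:
            k = 1
        r = config.scatter_radius * math.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * math.pi)
        area = float(
            max(
                0.05,
                sum(rng.normal(config.mean_single_area, config.area_sigma) for _ in range(k)),
            )
        )
        rows.append(
            {
                "punctum_id": punctum_id,
                "x_um": cx + r * math.cos(phi),
                "y_um": cy + r * math.sin(phi),
                "area_um2": area,
                "true_cell_id": cell_id,
                "true_k": k,
            }
        )
        punctum_id += 1
        remaining -= k
    return punctum_id


def _poisson_disc(rng, n: int, origin, size, min_spacing: float, max_tries: int = 20000):
    """Uniform points with a minimum pairwise spacing (dart throwing)."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < max_tries:
        tries += 1
        x = origin[0] + rng.uniform(0, size[0])
        y = origin[1] + rng.uniform(0, size[1])
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing**2 for px, py in pts):
            pts.append((x, y))
    return pts
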