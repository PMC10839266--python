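"""Three-channel perisynaptic distance and overlap analysis.

For a reference channel (e.g. a presynaptic marker) against two partner
channels (postsynaptic and perisynaptic markers), each reference punctum gets
the minimum Euclidean center-to-center distance to each partner channel —
d = √((x₂−x₁)² + (y₂−y₁)² + (z₂−z₁)²) over punctum center points.  Rows where
both partner distances are strictly below the synaptic radius (default 1 μm)
pass the synaptic filter; scatter tables and violin summaries are computed on
seeded uniform subsamples (defaults n = 1000 and n = 300 respectively) so
figure-scale outputs are reproducible.  Voxel overlap fractions between
thresholded channel masks quantify signal independence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spot_detection import ImageStack, PunctumSet

SYNAPTIC_RADIUS_UM = 1.0


def pairwise_min_distance(ref: PunctumSet, target: PunctumSet) -> pd.DataFrame:
    """Per-reference-punctum minimum distance to the target channel.

    Distances are exact (chunked exhaustive search); ties resolve to the
    lowest target punctum id.  Returns columns ref_id, distance, target_id.
    """
    if len(target) == 0:
        raise ValueError(f"target channel {target.channel!r} is empty")
    if len(ref) == 0:
        return pd.DataFrame(columns=["ref_id", "distance", "target_id"])
    tgt = target.table.sort_values("punctum_id", kind="stable")
    tgt_xyz = tgt[["x_um", "y_um", "z_um"]].to_numpy(float)
    tgt_ids = tgt["punctum_id"].to_numpy()
    ref_xyz = ref.centers()
    dists = np.empty(len(ref_xyz))
    idx = np.empty(len(ref_xyz), dtype=int)
    chunk = max(1, int(4e6 // max(1, len(tgt_xyz))))
    for lo in range(0, len(ref_xyz), chunk):
        d = np.linalg.norm(ref_xyz[lo : lo + chunk, None, :] - tgt_xyz[None, :, :], axis=2)
        idx[lo : lo + chunk] = d.argmin(axis=1)  # argmin → first minimum → lowest id
        dists[lo : lo + chunk] = d[np.arange(len(d)), idx[lo : lo + chunk]]
    return pd.DataFrame(
        {
            "ref_id": ref.table["punctum_id"].to_numpy(),
            "distance": dists,
            "target_id": tgt_ids[idx],
        }
    )


@dataclass
class ViolinSummary:
    """Distribution summary for one channel pair (mean with 25/75% quartiles)."""

    pair: str
    n: int
    mean: float
    q25: float
    q75: float
    distances: np.ndarray

    @classmethod
    def from_distances(cls, pair: str, d: np.ndarray) -> "ViolinSummary":
        d = np.asarray(d, float)
        if len(d) == 0:
            return cls(pair, 0, float("nan"), float("nan"), float("nan"), d)
        return cls(
            pair,
            len(d),
            float(d.mean()),
            float(np.percentile(d, 25)),
            float(np.percentile(d, 75)),
            d,
        )


@dataclass
class TripletResult:
    """Output of :func:`triplet_analysis`."""

    table: pd.DataFrame  # full per-reference table (all chA puncta)
    scatter: pd.DataFrame  # seeded subsample for scatter display
    violins: dict[str, ViolinSummary]
    seed: int


def _min_table(ref: PunctumSet, a: PunctumSet, b: PunctumSet, synaptic_radius: float) -> pd.DataFrame:
    da = pairwise_min_distance(ref, a)
    db = pairwise_min_distance(ref, b)
    t = pd.DataFrame(
        {
            "ref_channel": ref.channel,
            "ref_id": da["ref_id"],
            "d_to_A": da["distance"],
            "d_to_B": db["distance"],
            "nearest_A_id": da["target_id"],
            "nearest_B_id": db["target_id"],
        }
    )
    t["synaptic"] = (t["d_to_A"] < synaptic_radius) & (t["d_to_B"] < synaptic_radius)
    return t


def _subsample(df: pd.DataFrame, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if len(df) <= n:
        return df.reset_index(drop=True)
    pick = np.sort(rng.choice(len(df), size=n, replace=False))
    return df.iloc[pick].reset_index(drop=True)


def triplet_analysis(
    chA: PunctumSet,
    chB: PunctumSet,
    chC: PunctumSet,
    synaptic_radius: float = SYNAPTIC_RADIUS_UM,
    subsample_scatter: int = 1000,
    subsample_violin: int = 300,
    seed: int = 0,
) -> TripletResult:
    """Full three-channel minimum-distance analysis.

    The per-reference table uses ``chA`` as reference against B and C.  Violin
    summaries are produced for each ordered pair (A–B, A–C, B–C), each over a
    seeded subsample of reference rows passing the synaptic filter (both
    partner distances strictly < ``synaptic_radius``).
    """
    for ch in (chA, chB, chC):
        if len(ch) == 0:
            raise ValueError(f"channel {ch.channel!r} is empty")
    rng = np.random.default_rng(seed)
    table = _min_table(chA, chB, chC, synaptic_radius)
    scatter = _subsample(table, subsample_scatter, rng)

    violins: dict[str, ViolinSummary] = {}
    pair_defs = [
        (chA, chB, chC, "d_to_A", f"{chA.channel}-{chB.channel}"),
        (chA, chC, chB, "d_to_A", f"{chA.channel}-{chC.channel}"),
        (chB, chC, chA, "d_to_A", f"{chB.channel}-{chC.channel}"),
    ]
    for ref, first, second, col, name in pair_defs:
        t = _min_table(ref, first, second, synaptic_radius)
        syn = t[t["synaptic"]]
        if len(syn) == 0:
            warnings.warn(f"no synaptic rows for pair {name}; empty violin", stacklevel=2)
            violins[name] = ViolinSummary.from_distances(name, np.empty(0))
            continue
        sub = _subsample(syn, subsample_violin, rng)
        violins[name] = ViolinSummary.from_distances(name, sub[col].to_numpy())
    return TripletResult(table=table, scatter=scatter, violins=violins, seed=seed)


def overlap_fractions(
    stacks: dict[str, ImageStack], thresholds: dict[str, float]
) -> pd.DataFrame:
    """Percent of each channel's above-threshold voxels shared with each partner.

    For every ordered pair (A, B): 100 · |maskA ∧ maskB| / |maskA|.  Channels
    whose mask is empty yield NaN with an ``undefined`` flag.
    """
    names = list(stacks)
    shapes = {stacks[n].voxels.shape for n in names}
    if len(shapes) > 1:
        raise ValueError(f"stacks must be voxel-aligned with equal shape, got {shapes}")
    masks = {n: stacks[n].voxels > thresholds[n] for n in names}
    rows = []
    for a in names:
        na = int(masks[a].sum())
        for b in names:
            if a == b:
                continue
            if na == 0:
                warnings.warn(f"channel {a!r} mask empty; overlap undefined", stacklevel=2)
                frac, undef = float("nan"), True
            else:
                frac = 100.0 * int((masks[a] & masks[b]).sum()) / na
                undef = False
            rows.append({"channel": a, "partner": b, "overlap_fraction": frac, "undefined": undef})
    return pd.DataFrame(rows)


def violin_table(violins: dict[str, ViolinSummary]) -> pd.DataFrame:
    rows = [
        {"pair": v.pair, "n": v.n, "mean_um": v.mean, "q25_um": v.q25, "q75_um": v.q75}
        for v in violins.values()
    ]
    return pd.DataFrame(rows)
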