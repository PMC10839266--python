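"""smFISH field quantification: region grids, transcript counts, cell classes.

Fields are surveyed through rectangular regions (600 px wide, ≈132 μm at the
default 0.22 μm/px) drawn over the pyramidal layer, each split into deep and
superficial halves at the midline.  Cells are classified four ways by the
neuronal marker (NeuN) and probe positivity (NeuN+/L2+, NeuN+/L2−, NeuN−/L2+,
NeuN−/L2−); per-group transcript levels are total probe puncta divided by the
number of probe-positive cells in the group.  Dense merged clusters are
counted by area relative to the average isolated punctum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_PIXEL_SIZE_UM = 0.22  # back-derived from a 600 px ≈ 132 μm region width
DEFAULT_CAPTURE_RADIUS_UM = 8.0  # typical somatic extent; not a measured value

CLASS_LABELS = ("NeuN+/L2+", "NeuN+/L2-", "NeuN-/L2+", "NeuN-/L2-")


@dataclass(frozen=True)
class RegionRect:
    """One survey rectangle: origin is the corner at minimal (x, y), μm.

    ``depth_axis`` is the axis along which deep → superficial runs ("x" or
    "y"); ``deep_at_min`` says whether the deep half sits at the low end.
    """

    region: str
    origin: tuple[float, float]
    width: float
    height: float
    depth_axis: str = "y"
    deep_at_min: bool = True


@dataclass
class RegionGrid:
    rectangles: list[RegionRect]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def locate(self, x: float, y: float) -> tuple[str, str] | None:
        """(region, layer) of a point, or None if outside every rectangle."""
        for r in self.rectangles:
            dx, dy = x - r.origin[0], y - r.origin[1]
            if not (0 <= dx <= r.width and 0 <= dy <= r.height):
                continue
            depth_frac = (dx / r.width) if r.depth_axis == "x" else (dy / r.height)
            in_low_half = depth_frac < 0.5
            layer = "deep" if (in_low_half == r.deep_at_min) else "superficial"
            return r.region, layer
        return None


def build_region_grid(
    rect_specs: list[dict], pixel_size: float = DEFAULT_PIXEL_SIZE_UM
) -> RegionGrid:
    """Build a grid from config rectangles (widths given in pixels).

    Each spec needs region, origin (μm), width_px, height_px; optional
    depth_axis and deep_at_min.  Degenerate rectangles are an error;
    overlapping ones only warn (regions may abut imperfectly in practice).
    """
    rects = []
    for spec in rect_specs:
        w = spec["width_px"] * pixel_size
        h = spec["height_px"] * pixel_size
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate rectangle for region {spec.get('region')!r}")
        rects.append(
            RegionRect(
                region=str(spec["region"]),
                origin=tuple(spec["origin"]),
                width=w,
                height=h,
                depth_axis=spec.get("depth_axis", "y"),
                deep_at_min=bool(spec.get("deep_at_min", True)),
            )
        )
    for i, a in enumerate(rects):
        for b in rects[i + 1 :]:
            if _rects_overlap(a, b):
                warnings.warn(f"regions {a.region!r} and {b.region!r} overlap", stacklevel=2)
    return RegionGrid(rectangles=rects, pixel_size=pixel_size)


def _rects_overlap(a: RegionRect, b: RegionRect) -> bool:
    ax0, ay0 = a.origin
    bx0, by0 = b.origin
    return (
        ax0 < bx0 + b.width
        and bx0 < ax0 + a.width
        and ay0 < by0 + b.height
        and by0 < ay0 + a.height
    )


# ---------------------------------------------------------------------------
# Transcript assignment and counting
# ---------------------------------------------------------------------------

def assign_puncta_to_cells(
    puncta: pd.DataFrame,
    cells: pd.DataFrame,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS_UM,
    mean_single_area: float | None = None,
) -> pd.DataFrame:
    """Assign each punctum to its nearest nucleus within ``capture_radius`` μm.

    ``puncta`` needs x_um, y_um and optionally area_um2 (cluster estimation);
    ``cells`` needs cell_id, x_um, y_um.  Ties go to the lower cell id.
    Returns the puncta table with ``cell_id`` (−1 if unassigned) and
    ``est_count`` — 1 per isolated punctum, area-based for merged clusters.
    """
    if capture_radius <= 0:
        raise ValueError("capture_radius must be > 0")
    out = puncta.copy()
    if len(puncta) == 0 or len(cells) == 0:
        out["cell_id"] = pd.Series(dtype=int)
        out["est_count"] = pd.Series(dtype=int)
        return out
    cells_sorted = cells.sort_values("cell_id", kind="stable")
    cxy = cells_sorted[["x_um", "y_um"]].to_numpy(float)
    pxy = out[["x_um", "y_um"]].to_numpy(float)
    d = np.linalg.norm(pxy[:, None, :] - cxy[None, :, :], axis=2)
    j = d.argmin(axis=1)  # first minimum → lowest cell_id
    dmin = d[np.arange(len(d)), j]
    ids = cells_sorted["cell_id"].to_numpy()[j]
    out["cell_id"] = np.where(dmin <= capture_radius, ids, -1)

    if "area_um2" in out.columns:
        areas = out["area_um2"].to_numpy(float)
        if mean_single_area is None:
            mean_single_area = float(np.median(areas))
        is_cluster = areas > 1.5 * mean_single_area
        est = np.ones(len(out), dtype=int)
        est[is_cluster] = [
            estimate_cluster_count(a, mean_single_area) for a in areas[is_cluster]
        ]
        out["est_count"] = est
    else:
        out["est_count"] = 1
    return out


def estimate_cluster_count(cluster_area: float, mean_single_area: float) -> int:
    """Estimated transcript count in a merged cluster, by relative area.

    count = round(cluster_area / mean_single_area), floored at 1.
    """
    if mean_single_area <= 0:
        raise ValueError("mean_single_area must be > 0")
    if cluster_area <= 0:
        raise ValueError("cluster_area must be > 0")
    return max(1, int(round(cluster_area / mean_single_area)))


def count_transcripts(assigned_puncta: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Sum estimated transcript counts per cell; cells with none get 0."""
    out = cells.copy()
    if len(assigned_puncta):
        per_cell = (
            assigned_puncta[assigned_puncta["cell_id"] >= 0]
            .groupby("cell_id")["est_count"]
            .sum()
        )
    else:
        per_cell = pd.Series(dtype=int)
    out["lphn2_count"] = out["cell_id"].map(per_cell).fillna(0).astype(int)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_cells(
    cells: pd.DataFrame,
    grid: RegionGrid | None = None,
    positivity_min: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Four-way NeuN/probe classification with per-(region, layer) summaries.

    ``cells`` needs cell_id, x_um, y_um, neun_positive, lphn2_count, and —
    when no grid is given — region and layer columns.  Returns the annotated
    cell table and a summary with class percentages (summing to 100 per
    stratum) and the per-group transcript level: total probe puncta divided by
    the number of probe-positive cells in the group.
    """
    out = cells.copy()
    if grid is not None:
        locs = [grid.locate(x, y) for x, y in out[["x_um", "y_um"]].to_numpy(float)]
        out["region"] = [l[0] if l else "" for l in locs]
        out["layer"] = [l[1] if l else "" for l in locs]
        n_out = sum(l is None for l in locs)
        if n_out:
            warnings.warn(f"{n_out} cells fall outside every region; dropped", stacklevel=2)
        out = out[out["region"] != ""].reset_index(drop=True)
    lphn2_pos = out["lphn2_count"] >= positivity_min
    neun = out["neun_positive"].astype(bool)
    out["classification"] = np.select(
        [neun & lphn2_pos, neun & ~lphn2_pos, ~neun & lphn2_pos],
        ["NeuN+/L2+", "NeuN+/L2-", "NeuN-/L2+"],
        default="NeuN-/L2-",
    )

    rows = []
    for (region, layer), grp in out.groupby(["region", "layer"]):
        n = len(grp)
        if n == 0:
            continue
        for cls in CLASS_LABELS:
            sub = grp[grp["classification"] == cls]
            pos = sub[sub["lphn2_count"] >= positivity_min]
            level = (
                float(pos["lphn2_count"].sum() / len(pos)) if len(pos) else float("nan")
            )
            rows.append(
                {
                    "region": region,
                    "layer": layer,
                    "classification": cls,
                    "n_cells": len(sub),
                    "pct": 100.0 * len(sub) / n,
                    "transcripts_per_positive_cell": level,
                }
            )
    summary = pd.DataFrame(rows)
    return out, summary


def transcript_levels(cell_table: pd.DataFrame, positivity_min: int = 1) -> pd.DataFrame:
    """Probe level among probe-positive cells, split neuron vs non-neuronal.

    Pooled across strata; this is the per-cell-type expression summary
    (transcripts per positive cell).
    """
    pos = cell_table[cell_table["lphn2_count"] >= positivity_min]
    rows = []
    for name, mask in (("neuron", pos["neun_positive"].astype(bool)), ("non_neuronal", ~pos["neun_positive"].astype(bool))):
        grp = pos[mask]
        if len(grp) == 0:
            continue
        counts = grp["lphn2_count"].to_numpy(float)
        rows.append(
            {
                "cell_type": name,
                "n_cells": len(grp),
                "mean_transcripts": float(counts.mean()),
                "sem_transcripts": float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
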