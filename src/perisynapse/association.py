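"""Puncta-to-dendrite association, shaft/spine classification, density tables.

A punctum is dendrite-associated when its center lies strictly within the
association threshold (default 0.5 μm) of the reconstructed dendrite surface;
associated puncta are classified shaft- or spine-associated by whichever
compartment is nearest.  Densities are puncta per μm of cable, binned per cell
by (domain, subdivision) or by branch order; normalized densities divide each
category by the mean density across that cell's categories, so the per-cell
mean of normalized values is exactly 1.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .morphology import (
    BranchLabel,
    Compartment,
    DendriteTree,
    surface_distances,
)
from .spot_detection import PunctumSet

ASSOCIATION_THRESHOLD_UM = 0.5

ASSOCIATION_COLUMNS = [
    "punctum_id",
    "surface_distance",
    "associated",
    "category",
    "branch_id",
    "subdivision",
    "domain",
    "branch_order",
]


def associate_puncta(
    puncta: PunctumSet,
    tree: DendriteTree,
    labels: Mapping[int, BranchLabel],
    threshold: float = ASSOCIATION_THRESHOLD_UM,
) -> pd.DataFrame:
    """One association record per punctum (strict ``<`` at the threshold)."""
    if len(puncta) == 0:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    centers_xyz = puncta.centers()
    hits = surface_distances(centers_xyz, tree)
    rows = []
    for pid, hit in zip(puncta.table["punctum_id"], hits):
        associated = hit.surface_distance < threshold
        if associated:
            category = "spine" if hit.nearest_compartment is Compartment.SPINE else "shaft"
            lbl = labels.get(hit.nearest_branch_id)
        else:
            category, lbl = "none", None
        rows.append(
            {
                "punctum_id": pid,
                "surface_distance": hit.surface_distance,
                "associated": associated,
                "category": category,
                "branch_id": hit.nearest_branch_id if associated else -1,
                "subdivision": lbl.subdivision.value if lbl else "",
                "domain": lbl.domain.value if lbl else "",
                "branch_order": lbl.branch_order if lbl else 0,
            }
        )
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def _spine_counts_per_branch(tree: DendriteTree) -> pd.Series:
    """Number of spines attached to each branch (spine = maximal spine subtree)."""
    # count spine roots: spine nodes whose parent is not a spine
    counts: dict[int, int] = {}
    node_branch = {}
    for bid, arr in _branch_nodes(tree).items():
        for nid in arr:
            node_branch[nid] = bid
    for n in tree.nodes.values():
        if n.compartment is not Compartment.SPINE:
            continue
        parent = tree.nodes.get(n.parent_id) if n.parent_id is not None else None
        if parent is None or parent.compartment is Compartment.SPINE:
            continue
        bid = node_branch.get(parent.node_id)
        if bid is not None:
            counts[bid] = counts.get(bid, 0) + 1
    return pd.Series(counts, dtype=int)


def _branch_nodes(tree: DendriteTree) -> dict[int, tuple[int, ...]]:
    from .morphology import classify_branches

    return {bid: lbl.node_ids for bid, lbl in classify_branches(tree).items()}


def density_table(
    records: pd.DataFrame,
    labels: Mapping[int, BranchLabel],
    tree: DendriteTree,
    group_by: str = "domain_subdivision",
    cell_id: str = "cell",
) -> pd.DataFrame:
    """Per-category density table for one cell.

    ``group_by`` is ``"domain_subdivision"`` or ``"branch_order"``.  Density is
    associated-punctum count divided by the category's cable length (per μm);
    spine density is computed identically from spine attachment counts.
    Categories with zero cable length are excluded with a warning.
    """
    if group_by not in ("domain_subdivision", "branch_order"):
        raise ValueError(f"unknown group_by {group_by!r}")

    lbl_df = pd.DataFrame(
        {
            "branch_id": [l.branch_id for l in labels.values()],
            "domain": [l.domain.value for l in labels.values()],
            "subdivision": [l.subdivision.value for l in labels.values()],
            "branch_order": [l.branch_order for l in labels.values()],
            "cable_length": [l.length for l in labels.values()],
        }
    )
    spines = _spine_counts_per_branch(tree)
    lbl_df["spine_count"] = lbl_df["branch_id"].map(spines).fillna(0).astype(int)

    keys = ["domain", "subdivision"] if group_by == "domain_subdivision" else ["branch_order"]
    geom = lbl_df.groupby(keys, as_index=False)[["cable_length", "spine_count"]].sum()

    assoc = records[records["associated"]] if len(records) else records
    if len(assoc):
        counts = assoc.groupby(keys).agg(
            punctum_count=("punctum_id", "size"),
            spine_assoc=("category", lambda s: int((s == "spine").sum())),
            shaft_assoc=("category", lambda s: int((s == "shaft").sum())),
        )
        geom = geom.merge(counts, on=keys, how="left")
    else:
        geom["punctum_count"] = 0
        geom["spine_assoc"] = 0
        geom["shaft_assoc"] = 0
    for c in ("punctum_count", "spine_assoc", "shaft_assoc"):
        geom[c] = geom[c].fillna(0).astype(int)

    zero_len = geom["cable_length"] <= 0
    if zero_len.any():
        warnings.warn(
            f"excluding {int(zero_len.sum())} categories with zero cable length", stacklevel=2
        )
        geom = geom[~zero_len].reset_index(drop=True)

    geom.insert(0, "cell_id", cell_id)
    geom["density"] = geom["punctum_count"] / geom["cable_length"]
    geom["spine_density"] = geom["spine_count"] / geom["cable_length"]
    n_assoc = geom["spine_assoc"] + geom["shaft_assoc"]
    with np.errstate(invalid="ignore", divide="ignore"):
        geom["pct_spine_associated"] = np.where(n_assoc > 0, 100.0 * geom["spine_assoc"] / n_assoc, np.nan)
        geom["pct_shaft_associated"] = np.where(n_assoc > 0, 100.0 * geom["shaft_assoc"] / n_assoc, np.nan)
    return geom


def normalize_densities(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_density``: density / mean density across the cell's categories.

    Cells whose densities are all zero have no defined normalization; their
    rows are flagged (``normalized_density`` NaN) and a warning is emitted.
    """
    out = table.copy()
    out["normalized_density"] = np.nan
    for cell, idx in out.groupby("cell_id").groups.items():
        mean = out.loc[idx, "density"].mean()
        if mean > 0:
            out.loc[idx, "normalized_density"] = out.loc[idx, "density"] / mean
        else:
            warnings.warn(f"cell {cell!r} has all-zero densities; normalization undefined", stacklevel=2)
    return out


def shaft_spine_fractions(
    records: pd.DataFrame,
    by: list[str] | None = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Percent shaft- vs spine-associated over associated puncta, per group.

    Groups with zero associated puncta are omitted with a warning; groups with
    fewer than ``min_count`` puncta are flagged ``low_n``.
    """
    assoc = records[records["associated"]]
    if by:
        grouped = assoc.groupby(by)
    else:
        grouped = [((), assoc)]
    rows = []
    for key, grp in grouped:
        n = len(grp)
        if n == 0:
            warnings.warn(f"group {key!r} has no associated puncta; omitted", stacklevel=2)
            continue
        n_spine = int((grp["category"] == "spine").sum())
        row = dict(zip(by or [], key if isinstance(key, tuple) else (key,)))
        row.update(
            n=n,
            pct_spine=100.0 * n_spine / n,
            pct_shaft=100.0 * (n - n_spine) / n,
            low_n=n < min_count,
        )
        rows.append(row)
    if not rows:
        warnings.warn("no associated puncta in any group", stacklevel=2)
        return pd.DataFrame(columns=(by or []) + ["n", "pct_spine", "pct_shaft", "low_n"])
    return pd.DataFrame(rows)
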