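"""Group comparisons, significance stars, firing-pattern classification, report tables.

Two-group comparisons use the Mann-Whitney rank-sum test (exact null for
small samples without ties, normal approximation with tie correction
otherwise); three or more groups use one-way ANOVA with post hoc Tukey HSD.
Stars follow the usual convention: * p < 0.05, ** p < 0.01, *** p < 0.001.
Every summary states its n and the unit n counts (cells or animals), since
figure-level statistics legitimately mix both.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multicomp import pairwise_tukeyhsd


def significance_stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    groups: list[str]
    test: str  # "mann_whitney" | "anova_tukey"
    statistic: float
    p_value: float
    stars: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    n_unit: str
    pairwise: pd.DataFrame | None = None  # Tukey table for >= 3 groups


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else float("nan")
    return mean, sem


def compare_groups(
    groups: dict[str, "np.ndarray | list[float]"],
    n_unit: str = "cells",
    exact_max_n: int = 8,
) -> ComparisonResult:
    """Compare ≥2 groups: rank-sum for two, one-way ANOVA + Tukey for more.

    The rank-sum null is exact when both groups have at most ``exact_max_n``
    observations and no ties span the groups; identical constant groups take
    the degenerate p = 1 path instead of crashing.
    """
    names = list(groups)
    data = {k: np.asarray(v, float) for k, v in groups.items()}
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for k, v in data.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    means, sems, ns = {}, {}, {}
    for k, v in data.items():
        means[k], sems[k] = _mean_sem(v)
        ns[k] = len(v)

    if len(names) == 2:
        a, b = data[names[0]], data[names[1]]
        pooled = np.concatenate([a, b])
        if np.ptp(pooled) == 0:
            stat, p = float(len(a) * len(b) / 2), 1.0
        else:
            has_ties = len(np.unique(pooled)) < len(pooled)
            method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        return ComparisonResult(
            names, "mann_whitney", stat, p, significance_stars(p), means, sems, ns, n_unit
        )

    arrays = [data[k] for k in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
        tukey_df = None
    else:
        f, p = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        labels = np.concatenate([[k] * len(data[k]) for k in names])
        tk = pairwise_tukeyhsd(values, labels)
        tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return ComparisonResult(
        names, "anova_tukey", float(f), float(p), significance_stars(float(p)),
        means, sems, ns, n_unit, pairwise=tukey_df,
    )


# ---------------------------------------------------------------------------
# Firing-pattern classification
# ---------------------------------------------------------------------------

def classify_firing_pattern(
    spike_times_ms: "list[float] | np.ndarray",
    burst_window: float = 60.0,
    burst_isi_max: float = 15.0,
) -> str:
    """Classify a minimal-suprathreshold-step spike train.

    ``early_bursting`` requires more than two spikes at step onset — inside
    ``burst_window`` ms with every consecutive inter-spike interval at most
    ``burst_isi_max`` ms.  A single onset spike, or exactly two burst spikes,
    is ``regular_late_bursting``; an empty train is ``unclassified``.
    """
    t = np.sort(np.asarray(spike_times_ms, float))
    if len(t) == 0:
        return "unclassified"
    if np.any(t < 0):
        raise ValueError("spike times must be non-negative (relative to step onset)")
    burst_len = 1
    for i in range(1, len(t)):
        if t[i] > burst_window or (t[i] - t[i - 1]) > burst_isi_max:
            break
        burst_len += 1
    return "early_bursting" if burst_len > 2 else "regular_late_bursting"


# ---------------------------------------------------------------------------
# Figure-style report tables
# ---------------------------------------------------------------------------

def _provenance_header(seed: int | None, config: dict | None) -> str:
    cfg = json.dumps(config or {}, sort_keys=True, default=str)
    digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    return f"# seed={seed} config_sha256={digest}\n"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None, config: dict | None = None) -> None:
    """Write a TSV with a provenance header; byte-identical for identical inputs."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_header(seed, config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def figure_tables(run_dir: str | Path, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Build summary tables from a pipeline run directory.

    Expects the TSVs the pipeline stages write (``associations.tsv``,
    ``density_by_domain.tsv``, ``triplet_violin.tsv``, ``class_summary.tsv``;
    missing inputs raise a named error for that table).  Each output carries
    a provenance header and is schema-checked to be non-empty.
    """
    run_dir, out_dir = Path(run_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def require(name: str) -> pd.DataFrame:
        p = run_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing upstream table {name} in {run_dir}")
        return pd.read_csv(p, sep="\t", comment="#")

    # density-by-domain summary (figure-3/4 shaped)
    dens = require("density_by_domain.tsv")
    dens_summary = dens.groupby(["domain", "subdivision"], as_index=False).agg(
        mean_density=("density", "mean"),
        mean_normalized=("normalized_density", "mean"),
        n=("cell_id", "nunique"),
    )
    p = out_dir / "summary_density_by_domain.tsv"
    write_table(dens_summary, p, seed=seed)
    written["density_by_domain"] = p

    # shaft/spine percentages (figure-3B shaped)
    assoc = require("associations.tsv")
    from .association import shaft_spine_fractions

    frac = shaft_spine_fractions(assoc, by=["domain"])
    p = out_dir / "summary_shaft_spine.tsv"
    write_table(frac, p, seed=seed)
    written["shaft_spine"] = p

    # triplet distance summary (figure-5 shaped)
    violin = require("triplet_violin.tsv")
    p = out_dir / "summary_triplet_distances.tsv"
    write_table(violin, p, seed=seed)
    written["triplet_distances"] = p

    # smFISH class summary (figure-1/6 shaped)
    cls = require("class_summary.tsv")
    p = out_dir / "summary_fish_classes.tsv"
    write_table(cls, p, seed=seed)
    written["fish_classes"] = p
    return written
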