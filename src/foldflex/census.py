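"""Aggregation of per-instance metrics into the fold-flexibility census.

Each group (sub-cluster, topology/fold, or class) is summarized by robust
statistics of its RMSD distribution to the predicted reference — median,
scaled MAD (1.4826 × median absolute deviation, a robust standard
deviation), IQR, min/max — plus tier fractions (share of instances within
2.5 Å and 5.0 Å) and medians of the geometry metrics. The census rows feed
the spectrum orderings, the tier census of folds, and the geometry-vs-RMSD
trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAD_SCALE = 1.4826
DEFAULT_TIERS = (2.5, 5.0)
DEFAULT_RMSD_BINS = (0.0, 1.5, 2.5, 5.0, np.inf)


@dataclass
class GroupCensusRow:
    group_id: str
    level: str
    n_instances: int
    median_rmsd: float
    mad_rmsd: float
    iqr_rmsd: float
    min_rmsd: float
    max_rmsd: float
    frac_le_2_5: float
    frac_le_5: float
    median_rmsd100: float | None = None
    median_av_ratio: float | None = None
    median_be_ratio: float | None = None
    protein_accs: tuple[str, ...] = field(default_factory=tuple)


def _median(values) -> float | None:
    v = pd.Series(values).dropna()
    return float(v.median()) if len(v) else None


def aggregate_group(
    rows: pd.DataFrame,
    level: str,
    group_id: str,
    scaled_mad: bool = True,
    tiers: tuple[float, float] = DEFAULT_TIERS,
) -> GroupCensusRow:
    """Summarize the per-instance metric rows of one group.

    ``rows`` must carry an ``rmsd`` column; geometry columns are optional
    and their medians are computed over present values only.
    """
    if len(rows) == 0:
        raise ValueError(f"group {group_id}: empty")
    r = rows["rmsd"].to_numpy(float)
    if np.any(np.isnan(r)):
        raise ValueError(f"group {group_id}: missing rmsd values")
    med = float(np.median(r))
    mad = float(np.median(np.abs(r - med)))
    if scaled_mad:
        mad *= MAD_SCALE
    q75, q25 = np.percentile(r, [75, 25])
    return GroupCensusRow(
        group_id=group_id,
        level=level,
        n_instances=len(r),
        median_rmsd=med,
        mad_rmsd=mad,
        iqr_rmsd=float(q75 - q25),
        min_rmsd=float(r.min()),
        max_rmsd=float(r.max()),
        frac_le_2_5=float(np.mean(r <= tiers[0])),
        frac_le_5=float(np.mean(r <= tiers[1])),
        median_rmsd100=_median(rows.get("rmsd100")),
        median_av_ratio=_median(rows.get("av_ratio")),
        median_be_ratio=_median(rows.get("be_ratio")),
        protein_accs=tuple(sorted(rows["protein_acc"].unique()))
        if "protein_acc" in rows
        else (),
    )


def build_census(
    metrics: pd.DataFrame,
    level: str,
    group_col: str,
    weight: str = "instance",
    scaled_mad: bool = True,
) -> list[GroupCensusRow]:
    """One census row per group in ``metrics``.

    ``weight="instance"`` aggregates raw instances; ``weight="subcluster"``
    first collapses each sub-cluster to its median RMSD (requires a
    ``subcluster_id`` column), damping over-represented near-duplicates.
    """
    if weight == "subcluster" and group_col != "subcluster_id":
        collapsed = (
            metrics.groupby(["subcluster_id", group_col], as_index=False)
            .median(numeric_only=True)
        )
        if "protein_acc" in metrics:
            accs = metrics.groupby("subcluster_id")["protein_acc"].first()
            collapsed["protein_acc"] = collapsed["subcluster_id"].map(accs)
        metrics = collapsed
    rows = [
        aggregate_group(g, level, str(gid), scaled_mad=scaled_mad)
        for gid, g in sorted(metrics.groupby(group_col), key=lambda kv: str(kv[0]))
    ]
    return rows


def census_frame(rows: list[GroupCensusRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    if "protein_accs" in df:
        df["protein_accs"] = df["protein_accs"].map(lambda t: ";".join(t))
    return df


def tier_census(rows: list[GroupCensusRow], cutoff: float) -> dict[str, float]:
    """Fractions of groups by how their members sit around an RMSD cutoff.

    Returns the fraction of groups with at least one member within the
    cutoff, with at least one member beyond it, and with all members within.
    """
    n = len(rows)
    if n == 0:
        return {"frac_any_within": np.nan, "frac_any_beyond": np.nan, "frac_all_within": np.nan}
    return {
        "frac_any_within": sum(r.min_rmsd <= cutoff for r in rows) / n,
        "frac_any_beyond": sum(r.max_rmsd > cutoff for r in rows) / n,
        "frac_all_within": sum(r.max_rmsd <= cutoff for r in rows) / n,
    }


@dataclass
class SSEDiffDistribution:
    cutoffs: tuple[int, ...]
    frac_exceeding: tuple[float, ...]


def sse_diff_distribution(
    diffs, cutoffs: tuple[int, ...] = (1, 2, 4, 8)
) -> SSEDiffDistribution:
    """Fraction of instances whose prediction has more than k extra structured residues."""
    d = np.asarray(list(diffs), float)
    fracs = tuple(float(np.mean(d > c)) if len(d) else 0.0 for c in cutoffs)
    return SSEDiffDistribution(cutoffs=tuple(cutoffs), frac_exceeding=fracs)


def spectrum_order(rows: list[GroupCensusRow]) -> pd.DataFrame:
    """Census frame with stable rank columns by median and by MAD.

    Ties break lexicographically on group_id, so ranks are permutation
    invariant.
    """
    df = census_frame(rows)
    for col, rank_col in (("median_rmsd", "rank_median"), ("mad_rmsd", "rank_mad")):
        order = df.sort_values([col, "group_id"], kind="stable").index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[rank_col] = ranks
    return df.sort_values("group_id").reset_index(drop=True)


def geometry_trend(
    rows: list[GroupCensusRow],
    rmsd_bins: tuple[float, ...] = DEFAULT_RMSD_BINS,
) -> pd.DataFrame:
    """Per-RMSD-bin medians of group AVratio and BEratio.

    Groups are binned by median RMSD into (lo, hi] intervals; empty bins
    yield NaN medians.
    """
    df = census_frame(rows)
    edges = list(rmsd_bins)
    out = []
    for lo, hi in zip(edges, edges[1:]):
        sel = df[(df["median_rmsd"] > lo) & (df["median_rmsd"] <= hi)]
        out.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_groups": len(sel),
                "median_av_ratio": float(sel["median_av_ratio"].median()) if len(sel) else np.nan,
                "median_be_ratio": float(sel["median_be_ratio"].median()) if len(sel) else np.nan,
            }
        )
    return pd.DataFrame(out)
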