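"""Biology-facing analyses on top of the census.

Two capabilities:

* **Two-region conformational clustering** (the RAS-switch analysis): for a
  set of conformers of one protein, compute the RMSD of each of two mobile
  regions to the predicted reference under the whole-domain superposition,
  then cluster conformers in that 2D RMSD plane (Ward agglomerative
  clustering; k chosen by silhouette when automatic) to identify discrete
  conformational patterns, e.g. open/closed switch combinations.

* **Annotation enrichment**: compare proteins owning a heterogeneous domain
  group (median RMSD above a cutoff) against proteins owning a group from
  the lowest decile of median RMSD, scoring each annotation term with a
  one-sided hypergeometric tail probability plus Benjamini–Hochberg
  adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .census import GroupCensusRow
from .structio import DomainInstance
from .structmetrics import region_rmsd, superpose_instances


@dataclass
class RegionSpec:
    """A named residue-number interval in reference numbering."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.name}: start must be < end")

    @property
    def range(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ConformationCluster:
    labels: dict[str, int]
    k: int
    centers: np.ndarray  # (k, 2) mean 2D-RMSD per cluster


@dataclass
class EnrichmentResult:
    term: str
    count_het: int
    count_con: int
    count_diff: int
    direction: str  # which set the term is over-represented in
    p_value: float
    adjusted_p: float = np.nan


def two_region_rmsd(
    instances: list[DomainInstance],
    predicted_ref: DomainInstance,
    regions: tuple[RegionSpec, RegionSpec],
    pair_maps: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Per-instance RMSD of two regions to the predicted reference.

    All instances must map to the same predicted reference; each is
    superposed over its full mapped core and the two region RMSDs are read
    off without refit. Instances lacking residues in either region are
    flagged ``excluded`` (kept in the table, dropped from clustering).
    """
    rows = []
    for inst in instances:
        pairs = pair_maps.get(inst.instance_id) if pair_maps else None
        sup, used = superpose_instances(inst, predicted_ref, pairs)
        r1 = region_rmsd(sup, inst, predicted_ref, used, regions[0].range)
        r2 = region_rmsd(sup, inst, predicted_ref, used, regions[1].range)
        rows.append(
            {
                "instance_id": inst.instance_id,
                f"rmsd_{regions[0].name}": r1,
                f"rmsd_{regions[1].name}": r2,
                "excluded": r1 is None or r2 is None,
            }
        )
    return pd.DataFrame(rows)


def cluster_conformations(
    table: pd.DataFrame, k: int | str = "auto", k_max: int = 10
) -> ConformationCluster:
    """Cluster conformers in the 2D region-RMSD plane.

    Ward linkage on Euclidean distances; with ``k="auto"`` the cut
    maximizing the silhouette over k in 2..min(k_max, n-1) is chosen, and
    coincident points collapse to a single cluster. Labels are renumbered
    by cluster mean (ascending summed RMSD) so they are stable under
    permutation of the input rows.
    """
    cols = [c for c in table.columns if c.startswith("rmsd_")]
    if len(cols) != 2:
        raise ValueError("expected exactly two rmsd_<region> columns")
    t = table.loc[~table.get("excluded", False)].copy() if "excluded" in table else table.copy()
    t = t.sort_values("instance_id", kind="stable")
    x = t[cols].to_numpy(float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 instances with both region values")
    if np.allclose(x, x[0]):
        labels = np.zeros(n, int)
        k_best = 1
    else:
        z = linkage(x, method="ward")
        if k == "auto":
            best, k_best, labels = -np.inf, None, None
            for kk in range(2, min(k_max, n - 1) + 1):
                lab = fcluster(z, kk, criterion="maxclust") - 1
                if len(np.unique(lab)) < 2:
                    continue
                s = silhouette_score(x, lab)
                if s > best + 1e-12:
                    best, k_best, labels = s, kk, lab
            if labels is None:
                labels, k_best = np.zeros(n, int), 1
        else:
            k_best = int(k)
            labels = fcluster(z, k_best, criterion="maxclust") - 1
    k_eff = len(np.unique(labels))
    centers = np.array([x[labels == c].mean(axis=0) for c in np.unique(labels)])
    order = np.argsort(centers.sum(axis=1), kind="stable")
    remap = {int(old): new for new, old in enumerate(np.unique(labels)[order])}
    labels = np.array([remap[int(c)] for c in labels])
    centers = centers[order]
    return ConformationCluster(
        labels=dict(zip(t["instance_id"], (int(v) for v in labels))),
        k=k_eff,
        centers=centers,
    )


def threshold_fractions(
    table: pd.DataFrame, cutoffs: tuple[float, ...] = (1.0, 2.5, 5.0)
) -> dict[float, float]:
    """Fraction of instances with *both* regions within each cutoff."""
    cols = [c for c in table.columns if c.startswith("rmsd_")]
    t = table.loc[~table.get("excluded", False)] if "excluded" in table else table
    if len(t) == 0:
        raise ValueError("empty region table")
    worst = t[cols].to_numpy(float).max(axis=1)
    return {c: float(np.mean(worst <= c)) for c in cutoffs}


def select_protein_sets(
    rows: list[GroupCensusRow],
    het_cutoff: float = 2.5,
    con_decile: float = 0.10,
) -> tuple[set[str], set[str]]:
    """Heterogeneous vs consistent protein sets from the census.

    Heterogeneous: proteins owning at least one group with median RMSD
    above ``het_cutoff``. Consistent: proteins owning a group from the
    lowest decile of group medians (ties at the boundary included).
    Proteins qualifying for both go to the heterogeneous set only.
    """
    if not rows:
        return set(), set()
    medians = np.array([r.median_rmsd for r in rows])
    decile_cut = np.quantile(medians, con_decile)
    het, con = set(), set()
    for r in rows:
        if r.median_rmsd > het_cutoff:
            het.update(r.protein_accs)
        if r.median_rmsd <= decile_cut:
            con.update(r.protein_accs)
    con -= het
    return het, con


def hypergeom_enrich(
    het: set[str],
    con: set[str],
    annotations: pd.DataFrame,
    min_annotated: int = 1,
) -> list[EnrichmentResult]:
    """Per-term hypergeometric over-representation in either protein set.

    ``annotations`` is a two-column frame (``protein_acc``, ``term``). The
    universe is het ∪ con. For each term and each direction, the one-sided
    tail probability of drawing at least the observed number of annotated
    proteins into that set is computed; Benjamini–Hochberg adjustment is
    applied across all reported tests.
    """
    universe = het | con
    if not universe:
        return []
    ann = annotations[annotations["protein_acc"].isin(universe)]
    results: list[EnrichmentResult] = []
    m = len(universe)
    for term, grp in sorted(ann.groupby("term"), key=lambda kv: str(kv[0])):
        annotated = set(grp["protein_acc"])
        k_total = len(annotated)
        if k_total < min_annotated:
            continue
        c_het = len(annotated & het)
        c_con = len(annotated & con)
        for direction, count, size in (("het", c_het, len(het)), ("con", c_con, len(con))):
            if size == 0:
                continue
            p = float(hypergeom.sf(count - 1, m, k_total, size))
            results.append(
                EnrichmentResult(
                    term=str(term),
                    count_het=c_het,
                    count_con=c_con,
                    count_diff=c_con - c_het,
                    direction=direction,
                    p_value=p,
                )
            )
    if results:
        adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
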