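"""Fingerprint normalization, hierarchical clustering, and polytherapy
selection by iterative cluster elimination.

Condition fingerprints (rows = conditions such as ``WT-0h``, ``Mut-0h`` or
``Mut-4h-drugA``; columns = the 165 connectivity metrics) are z-normalized
per metric across conditions, clustered with Ward linkage on Euclidean
distances, and cut at the largest merge-height gap. The polytherapy
selector then repeats: find the non-reference cluster closest to the
untreated wild-type (reference) cluster, pick the compound in it closest to
the reference centroid, eliminate that whole cluster, and recluster --
yielding an ordered list of complementary hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


@dataclass
class ClusterTree:
    """Hierarchical clustering with a flat cut and a reference cluster."""

    linkage: np.ndarray
    labels: list[str]
    assignment: np.ndarray            # flat cluster id per row (1-based)
    reference_cluster: int
    X: pd.DataFrame                   # the clustered matrix (rows aligned)

    def members(self, cluster_id: int) -> list[str]:
        return [l for l, a in zip(self.labels, self.assignment) if a == cluster_id]

    def centroid(self, cluster_id: int) -> np.ndarray:
        rows = self.assignment == cluster_id
        return self.X.values[rows].mean(axis=0)

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.assignment)


@dataclass
class SelectionRound:
    selected: str
    cluster_members: list[str]
    cluster_distance: float           # cluster centroid to reference centroid
    compound_distance: float          # selected row to reference centroid


@dataclass
class SelectionResult:
    """Ordered complementary hits from iterative cluster elimination."""

    rounds: list[SelectionRound] = field(default_factory=list)
    eliminated: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [r.selected for r in self.rounds]


def normalize_matrix(raw: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-normalization (X - X_mean) / X_STD across conditions.

    Missing values are mean-imputed per column first (logged); constant
    columns map to all-zero rather than dividing by zero.
    """
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 condition rows to normalize")
    X = raw.copy().astype(float)
    n_missing = int(X.isna().sum().sum())
    if n_missing:
        logger.warning("mean-imputing %d missing fingerprint entries", n_missing)
        X = X.fillna(X.mean())
        X = X.fillna(0.0)  # columns missing everywhere
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mu).div(sd.replace(0.0, np.inf), axis=1)
    return Z


def _gap_cut(Z: np.ndarray, n_rows: int, min_clusters: int, max_clusters: int | None) -> int:
    """Number of flat clusters chosen at the largest *relative* gap between
    successive merge heights.

    The relative gap h_m / h_{m-1} is scale-free, so tight within-cluster
    merges followed by a first between-cluster merge produce a sharp
    maximum at the natural cut regardless of the matrix's overall scale.
    Near-zero lower heights are floored at a small fraction of the tallest
    merge so duplicated rows do not force a maximal cut.
    """
    heights = Z[:, 2]
    max_clusters = max_clusters if max_clusters is not None else n_rows
    floor = 1e-3 * max(heights[-1], 1e-300)
    best_k, best_score = min(max(min_clusters, 2), n_rows), -1.0
    # Cutting between merge m-1 and merge m leaves n_rows - m clusters.
    for m in range(1, len(heights)):
        k = n_rows - m
        if not (min_clusters <= k <= max_clusters):
            continue
        score = heights[m] / max(heights[m - 1], floor)
        if score > best_score:
            best_score, best_k = score, k
    return best_k


def cluster_fingerprints(
    M: pd.DataFrame,
    reference_rows: list[str],
    method: str = "ward",
    n_clusters: int | None = None,
    min_clusters: int = 2,
    max_clusters: int | None = None,
) -> ClusterTree:
    """Agglomerative clustering of normalized fingerprints.

    Ward linkage on Euclidean distances by default; the flat cut uses the
    largest gap between successive merge heights unless ``n_clusters`` is
    given. The reference cluster is the one holding the (majority of the)
    ``reference_rows``.
    """
    labels = list(M.index)
    if len(labels) == 1:
        return ClusterTree(np.empty((0, 4)), labels, np.array([1]), 1, M)
    Z = hierarchy.linkage(M.values, method=method)
    if n_clusters is None:
        n_clusters = _gap_cut(Z, len(labels), min_clusters, max_clusters)
    assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    ref_idx = [labels.index(r) for r in reference_rows if r in labels]
    if not ref_idx:
        raise ValueError("no reference rows present in the matrix")
    ref_assign = assign[ref_idx]
    vals, counts = np.unique(ref_assign, return_counts=True)
    ref_cluster = int(vals[np.argmax(counts)])
    if len(vals) > 1:
        logger.warning(
            "reference rows split across clusters %s; using majority cluster %d",
            vals.tolist(), ref_cluster,
        )
    return ClusterTree(Z, labels, assign, ref_cluster, M)


def distance_to_reference(row: str | np.ndarray, tree: ClusterTree) -> float:
    """Euclidean distance from a row (name or vector) to the reference
    cluster centroid."""
    vec = tree.X.loc[row].values if isinstance(row, str) else np.asarray(row)
    return float(np.linalg.norm(vec - tree.centroid(tree.reference_cluster)))


def cluster_quality(
    M: pd.DataFrame, wt_rows: list[str], mut_rows: list[str]
) -> tuple[float, float]:
    """(BCD, WCD) cluster-quality metrics.

    BCD -- Euclidean distance between wild-type and mutant centroids (the
    larger the better); WCD -- mean distance of wild-type rows to their own
    centroid (the smaller the better).
    """
    if len(wt_rows) < 2:
        raise ValueError("WCD undefined with fewer than 2 wild-type rows")
    if len(mut_rows) < 2:
        raise ValueError("need at least 2 mutant rows")
    W = M.loc[wt_rows].values
    U = M.loc[mut_rows].values
    bcd = float(np.linalg.norm(W.mean(axis=0) - U.mean(axis=0)))
    wcd = float(np.mean(np.linalg.norm(W - W.mean(axis=0), axis=1)))
    return bcd, wcd


def select_polytherapy(
    M: pd.DataFrame,
    reference_rows: list[str],
    compound_rows: list[str],
    context_rows: list[str] | None = None,
    n_rounds: int = 3,
    **cluster_kwargs,
) -> SelectionResult:
    """Iterative cluster-elimination selection of complementary compounds.

    Each round reclusters the remaining compound rows together with the
    fixed reference (and optional context) rows, finds the non-reference
    cluster whose centroid is nearest the reference centroid, selects the
    compound row in it closest to the reference centroid, and eliminates
    the cluster's compound rows. Reference and context rows are never
    selectable. Ties break lexicographically, so the result is
    deterministic and invariant to row order.
    """
    context_rows = context_rows or []
    remaining = sorted(compound_rows)
    result = SelectionResult()
    for _ in range(n_rounds):
        if not remaining:
            logger.warning("compound clusters exhausted after %d rounds", len(result.rounds))
            break
        rows = sorted(set(reference_rows) | set(context_rows)) + remaining
        sub = M.loc[rows]
        tree = cluster_fingerprints(sub, reference_rows, **cluster_kwargs)
        ref_centroid = tree.centroid(tree.reference_cluster)
        candidates = []
        for cid in tree.cluster_ids:
            if cid == tree.reference_cluster:
                continue
            members = tree.members(int(cid))
            selectable = sorted(m for m in members if m in remaining)
            if not selectable:
                continue
            d = float(np.linalg.norm(tree.centroid(int(cid)) - ref_centroid))
            candidates.append((d, int(cid), members, selectable))
        if not candidates:
            logger.warning("no selectable cluster left after %d rounds", len(result.rounds))
            break
        candidates.sort(key=lambda c: (c[0], c[3][0]))
        d_cluster, cid, members, selectable = candidates[0]
        dists = {m: float(np.linalg.norm(sub.loc[m].values - ref_centroid)) for m in selectable}
        best = min(selectable, key=lambda m: (dists[m], m))
        result.rounds.append(
            SelectionRound(
                selected=best,
                cluster_members=members,
                cluster_distance=d_cluster,
                compound_distance=dists[best],
            )
        )
        eliminated = [m for m in members if m in remaining]
        result.eliminated.extend(eliminated)
        remaining = [m for m in remaining if m not in eliminated]
    return result
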