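"""Multi-measure gene analyses: Z-scoring, correlation-distance clustering, set overlaps.

Gene score matrices (rows = genes, columns = measures such as GTS, LOEUF,
lnGDI, rare-variant count, HIPred, P(HI)) are Z-scored per measure, row
centred without scaling, and clustered by complete linkage of correlation
distances ``d = 1 - Pearson r`` between gene rows.  Linkage is agglomerative
with a deterministic lowest-index tie-break; a scipy-compatible linkage
matrix is produced so dendrograms and flat cuts behave as usual.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each measure column (sample sd), then centre rows without scaling.

    Zero-variance measures are dropped with a warning; missing values are
    ignored in the statistics and preserved in the output.
    """
    out = matrix.astype(float).copy()
    drop = []
    for col in out.columns:
        v = out[col]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            drop.append(col)
            continue
        out[col] = (v - v.mean()) / sd
    if drop:
        logger.warning("dropping zero-variance measures: %s", drop)
        out = out.drop(columns=drop)
    return out.sub(out.mean(axis=1), axis=0)


def correlation_distance_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise ``1 - Pearson r`` between gene rows, pairwise-complete over missing values."""
    corr = matrix.T.corr(min_periods=2).to_numpy()
    d = 1.0 - corr
    if np.isnan(d).any():
        logger.warning("gene pairs with <2 shared measures; distance set to 1.0")
        d = np.where(np.isnan(d), 1.0, d)
    np.fill_diagonal(d, 0.0)
    return d


def complete_linkage(dist: np.ndarray) -> np.ndarray:
    """Agglomerative complete linkage; ties broken by the lowest-index pair.

    Returns a scipy-style linkage matrix: each row ``[a, b, height, size]``
    merges clusters a and b (original genes are 0..n-1, merged clusters get
    ids n, n+1, ...).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    # cluster-to-cluster complete-linkage distances, keyed by sorted pair
    d = {
        (i, j): float(dist[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai, a in enumerate(ids):
            for b in ids[ai + 1 :]:
                dd = d[(a, b)]
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, a, b)
        dd, a, b = best
        members = active.pop(a) + active.pop(b)
        for c in active:
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d[(min(next_id, c), max(next_id, c))] = max(d[key_a], d[key_b])
        active[next_id] = members
        Z[step] = [a, b, dd, len(members)]
        next_id += 1
    return Z


def flat_clusters(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    """Cut a linkage matrix into ``n_clusters`` flat clusters (labels 0..k-1)."""
    n = Z.shape[0] + 1
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    for a, b, _, _ in Z[: n - n_clusters]:
        members[next_id] = members.pop(int(a)) + members.pop(int(b))
        next_id += 1
    labels = np.zeros(n, dtype=int)
    for k, (_, mem) in enumerate(sorted(members.items())):
        labels[mem] = k
    return labels


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Dendrogram as a Newick string with merge heights as branch spans."""
    n = Z.shape[0] + 1
    node = {i: (names[i], 0.0) for i in range(n)}
    for step, (a, b, h, _) in enumerate(Z):
        (sa, ha), (sb, hb) = node.pop(int(a)), node.pop(int(b))
        node[n + step] = (f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", h)
    (tree, _), = node.values()
    return tree + ";"


def cluster_genes(
    matrix: pd.DataFrame, n_clusters: int = 20, standardize: bool = True
) -> pd.DataFrame:
    """Cluster genes over their measure profiles; returns assignments.

    Pipeline: optional Z-score + row centring, correlation distances,
    complete linkage, flat cut into ``n_clusters``.  Genes with fewer than
    2 non-missing measures are excluded with a log message.

    Returns a DataFrame (gene, cluster) in input order; the linkage matrix
    and gene names are attached as ``.attrs['linkage']`` / ``.attrs['genes']``.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 genes to cluster")
    enough = matrix.notna().sum(axis=1) >= 2
    if not enough.all():
        logger.info("excluding %d genes with <2 non-missing measures", (~enough).sum())
    data = matrix.loc[enough]
    if standardize:
        data = zscore(data)
    D = correlation_distance_matrix(data)
    Z = complete_linkage(D)
    labels = flat_clusters(Z, min(n_clusters, len(data)))
    out = pd.DataFrame({"gene": data.index, "cluster": labels})
    out.attrs["linkage"] = Z
    out.attrs["genes"] = list(data.index)
    return out


def set_overlap(setA, setB, setC) -> dict[str, int]:
    """Counts of the seven regions of a three-set Venn diagram."""
    A, B, C = set(setA), set(setB), set(setC)
    return {
        "A_only": len(A - B - C),
        "B_only": len(B - A - C),
        "C_only": len(C - A - B),
        "AB": len((A & B) - C),
        "AC": len((A & C) - B),
        "BC": len((B & C) - A),
        "ABC": len(A & B & C),
    }
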