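"""Multi-layer integration: ECDF percentiles, k-means, set enrichment.

The union of non-additive genes across the three layers is described by a
triplet of within-layer ECDF percentiles (mRNA abundance, m6A level, TE)
and grouped by Euclidean k-means. Per-cluster gene-set enrichment uses a
hypergeometric upper tail with a min-p permutation family correction.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

import logging

logger = logging.getLogger("trilayer")


def ecdf_percentile(values: pd.Series) -> pd.Series:
    """Empirical-CDF percentile of each value within its layer.

    ``pct(g) = #(values <= value(g)) / N``; ties share the upper value;
    missing values (e.g. no m6A peak) are set to 0 before transforming.
    """
    v = values.fillna(0.0)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    arr = v.to_numpy(dtype=float)
    if np.allclose(arr, arr[0]):
        logger.warning("ecdf_percentile: all values identical; percentiles all 1.0")
    order = np.sort(arr)
    pct = np.searchsorted(order, arr, side="right") / len(arr)
    return pd.Series(pct, index=v.index)


def percentile_triplets(
    mrna: pd.Series, m6a: pd.Series, te: pd.Series, genes: Sequence[str]
) -> pd.DataFrame:
    """ECDF percentiles of the three layers restricted to ``genes``.

    Each layer is transformed over the supplied gene set; genes lacking a
    layer value enter at 0 (unmodified genes sit at the low end rather than
    being dropped).
    """
    idx = pd.Index(genes)
    out = pd.DataFrame(
        {
            "pct_mrna": ecdf_percentile(mrna.reindex(idx)),
            "pct_m6a": ecdf_percentile(m6a.reindex(idx)),
            "pct_te": ecdf_percentile(te.reindex(idx)),
        },
        index=idx,
    )
    out.index.name = "gene_id"
    return out


def kmeans_cluster(
    triplets: pd.DataFrame, k: int, seed: int, restarts: int = 100
) -> tuple[pd.Series, np.ndarray]:
    """Euclidean k-means on the percentile triplets.

    k-means++ initialization, best of ``restarts`` runs by within-cluster
    sum of squares, deterministic given ``seed``. Cluster labels are 1..k,
    renumbered by decreasing cluster size (ties by original label).

    Returns (assignments, centers) with centers ordered by the new labels.
    """
    if k > len(triplets):
        raise ValueError(f"k={k} exceeds number of genes ({len(triplets)})")
    X = triplets.to_numpy(dtype=float)
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = pd.Series(remap[raw], index=triplets.index, name="cluster")
    centers = km.cluster_centers_[order]
    return labels, centers


def set_enrichment(
    cluster_genes: set[str],
    annotation: Mapping[str, set[str]],
    universe: set[str],
    n_perm: int = 1000,
    seed: int = 17,
    sig_level: float = 0.001,
) -> pd.DataFrame:
    """Hypergeometric enrichment with min-p permutation family correction.

    For each annotation set, ``p_raw`` is the hypergeometric upper tail of
    the overlap with ``cluster_genes`` in ``universe``. The corrected
    p-value is the fraction of ``n_perm`` random same-size draws from the
    universe whose *minimum* p_raw over all sets is <= the observed p_raw.
    Sets with no universe overlap are skipped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cluster = set(cluster_genes) & universe
    if cluster - set(cluster_genes):
        raise ValueError("cluster_genes must be a subset of universe")
    uni = sorted(universe)
    uni_idx = {g: i for i, g in enumerate(uni)}
    N, m = len(uni), len(cluster)
    sets = {
        sid: np.array(sorted(uni_idx[g] for g in genes if g in uni_idx), dtype=int)
        for sid, genes in annotation.items()
    }
    sets = {sid: idx for sid, idx in sets.items() if idx.size > 0}
    if not sets or m == 0:
        return pd.DataFrame(
            columns=["overlap", "set_size", "p_raw", "p_adj_perm", "significant"]
        )

    member = np.zeros(N, dtype=bool)
    member[[uni_idx[g] for g in cluster]] = True

    def raw_p(mask: np.ndarray) -> dict[str, tuple[int, float]]:
        out = {}
        for sid, idx in sets.items():
            k = int(mask[idx].sum())
            K = idx.size
            out[sid] = (k, float(stats.hypergeom.sf(k - 1, N, K, m)))
        return out

    observed = raw_p(member)
    rng = np.random.default_rng(seed)
    min_ps = np.empty(n_perm)
    mask = np.zeros(N, dtype=bool)
    for b in range(n_perm):
        mask[:] = False
        mask[rng.choice(N, size=m, replace=False)] = True
        min_ps[b] = min(p for _, p in raw_p(mask).values())

    rows = []
    for sid, (k, p) in observed.items():
        p_adj = float(np.mean(min_ps <= p))
        rows.append(
            {
                "set_id": sid,
                "overlap": k,
                "set_size": int(sets[sid].size),
                "p_raw": p,
                "p_adj_perm": p_adj,
                "significant": p_adj < sig_level,
            }
        )
    return pd.DataFrame(rows).set_index("set_id").sort_values("p_raw")


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (set_id, gene_id) -> mapping of gene sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"annotation {path}: need two columns (set_id, gene_id)")
    sid, gid = df.columns[:2]
    out: dict[str, set[str]] = {}
    for s, g in zip(df[sid], df[gid]):
        out.setdefault(s, set()).add(g)
    return out
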