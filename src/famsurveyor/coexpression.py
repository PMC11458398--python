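"""Expression filtering, pattern classes, k-means profiles, WGCNA-style
soft thresholding, topological-overlap networks, hub ranking and
hypergeometric enrichment.

The co-expression stage mixes node types — family genes, pathway enzyme
genes and metabolites — in one correlation matrix after per-feature
z-scaling.  Adjacency is |Pearson r|^beta (unsigned, soft threshold), the
topological overlap of two nodes adds their shared-neighbor similarity to
the direct adjacency, and edges with TOM above a weight cutoff (0.3 by
default) form the reported network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkEdge",
    "filter_expressed",
    "classify_patterns",
    "tissue_specificity_tau",
    "kmeans_profiles",
    "scale_free_fit",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_matrix",
    "tom_network",
    "hub_rank",
    "enrich",
]


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str  # canonical order node_a < node_b
    node_b: str
    weight: float  # TOM value in [0, 1]


def filter_expressed(
    matrix: pd.DataFrame, min_value: float = 1.0
) -> tuple[pd.DataFrame, list[str]]:
    """Keep features with at least one sample at or above ``min_value``
    (the "below 1 everywhere" exclusion rule); returns (kept, excluded)."""
    keep = (matrix >= min_value).any(axis=1)
    excluded = list(matrix.index[~keep])
    kept = matrix.loc[keep]
    if kept.empty:
        logger.warning("no feature passed the expression filter")
    return kept, excluded


def tissue_specificity_tau(values: np.ndarray) -> float:
    """Tau specificity index on log2(x+1)-scaled, max-normalized profiles:
    0 for a flat profile, 1 for single-sample expression."""
    x = np.log2(np.asarray(values, dtype=float) + 1.0)
    m = x.max()
    if m <= 0:
        return math.nan
    xhat = x / m
    return float((1.0 - xhat).sum() / (len(x) - 1))


def classify_patterns(
    matrix: pd.DataFrame, tau_threshold: float = 0.8, low_max: float = 1.0
) -> pd.DataFrame:
    """Classify each feature as not_detected (all zero), low (max below
    ``low_max``), tissue_specific (tau >= threshold) or broad."""
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    classes, taus = [], []
    for _, row in matrix.iterrows():
        v = row.to_numpy(dtype=float)
        tau = tissue_specificity_tau(v)
        taus.append(tau)
        if v.max() == 0:
            classes.append("not_detected")
        elif v.max() < low_max:
            classes.append("low")
        elif tau >= tau_threshold:
            classes.append("tissue_specific")
        else:
            classes.append("broad")
    return pd.DataFrame({"pattern": classes, "tau": taus}, index=matrix.index)


def kmeans_profiles(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[pd.Series, np.ndarray]:
    """K-means clustering of expression profiles (k-means++ greedy seeding
    plus Lloyd iterations, via scikit-learn), on row-z-scored profiles by
    default.  Deterministic for a fixed seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds feature count {matrix.shape[0]}")
    X = matrix.to_numpy(dtype=float)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                tol=1e-8, random_state=seed)
    labels = km.fit_predict(X)
    return pd.Series(labels, index=matrix.index, name="cluster"), km.cluster_centers_


# ---------------------------------------------------------------------------
# Soft threshold and TOM

def adjacency_matrix(matrix: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta between features
    (rows); constant rows are dropped with a warning."""
    X = matrix.to_numpy(dtype=float)
    keep = X.std(axis=1) > 0
    if not keep.all():
        logger.warning("dropping %d constant feature(s)", int((~keep).sum()))
    sub = matrix.loc[keep]
    cor = np.corrcoef(sub.to_numpy(dtype=float))
    a = np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=sub.index, columns=sub.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit index from a connectivity vector.

    Connectivity values are binned, log10 frequency is regressed on log10
    mean connectivity per bin, and the squared correlation is signed by
    the negative of the slope (WGCNA convention: positive only for a
    decreasing degree distribution).  Returns (signed R^2, slope).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3:
        return math.nan, math.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return math.nan, math.nan
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r * r), float(slope)


def pick_soft_threshold(
    matrix: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power beta.

    For each candidate power the scale-free fit R^2 and mean connectivity
    are tabulated; beta is the smallest power whose signed R^2 reaches the
    target, else the argmax-R^2 power (flagged in the table).
    """
    if matrix.shape[1] < 8:
        logger.warning("fewer than 8 samples: soft-threshold fit is unstable")
    rows = []
    for p in powers:
        a = adjacency_matrix(matrix, beta=p).to_numpy()
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": p, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2"] >= r2_target]
    if not ok.empty:
        beta = int(ok.iloc[0]["power"])
        table.attrs["reached_target"] = True
    else:
        beta = int(table.loc[table["r2"].idxmax(), "power"])
        table.attrs["reached_target"] = False
        logger.warning("no power reached R2 target %.2f; using argmax beta=%d", r2_target, beta)
    return beta, table


def tom_matrix(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    With fewer than three nodes the overlap degenerates to the adjacency.
    """
    a = adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    if n < 3:
        t = a.copy()
        np.fill_diagonal(t, 1.0)
        return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)
    k = a.sum(axis=1)
    # diag(a) = 0, so (a @ a)_ij already equals sum over u != i, j
    num = a @ a + a
    den = np.minimum(k[:, None], k[None, :]) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


def tom_network(
    matrix: pd.DataFrame, beta: float, min_weight: float = 0.3
) -> list[NetworkEdge]:
    """TOM edges above ``min_weight`` from an expression matrix."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = adjacency_matrix(matrix, beta=beta)
    t = tom_matrix(a)
    ids = list(t.index)
    tv = t.to_numpy()
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if tv[i, j] > min_weight:
                x, y = sorted((ids[i], ids[j]))
                edges.append(NetworkEdge(x, y, float(tv[i, j])))
    return edges


def hub_rank(
    edges: Sequence[NetworkEdge], node_types: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Degree table of the thresholded network, sorted by degree then id;
    includes per-node type when given."""
    if not edges:
        raise ValueError("empty edge list")
    deg: dict[str, int] = {}
    for e in edges:
        deg[e.node_a] = deg.get(e.node_a, 0) + 1
        deg[e.node_b] = deg.get(e.node_b, 0) + 1
    df = pd.DataFrame(
        {"node": list(deg), "degree": list(deg.values())}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    if node_types is not None:
        df["type"] = df["node"].map(lambda n: node_types.get(n, "unknown"))
    return df


# ---------------------------------------------------------------------------
# Enrichment

def enrich(
    query: Iterable[str],
    annotation: Mapping[str, set[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric (upper-tail) term enrichment with BH correction.

    For a term with K members in a universe of N, a query of n with k hits
    gets p = P(X >= k), X ~ Hypergeom(N, K, n).  Output sorted by p.
    """
    if not annotation:
        raise ValueError("empty annotation")
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    terms: dict[str, set[str]] = {}
    for feat, ts in annotation.items():
        if feat in universe:
            for t in ts:
                terms.setdefault(t, set()).add(feat)
    rows = []
    for term, members in sorted(terms.items()):
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "term"], ignore_index=True)
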