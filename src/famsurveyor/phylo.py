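"""Distance-based phylogenetics and subfamily analysis.

Pipeline: protein distances from the domain alignment (p-distance with a
Poisson or Kimura correction, pairwise or complete gap deletion), a
neighbor-joining tree (Saitou–Nei Q criterion, deterministic tie-breaks),
non-parametric bootstrap supports mapped onto the full-data tree, subfamily
assignment by reference-anchored clades, subfamily-size variability
statistics, and Wagner (linear-cost) parsimony for per-branch family-size
expansion and contraction on a species tree.

Trees are dendropy objects throughout; newick I/O is dendropy's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .align import MultipleAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "nj_tree",
    "bootstrap_support",
    "assign_subfamilies",
    "size_variability",
    "parsimony_gain_loss",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal; substitutions/site

    def __post_init__(self):
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("shape mismatch")


def _msa_arrays(msa: MultipleAlignment) -> tuple[list[str], np.ndarray, np.ndarray]:
    ids = list(msa.rows)
    arr = np.array([list(msa.rows[i]) for i in ids])
    codes = arr.view(np.uint32).reshape(arr.shape)  # unicode code points
    gaps = arr == "-"
    return ids, codes, gaps


def protein_distance(
    msa: MultipleAlignment,
    model: str = "kimura",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise evolutionary distances from a protein alignment.

    models: ``p`` (raw proportion of differences), ``poisson``
    (d = -ln(1-p)) and ``kimura`` (d = -ln(1 - p - p^2/5)).  ``pairwise``
    deletion drops, per pair, only the columns gapped in that pair;
    ``complete`` drops every column containing any gap.  Saturated pairs
    (correction argument <= 0) get ``inf``.
    """
    ids, codes, gaps = _msa_arrays(msa)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 rows")
    if deletion == "complete":
        keep = ~gaps.any(axis=0)
        codes, gaps = codes[:, keep], gaps[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode: {deletion}")
    valid = ~gaps
    shared = valid.astype(np.int64) @ valid.T.astype(np.int64)
    diff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        neq = (codes[i][None, :] != codes) & valid[i][None, :] & valid
        diff[i] = neq.sum(axis=1)
    offdiag = ~np.eye(n, dtype=bool)
    if (shared[offdiag] == 0).any():
        i, j = np.argwhere((shared == 0) & offdiag)[0]
        raise ValueError(f"no shared ungapped columns for pair ({ids[i]}, {ids[j]})")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, diff / np.maximum(shared, 1), 0.0)
        if model == "p":
            d = p
        elif model == "poisson":
            arg = 1.0 - p
            d = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)), np.inf)
        elif model == "kimura":
            arg = 1.0 - p - p * p / 5.0
            d = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)), np.inf)
        else:
            raise ValueError(f"unknown model: {model}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Q-criterion joins with ties broken by the lexicographically smallest
    pair of cluster representatives (the smallest leaf label in each
    cluster); negative branch lengths are clamped to zero with a warning.
    Returns an unrooted tree stored with a trifurcating seed node.
    """
    n0 = len(D.ids)
    if n0 < 2:
        raise ValueError("need >= 2 taxa")
    if not np.isfinite(D.d).all():
        raise ValueError("non-finite distances (saturated pair?)")
    tns = dendropy.TaxonNamespace(D.ids)
    tree = dendropy.Tree(taxon_namespace=tns)

    nodes: list[dendropy.Node] = []
    reps: list[str] = []
    for label in D.ids:
        nd = dendropy.Node(taxon=tns.get_taxon(label))
        nodes.append(nd)
        reps.append(label)
    d = D.d.astype(float).copy()
    active = list(range(n0))

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [
            (min(reps[active[i]], reps[active[j]]), max(reps[active[i]], reps[active[j]]), i, j)
            for i, j in zip(*np.nonzero(np.isclose(Q, qmin, rtol=0, atol=1e-12)))
            if i < j
        ]
        _, _, ii, jj = min(cands)
        a, b = active[ii], active[jj]
        dij = d[a, b]
        la = dij / 2 + (R[ii] - R[jj]) / (2 * (r - 2))
        lb = dij - la
        parent = dendropy.Node()
        na, nb = nodes[a], nodes[b]
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = clamp(la)
        nb.edge.length = clamp(lb)
        # new distances
        new_idx = len(nodes)
        nodes.append(parent)
        reps.append(min(reps[a], reps[b]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (a, b):
                continue
            d[new_idx, k] = d[k, new_idx] = (d[a, k] + d[b, k] - dij) / 2
        active = [k for k in active if k not in (a, b)] + [new_idx]

    seed = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        la = (d[a, b] + d[a, c] - d[b, c]) / 2
        lb = (d[a, b] + d[b, c] - d[a, c]) / 2
        lc = (d[a, c] + d[b, c] - d[a, b]) / 2
        for idx, ln in zip((a, b, c), (la, lb, lc)):
            seed.add_child(nodes[idx])
            nodes[idx].edge.length = clamp(ln)
    else:  # two clusters remain
        a, b = active
        seed.add_child(nodes[a]); seed.add_child(nodes[b])
        nodes[a].edge.length = clamp(d[a, b] / 2)
        nodes[b].edge.length = clamp(d[a, b] / 2)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> dict[int, frozenset[str]]:
    """Internal-edge bipartitions as canonical leaf-label sets.

    The canonical side is the one not containing the alphabetically first
    leaf, so representations agree across trees on the same taxa.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = labels[0]
    full = frozenset(labels)
    out: dict[int, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        canon = below if anchor not in below else full - below
        if 1 < len(canon) < len(full) - 1:
            out[id(node)] = canon
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 1000,
    seed: int = 0,
    model: str = "kimura",
    deletion: str = "pairwise",
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each bipartition of the full-data tree is the percentage of
    replicate trees containing it (stored as ``node.label`` and
    ``node.support``, MEGA-style mapping onto the point-estimate tree).
    """
    point = nj_tree(protein_distance(msa, model=model, deletion=deletion))
    biparts = _bipartitions(point)
    counts = {bp: 0 for bp in biparts.values()}
    rng = np.random.default_rng(seed)
    ids = list(msa.rows)
    arr = np.array([list(msa.rows[i]) for i in ids])
    L = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = MultipleAlignment({i: "".join(row) for i, row in zip(ids, arr[:, cols])})
        try:
            rep_tree = nj_tree(protein_distance(rep, model=model, deletion=deletion))
        except ValueError:
            continue  # saturated or empty-overlap replicate
        rep_bp = set(_bipartitions(rep_tree).values())
        for bp in counts:
            if bp in rep_bp:
                counts[bp] += 1
    for node in point.preorder_node_iter():
        bp = biparts.get(id(node))
        if bp is not None:
            support = 100.0 * counts[bp] / n_replicates
            node.support = support
            node.label = f"{support:.0f}"
    return point


# ---------------------------------------------------------------------------
# Subfamilies

def assign_subfamilies(
    tree: dendropy.Tree, reference_labels: Mapping[str, str]
) -> dict[str, str]:
    """Label each unlabeled leaf by the majority reference label in the
    smallest clade containing it and at least one reference leaf; label
    ties yield "orphan" (logged)."""
    if not reference_labels:
        raise ValueError("need >= 1 labeled reference leaf")
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(reference_labels) - leaf_names
    if missing:
        raise KeyError(f"reference ids not in tree: {sorted(missing)}")
    out: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference_labels:
            continue
        node = leaf
        labels: list[str] = []
        while node is not None:
            labels = [
                reference_labels[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon.label in reference_labels
            ]
            if labels:
                break
            node = node.parent_node
        if not labels:
            out[name] = "orphan"
            continue
        counts = pd.Series(labels).value_counts()
        top = counts[counts == counts.iloc[0]]
        if len(top) > 1:
            logger.info("subfamily tie for %s (%s): orphan", name, list(top.index))
            out[name] = "orphan"
        else:
            out[name] = str(top.index[0])
    return out


def size_variability(counts: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Subfamily-size variability across species.

    ``counts``: species x subfamily integer matrix.  Returns the
    per-subfamily coefficient of variation (sample SD / mean x 100, in %),
    and the Pearson correlation (with two-sided p) between per-subfamily SD
    and mean — the larger-families-vary-more statistic.
    """
    if counts.shape[1] < 3 or counts.shape[0] < 2:
        raise ValueError("need >= 3 subfamilies and >= 2 species")
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    cv = sd / mean.replace(0, np.nan) * 100.0
    if sd.nunique() == 1 or mean.nunique() == 1:
        logger.warning("zero-variance SD or mean vector: correlation undefined")
        return cv, math.nan, math.nan
    r, p = stats.pearsonr(sd, mean)
    return cv, float(r), float(p)


# ---------------------------------------------------------------------------
# Wagner parsimony gain/loss

def parsimony_gain_loss(
    species_tree: dendropy.Tree, counts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear-cost (Wagner) parsimony of family sizes on a species tree.

    Sankoff dynamic programming over ancestral integer states 0..max(count)
    with cost |i - j| per branch; ties resolved toward minimal total change
    and then the smaller ancestral count.  Returns per-branch deltas
    (child state - parent state) for every subfamily, and per-species
    expansion/contraction tallies over terminal branches.
    """
    leaves = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    if leaves != set(counts.index):
        raise ValueError(
            f"species tree leaves {sorted(leaves)} != count rows {sorted(counts.index)}"
        )
    deltas: dict[str, dict[str, int]] = {}
    post = list(species_tree.postorder_node_iter())
    for sub in counts.columns:
        smax = int(counts[sub].max())
        states = np.arange(smax + 1)
        cost: dict[int, np.ndarray] = {}
        for node in post:
            if node.is_leaf():
                c = np.full(smax + 1, np.inf)
                c[int(counts.loc[node.taxon.label, sub])] = 0.0
            else:
                c = np.zeros(smax + 1)
                for child in node.child_nodes():
                    trans = np.abs(states[:, None] - states[None, :])  # parent x child
                    c = c + (trans + cost[id(child)][None, :]).min(axis=1)
            cost[id(node)] = c
        # backtrack, preferring smaller states on ties
        assign: dict[int, int] = {}
        root = species_tree.seed_node
        assign[id(root)] = int(np.argmin(cost[id(root)]))
        for node in species_tree.preorder_node_iter():
            if node is root:
                continue
            s_par = assign[id(node.parent_node)]
            totals = cost[id(node)] + np.abs(states - s_par)
            assign[id(node)] = int(np.argmin(totals))
        col = {}
        for node in species_tree.preorder_node_iter():
            if node is root:
                continue
            name = node.taxon.label if node.is_leaf() else f"node{_node_index(post, node)}"
            col[name] = assign[id(node)] - assign[id(node.parent_node)]
        deltas[sub] = col
    delta_df = pd.DataFrame(deltas).fillna(0).astype(int)
    tallies = pd.DataFrame(
        {
            "expanded": (delta_df.loc[list(leaves)] > 0).sum(axis=1),
            "contracted": (delta_df.loc[list(leaves)] < 0).sum(axis=1),
        }
    )
    return delta_df, tallies


def _node_index(post_order: list, node) -> int:
    for i, nd in enumerate(post_order):
        if nd is node:
            return i
    return -1
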