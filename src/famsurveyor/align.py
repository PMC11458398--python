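"""Family domain alignment and per-column conservation.

A small progressive aligner (pairwise Gotoh + UPGMA guide tree + profile
merging) builds the multiple alignment of the ~60-residue family domains;
column statistics then give the conservation ratio (modal non-gap residue
frequency) and a normalized Shannon entropy, from which conserved and
highly conserved sites are called.

Entropy is normalized by ln 20 so that an invariant column scores 0 and a
column uniform over the twenty amino acids scores 1; an un-normalized
(raw nats) mode is available.  Gaps are excluded from the frequency
vectors, the usual sequence-logo convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MultipleAlignment",
    "ColumnProfile",
    "pairwise_global_align",
    "progressive_align",
    "column_stats",
    "conserved_sites",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in AA_ORDER."""
    b = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, c in enumerate(AA_ORDER):
            m[i, j] = b[a][c]
    return m


@dataclass
class MultipleAlignment:
    rows: dict[str, str]  # id -> gapped sequence

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")

    def to_array(self) -> np.ndarray:
        ids = list(self.rows)
        return np.array([list(self.rows[i]) for i in ids])


# ---------------------------------------------------------------------------
# Pairwise global alignment (Gotoh affine)

def pairwise_global_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[tuple[str, str], float]:
    """Optimal global alignment with affine gaps (first gap residue costs
    ``gap_open``, each further residue ``gap_extend``).

    Traceback ties are resolved by preferring diagonal over up (gap in
    ``b``) over left (gap in ``a``), making the reported alignment
    deterministic.  Returns ``((gapped_a, gapped_b), score)``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = blosum62_matrix()
    n, m = len(a), len(b)
    ai = np.array([_AA_INDEX[c] for c in a])
    bi = np.array([_AA_INDEX[c] for c in b])
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a; "up")
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b; "left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        srow = matrix[ai[i - 1]]
        for j in range(1, m + 1):
            s = srow[bi[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                           Iy[i - 1, j] + gap_open)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend,
                           Ix[i, j - 1] + gap_open)
    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback, preference diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    if M[n, m] >= max(Ix[n, m], Iy[n, m]):
        state = "M"
    elif Ix[n, m] >= Iy[n, m]:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            s = matrix[ai[i - 1], bi[j - 1]]
            prev = M[i, j] - s
            out_a.append(a[i - 1]); out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif Ix[i, j] == prev:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1]); out_b.append("-")
            cur = Ix[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == cur:
                state = "M"
            elif Ix[i, j] + gap_extend == cur:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-"); out_b.append(b[j - 1])
            cur = Iy[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + gap_open == cur:
                state = "M"
            elif Iy[i, j] + gap_extend == cur:
                state = "Y"
            else:
                state = "X"
    return ("".join(reversed(out_a)), "".join(reversed(out_b))), float(score)


# ---------------------------------------------------------------------------
# Progressive multiple alignment

def _profile(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequency profile; gaps contribute nothing."""
    L = len(rows[0])
    p = np.zeros((L, 20))
    for r in rows:
        for k, c in enumerate(r):
            if c != "-":
                p[k, _AA_INDEX[c]] += 1
    return p / len(rows)


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Affine-gap DP between two column-frequency profiles; the column score
    is the expected substitution value under the two frequency vectors."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    n, m = pa.shape[0], pb.shape[0]
    col_score = pa @ matrix @ pb.T  # (n, m)
    NEG = -math.inf
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)  # predecessor state per state
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
        ptr[i, 0, 1] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
        ptr[0, j, 2] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            opts = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(opts))
            M[i, j] = col_score[i - 1, j - 1] + opts[k]
            ptr[i, j, 0] = k
            opts = (M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend, Iy[i - 1, j] + gap_open)
            k = int(np.argmax(opts))
            Ix[i, j] = opts[k]
            ptr[i, j, 1] = k
            opts = (M[i, j - 1] + gap_open, Ix[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            k = int(np.argmax(opts))
            Iy[i, j] = opts[k]
            ptr[i, j, 2] = k
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(finals))
    # walk back collecting column operations
    ops: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[i, j, state]
        if state == 0:
            ops.append("D"); i -= 1; j -= 1
        elif state == 1:
            ops.append("U"); i -= 1
        else:
            ops.append("L"); j -= 1
        state = int(prev)
    ops.reverse()
    new_a = ["" for _ in rows_a]
    new_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for r, row in enumerate(rows_a):
                new_a[r] += row[ia]
            ia += 1
        else:
            for r in range(len(rows_a)):
                new_a[r] += "-"
        if op in ("D", "L"):
            for r, row in enumerate(rows_b):
                new_b[r] += row[ib]
            ib += 1
        else:
            for r in range(len(rows_b)):
                new_b[r] += "-"
    return new_a, new_b


def progressive_align(
    domains: Mapping[str, str],
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Progressive multiple alignment: UPGMA guide tree on pairwise
    alignment-score distances, then profile–profile merging in guide-tree
    order.  Deterministic for a fixed input order; no randomness anywhere.
    """
    ids = list(domains)
    if not ids:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return MultipleAlignment({ids[0]: domains[ids[0]]})
    default_matrix = matrix is None
    if matrix is None:
        matrix = blosum62_matrix()
    n = len(ids)
    self_scores = {}
    for i in ids:
        s = domains[i]
        self_scores[i] = sum(matrix[_AA_INDEX[c], _AA_INDEX[c]] for c in s)
    # guide-tree distances from pairwise alignment scores; with the default
    # matrix the fast C aligner computes the same global affine score as
    # pairwise_global_align (cross-checked in the test suite)
    fast = None
    if default_matrix:
        fast = PairwiseAligner()
        fast.substitution_matrix = substitution_matrices.load("BLOSUM62")
        fast.open_gap_score = gap_open
        fast.extend_gap_score = gap_extend
        fast.mode = "global"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fast is not None:
                sc = float(fast.score(domains[ids[i]], domains[ids[j]]))
            else:
                _, sc = pairwise_global_align(
                    domains[ids[i]], domains[ids[j]], matrix, gap_open, gap_extend
                )
            norm = min(self_scores[ids[i]], self_scores[ids[j]])
            d = 1.0 - sc / norm if norm > 0 else 1.0
            D[i, j] = D[j, i] = max(d, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    # clusters as (ids, gapped rows)
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [domains[ids[i]]]) for i in range(n)
    }
    nxt = n
    for a_idx, b_idx, _, _ in Z:
        ida, rows_a = clusters.pop(int(a_idx))
        idb, rows_b = clusters.pop(int(b_idx))
        new_a, new_b = _align_profiles(rows_a, rows_b, matrix, gap_open, gap_extend)
        clusters[nxt] = (ida + idb, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    return MultipleAlignment(dict(zip(final_ids, final_rows)))


# ---------------------------------------------------------------------------
# Column statistics

@dataclass(frozen=True)
class ColumnProfile:
    index: int  # 1-based column
    modal_residue: str
    ratio: float  # modal non-gap frequency; nan for all-gap columns
    entropy: float  # normalized Shannon entropy in [0, 1]; nan for all-gap
    gap_fraction: float
    flagged: bool  # all-gap or gap fraction > 0.5


def column_stats(msa: MultipleAlignment, normalize_entropy: bool = True) -> list[ColumnProfile]:
    """Per-column modal-residue ratio and Shannon entropy over non-gap
    symbols.  Entropy is divided by ln 20 unless ``normalize_entropy`` is
    False; all-gap columns yield NaN statistics and are flagged."""
    if not msa.rows:
        raise ValueError("empty alignment")
    arr = msa.to_array()
    n_rows, n_cols = arr.shape
    out = []
    for k in range(n_cols):
        col = arr[:, k]
        residues = col[col != "-"]
        gap_fraction = 1.0 - residues.size / n_rows
        if residues.size == 0:
            out.append(ColumnProfile(k + 1, "-", math.nan, math.nan, 1.0, True))
            continue
        vals, counts = np.unique(residues, return_counts=True)
        freqs = counts / residues.size
        modal = int(np.argmax(counts))
        ent = float(-(freqs * np.log(freqs)).sum())
        if normalize_entropy:
            ent /= math.log(20)
        out.append(
            ColumnProfile(
                index=k + 1,
                modal_residue=str(vals[modal]),
                ratio=float(counts[modal] / residues.size),
                entropy=ent,
                gap_fraction=gap_fraction,
                flagged=gap_fraction > 0.5,
            )
        )
    return out


def conserved_sites(
    profiles: Sequence[ColumnProfile],
    ratio_threshold: float = 0.5,
    high_threshold: float = 0.8,
    entropy_threshold: float = 0.6,
) -> tuple[list[str], list[str]]:
    """Conserved sites (ratio > 50% and entropy < 0.6) and highly conserved
    sites (ratio >= 80%), named residue + 1-based column, e.g. 'R17'."""
    conserved, high = [], []
    for p in profiles:
        if math.isnan(p.ratio):
            continue
        name = f"{p.modal_residue}{p.index}"
        if p.ratio > ratio_threshold and p.entropy < entropy_threshold:
            conserved.append(name)
        if p.ratio >= high_threshold:
            high.append(name)
    return conserved, high
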