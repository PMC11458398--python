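"""Interaction-network projection through orthology.

A reference species' protein–protein interaction edge list (e.g. an
Arabidopsis-style table) is projected onto the family under study: family
members are mapped to reference proteins by reciprocal best hits (RBH),
then every reference edge whose endpoints are both hit becomes an edge
between the corresponding members.  Many members may share one reference
ortholog (family expansion), in which case each inherits the edge;
self-edges are never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd
from Bio.Align import PairwiseAligner

from .duplication import _aligner, _self_score

logger = logging.getLogger(__name__)

__all__ = ["OrthologMap", "reciprocal_best_hits", "project_network"]


@dataclass
class OrthologMap:
    """Partial map family member -> (reference protein, normalized score);
    every entry is a mutual best hit."""

    mapping: dict[str, tuple[str, float]]

    def __getitem__(self, member: str) -> str:
        return self.mapping[member][0]

    def __contains__(self, member: str) -> bool:
        return member in self.mapping

    def items(self):
        return self.mapping.items()


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    min_score: float = 0.3,
) -> OrthologMap:
    """RBH ortholog map from ``proteome_a`` members to ``proteome_b``.

    Scores are normalized global alignment scores (score / min self-score).
    A tie for the best hit in either direction drops the pair with a
    warning, keeping the map unambiguous.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    al = _aligner()
    matrix = al.substitution_matrix
    selfs_a = {g: _self_score(s, matrix) for g, s in proteome_a.items()}
    selfs_b = {g: _self_score(s, matrix) for g, s in proteome_b.items()}
    scores: dict[tuple[str, str], float] = {}
    for ga, sa in proteome_a.items():
        for gb, sb in proteome_b.items():
            norm = min(selfs_a[ga], selfs_b[gb])
            if norm <= 0:
                continue
            sc = float(al.score(sa, sb)) / norm
            if sc >= min_score:
                scores[(ga, gb)] = sc

    def best(direction_keys, key_idx):
        out: dict[str, tuple[str, float] | None] = {}
        for (ga, gb), sc in scores.items():
            src = (ga, gb)[key_idx]
            tgt = (ga, gb)[1 - key_idx]
            cur = out.get(src)
            if cur is None or sc > cur[1]:
                out[src] = (tgt, sc)
            elif cur is not None and sc == cur[1] and tgt != cur[0]:
                out[src] = ("", sc)  # tie sentinel
        return out

    best_a = best(scores, 0)
    best_b = best(scores, 1)
    mapping: dict[str, tuple[str, float]] = {}
    for ga, hit in best_a.items():
        if hit is None or hit[0] == "":
            if hit is not None and hit[0] == "":
                logger.warning("best-hit score tie for %s: pair dropped", ga)
            continue
        gb, sc = hit
        back = best_b.get(gb)
        if back is None or back[0] == "":
            if back is not None and back[0] == "":
                logger.warning("best-hit score tie for %s: pair dropped", gb)
            continue
        if back[0] == ga:
            mapping[ga] = (gb, sc)
    return OrthologMap(mapping)


def project_network(
    orthomap: OrthologMap, reference_edges: pd.DataFrame
) -> tuple[nx.Graph, pd.DataFrame]:
    """Project reference edges (columns ``protein_a``, ``protein_b``) onto
    family members.  Every member pair (m1, m2) with orthologs on a
    reference edge inherits it; duplicates collapse; returns the graph and
    a degree table sorted by degree then id."""
    inverse: dict[str, list[str]] = {}
    for member, (ref, _) in orthomap.items():
        inverse.setdefault(ref, []).append(member)
    g = nx.Graph()
    for _, row in reference_edges.iterrows():
        r1, r2 = row["protein_a"], row["protein_b"]
        for m1 in inverse.get(r1, []):
            for m2 in inverse.get(r2, []):
                if m1 != m2:
                    g.add_edge(m1, m2)
    degree = pd.DataFrame(
        {"node": [n for n in g.nodes], "degree": [g.degree[n] for n in g.nodes]}
    ).sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)
    return g, degree
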