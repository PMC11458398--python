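"""Family membership from a proteome: consensus-domain scanning with a
mismatch budget, longest-isoform selection, positional naming and basic
protein properties (molecular weight, isoelectric point).

The identifier is a consensus scan: a family domain is written as an
amino-acid string in which '.' marks positions free to vary, and a protein
is a member when some window matches the consensus with at most
``max_mismatch`` mismatches at the non-wildcard positions (the plant bHLH
convention allows 13).  Membership requires a full-length window — partial
or truncated domains never qualify.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight

from .io import GeneModel, GeneSet, chromosome_sort_key

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "ProteinProperties",
    "scan_consensus",
    "select_longest_isoform",
    "name_by_position",
    "protein_properties",
    "PKA_PROTPARAM",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    window_start: int  # 0-based half-open protein coordinates
    window_end: int
    mismatches: int
    consensus_length: int
    primary: bool = False


def scan_consensus(
    protein: str,
    consensus: str,
    max_mismatch: int,
    gene_id: str = "",
) -> list[DomainHit]:
    """Every full-length window matching ``consensus`` within the budget.

    Wildcard positions ('.') in the consensus never count as mismatches.
    The best hit (fewest mismatches, then leftmost) is flagged primary.
    A protein shorter than the consensus has no hits and is simply not a
    member; that is not an error.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    L, n = len(consensus), len(protein)
    if n < L:
        return []
    informative = np.array([c != "." for c in consensus])
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    prot = np.frombuffer(protein.encode(), dtype=np.uint8)
    # windows x consensus-length comparison, vectorised
    idx = np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]
    mism = ((prot[idx] != cons[None, :]) & informative[None, :]).sum(axis=1)
    keep = np.nonzero(mism <= max_mismatch)[0]
    if keep.size == 0:
        return []
    best = keep[np.argmin(mism[keep])]  # argmin takes the leftmost on ties
    return [
        DomainHit(gene_id, int(s), int(s) + L, int(mism[s]), L, primary=(s == best))
        for s in keep
    ]


def scan_proteome(
    proteins: Mapping[str, str],
    consensus: str,
    max_mismatch: int,
    hmm_hits: Iterable[str] | None = None,
) -> dict[str, list[DomainHit]]:
    """Scan every protein; genes without a hit are excluded from the family.

    ``hmm_hits`` optionally intersects the result with an externally produced
    list of candidate ids (e.g. a profile-HMM search done elsewhere).
    """
    members: dict[str, list[DomainHit]] = {}
    allowed = set(hmm_hits) if hmm_hits is not None else None
    for gid, seq in proteins.items():
        if allowed is not None and gid not in allowed:
            continue
        hits = scan_consensus(seq, consensus, max_mismatch, gene_id=gid)
        if hits:
            members[gid] = hits
    return members


def select_longest_isoform(genes: Iterable[GeneModel]) -> dict[str, str]:
    """One representative protein per gene (longest isoform; ties by
    lexicographically smallest isoform id, logged)."""
    out: dict[str, str] = {}
    for g in genes:
        if not g.isoforms:
            raise ValueError(f"gene {g.gene_id} has no isoforms")
        lengths = {len(iso.protein) for iso in g.isoforms}
        chosen = g.longest_isoform()
        if len(g.isoforms) > len(lengths):
            logger.warning(
                "gene %s: isoform length tie, keeping %s", g.gene_id, chosen.isoform_id
            )
        out[g.gene_id] = chosen.protein
    return out


def name_by_position(
    member_ids: Iterable[str],
    annotation: GeneSet,
    prefix: str = "FAM",
    chromosome_order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assign family names by chromosomal position.

    Genes are ordered by chromosome (configured order, scaffolds last), then
    ascending start; names are ``prefix`` + zero-padded index whose width is
    the decimal width of the family size (167 members -> width 3).
    """
    member_ids = list(member_ids)
    for gid in member_ids:
        if gid not in annotation:
            raise KeyError(f"family member {gid} missing from annotation")
    ordered = sorted(
        member_ids,
        key=lambda gid: (
            chromosome_sort_key(annotation[gid].chromosome, chromosome_order),
            annotation[gid].start,
            gid,
        ),
    )
    width = len(str(len(ordered)))
    return {gid: f"{prefix}{i + 1:0{width}d}" for i, gid in enumerate(ordered)}


# ---------------------------------------------------------------------------
# Protein properties

# ProtParam-convention pKa values (N/C termini and ionizable side chains);
# an alternative table may be passed to protein_properties.
PKA_PROTPARAM: dict[str, float] = {
    "Nterm": 9.094,
    "Cterm": 2.869,
    "K": 10.67,
    "R": 12.10,
    "H": 6.04,
    "D": 3.872,
    "E": 4.412,
    "C": 7.555,
    "Y": 10.85,
}


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    mw: float  # kDa
    pi: float  # pH units


def _net_charge(counts: Mapping[str, int], ph: float, pka: Mapping[str, float]) -> float:
    pos = 10 ** -ph / (10 ** -ph + 10 ** -pka["Nterm"])
    for aa in ("K", "R", "H"):
        pos += counts.get(aa, 0) * 10 ** -ph / (10 ** -ph + 10 ** -pka[aa])
    neg = 10 ** -pka["Cterm"] / (10 ** -ph + 10 ** -pka["Cterm"])
    for aa in ("D", "E", "C", "Y"):
        neg += counts.get(aa, 0) * 10 ** -pka[aa] / (10 ** -ph + 10 ** -pka[aa])
    return pos - neg


def isoelectric_point(
    protein: str,
    pka: Mapping[str, float] = PKA_PROTPARAM,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge by bisection on the Henderson–Hasselbalch
    charge curve, to |charge| < ``tol``.

    The charge is strictly decreasing in pH, so bisection on [0, 14] is
    guaranteed to converge.
    """
    counts = {aa: protein.count(aa) for aa in "KRHDECY"}
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2
        q = _net_charge(counts, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(
    protein: str, pka: Mapping[str, float] = PKA_PROTPARAM
) -> ProteinProperties:
    """Length, average-mass MW in kDa, and isoelectric point.

    MW is the sum of residue average masses minus (n-1) waters — the
    ProtParam convention (delegated to Biopython's average-mass table).
    """
    bad = sorted(set(protein) - STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue(s): {', '.join(bad)}")
    if not protein:
        raise ValueError("empty protein")
    mw_da = molecular_weight(protein, seq_type="protein", monoisotopic=False)
    return ProteinProperties(
        length=len(protein),
        mw=mw_da / 1000.0,
        pi=isoelectric_point(protein, pka=pka),
    )
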