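"""Synthetic genomes, expression matrices and qPCR tables with planted truth.

Every downstream stage of the survey is testable against this generator:
family genes carry a mutated copy of the consensus domain inside random
background protein sequence; duplicate pairs are laid out on the synthetic
chromosomes so that each planted pair satisfies the classifier's definition
of its mode (WGD pairs are anchors of duplicated collinear segments, TD
pairs are rank-adjacent, PD pairs sit within the proximal window, TRD pairs
have exactly one gene inside a collinear-block span, DSD pairs neither);
expression matrices carry planted k-means clusters and co-expression
modules with a designated hub; qPCR tables carry planted per-group fold
changes under the 2^-ddCt model.

A single integer seed determines every output byte.

Layout strategy for duplication planting: collinear segments are assigned
distinct chromosome pairs, and loose pairs (TRD partners, DSD) are spread
over the remaining chromosome pairs with at most ``min_anchors - 1``
anchors per pair of chromosomes — so no spurious collinear chain can ever
reach the block threshold, and the planted blocks are exactly the blocks
the chain finder reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GeneModel, GeneSet, Isoform, write_fasta, write_gff3

__all__ = [
    "SyntheticConfig",
    "TruthTable",
    "GenomeBundle",
    "generate_genome",
    "generate_expression",
    "generate_qpcr",
    "DEFAULT_CONSENSUS",
]

AA = "ACDEFGHIKLMNPQRSTVWY"

# one fixed codon per amino acid: deterministic back-translation
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
# an alternative synonymous codon per amino acid (W/M have none)
ALT_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "TCC", "T": "ACC", "V": "GTC", "Y": "TAC",
}

# invented ~bHLH-like consensus used as the generator default; real runs
# supply their own consensus string ('.' = wildcard position)
DEFAULT_CONSENSUS = "AR.RRRQANARER.RRSKLNDAFAELRRLLPT.PPDKKLSKAETLRLAASYI.HLR"

MODES = ("WGD", "TD", "PD", "TRD", "DSD")


class ConfigError(ValueError):
    """Infeasible or invalid synthetic configuration."""


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 8
    genes_per_chromosome: int = 60
    n_family_genes: int = 140
    consensus: str = DEFAULT_CONSENSUS
    mismatch_rate: float = 0.1
    duplication_plan: dict[str, int] = field(
        default_factory=lambda: {"WGD": 4, "TD": 1, "PD": 3, "TRD": 11, "DSD": 48}
    )
    n_subfamilies: int = 5
    expression_plan: dict = field(
        default_factory=lambda: {
            # pod-stage layout: 6 stages x 3 replicates; noise_sd is in
            # expression units against a latent module amplitude of 3, so
            # 1.8 leaves hub-partner correlation ~0.86 but partner-partner
            # ~0.74 — the hub is the designed network center
            "n_samples": 18,
            "n_clusters": 5,
            "cluster_size": 25,
            "module_sizes": [13, 10],
            "hub_degree": 12,
            "noise_sd": 1.8,
            "n_low": 8,
        }
    )
    qpcr_plan: dict = field(
        default_factory=lambda: {
            "n_groups": 4,
            "n_replicates": 3,
            "effect_sizes": [1.0, 4.0, 0.5, 2.0],
            "ct_sd": 0.15,
        }
    )
    # classifier-facing layout parameters (must match the classifier's)
    min_anchors: int = 5
    proximal_max: int = 10
    protein_length: tuple[int, int] = (140, 240)
    pair_nonsyn: int = 2
    pair_syn: int = 4

    def __post_init__(self):
        if not (0 <= self.mismatch_rate < 1):
            raise ConfigError("mismatch_rate must be in [0, 1)")
        if self.n_chromosomes < 2 or self.genes_per_chromosome < 1:
            raise ConfigError("need >= 2 chromosomes with >= 1 gene each")
        for key, v in self.duplication_plan.items():
            if key not in MODES:
                raise ConfigError(f"unknown duplication mode {key!r}")
            if v < 0:
                raise ConfigError("duplication counts must be >= 0")
        if self.expression_plan.get("noise_sd", 0) < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.qpcr_plan.get("n_replicates", 3) < 2:
            raise ConfigError("need >= 2 qPCR replicates")
        if self.expression_plan.get("n_samples", 4) < 4:
            raise ConfigError("need >= 4 expression samples")


@dataclass
class TruthTable:
    planted_domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_modes: dict[tuple[str, str], str] = field(default_factory=dict)
    planted_clusters: dict[str, int] = field(default_factory=dict)
    planted_modules: dict[str, int] = field(default_factory=dict)
    planted_hubs: dict[int, str] = field(default_factory=dict)
    planted_group_means: dict[str, float] = field(default_factory=dict)
    family_members: set[str] = field(default_factory=set)
    node_types: dict[str, str] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "domains": pd.DataFrame(
                [(g, s, e) for g, (s, e) in sorted(self.planted_domains.items())],
                columns=["gene", "domain_start", "domain_end"],
            ),
            "modes": pd.DataFrame(
                [(a, b, m) for (a, b), m in sorted(self.planted_modes.items())],
                columns=["gene_a", "gene_b", "mode"],
            ),
            "clusters": pd.DataFrame(
                sorted(self.planted_clusters.items()), columns=["feature", "cluster"]
            ),
            "modules": pd.DataFrame(
                sorted(self.planted_modules.items()), columns=["node", "module"]
            ),
            "group_means": pd.DataFrame(
                sorted(self.planted_group_means.items()), columns=["group", "fold"]
            ),
        }


@dataclass
class GenomeBundle:
    proteins: dict[str, str]  # mRNA id -> protein
    cds: dict[str, str]  # mRNA id -> CDS
    annotation: GeneSet
    truth: TruthTable


# ---------------------------------------------------------------------------
# genome helpers

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def back_translate(protein: str) -> str:
    return "".join(CODON_OF[c] for c in protein)


def _plant_domain(rng: np.random.Generator, protein: str, consensus: str,
                  mismatch_rate: float) -> tuple[str, int, int]:
    """Embed a mutated consensus copy at a random offset; the number of
    mutated informative positions is floor(rate * n_informative), which
    keeps every planted domain inside a rate-matched mismatch budget."""
    informative = [i for i, c in enumerate(consensus) if c != "."]
    n_mut = int(np.floor(mismatch_rate * len(informative)))
    dom = list(consensus)
    for i in range(len(dom)):
        if dom[i] == ".":
            dom[i] = rng.choice(list(AA))
    for i in rng.choice(informative, size=n_mut, replace=False):
        alternatives = [a for a in AA if a != consensus[i]]
        dom[i] = rng.choice(alternatives)
    offset = int(rng.integers(10, len(protein) - len(consensus) - 10))
    planted = protein[:offset] + "".join(dom) + protein[offset + len(consensus):]
    return planted, offset, offset + len(consensus)


def _mutate_copy(rng: np.random.Generator, protein: str, cds: str,
                 span: tuple[int, int], n_nonsyn: int, n_syn: int) -> tuple[str, str]:
    """Duplicate-pair second member: a few nonsynonymous changes outside
    the domain span plus synonymous codon swaps (CDS still translates to
    the protein exactly)."""
    prot = list(protein)
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(protein))]
    outside = [i for i in range(len(prot)) if not (span[0] <= i < span[1])]
    if n_nonsyn > 0 and outside:
        for i in rng.choice(outside, size=min(n_nonsyn, len(outside)), replace=False):
            prot[i] = rng.choice([a for a in AA if a != prot[i]])
            codons[i] = CODON_OF[prot[i]]
    swappable = [i for i, a in enumerate(prot) if a in ALT_CODON]
    if n_syn > 0 and swappable:
        for i in rng.choice(swappable, size=min(n_syn, len(swappable)), replace=False):
            codons[i] = ALT_CODON[prot[i]]
    return "".join(prot), "".join(codons)


class _ChromBuilder:
    """Accumulates (protein, cds, tag) gene specs per chromosome."""

    def __init__(self, n_chromosomes: int):
        self.chroms: list[list[dict]] = [[] for _ in range(n_chromosomes)]

    def append(self, chrom: int, protein: str, cds: str, tag: str = "",
               second_isoform: bool = False) -> tuple[int, int]:
        self.chroms[chrom].append(
            {"protein": protein, "cds": cds, "tag": tag, "iso2": second_isoform}
        )
        return (chrom, len(self.chroms[chrom]) - 1)


def _chromosome_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered chromosome pairs in a balanced rotation order, so
    consecutive assignments spread across chromosomes."""
    seen = set()
    out = []
    for offset in range(1, n):
        for i in range(n):
            a, b = i, (i + offset) % n
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def generate_genome(config: SyntheticConfig) -> GenomeBundle:
    """Synthetic proteome + CDS + annotation with planted family members
    and duplication modes; raises :class:`ConfigError` on infeasible plans."""
    rng = np.random.default_rng(config.seed)
    plan = {m: int(config.duplication_plan.get(m, 0)) for m in MODES}
    C = config.n_chromosomes
    truth = TruthTable()
    builder = _ChromBuilder(C)
    lo, hi = config.protein_length

    n_pair_genes = 2 * sum(plan.values())
    if config.n_family_genes < n_pair_genes:
        raise ConfigError(
            f"n_family_genes={config.n_family_genes} cannot host "
            f"{n_pair_genes} planted pair genes"
        )

    pairs_order = _chromosome_pairs(C)
    n_segments = plan["WGD"] + max(1 if plan["TRD"] else 0, -(-plan["TRD"] // 3))
    if n_segments > len(pairs_order):
        raise ConfigError("more collinear segments than chromosome pairs")
    seg_keys = pairs_order[:n_segments]
    loose_keys = pairs_order[n_segments:]
    loose_capacity = len(loose_keys) * (config.min_anchors - 1)
    if plan["DSD"] + plan["TRD"] > loose_capacity:
        raise ConfigError(
            f"plan needs {plan['DSD'] + plan['TRD']} dispersed/transposed slots, "
            f"only {loose_capacity} available; add chromosomes"
        )
    if plan["TD"] + plan["PD"] > 4 * C:
        raise ConfigError("too many tandem/proximal pairs for the chromosome count")

    def new_family_protein() -> tuple[str, str, tuple[int, int]]:
        base = _random_protein(rng, int(rng.integers(lo, hi)))
        prot, s, e = _plant_domain(rng, base, config.consensus, config.mismatch_rate)
        return prot, back_translate(prot), (s, e)

    placements: list[tuple[tuple[int, int], tuple[int, int], str]] = []
    pair_seq = itertools.count(1)

    # --- collinear segments (WGD pairs + ancestral loci for TRD parents)
    trd_parent_slots: list[tuple[int, int]] = []  # chromosome-side positions
    trd_remaining = plan["TRD"]
    for seg_idx, (ca, cb) in enumerate(seg_keys):
        is_wgd_seg = seg_idx < plan["WGD"]
        n_bg = config.min_anchors if is_wgd_seg else config.min_anchors + 1
        bg = [_random_protein(rng, int(rng.integers(lo, hi))) for _ in range(n_bg)]
        insert_at = n_bg // 2
        parents_here = 0 if is_wgd_seg else min(3, trd_remaining)
        trd_remaining -= parents_here
        # copy A: background anchors, with the family WGD anchor or the TRD
        # parents interleaved
        pos_a = []
        fam_a = fam_b = None
        for i, prot in enumerate(bg):
            if is_wgd_seg and i == insert_at:
                fprot, fcds, span = new_family_protein()
                fam_a = builder.append(ca, fprot, fcds, tag="wgd_a")
                placements.append((fam_a, span, "family"))
            if not is_wgd_seg and i in range(1, 1 + parents_here):
                pprot, pcds, span = new_family_protein()
                slot = builder.append(ca, pprot, pcds, tag="trd_parent")
                placements.append((slot, span, "family"))
                trd_parent_slots.append(slot)
            pos_a.append(builder.append(ca, prot, back_translate(prot), tag="anchor"))
        # copy B mirrors the anchors (identical background copies)
        for i, prot in enumerate(bg):
            if is_wgd_seg and i == insert_at:
                fprot_a = builder.chroms[fam_a[0]][fam_a[1]]["protein"]
                fcds_a = builder.chroms[fam_a[0]][fam_a[1]]["cds"]
                span = next(sp for slot, sp, _ in placements if slot == fam_a)
                prot_b, cds_b = _mutate_copy(
                    rng, fprot_a, fcds_a, span, config.pair_nonsyn, config.pair_syn
                )
                fam_b = builder.append(cb, prot_b, cds_b, tag="wgd_b")
                placements.append((fam_b, span, "family"))
            builder.append(cb, prot, back_translate(prot), tag="anchor")
        if is_wgd_seg:
            placements.append(((-1, -1), (0, 0), f"pairWGD:{fam_a}:{fam_b}"))

    if trd_remaining:
        raise ConfigError("could not place all TRD parents in ancestral segments")

    # --- tandem and proximal pairs
    td_pd_chrom = itertools.cycle(range(C))
    for mode, count, gap in (("TD", plan["TD"], 0), ("PD", plan["PD"], 2)):
        for _ in range(count):
            c = next(td_pd_chrom)
            prot, cds, span = new_family_protein()
            slot_a = builder.append(c, prot, cds, tag=mode.lower())
            placements.append((slot_a, span, "family"))
            for _ in range(gap):
                f = _random_protein(rng, int(rng.integers(lo, hi)))
                builder.append(c, f, back_translate(f), tag="filler")
            prot_b, cds_b = _mutate_copy(rng, prot, cds, span,
                                         config.pair_nonsyn, config.pair_syn)
            slot_b = builder.append(c, prot_b, cds_b, tag=mode.lower())
            placements.append((slot_b, span, "family"))
            placements.append(((-1, -1), (0, 0), f"pair{mode}:{slot_a}:{slot_b}"))

    # --- loose pairs: TRD partners and DSD pairs
    loose_used: dict[tuple[int, int], int] = {k: 0 for k in loose_keys}

    def alloc_key(require_chrom: int | None = None) -> tuple[int, int]:
        for k in loose_keys:
            if loose_used[k] >= config.min_anchors - 1:
                continue
            if require_chrom is None or require_chrom in k:
                loose_used[k] += 1
                return k
        raise ConfigError("no loose chromosome-pair slot available")

    for parent_slot in trd_parent_slots:
        pc = parent_slot[0]
        key = alloc_key(require_chrom=pc)
        partner_chrom = key[0] if key[1] == pc else key[1]
        pprot = builder.chroms[parent_slot[0]][parent_slot[1]]["protein"]
        pcds = builder.chroms[parent_slot[0]][parent_slot[1]]["cds"]
        span = next(sp for slot, sp, _ in placements if slot == parent_slot)
        prot_b, cds_b = _mutate_copy(rng, pprot, pcds, span,
                                     config.pair_nonsyn, config.pair_syn)
        slot_b = builder.append(partner_chrom, prot_b, cds_b, tag="trd_partner")
        placements.append((slot_b, span, "family"))
        placements.append(((-1, -1), (0, 0), f"pairTRD:{parent_slot}:{slot_b}"))

    for _ in range(plan["DSD"]):
        key = alloc_key()
        prot, cds, span = new_family_protein()
        slot_a = builder.append(key[0], prot, cds, tag="dsd")
        placements.append((slot_a, span, "family"))
        prot_b, cds_b = _mutate_copy(rng, prot, cds, span,
                                     config.pair_nonsyn, config.pair_syn)
        slot_b = builder.append(key[1], prot_b, cds_b, tag="dsd")
        placements.append((slot_b, span, "family"))
        placements.append(((-1, -1), (0, 0), f"pairDSD:{slot_a}:{slot_b}"))

    # --- family singletons and padding
    n_singletons = config.n_family_genes - n_pair_genes
    sing_chrom = itertools.cycle(range(C))
    for _ in range(n_singletons):
        prot, cds, span = new_family_protein()
        slot = builder.append(next(sing_chrom), prot, cds, tag="singleton",
                              second_isoform=True)
        placements.append((slot, span, "family"))
    for c in range(C):
        while len(builder.chroms[c]) < config.genes_per_chromosome:
            f = _random_protein(rng, int(rng.integers(lo, hi)))
            # every 7th filler carries a shorter second isoform to exercise
            # longest-isoform selection
            iso2 = len(builder.chroms[c]) % 7 == 0
            builder.append(c, f, back_translate(f), tag="filler", second_isoform=iso2)
        if len(builder.chroms[c]) > config.genes_per_chromosome:
            raise ConfigError(
                f"chromosome {c} needs {len(builder.chroms[c])} genes, "
                f"genes_per_chromosome={config.genes_per_chromosome} too small"
            )

    # --- materialize gene models
    gene_id_of: dict[tuple[int, int], str] = {}
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    for c in range(C):
        chrom_name = f"chr{c + 1}"
        for pos, spec in enumerate(builder.chroms[c]):
            gid = f"g{c + 1:02d}_{pos + 1:04d}"
            gene_id_of[(c, pos)] = gid
            start = 1 + pos * 2000
            end = start + len(spec["cds"]) - 1
            isoforms = [Isoform(f"{gid}.t1", spec["protein"], spec["cds"], 1)]
            if spec["iso2"] and len(spec["protein"]) > 40:
                short = spec["protein"][: len(spec["protein"]) // 2]
                isoforms.append(Isoform(f"{gid}.t2", short, back_translate(short), 1))
            genes.append(GeneModel(gid, chrom_name, start, end, "+", isoforms=isoforms))
            for iso in isoforms:
                proteins[iso.isoform_id] = iso.protein
                cds_map[iso.isoform_id] = iso.cds

    annotation = GeneSet(genes)

    for slot, span, kind in placements:
        if kind == "family":
            gid = gene_id_of[slot]
            truth.family_members.add(gid)
            truth.planted_domains[gid] = span
        elif kind.startswith("pair"):
            mode, sa, sb = kind[4:].split(":")
            slot_a = tuple(int(x) for x in sa.strip("()").split(","))
            slot_b = tuple(int(x) for x in sb.strip("()").split(","))
            ga, gb = gene_id_of[slot_a], gene_id_of[slot_b]
            key = (ga, gb) if ga < gb else (gb, ga)
            truth.planted_modes[key] = mode

    return GenomeBundle(proteins, cds_map, annotation, truth)


def write_genome(bundle: GenomeBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "proteins.faa", bundle.proteins)
    write_fasta(out / "cds.fna", bundle.cds)
    write_gff3(out / "annotation.gff3", bundle.annotation)
    for name, df in bundle.truth.to_frames().items():
        df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression

def generate_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Gene and metabolite matrices with planted clusters and co-expression
    modules.

    Cluster members share a structured mean profile (high in one sample,
    baseline elsewhere; later clusters invert) plus Gaussian noise; module
    members follow a latent profile z with independent noise, the hub being
    the noise-free z — so hub–member correlation exceeds member–member
    correlation and the hub is the designed center.  A few genes sit below
    1 everywhere to exercise the expression filter.
    """
    plan = config.expression_plan
    n_samples = int(plan["n_samples"])
    n_clusters = int(plan["n_clusters"])
    cluster_size = int(plan.get("cluster_size", 25))
    module_sizes = list(plan.get("module_sizes", [13, 10]))
    hub_degree = int(plan.get("hub_degree", 12))
    noise_sd = float(plan["noise_sd"])
    n_low = int(plan.get("n_low", 8))
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if module_sizes:
        module_sizes[0] = hub_degree + 1  # designated hub + its partners
    rng = np.random.default_rng(config.seed + 1)
    truth = TruthTable()
    samples = [f"S{i + 1}" for i in range(n_samples)]
    rows: dict[str, np.ndarray] = {}

    # planted clusters
    for c in range(n_clusters):
        base = np.full(n_samples, 5.0)
        focus = c % n_samples
        if c < n_samples:
            base[focus] = 50.0
        else:
            base = np.full(n_samples, 30.0)
            base[focus] = 5.0
        for g in range(cluster_size):
            gid = f"gene_c{c + 1:02d}_{g + 1:03d}"
            vals = base + rng.normal(0.0, noise_sd, n_samples)
            rows[gid] = np.clip(vals, 0.0, None)
            truth.planted_clusters[gid] = c
            truth.node_types[gid] = "family_gene"

    # low-expression genes (filtered out downstream)
    for g in range(n_low):
        gid = f"gene_low_{g + 1:02d}"
        rows[gid] = np.clip(rng.uniform(0.0, 0.9, n_samples), 0.0, None)
        truth.node_types[gid] = "family_gene"

    # co-expression modules over genes, enzymes and metabolites.  Members
    # are cos(t)*z + sin(t)*e_i with e_i orthonormal in centered sample
    # space, so hub-member correlation is exactly cos(t) = 1/sqrt(1+s^2)
    # (s = noise_sd / latent amplitude 3) and member-member correlation is
    # exactly cos(t)^2 — the hub is the center in every realization.
    met_rows: dict[str, np.ndarray] = {}
    for m, size in enumerate(module_sizes):
        z = rng.normal(0.0, 1.0, n_samples)
        z = (z - z.mean()) / z.std()
        s = noise_sd / 3.0
        cos_t = 1.0 / np.sqrt(1.0 + s * s)
        sin_t = s * cos_t
        basis = _orthonormal_noise(rng, n_samples, size - 1, z)
        hub_id = f"hub_m{m + 1}"
        rows[hub_id] = 10.0 + 3.0 * z
        truth.planted_modules[hub_id] = m
        truth.planted_hubs[m] = hub_id
        truth.node_types[hub_id] = "family_gene"
        for i in range(size - 1):
            if basis is not None:
                e = basis[i]
            else:  # more members than centered dimensions: plain noise
                e = rng.normal(0.0, 1.0, n_samples)
            vals = 10.0 + 3.0 * (cos_t * z + sin_t * e)
            if i % 3 == 2:
                nid = f"met_m{m + 1}_{i + 1:02d}"
                met_rows[nid] = vals
                truth.node_types[nid] = "metabolite"
            elif i % 3 == 1:
                nid = f"enz_m{m + 1}_{i + 1:02d}"
                rows[nid] = vals
                truth.node_types[nid] = "enzyme_gene"
            else:
                nid = f"gene_m{m + 1}_{i + 1:02d}"
                rows[nid] = vals
                truth.node_types[nid] = "family_gene"
            truth.planted_modules[nid] = m

    expr = pd.DataFrame.from_dict(rows, orient="index", columns=samples).sort_index()
    mets = pd.DataFrame.from_dict(met_rows, orient="index", columns=samples).sort_index()
    return expr, mets, truth


def _orthonormal_noise(
    rng: np.random.Generator, n: int, count: int, z: np.ndarray
) -> list[np.ndarray] | None:
    """``count`` vectors of unit sample SD, zero mean, mutually
    uncorrelated and uncorrelated with ``z`` (Gram–Schmidt in centered
    space); None when the sample space is too small."""
    if count > n - 2:
        return None
    basis: list[np.ndarray] = []
    zc = z - z.mean()
    while len(basis) < count:
        v = rng.normal(0.0, 1.0, n)
        v = v - v.mean()
        v = v - (v @ zc) / (zc @ zc) * zc
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        nrm = np.sqrt((v @ v) / n)
        if nrm < 1e-8:
            continue
        basis.append(v / nrm)
    return basis


# ---------------------------------------------------------------------------
# qPCR

def generate_qpcr(
    config: SyntheticConfig,
    reference_gene: str = "EF1a",
    target_gene: str = "TARGET",
    baseline_ct: float = 28.0,
    reference_ct: float = 20.0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Ct table with planted per-group fold changes.

    Target Ct = baseline - log2(planted fold) + noise; reference Ct is
    constant + noise; the first group is the calibrator (fold 1).
    """
    plan = config.qpcr_plan
    n_groups = int(plan["n_groups"])
    n_reps = int(plan["n_replicates"])
    effects = list(plan["effect_sizes"])
    ct_sd = float(plan["ct_sd"])
    if n_reps < 2:
        raise ConfigError("need >= 2 replicates")
    if len(effects) != n_groups:
        raise ConfigError("effect_sizes must have one entry per group")
    rng = np.random.default_rng(config.seed + 2)
    truth = TruthTable()
    rows = []
    for g in range(n_groups):
        group = f"G{g + 1}"
        truth.planted_group_means[group] = float(effects[g])
        for r in range(n_reps):
            rows.append({
                "group": group, "gene": target_gene, "replicate": r + 1,
                "ct": baseline_ct - float(np.log2(effects[g])) + rng.normal(0, ct_sd),
            })
            rows.append({
                "group": group, "gene": reference_gene, "replicate": r + 1,
                "ct": reference_ct + rng.normal(0, ct_sd),
            })
    return pd.DataFrame(rows), truth
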