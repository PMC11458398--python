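"""End-to-end orchestration of the survey stages behind one configuration.

Stages run in dependency order: identify -> conserve -> phylo -> dup
(duplication + Ka/Ks) -> coexpr -> ppi -> qpcr.  A stage can be toggled
off; its dependents are then skipped with a warning.  A reproducibility
manifest (seeds, parameter values, input hashes, package version) is
written next to the outputs, and a rerun from the same manifest reproduces
every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import align, coexpression, duplication, identify, interaction, phylo, qpcr
from .io import read_edge_list, read_fasta, read_gff3, write_fasta
from .synthetic import (
    SyntheticConfig,
    generate_expression,
    generate_genome,
    generate_qpcr,
    write_genome,
)

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "simulate_bundle"]

STAGE_DEPS = {
    "identify": (),
    "conserve": ("identify",),
    "phylo": ("conserve",),
    "dup": ("identify",),
    "coexpr": (),
    "ppi": ("identify",),
    "qpcr": (),
}


def default_config(seed: int = 1) -> dict[str, Any]:
    """Pipeline defaults: every stage on, parameters at their documented
    module defaults."""
    return {
        "seed": seed,
        "stages": {s: True for s in STAGE_DEPS},
        "identify": {"max_mismatch": 13, "prefix": "FAM"},
        "conserve": {"ratio_threshold": 0.5, "high_threshold": 0.8, "entropy_threshold": 0.6},
        "phylo": {"model": "kimura", "deletion": "pairwise", "bootstrap": 100},
        "dup": {"min_score": 0.5, "min_anchors": 5, "max_gap": 25, "proximal_max": 10},
        "coexpr": {"beta": 6, "min_weight": 0.3, "k": 5, "min_value": 1.0},
        "ppi": {"min_score": 0.3},
        "qpcr": {"reference_gene": "EF1a", "calibrator_group": "G1", "alpha": 0.05},
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_bundle(config: SyntheticConfig, outdir: str | Path) -> None:
    """Write the full synthetic input bundle (genome, expression,
    metabolites, qPCR, reference PPI fixtures, consensus) to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_genome(config)
    write_genome(bundle, out)
    (out / "consensus.txt").write_text(config.consensus + "\n")
    expr, mets, etruth = generate_expression(config)
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="feature")
    mets.to_csv(out / "metabolites.tsv", sep="\t", index_label="feature")
    pd.DataFrame(
        sorted(etruth.node_types.items()), columns=["node", "type"]
    ).to_csv(out / "node_types.tsv", sep="\t", index=False)
    for name, df in etruth.to_frames().items():
        if not df.empty:
            df.to_csv(out / f"truth_expr_{name}.tsv", sep="\t", index=False)
    ct, qtruth = generate_qpcr(config)
    ct.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)
    qtruth.to_frames()["group_means"].to_csv(
        out / "truth_qpcr.tsv", sep="\t", index=False
    )
    # reference interaction fixture: family members projected onto a mock
    # reference proteome (identical sequences under reference ids) with a
    # deterministic random edge list among them
    rng = np.random.default_rng(config.seed + 3)
    members = sorted(bundle.truth.family_members)[:40]
    ref = {f"REF{i + 1:03d}": bundle.proteins[f"{gid}.t1"] for i, gid in enumerate(members)}
    write_fasta(out / "reference_proteome.faa", ref)
    ids = sorted(ref)
    edges = set()
    while len(edges) < 3 * len(ids):
        a, b = rng.choice(ids, size=2, replace=False)
        edges.add((min(a, b), max(a, b)))
    pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"]).to_csv(
        out / "reference_edges.tsv", sep="\t", index=False
    )


def run_pipeline(config: dict[str, Any], indir: str | Path, outdir: str | Path) -> dict:
    """Run the enabled stages on the input bundle in ``indir``; returns the
    manifest (also written as ``manifest.json``)."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = dict(config.get("stages", {s: True for s in STAGE_DEPS}))
    # disable dependents of disabled stages
    for s, deps in STAGE_DEPS.items():
        if stages.get(s, True) and any(not stages.get(d, True) for d in deps):
            logger.warning("stage %s skipped: dependency disabled", s)
            stages[s] = False
    manifest: dict[str, Any] = {
        "package": "famsurveyor",
        "version": __version__,
        "seed": config.get("seed", 0),
        "parameters": {k: v for k, v in config.items() if k not in ("stages",)},
        "stages_run": [],
        "inputs": {},
    }
    for f in sorted(indir.glob("*")):
        if f.is_file():
            manifest["inputs"][f.name] = _sha256(f)

    state: dict[str, Any] = {}
    try:
        if stages.get("identify", True):
            _stage_identify(config, indir, outdir, state)
            manifest["stages_run"].append("identify")
        if stages.get("conserve", True):
            _stage_conserve(config, outdir, state)
            manifest["stages_run"].append("conserve")
        if stages.get("phylo", True):
            _stage_phylo(config, outdir, state)
            manifest["stages_run"].append("phylo")
        if stages.get("dup", True):
            _stage_dup(config, indir, outdir, state)
            manifest["stages_run"].append("dup")
        if stages.get("coexpr", True):
            _stage_coexpr(config, indir, outdir)
            manifest["stages_run"].append("coexpr")
        if stages.get("ppi", True):
            _stage_ppi(config, indir, outdir, state)
            manifest["stages_run"].append("ppi")
        if stages.get("qpcr", True):
            _stage_qpcr(config, indir, outdir)
            manifest["stages_run"].append("qpcr")
    except Exception as exc:  # partial outputs stay on disk for inspection
        failed = len(manifest["stages_run"])
        stage_name = list(STAGE_DEPS)[failed] if failed < len(STAGE_DEPS) else "?"
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# stage implementations

def _stage_identify(config, indir: Path, outdir: Path, state: dict) -> None:
    params = config.get("identify", {})
    proteins = read_fasta(indir / "proteins.faa")
    cds = read_fasta(indir / "cds.fna")
    annotation = read_gff3(indir / "annotation.gff3", proteins=proteins, cds=cds)
    consensus = (indir / "consensus.txt").read_text().strip()
    representative = identify.select_longest_isoform(annotation)
    hits = identify.scan_proteome(
        representative, consensus, params.get("max_mismatch", 13)
    )
    names = identify.name_by_position(
        hits.keys(), annotation, prefix=params.get("prefix", "FAM")
    )
    rows = []
    member_seqs: dict[str, str] = {}
    domain_seqs: dict[str, str] = {}
    for gid, hlist in hits.items():
        primary = next(h for h in hlist if h.primary)
        seq = representative[gid]
        props = identify.protein_properties(seq)
        g = annotation[gid]
        rows.append({
            "name": names[gid], "gene": gid, "chromosome": g.chromosome,
            "start": g.start, "end": g.end, "length": props.length,
            "mw_kda": round(props.mw, 3), "pi": round(props.pi, 2),
            "mismatches": primary.mismatches,
        })
        member_seqs[names[gid]] = seq
        domain_seqs[names[gid]] = seq[primary.window_start:primary.window_end]
    table = pd.DataFrame(rows).sort_values("name", ignore_index=True)
    table.to_csv(outdir / "members.tsv", sep="\t", index=False)
    write_fasta(outdir / "members.faa", dict(sorted(member_seqs.items())))
    state.update(
        names=names, members=member_seqs, domains=domain_seqs,
        representative=representative, annotation=annotation, cds=cds,
    )


def _stage_conserve(config, outdir: Path, state: dict) -> None:
    params = config.get("conserve", {})
    msa = align.progressive_align(dict(sorted(state["domains"].items())))
    write_fasta(outdir / "domains_aligned.faa", msa.rows)
    profiles = align.column_stats(msa)
    cons, high = align.conserved_sites(
        profiles,
        ratio_threshold=params.get("ratio_threshold", 0.5),
        high_threshold=params.get("high_threshold", 0.8),
        entropy_threshold=params.get("entropy_threshold", 0.6),
    )
    pd.DataFrame(
        [
            {"column": p.index, "modal_residue": p.modal_residue,
             "ratio": p.ratio, "entropy": p.entropy,
             "gap_fraction": p.gap_fraction, "flagged": p.flagged}
            for p in profiles
        ]
    ).to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    (outdir / "conserved_sites.txt").write_text(
        "conserved\t" + ",".join(cons) + "\nhighly_conserved\t" + ",".join(high) + "\n"
    )
    state["msa"] = msa


def _stage_phylo(config, outdir: Path, state: dict) -> None:
    params = config.get("phylo", {})
    n_boot = params.get("bootstrap", 100)
    if n_boot > 0:
        tree = phylo.bootstrap_support(
            state["msa"], n_replicates=n_boot, seed=config.get("seed", 0),
            model=params.get("model", "kimura"), deletion=params.get("deletion", "pairwise"),
        )
    else:
        tree = phylo.nj_tree(
            phylo.protein_distance(
                state["msa"], model=params.get("model", "kimura"),
                deletion=params.get("deletion", "pairwise"),
            )
        )
    tree.write(path=str(outdir / "family_nj.nwk"), schema="newick",
               suppress_rooting=True)
    state["tree"] = tree


def _stage_dup(config, indir: Path, outdir: Path, state: dict) -> None:
    params = config.get("dup", {})
    representative = state["representative"]
    annotation = state["annotation"]
    anchors = duplication.homolog_pairs(
        representative, min_score=params.get("min_score", 0.5)
    )
    blocks = duplication.collinear_blocks(
        anchors, annotation,
        min_anchors=params.get("min_anchors", 5), max_gap=params.get("max_gap", 25),
    )
    family = set(state["names"])
    records = duplication.classify_duplications(
        anchors, blocks, annotation,
        proximal_max=params.get("proximal_max", 10), family=family,
    )
    cds_by_gene = {
        gid: state["cds"][annotation[gid].longest_isoform().isoform_id]
        for gid in representative
        if annotation[gid].longest_isoform().isoform_id in state["cds"]
    }
    records = duplication.annotate_kaks(records, representative, cds_by_gene)
    pd.DataFrame(
        [
            {"gene_a": r.gene_a, "gene_b": r.gene_b, "mode": r.mode,
             "ka": r.ka, "ks": r.ks, "ratio": r.ratio, "flags": ";".join(r.flags)}
            for r in records
        ]
    ).to_csv(outdir / "duplications.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom_a": b.chrom_a, "chrom_b": b.chrom_b, "n_anchors": b.n_anchors,
             "orientation": b.orientation,
             "span_a": f"{b.span_a[0]}-{b.span_a[1]}",
             "span_b": f"{b.span_b[0]}-{b.span_b[1]}"}
            for b in blocks
        ]
    ).to_csv(outdir / "blocks.tsv", sep="\t", index=False)


def _stage_coexpr(config, indir: Path, outdir: Path) -> None:
    params = config.get("coexpr", {})
    expr = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
    kept, excluded = coexpression.filter_expressed(
        expr, min_value=params.get("min_value", 1.0)
    )
    patterns = coexpression.classify_patterns(expr)
    patterns.to_csv(outdir / "patterns.tsv", sep="\t", index_label="feature")
    labels, _ = coexpression.kmeans_profiles(
        kept, k=params.get("k", 5), seed=config.get("seed", 0)
    )
    labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t", index_label="feature")
    mets_path = indir / "metabolites.tsv"
    combined = kept
    if mets_path.exists():
        mets = pd.read_csv(mets_path, sep="\t", index_col=0)
        combined = pd.concat([kept, mets])
    beta = params.get("beta", "auto")
    if beta == "auto":
        beta, table = coexpression.pick_soft_threshold(combined)
        table.to_csv(outdir / "soft_threshold.tsv", sep="\t", index=False)
    edges = coexpression.tom_network(
        combined, beta=beta, min_weight=params.get("min_weight", 0.3)
    )
    pd.DataFrame(
        [{"node_a": e.node_a, "node_b": e.node_b, "weight": e.weight} for e in edges]
    ).to_csv(outdir / "tom_edges.tsv", sep="\t", index=False)
    if edges:
        coexpression.hub_rank(edges).to_csv(outdir / "hubs.tsv", sep="\t", index=False)


def _stage_ppi(config, indir: Path, outdir: Path, state: dict) -> None:
    params = config.get("ppi", {})
    ref_fa = indir / "reference_proteome.faa"
    ref_edges = indir / "reference_edges.tsv"
    if not ref_fa.exists() or not ref_edges.exists():
        logger.warning("ppi stage skipped: reference proteome/edges not provided")
        return
    ref = read_fasta(ref_fa)
    orthomap = interaction.reciprocal_best_hits(
        state["members"], ref, min_score=params.get("min_score", 0.3)
    )
    g, degree = interaction.project_network(orthomap, read_edge_list(ref_edges))
    pd.DataFrame(sorted(g.edges), columns=["node_a", "node_b"]).to_csv(
        outdir / "ppi_edges.tsv", sep="\t", index=False
    )
    degree.to_csv(outdir / "ppi_degree.tsv", sep="\t", index=False)


def _stage_qpcr(config, indir: Path, outdir: Path) -> None:
    params = config.get("qpcr", {})
    ct_path = indir / "qpcr_ct.tsv"
    if not ct_path.exists():
        logger.warning("qpcr stage skipped: no Ct table")
        return
    records = pd.read_csv(ct_path, sep="\t")
    folds = qpcr.ddct(
        records,
        reference_gene=params.get("reference_gene", "EF1a"),
        calibrator_group=params.get("calibrator_group", "G1"),
    )
    folds.to_csv(outdir / "qpcr_folds.tsv", sep="\t", index=False)
    rows = []
    for gene, sub in folds.groupby("gene"):
        groups = {g: grp["fold"].to_numpy() for g, grp in sub.groupby("group")}
        F, (df1, df2), p = qpcr.anova_oneway(groups)
        res = qpcr.duncan_mrt(groups, alpha=params.get("alpha", 0.05))
        for g in res.groups:
            rows.append({
                "gene": gene, "group": g, "mean_fold": res.means[g],
                "sd": float(np.std(groups[g], ddof=1)),
                "letters": res.letters[g], "anova_F": F, "anova_p": p,
            })
    pd.DataFrame(rows).to_csv(outdir / "qpcr_stats.tsv", sep="\t", index=False)
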