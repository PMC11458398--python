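"""Homolog search, collinear chaining, duplication-mode classification and
NG86 Ka/Ks."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from famsurveyor.duplication import (
    AnchorPair,
    classify_duplications,
    codon_align,
    collinear_blocks,
    cross_species_synteny,
    homolog_pairs,
    ka_ks,
    CODON_AA,
    STOP_CODONS,
)
from famsurveyor.io import GeneModel, GeneSet
from famsurveyor.synthetic import CODON_OF, SyntheticConfig, generate_genome

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# homolog pairs

class TestHomologPairs:
    def test_identical_duplicate_scores_one(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list(AAS), size=150))
        other = "".join(rng.choice(list(AAS), size=150))
        pairs = homolog_pairs({"a": seq, "b": seq, "c": other})
        assert len(pairs) == 1
        assert pairs[0].key == ("a", "b")
        assert pairs[0].score == pytest.approx(1.0)

    def test_random_pairs_fall_below_threshold(self):
        """Empirical null: unrelated 200-AA proteins never approach the
        0.5 normalized-score threshold."""
        rng = np.random.default_rng(2)
        prots = {f"p{i}": "".join(rng.choice(list(AAS), size=200)) for i in range(30)}
        pairs = homolog_pairs(prots, min_score=0.0, kmer_prefilter=False)
        assert max(p.score for p in pairs) < 0.25

    def test_prefilter_is_recall_safe(self, genome_bundle, representative_proteome):
        sub = dict(itertools.islice(representative_proteome.items(), 80))
        with_f = {p.key for p in homolog_pairs(sub, kmer_prefilter=True)}
        without = {p.key for p in homolog_pairs(sub, kmer_prefilter=False)}
        assert with_f == without


# ---------------------------------------------------------------------------
# collinear blocks

def _annotation(chrom_genes):
    """chrom_genes: {chrom: [gene ids in rank order]}"""
    genes = []
    for chrom, ids in chrom_genes.items():
        for i, gid in enumerate(ids):
            genes.append(GeneModel(gid, chrom, 1 + i * 1000, 900 + i * 1000))
    return GeneSet(genes)


def brute_force_longest_chain(points, max_gap):
    """Longest strictly-monotone chain (either orientation) by DFS."""
    best = 0
    pts = sorted(points)

    def extend(chain, orient):
        nonlocal best
        best = max(best, len(chain))
        x0, y0 = chain[-1]
        for x, y in pts:
            if not (0 < x - x0 <= max_gap):
                continue
            if orient in ("same", None) and 0 < y - y0 <= max_gap:
                extend(chain + [(x, y)], "same")
            if orient in ("inverted", None) and 0 < y0 - y <= max_gap:
                extend(chain + [(x, y)], "inverted")

    for p in pts:
        extend([p], None)
    return best


class TestCollinearBlocks:
    def test_planted_segment_found(self):
        ids_a = [f"a{i}" for i in range(10)]
        ids_b = [f"b{i}" for i in range(10)]
        ann = _annotation({"chr1": ids_a, "chr2": ids_b})
        anchors = [AnchorPair(*sorted((a, b)), score=1.0) for a, b in zip(ids_a, ids_b)]
        blocks = collinear_blocks(anchors, ann, min_anchors=5)
        assert len(blocks) == 1 and blocks[0].n_anchors == 10

    def test_below_min_anchors_dropped(self):
        ids_a = [f"a{i}" for i in range(4)]
        ids_b = [f"b{i}" for i in range(4)]
        ann = _annotation({"chr1": ids_a, "chr2": ids_b})
        anchors = [AnchorPair(*sorted((a, b)), score=1.0) for a, b in zip(ids_a, ids_b)]
        assert collinear_blocks(anchors, ann, min_anchors=5) == []

    def test_inverted_orientation_found(self):
        ids_a = [f"a{i}" for i in range(6)]
        ids_b = [f"b{i}" for i in range(6)]
        ann = _annotation({"chr1": ids_a, "chr2": ids_b})
        anchors = [
            AnchorPair(*sorted((a, b)), score=1.0)
            for a, b in zip(ids_a, reversed(ids_b))
        ]
        blocks = collinear_blocks(anchors, ann, min_anchors=5)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_chain_length_matches_exhaustive_search(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            n = int(rng.integers(5, 13))
            xs = rng.permutation(40)[:n]
            ys = rng.permutation(40)[:n]
            ids_a = [f"a{i}" for i in range(40)]
            ids_b = [f"b{i}" for i in range(40)]
            ann = _annotation({"chr1": ids_a, "chr2": ids_b})
            anchors = [
                AnchorPair(*sorted((ids_a[x], ids_b[y])), score=1.0)
                for x, y in zip(xs, ys)
            ]
            blocks = collinear_blocks(anchors, ann, min_anchors=1, max_gap=25)
            got = max(b.n_anchors for b in blocks)
            expected = brute_force_longest_chain(list(zip(xs, ys)), 25)
            assert got == expected


# ---------------------------------------------------------------------------
# classification

class TestClassification:
    def test_adjacent_pair_is_tandem(self):
        ann = _annotation({"chr1": ["a", "b", "c"]})
        anchors = [AnchorPair("a", "b", 0.9)]
        recs = classify_duplications(anchors, [], ann)
        assert recs[0].mode == "TD"

    def test_proximal_window(self):
        ann = _annotation({"chr1": [f"g{i}" for i in range(12)]})
        recs = classify_duplications([AnchorPair("g0", "g5", 0.9)], [], ann)
        assert recs[0].mode == "PD"
        recs = classify_duplications(
            [AnchorPair("g0", "g5", 0.9)], [], ann, proximal_max=3
        )
        assert recs[0].mode == "DSD"  # outside the window, best-hit fallback

    def test_wgd_precedence_over_tandem(self):
        # a pair that is both rank-adjacent and a block anchor pair -> WGD
        ids = [f"g{i}" for i in range(10)]
        ann = _annotation({"chr1": ids})
        anchors = [AnchorPair(ids[2 * i], ids[2 * i + 1], 1.0) for i in range(5)]
        blocks = collinear_blocks(anchors, ann, min_anchors=5, max_gap=25)
        assert blocks, "constructed anchors must chain"
        recs = classify_duplications(anchors, blocks, ann)
        assert {r.mode for r in recs} == {"WGD"}

    def test_planted_modes_recovered_exactly(
        self, genome_bundle, genome_anchors, genome_blocks
    ):
        """Noise-free synthetic genome with the default plan
        (WGD 4 / TD 1 / PD 3 / TRD 11 / DSD 48): classification equals the
        planted truth with no extra family records."""
        truth = genome_bundle.truth
        recs = classify_duplications(
            genome_anchors, genome_blocks, genome_bundle.annotation,
            family=truth.family_members,
        )
        got = {(r.gene_a, r.gene_b): r.mode for r in recs}
        assert got == truth.planted_modes
        assert Counter(got.values()) == Counter(
            {"DSD": 48, "TRD": 11, "WGD": 4, "PD": 3, "TD": 1}
        )


# ---------------------------------------------------------------------------
# codon alignment and Ka/Ks

def oracle_syn_sites(codon):
    s = 0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1 :]
            if mut not in STOP_CODONS and CODON_AA[mut] == CODON_AA[codon]:
                s += 1
    return s / 3.0


def oracle_diffs(c1, c2):
    """Pathway counting via explicit permutations of substitution orders."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2:
                blocked = True
            if CODON_AA[nxt] == CODON_AA[cur] and nxt not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    clean = [(s, n) for s, n, b in paths if not b]
    use = clean or [(s, n) for s, n, _ in paths]
    return (sum(s for s, _ in use) / len(use), sum(n for _, n in use) / len(use))


def oracle_ng86(codons_a, codons_b):
    S = sum((oracle_syn_sites(a) + oracle_syn_sites(b)) / 2 for a, b in zip(codons_a, codons_b))
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b):
        sd, nd = oracle_diffs(a, b)
        Sd += sd
        Nd += nd
    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(Sd / S if S else 0.0), jc(Nd / N if N else 0.0)


class TestCodonAlign:
    def test_gap_free(self):
        ca, cb = codon_align(("ACD", "ACD"), "GCTTGTGAT", "GCTTGTGAT")
        assert ca == cb == "GCTTGTGAT"

    def test_gap_expands_to_triple(self):
        ca, cb = codon_align(("ACD", "A-D"), "GCTTGTGAT", "GCTGAT")
        assert cb == "GCT---GAT"

    def test_stop_codon_trimmed(self):
        ca, cb = codon_align(("AC", "AC"), "GCTTGTTAA", "GCTTGT")
        assert ca == "GCTTGT"

    def test_length_mismatch_names_sequence(self):
        with pytest.raises(ValueError, match="b"):
            codon_align(("AC", "AC"), "GCTTGT", "GCTTG", names=("a", "b"))

    def test_retranslation_round_trip(self):
        prot_a, prot_b = "ACDEF", "AC-EF"
        cds_a = "".join(CODON_OF[c] for c in prot_a)
        cds_b = "".join(CODON_OF[c] for c in prot_b.replace("-", ""))
        ca, cb = codon_align((prot_a, prot_b), cds_a, cds_b)
        back = "".join(
            "-" if cb[i : i + 3] == "---" else CODON_AA[cb[i : i + 3]]
            for i in range(0, len(cb), 3)
        )
        assert back == prot_b


class TestKaKs:
    def test_identical_cds(self):
        res = ka_ks(("GCTTGTGAT", "GCTTGTGAT"))
        assert res.ka == 0.0 and res.ks == 0.0
        assert res.ratio is None and "ratio_undefined" in res.flags

    def test_phenylalanine_worked_example(self):
        # six Phe codons, one synonymous third-position change:
        # S = 6 * 1/3 = 2, ps = 0.5, ks = -3/4 ln(1/3)
        res = ka_ks(("TTT" * 6, "TTT" * 5 + "TTC"))
        assert res.ka == 0.0
        assert res.ks == pytest.approx(0.8239, abs=1e-4)

    def test_symmetry(self):
        a, b = "GCTTGTGATAAAGAA", "GCCTGCGATAGAGAG"
        r1, r2 = ka_ks((a, b)), ka_ks((b, a))
        assert r1.ka == pytest.approx(r2.ka) and r1.ks == pytest.approx(r2.ks)

    def test_all_codon_pairs_match_oracle(self):
        """Every two-codon alignment over a six-codon alphabet agrees with
        exhaustive site/pathway counting."""
        alphabet = ["TTT", "TTC", "TTA", "CTA", "ATT", "ACT"]
        for c1, c2 in itertools.product(alphabet, repeat=2):
            for d1, d2 in itertools.product(alphabet, repeat=2):
                res = ka_ks((c1 + d1, c2 + d2))
                oks, oka = oracle_ng86([c1, d1], [c2, d2])
                assert res.ks == pytest.approx(oks, abs=1e-12) or (
                    math.isinf(res.ks) and math.isinf(oks)
                )
                assert res.ka == pytest.approx(oka, abs=1e-12) or (
                    math.isinf(res.ka) and math.isinf(oka)
                )

    def test_internal_stop_is_error(self):
        with pytest.raises(ValueError, match="stop"):
            ka_ks(("TAATTT", "TTTTTT"))

    def test_synonymous_only_changes_give_ratio_zero(self):
        prot = "ACDEFKLMNP"
        cds_a = "".join(CODON_OF[c] for c in prot)
        from famsurveyor.synthetic import ALT_CODON

        codons = [CODON_OF[c] for c in prot]
        codons[1] = ALT_CODON[prot[1]]
        codons[4] = ALT_CODON[prot[4]]
        res = ka_ks((cds_a, "".join(codons)))
        assert res.ka == 0.0 and res.ks > 0
        assert res.ratio == 0.0

    def test_nonsynonymous_only_changes_flag_undefined_ratio(self):
        res = ka_ks(("ATGGCT", "ATGACT"))  # Ala -> Thr, no syn change
        assert res.ks == 0.0 and res.ka > 0
        assert res.ratio is None and "ratio_undefined" in res.flags

    def test_planted_pairs_under_purifying_regime(
        self, genome_bundle, genome_anchors, genome_blocks
    ):
        """Duplicate pairs carry mostly synonymous planted changes, so the
        estimated Ka/Ks sits below one (purifying selection)."""
        from famsurveyor.duplication import annotate_kaks, classify_duplications
        from famsurveyor.identify import select_longest_isoform

        truth = genome_bundle.truth
        recs = classify_duplications(
            genome_anchors, genome_blocks, genome_bundle.annotation,
            family=truth.family_members,
        )[:10]
        rep = select_longest_isoform(genome_bundle.annotation)
        cds = {
            gid: genome_bundle.cds[genome_bundle.annotation[gid].longest_isoform().isoform_id]
            for gid in rep
        }
        recs = annotate_kaks(recs, rep, cds)
        for r in recs:
            assert r.ks is not None and r.ks > 0
            assert r.ratio is not None and r.ratio < 1.0


# ---------------------------------------------------------------------------
# cross-species synteny

class TestCrossSpecies:
    def test_identical_genomes_fully_collinear(self):
        cfg = SyntheticConfig(
            seed=5, n_chromosomes=2, genes_per_chromosome=12, n_family_genes=4,
            duplication_plan={m: 0 for m in ("WGD", "TD", "PD", "TRD", "DSD")},
        )
        b = generate_genome(cfg)
        from famsurveyor.identify import select_longest_isoform

        rep_a = select_longest_isoform(b.annotation)
        rep_b = {f"X{g}": s for g, s in rep_a.items()}
        genes_b = [
            GeneModel(f"X{g.gene_id}", g.chromosome, g.start, g.end)
            for g in b.annotation
        ]
        ann_b = GeneSet(genes_b)
        merged = dict(rep_a) | rep_b
        anchors = homolog_pairs(
            merged, within_genome=False,
            cross_ids=(set(rep_a), set(rep_b)),
        )
        fam_b = {f"X{g}" for g in b.truth.family_members}
        blocks, fam_count = cross_species_synteny(
            anchors, b.annotation, ann_b,
            family_a=b.truth.family_members, family_b=fam_b,
        )
        covered = {a.key for bl in blocks for a in bl.anchors}
        assert len(covered) == len(rep_a)  # every gene sits in a block
        assert fam_count == len(b.truth.family_members)

    def test_shuffled_gene_order_destroys_blocks(self):
        # shuffle with longest increasing run 4 and decreasing run 3:
        # below the block threshold in either orientation
        perm = [2, 1, 0, 5, 4, 3, 8, 7, 6, 11, 10, 9]
        n = len(perm)
        ids_a = [f"a{i}" for i in range(n)]
        ids_b = [f"b{i}" for i in perm]
        ann_a = _annotation({"chr1": ids_a})
        ann_b = _annotation({"chr1": ids_b})
        anchors = [
            AnchorPair(*sorted((f"a{i}", f"b{i}")), score=1.0, within_genome=False)
            for i in range(n)
        ]
        blocks, _ = cross_species_synteny(anchors, ann_a, ann_b, min_anchors=5)
        assert blocks == []
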