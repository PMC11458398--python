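# Methods

This note documents the models and procedures famsurveyor implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Family identification

The identifier is a consensus-domain scan: the family domain is a string
over the 20 amino acids with `.` marking free positions, and a protein is a
member when some window matches the consensus with at most `max_mismatch`
mismatches at the informative positions (default 13, the budget commonly
used for the plant bHLH consensus). The scan is exhaustive over windows;
a membership call requires a *full-length* window, so truncated or partial
domains never qualify. Profile-HMM searching is deliberately out of scope:
an externally produced HMM hit list can be intersected via
`scan_proteome(..., hmm_hits=...)`, but the consensus rule is the only
identifier implemented here because it is fully specified and exactly
testable. Whether a practitioner applies the mismatch rule to all
candidates or only ambiguous ones varies between studies; this pipeline
applies it uniformly.

Longest-isoform selection breaks length ties by the lexicographically
smallest isoform id (and logs the tie). Family names are assigned by
chromosome (natural numeric order; scaffolds and contigs after all
chromosomes), then ascending start coordinate, zero-padded to the decimal
width of the family size.

Molecular weight is the sum of residue average masses minus one water per
peptide bond (Biopython's average-mass table, reported in kDa). The
isoelectric point solves net charge = 0 by bisection on the
Henderson–Hasselbalch charge curve with a ProtParam-convention pKa table
(N-terminus 9.094, C-terminus 2.869, K 10.67, R 12.10, H 6.04, D 3.872,
E 4.412, C 7.555, Y 10.85); the curve is strictly decreasing in pH, so
bisection on [0, 14] converges unconditionally (tolerance |charge| < 1e-4).
An alternative pKa table can be passed in.

## Alignment and conservation

Pairwise global alignment is Gotoh's affine-gap dynamic programming
(BLOSUM62; opening a gap costs −10 for its first residue and −0.5 for each
extension). Traceback ties prefer diagonal over up (gap in the second
sequence) over left, which fixes a deterministic optimal alignment. The
multiple alignment is progressive: UPGMA guide tree on score-derived
distances d = 1 − score/min(self-scores), then profile–profile alignment
with the same gap model, where a column pair scores the expectation of the
substitution matrix under the two frequency profiles. For ~60-residue,
nearly gap-free family domains this is adequate; it is not a general MSA
replacement (no iterative refinement, no consistency scoring).

Column conservation uses the sequence-logo convention: gaps are excluded
from the frequency vector; the conservation ratio is the modal residue
frequency; entropy is −Σ fₐ ln fₐ normalized by ln 20, so an invariant
column scores exactly 0 and a column uniform over all twenty amino acids
scores exactly 1 (a raw-nats mode exists). Conserved sites require
ratio > 0.5 *and* entropy < 0.6; highly conserved sites require
ratio ≥ 0.8. All three thresholds are arguments. Columns with gap fraction
above 0.5, and all-gap columns, are flagged.

## Phylogeny and subfamilies

Protein distances support p-distance, the Poisson correction
d = −ln(1 − p) and the Kimura correction d = −ln(1 − p − p²/5); pairwise
deletion drops, per pair, only the columns gapped in that pair, complete
deletion drops every gapped column. Kimura + pairwise deletion is the
default stand-in for maximum-likelihood JTT distances, which are not
implemented — topology-level results, not branch lengths, are the tested
contract. Saturated corrections flag the distance infinite, and
tree-building refuses non-finite inputs by design.

Neighbor joining follows the Saitou–Nei Q criterion; ties in Q are broken
by the lexicographically smallest pair of cluster representatives, and
negative branch lengths are clamped to zero with a warning. On additive
matrices the algorithm provably recovers the generating topology and
branch lengths; the test suite checks this exactly (random additive trees,
RF distance 0, patristic distances to 1e-9).

Bootstrap supports resample alignment columns with replacement and count,
for each internal bipartition of the full-data tree, the percentage of
replicate trees containing it — supports are mapped onto the point
estimate, not a consensus topology. Subfamily assignment walks from each
query leaf toward the root until the enclosing clade contains at least one
labeled reference leaf and takes the majority reference label; ties become
"orphan". This treats the (arbitrarily rooted) NJ tree as rooted, which is
the usual practice when references are spread across all subfamilies.

Family-size evolution on a species tree is Wagner parsimony: Sankoff
dynamic programming over integer ancestral states 0..max(observed) with
cost |i − j| per branch, ties resolved toward minimal total change then
the smaller ancestral count. This replaces birth–death likelihood methods
(e.g. CAFE-style λ estimation) deliberately: at desk scale the reported
artifact is per-branch expansion/contraction counts, which parsimony
reproduces structurally and which an exhaustive enumeration oracle can
verify. Subfamily-size variability reports the per-subfamily coefficient
of variation (sample SD, n−1) and the Pearson correlation of SD against
mean with its two-sided t-based p.

## Duplication modes and Ka/Ks

Homolog pairs are called by normalized global alignment score
score(a,b)/min(selfscore(a), selfscore(b)) with default threshold 0.5.
The threshold was calibrated once against an empirical null of unrelated
uniform-composition proteins, whose normalized scores stay below ~0.1;
genuinely duplicated sequences score near 1, and sequences sharing only a
~60-residue domain inside unrelated backgrounds score well below 0.5.
A database-size-dependent E-value threshold is meaningless in this
self-contained setting, which is why a score threshold replaces it. The
k-mer prefilter (≥ 3 shared 5-mers) only skips pairs that could not reach
the threshold; prefilter-on/off agreement is asserted in tests.

Collinear blocks chain anchors per chromosome pair by longest-chain
dynamic programming, separately for the two orientations, with strict rank
monotonicity and per-step gaps ≤ `max_gap` (default 25) on both axes;
chains shorter than `min_anchors` (default 5, the MCScanX convention) are
dropped, and extraction repeats after removing a found block's anchors.

Classification applies the precedence WGD > TD > PD > TRD > DSD per pair:

* **WGD** — the pair itself is an anchor pair of a within-genome block;
* **TD** — same chromosome, adjacent ranks;
* **PD** — same chromosome, rank difference in (1, `proximal_max`]
  (default 10);
* **TRD** — a best-hit pair with exactly one gene inside the rank span of
  any collinear block (the "ancestral locus" approximation: span
  membership within the analyzed genome, rather than outgroup-epoch
  logic — a documented simplification);
* **DSD** — the remaining best-hit pairs.

Transposed/dispersed calls are restricted to pairs that are the
best-scoring hit of at least one member; leftover weak pairs get no
record. A per-gene summary takes each gene's highest-precedence mode.

Ka/Ks is NG86: per codon, the synonymous site count is the fraction of the
nine single-nucleotide changes that preserve the amino acid (changes to a
stop codon count as nonsynonymous), averaged over the two sequences;
differences between codons average synonymous/nonsynonymous counts over
all substitution orders, excluding pathways through stop codons unless
every pathway is blocked; both proportions receive the Jukes–Cantor
correction d = −¾ ln(1 − 4p/3), with p ≥ ¾ flagged as saturated and
ks = 0 leaving the ratio undefined rather than infinite. NG86 was chosen
over transition/transversion-weighted models because it is exactly
specifiable and verifiable against a brute-force counting oracle; the
regime-level conclusion (ratio < 1, purifying selection) is what the
pipeline reports, not third-decimal agreement with other estimators.

## Co-expression

Features (family genes, enzyme genes, metabolites) enter one correlation
computation after per-feature z-scaling inside the k-means step and raw
Pearson correlation for networks. The expression filter keeps features
with any sample ≥ 1 (so a value of exactly 1 is kept). Pattern classes —
not detected (all zero), low (max < 1), tissue-specific (τ ≥ 0.8), broad —
use the tau specificity index computed on log2(x+1)-scaled, max-normalized
profiles; the class thresholds are explicit arguments because published
three-way pattern splits are rarely defined quantitatively.

The soft threshold β is the smallest power in 1..20 whose signed
scale-free fit R² (regression of log10 frequency on log10 binned
connectivity, sign from the negative slope — the WGCNA convention) reaches
0.8, else the argmax power, flagged. Unsigned adjacency |r|^β feeds the
topological overlap TOMᵢⱼ = (Σ_{u≠i,j} aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ)+1−aᵢⱼ)
with TOMᵢᵢ = 1; below three nodes TOM degenerates to the adjacency
(documented). Edges with TOM above `min_weight` (default 0.3) form the
network; hubs are ranked by degree with ties broken by id. Module
detection by dendrogram cutting is intentionally not implemented — the
reported artifacts are the thresholded TOM network and its hubs.
Enrichment is the hypergeometric upper tail with Benjamini–Hochberg FDR.

## Interaction projection

Orthology to the reference species uses reciprocal best hits on the same
normalized alignment score (default floor 0.3; best-hit ties drop the pair
with a warning, keeping the map a partial function). Every reference edge
whose endpoints are both hit projects to all corresponding member pairs —
many-to-one orthology is allowed, because family expansions are exactly
the situation under study — and self-edges are never emitted. Interaction
*prediction* is out of scope; the reference edge list is an input file.

## qPCR

ΔCt(rep) = Ct_target(rep) − mean Ct_ref(group); ΔΔCt subtracts the
calibrator group's mean ΔCt; fold = 2^−ΔΔCt. Group statistics run on
per-replicate fold values by default (matching how such results are
plotted); a ΔCt-scale analysis is a caller-side one-liner since the table
carries both columns. One-way ANOVA handles the all-constant degenerate
case as F = 0, p = 1 with a log flag.

Duncan's multiple range test sorts the k group means and compares the
range of every span of p ordered means against
R_p = q(α_p, p, df_error)·√(MSE/n_h), α_p = 1 − (1−α)^(p−1), with n_h the
harmonic mean group size; the studentized-range quantile comes from
scipy's numerical CDF inversion (cached per (α, p, df)). A span whose
range fails R_p protects all its sub-spans (the standard stepwise rule),
which makes the non-significance relation a union of intervals in mean
order; the compact letter display assigns one letter per maximal
non-significant interval, so two groups share a letter exactly when the
procedure does not separate them — the duality is asserted in tests, both
directions. Under a complete null the probability that any two of k
groups receive distinct letters is 1 − (1−α)^(k−1), which equals the
nominal α only at k = 2; the Monte-Carlo calibration test therefore uses
two groups (and the k = 3 rate is checked against its own analytic value).

## The synthetic-data generator

The generator emulates the full input bundle of a family survey with
planted truth, and its defaults are the study conditions the test suite
and acceptance script run under:

* **Genome** (default 8 chromosomes × 60 genes): background proteins are
  uniform over the 20 amino acids (composition realism is not needed by
  any downstream contract), lengths 140–240. Family genes embed a mutated
  consensus copy; the number of mutated informative positions is
  ⌊mismatch_rate × n_informative⌋ (default rate 0.1 → 5 mismatches against
  a budget of 13), so every planted member is identifiable by
  construction, while a random background window matching within the
  budget is astronomically improbable.
* **Duplication planting** (default plan WGD 4, TD 1, PD 3, TRD 11,
  DSD 48; 67 pairs): collinear segments (duplicated runs of ≥ 5 identical
  background anchor pairs) occupy distinct chromosome pairs; WGD family
  pairs are planted *as anchors* inside a segment; TRD parents are
  inserted *between* anchors of an "ancestral" segment (inside its span
  but not anchors themselves) with their partners placed outside any
  span; TD/PD pairs are placed at rank offsets 1 and 3; DSD pairs and TRD
  partners are spread over the remaining chromosome pairs with at most
  min_anchors − 1 anchors per pair of chromosomes, so no spurious chain
  can ever reach the block threshold. This makes the planted configuration
  satisfy each mode's definition exactly, which is what lets the
  recovery tests demand precision = recall = 1.
* **CDS** uses one fixed codon per amino acid (deterministic
  back-translation); the second member of each planted pair carries 2
  nonsynonymous changes outside the domain plus 4 synonymous codon swaps,
  so NG86 yields ks > 0 and ratio < 1 — a purifying-selection regime.
* **Expression** (default 18 samples, emulating 6 developmental stages ×
  3 replicates): cluster members share a structured mean profile (high in
  one sample, baseline elsewhere; later clusters inverted) plus Gaussian
  noise. Co-expression modules are built geometrically: the hub is a
  standardized latent profile z, and each member is cos θ·z + sin θ·eᵢ
  with the eᵢ exactly orthonormal in centered sample space, so hub–member
  correlation is exactly cos θ = 1/√(1+s²) and member–member correlation
  exactly cos²θ (s = noise_sd / latent amplitude 3; default noise 1.8
  gives 0.857 vs 0.735). At β = 6 this puts hub edges above and
  member–member edges below the TOM 0.3 cutoff in every realization — the
  hub is the designed center, not a lucky draw. A few all-below-1 genes
  exercise the expression filter.
* **qPCR**: target Ct = baseline − log2(planted fold) + noise, reference
  Ct constant + noise (default 4 groups × 3 replicates, folds 1/4/0.5/2,
  Ct noise SD 0.15).

What the generator does **not** emulate: realistic amino-acid composition
or codon usage, intron structure, sequencing noise, count-based expression
error models, batch effects, or metabolite chemistry. Passing the planted
recovery tests therefore demonstrates the *algorithms* implement their
definitions correctly under clean, feasibility-checked conditions; it does
not certify performance on noisy real genomes, where domain divergence,
fragmented assemblies and tandem arrays blur every boundary the
classifier's rules draw sharply.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (NumPy `default_rng`); the
pipeline manifest records seeds, parameters and input SHA-256 hashes, and
a rerun reproduces every output byte. The test suite and acceptance
script run at desk scale by design — genomes of a few hundred genes,
alignments of ~60-residue domains, 10–100-instance oracle comparisons,
2000-replicate Monte-Carlo calibrations — sizes chosen so the exhaustive
oracles (alignment enumeration, pathway counting, ancestral-state
enumeration, chain enumeration) remain tractable while still exercising
every rule and tie-break.
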