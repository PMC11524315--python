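# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic study does and does not establish.

## Scope and data model

The pipeline analyses a catalogue of lignin-pathway genes on a
tetraploid genome whose chromosomes belong to two homoeologous
sub-genomes (At/Bt; names `chrA01`–`chrB19`, scaffolds for unplaced
genes). Coordinates are 1-based inclusive everywhere inside the
package; the only half-open conversion happens in the BED writer. Gene
annotations travel in GFF3 gene features with two custom attributes,
`family=` and `subgenome=`, so a single file carries the canonical
catalogue; when `subgenome` is absent it is inferred from the leading
A/B of the chromosome name.

## Family assignment

A candidate protein is assigned to the best-scoring of the eleven
families by optimal local alignment (BLOSUM62, gap open −11 / extend −1)
against per-family reference sequences, gated by a required-domain
check: the family's short protein patterns must occur as exact
substrings. The score threshold (default 100) plays the role a
similarity-search E-value cutoff would play; raw score is used because
the package targets recovery on catalogues of hundreds of genes, not
database-scale search statistics. Ties are broken by higher identity and
then family label, so assignment is independent of reference order.
Domain patterns here are presence/absence gates, not profile models —
adequate because the references and candidates are family-specific by
construction, and clearly weaker than profile HMMs on remote homologs.

## Duplications and hotspots

Duplicate detection aligns CDS pairs (match +1 / mismatch −1 / gap −2,
local) and keeps a pair when the aligned region covers **more than** 80%
of the longer gene and its identity (matching columns over aligned
columns, gap columns included) is **more than** 80% — both strict, per
the wording of the rule. Identity and coverage come from one optimal
alignment; when several alignments tie, the first reported optimum is
used deterministically. The pipeline restricts the search to same-family
pairs: the catalogue is family-structured and cross-family random CDS
cannot approach the 80/80 thresholds, so this is a pure n² saving; the
detector itself evaluates every pair it is given.

"Tandem" is not defined quantitatively in the source analyses; the
package uses same chromosome and an inter-gene gap of at most 100 kb,
exposed as configuration.

A hotspot is a run of at least 5 family-assigned genes (sorted by
start) whose span, first start to largest end, is **strictly** under
5 Mb. Reported hotspots are maximal by inclusion — no reported run is
contained in a larger qualifying run — and may overlap each other.
Merging overlapping runs unconditionally was rejected because a merged
region can exceed the 5 Mb definition it is supposed to satisfy; under
maximality, two overlapping runs merge exactly when their union still
qualifies.

## Phylogeny and family classes

Distances between aligned rows use pairwise deletion (per pair, only
columns where neither row has a gap) giving the difference fraction
*p*, corrected for multiple hits with the Poisson model
*d* = −ln(1 − *p*). A pair with *p* ≥ 1 or no comparable column is an
error rather than a silently clamped value. Trees are built with
neighbor joining (Saitou–Nei Q criterion); ties in Q are resolved by
first minimum in row-major order, so results are deterministic.
Negative branch-length estimates are clamped to zero; topology is
unaffected. NJ is guaranteed to recover the generating topology on
additive matrices, which the tests exercise against an independent
implementation. Bootstrap support is the percentage of
column-resampled replicates whose NJ tree contains the same
bipartition; 1000 replicates by default, seeded.

Family classes formalize three patterns over the taxon groups
(herbaceous monocots, herbaceous dicots, woody species):

* **Ib** — some internal vertex partitions the leaves into exactly the
  three groups (each a clade); checked first,
* **Ia** — otherwise, the monocots form one side of some split, which
  leaves the herbaceous dicots embedded among the woody taxa,
* **II** — otherwise: groups interleave (expanded family).

Ib is tested before Ia because any tripartition tree also has a
monocot-only split; the distinguishing feature is whether the
herbaceous dicots separate from the woody clade. The call is invariant
to leaf order and rerooting (verified by property test).

## Expression and DEGs

FPKM is counts × 10⁹ / (gene length × library size). The expression
filter keeps genes with FPKM **strictly** above 1 in at least one
replicate. Per gene, a two-sided Welch t-test on log₂(FPKM + 1)
compares the tall and short genotype groups; the per-gene test is a
configurable hook, while the decision rule is fixed: |log₂ fold
change| ≥ 1 (fold change on (mean + 1)-shifted FPKM so all-zero genes
are defined) and BH-adjusted p < 0.05. The t-test stands in for a
negative-binomial count model; it is deterministic, assumption-light at
n = 6 vs 6, and on the synthetic study's planted 4-fold effects it
reaches full sensitivity, but it is less powerful than count models for
weak effects at low counts, which bounds what the recovery numbers say
about marginal real-data DEGs.

## Phenotypes

Lignin content is 2.184 × ΔA / W (mg per g dry weight), the conversion
of the spectrophotometric acetylation assay; records carrying all three
quantities are validated against the identity. The height–lignin
association is the Pearson correlation over genotype means (default;
n = genotypes) with the exact t reference distribution for the p-value
— a permutation null is pointless at n = 4. A replicate-level mode
exists but is not the default, matching how the published statistic is
reproduced. Note that |r| = 0.62 at n = 4 is not significant under the
t test (p ≈ 0.38); the package reports the computed p rather than a
significance claim.

## Promoters and motifs

The promoter is the 2000 bp upstream of the annotated gene start (the
annotation model carries gene spans, not CDS sub-features, so the gene
start is the proxy for the start codon — a documented simplification).
Minus-strand promoters are reverse-complemented; promoters are
truncated at chromosome edges. Scanning is exact IUPAC matching on both
strands (implemented with lookahead regular expressions, verified
against a position-by-position oracle); every overlapping occurrence is
reported, and N in the promoter matches nothing. No position-weight
scoring is attempted. The bundled vocabulary of 23 motifs tagged with
TF-family names (MYB, AP2, bZIP, MADS, NAC, ARF, WRKY) is a synthetic
fixture list, not a curated database.

## Synthetic study

The generator emulates the study design with known ground truth, fully
deterministic per seed (byte-identical files):

* **Genome** — 38 chromosomes of 10–20 Mb, 11 × 18 = 198 genes, 26 of
  them unplaced on scaffolds; 7 hotspots of 5–6 genes within 2.5–4 Mb
  on chrA01/A08/A11/B08/B11/B16/B18; 6 duplicate pairs at identities
  0.85–0.95 and coverages 0.90–1.0, four tandem. Background genes are
  spaced ≥ 1.5 Mb apart and ≥ 5 Mb from hotspot members so that the
  planted hotspots are exactly the qualifying regions.
* **Sequences** — proteins are family ancestors with 12% random
  substitutions (the required-domain octamer protected); CDS are
  independent random DNA except duplicate copies, which are truncated,
  substitution-mutated copies of their parent. Substitutions only — no
  indels — so pair identity and coverage are controlled exactly, which
  is what makes the strict 80/80 boundary testable. An
  `engineer_duplicate_pair` helper redraws until the *measured* optimal
  alignment equals the target, because a substitution pattern
  occasionally admits a gapped alignment one point better than the
  planted one. No codon structure, introns or realistic evolution are
  modelled.
* **Counts** — negative binomial with mean/dispersion parameterization
  (variance μ + αμ², α = 0.05), 4 genotypes × 3 replicates; 60% of
  genes expressed with lognormal base means (median 5000 — deep enough
  that one stray read cannot pass the FPKM filter), the rest silent;
  23 planted DEGs at |log₂FC| = 2, 19 up in short and 4 up in tall
  genotypes, mirroring the predominance of down-regulation in tall
  plants.
* **Phenotypes** — genotype heights by height class (tall ≈ N(170, 20),
  short ≈ N(95, 20) cm), lignin drawn to hit a target genotype-mean
  correlation of −0.62 within ±0.1 by rejection sampling; ΔA and W are
  back-computed so the assay identity holds to machine precision.
* **Promoters** — 2000 bp random background; each motif planted with
  probability 0.5 per promoter at a recorded offset and strand, planted
  instances kept disjoint so every recorded hit is recoverable.
  Background chance matches are allowed and deliberately unrecorded.
* **Family alignments** — 500-column protein alignments simulated along
  explicit guide topologies over nine taxa (two monocots, two
  herbaceous dicots, five woody), one per planted class: Ia keeps the
  dicots interleaved among the woody taxa, Ib gives each group a clade,
  II crosses groups at the cherries. Substitution probabilities of
  0.05–0.06 per branch leave the signal strong enough for NJ to recover
  the guide reliably at 500 columns.

Because the generator plants clean, well-separated signals, passing
recovery tests demonstrates correctness of the detectors and decision
rules — not their power on real genomes, where duplicate identities
cluster near thresholds, hotspots abut other genes, dispersions vary
per gene, and alignments contain indels.

## Problem sizes and numerics

Default problem sizes (198 genes, 500-column alignments, 1000 bootstrap
replicates, 200-gene × 50-replicate null simulations) complete in about
a minute on one CPU; the test suite uses smaller seeded instances of
the same generators. Brute-force oracles (full Smith-Waterman DP,
subinterval enumeration, naive scans, step-up BH) run on reduced sizes
where they are exact. Floating-point comparisons in validation use
relative tolerances around 1e-6; the assay back-computation is exact to
1e-9 by construction.

## Known limitations

* Raw-score family gating has no E-value calibration; thresholds are
  tuned to the synthetic scale.
* The DEG test is a log-scale t-test, not a count model; see above.
* Promoter extraction uses gene starts, not annotated start codons.
* The class-II label is "neither Ia nor Ib": there is no quantitative
  measure of interleaving.
* The bootstrap resamples columns independently, ignoring any site
  correlation a real alignment would have.
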