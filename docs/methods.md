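# Methods

This note records the models, estimators, numerical conventions and design
choices behind `barcodekit`, and what the synthetic-data generator does and
does not emulate.

## Distances (`distmat`)

**K2P distance.** For two aligned sequences, sites where either carries a
gap, `N`, or an IUPAC ambiguity code are excluded (*pairwise deletion*).
Over the remaining comparable sites, with transition proportion *P* and
transversion proportion *Q*,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Conventions:

* `min_overlap` (default 50 sites) — pairs with fewer comparable sites are
  MISSING (NaN). The default suits markers of 200+ bp with patchy indel
  regions; lower it for toy alignments.
* Saturation — when `1-2P-Q <= 0` or `1-2Q <= 0` the logarithm is
  undefined; such pairs carry an infinite sentinel and are excluded from
  all min/max summaries (this mirrors distance software that reports such
  pairs as undefined). For tree building, where a number is unavoidable,
  saturated entries are capped at 1.5× the largest finite distance.
* Ambiguity codes contribute nothing to distances: K2P has no defined
  treatment for partial observations, so they are treated as missing.
* The all-pairs matrix is computed via one-hot indicator matrix products
  (exact integer counts, float64 logs), so bootstrap replicates over
  hundreds of sequences are cheap; entries agree with the scalar
  per-pair path to full precision.

**Barcode gap.** Per species: `max_intra` over conspecific pairs
(undefined for singletons), `min_inter` to any heterospecific sequence,
`has_gap = min_inter > max_intra` (*strict* — a tie is a failed gap, "above
the 1:1 line"). The percentage is reported over species with a defined
`max_intra` (singletons cannot fail or pass), rounded to one decimal.
`min_inter` is per species against all heterospecifics, the standard
barcode-gap reading, not per species pair. Hybrid-group specimens are
excluded from all intra/inter partitions: their distance to either parent
is neither class.

**Marker summary.** GC content counts G+C+S over unambiguous bases;
variable sites are columns with ≥ 2 distinct unambiguous bases; gap columns
are columns with a gap in ≥ 1 sequence (the column reading of "number of
alignment gaps", chosen because indel-rich plastid spacers are described by
how much of the alignment is gap-affected).

## Identification (`identify`)

Leave-one-out over all sequences with at least one valid conspecific (a
query without any conspecific reference could never succeed, and such
sequences are excluded from the denominators).

* **BM**: the tie set at the minimum distance (ties within 1e-12) decides:
  all conspecific → *success*; mixed including the query's species →
  *ambiguous*; none conspecific → *incorrect* (a tie among several wrong
  species is still *incorrect* — the match set carries only mismatched
  names).
* **BCM**: `best_distance > threshold` → *unidentified*; otherwise BM
  rules. The default threshold is the 95th percentile (linear
  interpolation) of all intraspecific pairwise distances. A fixed distance
  cutoff (e.g. a flat 5% rule) can be supplied instead — the percentile
  reading is the default because it adapts to the marker's intraspecific
  spread, which is the rule's purpose; both readings are defensible.

BCM can only demote BM verdicts to *unidentified*, so BCM success ≤ BM
success always.

## Trees and monophyly (`phylo`)

* **NJ** is Saitou–Nei with the standard Q-criterion, implemented
  in-package (an independent library implementation serves as a
  cross-check in the tests). Negative branch-length estimates are clamped
  to zero with the deficit moved to the sibling branch, preserving the
  joined pair's path length. On additive matrices the input is reproduced
  exactly. MISSING entries are refused rather than imputed — callers
  filter sequences first.
* **Bootstrap**: alignment columns resampled with replacement; each
  internal edge of the point-estimate tree is annotated with the
  percentage of replicate trees containing the same bipartition.
  Annotating the point tree (rather than building a bootstrap consensus)
  keeps branch lengths meaningful; both conventions exist in the field.
* **Monophyly**: a species passes iff some bipartition separates exactly
  its leaves AND that edge's support strictly exceeds 50% (configurable).
  Support attaches to bipartitions, not nodes, so verdicts are invariant
  to rerooting; `reroot_at_edge` preserves that association (plain Newick
  rerooting silently migrates support labels). Singleton species are
  trivially monophyletic but excluded from the percentage, consistent
  with the valid-conspecific filter used everywhere else. Edges without
  support values pass (for unannotated external trees). When several
  trees are scored (NJ plus external ML/BI), the reported value is the
  minimum — the conservative choice.
* **Partitioned scoring** reproduces the fallback of assessing monophyly
  within taxon partitions (e.g. per order, when a joint tree is
  unavailable): each species is tested against the leaves of its own
  partition only, and a species alone in its partition counts as
  monophyletic.

## Combination (`combine`)

All non-empty marker subsets are candidate barcodes (15 for four markers).
Concatenation is complete-case: specimens missing any constituent marker
are dropped, because gap-padding would mix pairwise-deletion denominators
across markers; `pad_missing=True` provides the padded variant for
sensitivity analysis. Concatenated distances are therefore site-pooled
K2P over the joined alignment — not the mean of per-marker distances — and
the tests pin that semantics.

## Diversity (`popdiv`)

Per species and per population (populations default to collection sites):

* Watterson `θ_w = S / (a_{n-1} L)` with `a_k = Σ 1/i`; *S* counts
  segregating columns among the subset, *L* counts columns where every
  subset sequence is unambiguous (complete deletion within the subset —
  *S* must be counted on a fixed site set).
* `π` = mean over unordered pairs of per-site p-distance with pairwise
  deletion (the conventional π; K2P correction is not applied).
* For n = 2 the two estimators coincide exactly.
* The table-level driver defaults to `min_n = 3` individuals (diversity
  from a single pair says little); the estimators themselves accept n ≥ 2.
* Both are per-site quantities (values like 0.001/bp), matching how such
  surveys report them.

Intraspecific distances are additionally split into within- vs
between-population pairs for the standard two-class scatter.

## Marker comparison (`markercmp`)

The pairing unit is the **species pair**: for each unordered species pair
present in both markers, the summary divergence is the mean of all
cross-species sequence-pair distances (the only unit consistent with rank
sums of the form N(N+1)/2 at N = C(species, 2); min/median summaries are
available). Wilcoxon signed-rank: zero differences dropped, midranks for
tied |d|, exact p by sign enumeration for N ≤ 25 (convolution over rank
values, so ties are handled exactly), otherwise normal approximation with
tie and continuity corrections. `cl_effect = W⁻/(W⁻+W⁺)` — 0 when the
"after" marker dominates every pair, 1 in the reverse case.

## Hybrids (`hybrids`)

Parental species are represented by strict-majority consensus sequences;
columns without a majority are excluded. Diagnostic columns are those
where both parent consensuses carry different unambiguous bases; an F1 is
expected to carry the two-base IUPAC code there (A/G→R, C/T→Y, …).
Parent-pair inference scans all candidate pairs with ≥ 3 diagnostic
columns and calls the pair maximizing the heterozygous fraction when it
reaches 0.8 (real F1s sit near 1.0; the margin absorbs consensus noise);
exact ties are unresolved, and sub-threshold cases report the best pair
without calling it. The maternal parent is the one whose chloroplast
consensus is closer to the hybrid's plastid sequence by ≥ 1 substitution;
equidistance is unresolved. Haplotype collapsing counts SNV columns and
maximal gap-affected runs (one indel event each, however wide) and groups
individuals by their variant-state vectors.

Known limit: when a third candidate species is barcode-identical (or
nearly so) to a true parent, the pair is unidentifiable in principle; the
implementation then reports a tie rather than guessing.

## Synthetic communities (`synthetic_data`)

The generator's defaults state the emulated world: ~30 species (40/20/40%
true-mangrove/associate/coastal), a pure-birth species tree scaled to
crown height 0.15 substitutions/site, four markers

| marker | length | rate | GC | indels | recovery | genome |
|---|---|---|---|---|---|---|
| rbcL | 570 | 0.25 | 0.44 | – | 98.6% | plastid |
| ITS2 | 679 | 1.00 | 0.60 | – | 87.9% | nuclear |
| matK | 902 | 0.60 | 0.34 | few | 70.0% | plastid |
| trnH-psbA | 1411 | 0.80 | 0.28 | many | 72.8% | plastid |

2 populations per species drawn from a 10-site pool, 3–6 individuals per
population, within-population θ = 0.002/site (scaled by the marker rate),
between-population stem divergence 0.002, and 2 F1 hybrids. Recovery
probabilities and alignment lengths mirror the sequencing outcomes of the
emulated community survey; rate multipliers reproduce the qualitative
interspecific ordering typical of these markers (ITS2 > trnH-psbA > matK
> rbcL at the distance level); tree height and θ are round values
consistent with the distance scales such surveys report (intraspecific
maxima of a few %, diversity ~0.001/bp).

Design choices:

* **Substitution process is K2P itself** (κ = 2), matched to the analysis
  distance so that distance recovery is analytically checkable. GC bias
  enters through the root composition only (K2P's stationary distribution
  is uniform; at these depths composition decays negligibly).
* **Within-population genealogies are Kingman coalescent trees** (not
  star genealogies): coalescence times Exp(j(j−1)/2), mutation rate θ/2
  per unit time. Under a star genealogy E[θ̂_w] = nθ/(2a_{n−1}) ≠ θ — a
  ~9% bias at n = 4 — whereas the coalescent makes both π̂ and θ̂_w
  unbiased, which the parameter-recovery tests verify to 3 Monte-Carlo
  standard errors. The coalescent is also only ~20 lines.
* **Hybrid parents** are drawn, by default, among species that differ
  from *every* other species by ≥ 8 sites on the typing (nuclear) marker
  (`hybrid_parent_rule="diagnosable"`). This states the field situation —
  named hybrids arise between well-differentiated, unambiguously
  identifiable species — and keeps the recovery task well-posed; pure-birth
  trees otherwise routinely contain sister species a hand-full of
  substitutions apart, for which no method could distinguish the true
  parent from its twin. `"random"` draws any distinct pair. The first
  parent is the designated mother; F1s are IUPAC-heterozygous at every
  parental diagnostic site of the nuclear marker by construction and carry
  the mother's plastid sequences.
* **Indels** are full-column gap events shared by random species subsets
  (geometric widths, mean ≈ 7), so emitted data are aligned by
  construction and no aligner is involved.
* Each individual's each marker is dropped independently with 1 −
  recovery, emulating PCR/sequencing failure.

What the generator does **not** emulate: recombination and gene-flow,
selection, rate heterogeneity across sites, alignment error (real
trnH-psbA alignments are far messier than full-column gaps — length
variation can leave almost every column gap-affected), later-generation
hybrids, and
chloroplast/nuclear effective-size differences (θ is shared across
markers up to the rate multiplier). A green test therefore establishes
correctness of the estimators and decision rules on data satisfying the
stated model, not robustness to alignment artifacts or model violation.

The `fixtures` module complements the stochastic generator with
hand-built datasets whose verdicts were enumerated by hand once and
frozen: perfect gaps, an engineered gap failure, exact BM tie cases,
NJ-provable paraphyly, an F1 trio with known mother, subspecies
haplotypes, and missing-marker patterns.

## Pipeline

`run_evaluation` derives one child seed per candidate barcode from the
master seed (`numpy.random.SeedSequence.spawn`), so the whole 15-barcode
report is reproducible end to end and insensitive to barcode order.
Reported percentages are rounded to one decimal, thresholds to four.

## Numerical conventions

* Tie tolerance for nearest-neighbour distances: 1e-12 (absolute).
* BCM threshold percentile: linear interpolation between order statistics.
* NJ joins break exact Q-ties deterministically by lowest index pair.
* Bootstrap with < 3 sequences, matrices with MISSING entries, empty
  specimen intersections in concatenation, and single-species gap analyses
  raise immediately rather than degrade.
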