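# barcodekit

Evaluation toolkit for community-scale DNA barcoding of plants.

When a regional flora — for example a mangrove community sampled at many
coastal sites — is to be identified from short marker sequences (rbcL,
matK, trnH-psbA, ITS2), the practical question is: *which marker, or which
concatenation of markers, discriminates these particular species?*
`barcodekit` implements the three standard answers and everything needed
to compute them from aligned FASTA files plus a specimen table:

1. **Genetic distance — the barcode gap.** For each species *s*, compare
   its maximum intraspecific K2P distance with its minimum distance to any
   heterospecific sequence; the species shows a gap when
   `min_inter(s) > max_intra(s)` (the point lies above the 1:1 line of the
   classic scatter plot). Distances follow the Kimura 2-parameter model,

   `d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`,

   with *P*, *Q* the transition/transversion proportions over comparable
   sites (pairwise deletion of gaps, Ns and ambiguity codes).
2. **Similarity — Best Match / Best Close Match.** Leave-one-out nearest
   neighbour identification with verdicts *success / ambiguous /
   incorrect*; BCM additionally declares a query *unidentified* when its
   best match exceeds a threshold (by default the 95th percentile of all
   intraspecific distances).
3. **Phylogeny — bootstrap monophyly.** Neighbor-joining trees on K2P
   distances with nonparametric (column-resampling) bootstrap; a species
   passes when its individuals form a single clade with support > 50%.
   Externally built trees (ML, Bayesian) can be scored through the same
   Newick interface, with the lowest percentage across methods reported.

Around that core: exhaustive multi-marker concatenation (4 markers → 15
candidate barcodes), Wilcoxon signed-rank comparison of interspecific
divergence between markers (with common-language effect size
`W⁻/(W⁻+W⁺)`), per-population diversity estimators (Watterson's
`θ_w = S/(a_{n-1} L)` and nucleotide diversity π), F1-hybrid diagnosis
from IUPAC-heterozygous sites with maternal-parent assignment via the
chloroplast, and haplotype collapsing for infraspecific variants.

Because real community datasets are large and archived elsewhere, the
package ships a **synthetic community generator** (`synthetic_data`) that
emulates the sampling design — tens of species in true-mangrove /
associate / coastal groups, several sites with 3–6 individuals per
species per site, four markers with realistic rate, GC, indel and
PCR-recovery profiles, plus F1 hybrids — and emits a ground-truth
manifest so every pipeline stage is testable offline.

## Worked example

```python
from barcodekit import pipeline, synthetic_data as sd

cfg = sd.SimConfig(seed=7, n_species=12)          # 4 default markers
dataset, truth = sd.simulate_community(cfg)       # 112 specimens
rows = pipeline.run_evaluation(dataset, pipeline.EvalConfig(seed=7, bootstrap_reps=100))
```

`rows` holds one line per candidate barcode (15 for four markers); the
first four render as:

```
           R: gap 100.0%  BM 100.0%  BCM 100.0%  monophyly 100.0%
           I: gap 100.0%  BM 100.0%  BCM 100.0%  monophyly 100.0%
           M: gap 100.0%  BM 100.0%  BCM  98.8%  monophyly 100.0%
           T: gap 100.0%  BM 100.0%  BCM 100.0%  monophyly 100.0%
```

Read: with 12 well-diverged species every marker separates all species by
all three criteria; matK loses 1.2% of queries to the BCM distance
threshold because some conspecific individuals sit farther apart than the
95th-percentile cutoff. On harder communities (more species, shallower
divergence, lower marker recovery) the columns separate and rank the
markers.

The same pipeline runs from the shell:

```sh
barcodekit simulate --seed 7 --out data/
barcodekit evaluate data/ --reps 100 --seed 7 --out report.tsv
barcodekit hybrids data/ --nuclear ITS2 --chloroplast rbcL,matK,trnH-psbA --out hybrids.tsv
```

Subcommands: `simulate validate distances gap identify tree monophyly
combine diversity compare hybrids evaluate report`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole analysis from scratch on a freshly simulated
community: marker characterization, the full 15-barcode evaluation
(barcode gap, BM/BCM, bootstrap monophyly), the three pairwise
marker-divergence rank tests, population diversity, and hybrid diagnosis,
then writes the results JSON. All randomness derives from `--seed`.

See `docs/methods.md` for the models, estimators, numerical conventions
and the simulator's stated assumptions.
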