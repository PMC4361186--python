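# barcodegap

Evaluation toolkit for DNA barcoding in recently radiated clades.

DNA barcoding assigns specimens to species from one or a few short
standardized loci. In groups that diversified recently — shallow
interspecific divergence, incomplete lineage sorting (ILS), occasional
introgression — the method is at its weakest, and evaluating *which*
markers (and combinations) still discriminate species requires a full
statistical pipeline. `barcodegap` provides that pipeline, plus a
multispecies-coalescent simulator that generates truth-labeled
datasets with exactly this difficult structure, so every stage can be
validated against known truth. It is aimed at researchers assessing
candidate barcode panels (e.g. the plastid rbcL/matK core plus
trnH-psbA, trnL-F and nuclear ITS) for taxonomically difficult plant
groups.

## What it computes

Given per-marker multiple sequence alignments and an
accession-to-species map:

1. **K2P distances** with pairwise deletion of gaps/ambiguities:
   `d = -½ ln(1−2P−Q) − ¼ ln(1−2Q)`, with P/Q the transition and
   transversion proportions. Undefined pairs (no shared sites, or
   saturation) are masked, never imputed.
2. **Barcoding-gap statistics** — intra- vs interspecific distance
   pools, their means/ranges/histograms, and the median and Wilcoxon
   two-sample tests (exact by enumeration at small n).
3. **Species resolution** — UPGMA and NJ trees with nonparametric
   bootstrap; a species is resolved when its accessions are
   monophyletic (clade on rooted trees, bipartition side on unrooted
   trees), and resolved-with-support when the edge's bootstrap ≥ 70.
4. **Identification success** — leave-one-out classification of every
   accession under three criteria: *best match*, *best close match*
   (nearest reference within a threshold — the 95th nearest-rank
   percentile of intraspecific distances), and *all species barcodes*
   (set-equality of within-threshold matches with all conspecific
   references).
5. **Marker combinations** — all of the above over a standard set of
   22 combinations of a five-marker panel (singles, pairs,
   core-anchored triples/quadruples, the full panel), with gap-filled
   union concatenation.

The simulator draws a Yule species tree compressed toward a star
radiation, per-marker coalescent gene trees (θ controls ILS),
organelle-capture-like introgression events, and K80 sequences at
per-marker rates — all byte-reproducible from one seed. See
`docs/methods.md` for the model details and design decisions.

## Worked example

Simulate a small radiation (10 species, 3-4 accessions each, five
markers with ITS-like fastest rates) and evaluate four combinations:

```python
import warnings
from barcodegap import SimulationConfig, simulate_dataset, evaluate_combinations

cfg = SimulationConfig(n_species=10, accessions_per_species=(3, 4), seed=7)
ds = simulate_dataset(cfg)
report = evaluate_combinations(
    ds.dataset,
    combos=[["rbcL"], ["ITS"], ["rbcL", "matK"], list(ds.dataset.markers)],
    n_boot=100,
    seed=1,
)
```

Output (31 accessions; one simulated introgression event moved
`sp09`'s matK lineages into `sp04`):

```
combo                            method   rate rate>=70
rbcL                             upgma    40.0     30.0
rbcL                             nj       50.0     20.0
ITS                              upgma    60.0     60.0
ITS                              nj       60.0     60.0
rbcL+matK                        upgma    40.0     30.0
rbcL+matK                        nj       60.0     50.0
rbcL+matK+trnH-psbA+trnL-F+ITS   upgma    70.0     50.0
rbcL+matK+trnH-psbA+trnL-F+ITS   nj       90.0     90.0

rbcL                             best_match  63.33  best_close_match  63.33
ITS                              best_match  86.67  best_close_match  86.67
rbcL+matK                        best_match  73.33  best_close_match  73.33
rbcL+matK+trnH-psbA+trnL-F+ITS   best_match  77.42  best_close_match  77.42

ITS gap: 31 intra (mean 0.0155), 404 inter (mean 0.0888), wilcoxon p = 1.53e-17
```

Reading it: `rate` is the percentage of species recovered as
monophyletic on that combination's tree; `rate>=70` restricts to
species whose clade has bootstrap support ≥ 70. The fast nuclear
marker (ITS) resolves more species than the slow plastid core, the
five-marker concatenation does best, and the identification
percentages show the same ordering — the qualitative signature of
barcode surveys in recently radiated groups. The gap line shows
intraspecific K2P distances running well below interspecific ones,
but with overlapping ranges (hence imperfect thresholds).

The same pipeline runs from the shell:

```bash
barcodegap simulate --n-species 10 --seed 7 --out data/
barcodegap evaluate \
    --fasta rbcL=data/rbcL.fasta --fasta ITS=data/ITS.fasta \
    --combos standard22 --n-boot 1000 --seed 1 --out report/
```

writing `profile.tsv`, `gap.tsv`, `resolution.tsv`,
`identification.tsv` and per-combination Newick trees. `gap`,
`identify` and `profile` subcommands run single stages.

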