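# Methods

`barcodegap` evaluates candidate DNA-barcode markers for species
discrimination in clades where that task is genuinely hard: recently
radiated groups with shallow interspecific divergence, incomplete
lineage sorting (ILS) and occasional introgression. It implements the
standard distance-based evaluation stack — Kimura 2-parameter (K2P)
distances, barcoding-gap statistics, UPGMA/NJ monophyly scoring with
nonparametric bootstrap, and leave-one-out identification criteria —
together with a multispecies-coalescent generator that produces
truth-labeled datasets with exactly that statistical structure, so
every stage of the pipeline can be validated against known truth.

## Distances

For two aligned sequences, only columns where both residues are
unambiguous bases (A/C/G/T) are compared (*pairwise deletion*); gaps
and IUPAC ambiguity codes never contribute. With transition proportion
P and transversion proportion Q over the n compared columns,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Two degenerate outcomes are *signalled*, never silently imputed: a
pair with no shared unambiguous columns, and a saturated pair where a
log argument is non-positive. Saturation is detected on the exact
integer numerators `n - 2·ts - tv` and `n - 2·tv`, which makes the
boundary decision immune to float rounding. Undefined entries are
carried in a boolean mask on the distance matrix; tree construction
refuses masked matrices outright (imputing a distance would silently
corrupt monophyly scores), and the pipeline instead drops the
accessions involved in undefined pairs (greedy, most-undefined first,
lexicographic tie-break) with a logged warning. The all-pairs matrix
is computed via one-hot count matrices (matrix products give exact
integer transition/transversion counts), and is bit-identical to the
per-pair scalar path.

## Barcoding-gap statistics

All defined off-diagonal distances are partitioned into intraspecific
and interspecific pools and compared with Mood's median test (values
equal to the grand median dropped; Fisher's exact p when any expected
cell is below 5, 1-df chi-square otherwise) and the two-sided Wilcoxon
rank-sum test (exact p by full enumeration of rank assignments when
n+m ≤ 12, tie-corrected normal approximation with continuity
correction otherwise). These tests treat pairwise distances as
independent observations, which they are not — every accession appears
in many pairs. The package replicates this convention because it is
how barcode surveys report the gap; the p-values should be read as
descriptive summaries, not calibrated error rates. Reported p-values
below 2.2e-16 are floored in text output ("< 2.2e-16"). Histograms use
half-open bins [k·w, (k+1)·w) with default width 0.005 substitutions
per site.

## Trees and monophyly

UPGMA (size-weighted average linkage; rooted, ultrametric) and
neighbor joining (Q-criterion; unrooted, exact on additive matrices)
are implemented directly so their tie-break behaviour is fully
specified: equal minimum criteria are broken on the lexicographically
smallest pair of cluster-representative labels, making every tree a
deterministic function of its input. Negative NJ branch estimates are
clamped to zero and counted on the tree object. Tests cross-check both
builders against scikit-bio's NJ and scipy's average linkage on
generic matrices, and against exact recovery oracles on additive /
ultrametric inputs.

Bootstrap supports resample alignment columns with replacement (the
whole concatenated matrix is the resampling unit), rebuild the tree
per replicate, and score each internal edge as the percentage of
successful replicates containing its bipartition, rounded to integer.
Replicates whose resampled matrix contains undefined distances are
skipped and counted; the support denominator is the number of
successful replicates, and a warning is raised when more than 10% are
skipped. The default replicate count is 1000, reducible for speed.

A species is *resolved* when its accessions are monophyletic: a
complete clade on a rooted (UPGMA) tree, or one side of an edge's
bipartition on an unrooted (NJ) tree — no outgroup is assumed, so NJ
monophyly is judged on the unrooted definition. A species is resolved
*with support* when the defining edge's bootstrap value meets the
threshold (default 70). A species represented by a single accession is
counted monophyletic in the raw rate (keeping the denominator at the
full species count) but never in the supported rate, since it defines
no internal edge; the policy is configurable (`singletons_count`) and
recorded per species in the report.

## Identification criteria

Every accession is queried leave-one-out against all others of the
same (possibly concatenated) alignment:

* **best match** — nearest reference(s) decide; a tie spanning several
  species is *ambiguous*, a wrong nearest species *incorrect*.
* **best close match** — as best match, but queries whose nearest
  reference lies beyond a distance threshold are *no match*. Ties at
  exactly the threshold are included (≤).
* **all species barcodes** — *correct* only when the set of references
  within the threshold is exactly the query's full set of conspecific
  references, with at least two of them; fewer than two conspecific
  references gives *no conspecific*; a strict subset of conspecifics
  (one conspecific barcode outside the threshold) is *incorrect*;
  heterospecific references inside the threshold give *ambiguous* or
  *incorrect* depending on whether any conspecific is also inside.

The threshold is the nearest-rank 95th percentile (rank =
⌈p/100·n⌉) of the pooled intraspecific distances of the combination
under evaluation, computed per combination; the percentile is a
parameter. When no intraspecific distances exist the threshold-using
criteria degrade to an infinite threshold, recorded on the result.
Masked distances are treated as farther than any defined distance, so
a query can never match through an undefined entry. Note that under
the set-equality reading of "all species barcodes", success rates can
legitimately be 0 in regimes where intra- and interspecific distances
interleave heavily — every query then sees either a missing
conspecific or an intruding heterospecific inside its threshold.

## The synthetic-data generator

The generator emulates the sampling design of a generic-level barcode
survey of a recently radiated plant genus: ~47 species, 3-6 accessions
per species, five markers with the aligned lengths of a standard
plastid + nuclear panel (1415, 847, 423, 927, 668 bp for the rbcL-,
matK-, trnH-psbA-, trnL-F- and ITS-like loci).

* **Species tree** — a Yule topology, rescaled so every root-to-tip
  path equals `tree_depth` (expected substitutions/site at the slowest
  marker; default 0.002, chosen so the slowest marker's interspecific
  distances land near 0.004, the magnitude typical of rbcL in such
  groups). Internal branches are then multiplied by
  `radiation_scale` (default 0.5) and pendant branches re-extended so
  tips stay at the same depth: `radiation_scale → 0` is a star
  radiation, the regime that produces gene-tree polytomies.
* **Gene trees** — one independent multispecies-coalescent draw per
  marker: within each species-tree branch, k lineages coalesce at rate
  k(k-1)/2 / θ in the same substitution-time units; survivors
  propagate rootward and everything coalesces in the unbounded root
  branch. θ (default 0.00125) is deliberately comparable to the
  compressed internal branches, so ILS is substantial — this is the
  study regime, not a corner case. θ = 0 reproduces the species tree
  exactly. No separate mutation-rate/generation-time layer exists;
  only relative rates matter to the evaluation.
* **Introgression** — with per-marker probability (default 0.2) one
  organelle-capture-like event transplants a recipient species'
  lineages into a donor species' clade: each recipient sample is
  re-grafted as sister to a donor sample at a uniform height on its
  pendant edge, donors cycled. This makes the recipient's
  non-monophyly on that marker structural (guaranteed whenever it has
  ≥ 2 samples) rather than probabilistic, mirroring the *systematic*
  cross-species associations that distinguish reticulation from ILS.
* **Sequences** — sites evolve independently under the two-parameter
  (Kimura) model with transition/transversion rate ratio κ (default
  2), uniform root composition, and branch lengths scaled by each
  marker's rate multiplier. The multipliers (1.0, 2.25, 6.5, 1.9, 9.1)
  are proportional to the mean interspecific divergences typical of
  the five loci, so the ITS-like marker is the fastest — matching the
  model family of the K2P estimator used downstream is intentional.
* **Missingness** — accession × marker entries are dropped with
  probability `missing_prob` (default 0.03) before the gene tree is
  drawn, emulating unequal per-marker sampling; no indels are
  simulated (missing data is whole-marker absence only, since indel
  realism adds nothing to the quantities evaluated here).

All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical configurations yield
byte-identical FASTA, Newick and TSV output.

What the generator does **not** emulate: alignment error (inputs are
born aligned), indels and length variation, rate heterogeneity across
sites, base-composition bias, polyploidy, and per-individual gene
flow (introgression moves whole sampled lineage sets). Passing tests
therefore demonstrate correctness of the evaluation machinery and
qualitative behaviour under radiation/ILS/introgression — not that
real data of any particular genus will yield particular rates.

## Scaled problem sizes in tests and the acceptance script

Test ensembles run at desk scale as the package's own choice of
problem size: the degradation sweep uses 10 species × 3 accessions
(one 668 bp marker, 100 bootstrap replicates, 20 seeds per θ level);
the marker-ranking check uses 15 species × 3-4 accessions over the
five-marker panel. The ranking check runs at mild ILS (θ = 2e-4,
depth 0.003) because it isolates the effect of substitution-rate
ordering: under the heavy-ILS defaults, which markers resolve which
species is dominated by the luck of independent gene-tree draws, a
property of the regime rather than of the code — the ILS effect itself
is probed by the θ-sweep. The easy-regime recovery check uses a single
fast marker (8× rate, depth 0.05) with θ = 1e-4 on the NJ tree.
`scripts/acceptance.py` reruns the full 22-combination evaluation on a
15-species dataset with 100 bootstrap replicates and reports the
headline quantities as JSON.

## Numerical and edge-case policy

* Distance ties in identification are exact float equalities; since
  distances are deterministic functions of integer counts, identical
  sequences tie exactly.
* UPGMA/NJ tie-breaks are lexicographic (above); NJ's Q matrix is
  compared across both triangles because summation order can differ by
  one ulp.
* `n = 2` NJ input yields the degenerate single-edge tree; `n = 3` the
  closed-form star resolution.
* An all-zero distance matrix yields zero branch lengths with
  tie-break-determined topology.
* Rates are rounded to 1 decimal (resolution) and 2 decimals
  (identification percentages); supports to the nearest integer.

## Known limitations

* The two-sample tests inherit the pseudo-replication caveat above.
* Monophyly on NJ trees with zero-length internal edges depends on the
  arbitrary (but deterministic) resolution of ties.
* The "all species barcodes" criterion is implemented from its
  set-equality definition; other software may count ambiguous or
  no-conspecific queries differently when reporting percentages, so
  all outcome classes are reported to allow recomputation under any
  convention.
* Maximum parsimony and maximum likelihood tree methods are out of
  scope; so is alignment itself (inputs must be pre-aligned) and any
  BLAST-based genus assignment.
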