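# Methods

`colchain` re-implements, as a tested and reusable pipeline, the analysis
steps used in collagen (I) phyloproteomics of ray-finned fishes: assembling
per-species α-chain sequences into a partitioned alignment, discriminating
α1 (I) from α3 (I) chains, comparing tree samples in quartet tree space,
and deriving per-chain amino-acid substitution rates. This note documents
the models, the parameters that matter, and the design decisions taken
where the procedure was genuinely open.

## Sequence model and containers

Collagen (I) α-chains are handled at three fixed helical-domain lengths:
α1 = 1058, α2 = 1041, α3 = 1062 aligned positions, giving a concatenated
alignment of exactly 3161 columns with contiguous partitions in α1, α2, α3
order (1-based closed intervals, stated in every output). Inputs are
assumed pre-aligned to these lengths; no de-novo alignment is performed. A
species enters the alignment only if both its α1 and α2 chains are
available; a missing α3 chain is dash-filled across its partition on the
assumption that absence is biological (many non-teleosts and a few teleost
lineages lack the chain). Tetraploid species carry diverged A/B isoforms
of each chain; one isoform per (taxon, chain) enters the alignment, by
default the A copy, overridable per taxon.

## Chain discrimination

Two independent lines of evidence separate 'true' α1 chains from α3 chains
(which are frequently deposited in public databases under an α1 label,
their genes COL1A1a/COL1A1b being paralogs):

1. **T32/33 rule.** The 17-residue window at α1 helical positions 334–350
   carries lysine (K) at its ninth position in α1 — so trypsin, which
   cleaves C-terminal to K/R but not before proline, splits it into two
   peptides — and glutamine (Q) in α3, leaving one peptide. In zebrafish
   the two windows are `GGPGVVGPKGATGEPGR` and `GANGPMGAQGASGESGR`.
2. **Position-1264 rule.** In full procollagen sequences the residue at
   position 1264 is cysteine in α1 and serine in α3.

The window (and position 1264) are located in a query by global pairwise
alignment with free end gaps against a bundled reference, using BLOSUM62
with affine gap penalties (open −11, extend −1); alignments scoring below
1 point per reference column raise a no-homology error rather than
producing a call. Residues outside {K, Q} / {C, S} yield an
*indeterminate* call — the rules are empirical regularities, and unseen
taxa may violate them — and disagreement between the two rules is reported
as a *conflict*, never silently resolved. Position 1264 is defined in the
bundled reference procollagen's own 1-based coordinates and transferred to
queries through the alignment; the literature does not state the numbering
landmark unambiguously, so anchoring to an explicit reference makes the
convention reproducible.

The bundled references are **synthetic stand-ins**, built deterministically
in code: collagen-like Gly-Xaa-Yaa scaffolds with conserved K/R tryptic
boundaries, carrying the zebrafish T32/33 windows verbatim at positions
334–350 and C/S at procollagen position 1264. They support coordinate
transfer by alignment but are not literal database accessions (no network
retrieval is in scope).

The trypsin proline rule is enabled by default (standard trypsin
specificity); the published worked example is insensitive to it.

## Tree space

Congruence between two trees on a common leaf set is counted over
non-trivial leaf bipartitions (unrooted mode, default) or internal clades
(rooted mode); because two trees may resolve different numbers of nodes,
fractions are reported in both directions. Trees are first pruned to the
shared leaf set, suppressing degree-2 nodes and summing branch lengths
along suppressed paths.

The quartet distance between two trees counts the 4-leaf subsets whose
induced topologies differ. Induced quartet states are read off the
four-point condition on unit-branch-length path distances, vectorised over
all C(n, 4) quartets; a star quartet (all three pairings tie) is
*unresolved*, and by default a resolved-vs-unresolved pair counts as
different (policy flag `ignore` available — fully resolved Bayesian
samples are insensitive to the choice). The test suite checks this
implementation quartet-by-quartet against an independent oracle that
extracts each 4-leaf induced subtree and inspects its cherries.

For visualisation, the pairwise quartet distance matrix is made Euclidean
by Cailliez's additive correction — the smallest constant c added to every
off-diagonal dissimilarity such that the double-centred Gram matrix is
positive semi-definite, computed as the largest real eigenvalue of the
standard 2n×2n companion linearisation of the quadratic eigenproblem (c = 0
for already-Euclidean input) — then embedded by classical MDS
(eigendecomposition; per-axis variance fractions are eigenvalues over the
sum of positive eigenvalues) or nonmetric MDS. NMDS is a SMACOF iteration
with isotonic (rank-monotone) disparities, minimising Kruskal stress-1 in
[0, 1]; defaults are 20 restarts (first start from classical MDS, the rest
seeded random), 500 iterations maximum, stress tolerance 1e-6, and the
per-iteration stress trace of the winning start is retained so
non-increase can be verified. Duplicate trees (quartet distance zero) are
counted per tree for density shading in plots.

## Substitution rates

**Clock-summary arithmetic.** Given a mean clock rate m (substitutions per
site per Ma) and relative partition-rate multipliers r_p from a Bayesian
relaxed-clock parameter summary (`.pstat` dialect: whitespace-delimited
table with a `Mean` column; clock rate row matched by name, multipliers as
`m{N}` with partition index N in α1, α2, α3 order), the per-site rate of
chain p is m·r_p and the whole-chain rate is R_p = m·r_p·L_p substitutions
per Ma. Multipliers are assumed mean-1 across partitions (the common
convention). Products are exact; rounding (half-up, one decimal for chain
rates) happens only at the presentation layer. The mean row is the
arithmetic mean of the three chains — with the published inputs
(0.00067/0.00088/0.00094 per site per Ma over 1058/1041/1062 sites) this
reproduces 0.7/0.9/1.0 and a mean of 0.9 substitutions per chain per Ma.

**Fixed-chronogram maximum likelihood.** The Bayesian relaxed-clock runs
themselves (MCMC, fossil calibrations) are out of scope; the in-repo
estimator of the same quantity holds a time-calibrated tree fixed and
maximises a partitioned pruning likelihood over the three per-site rates.
The substitution model is Dayhoff (PAM exchangeabilities and frequencies,
bundled as published constants; rate matrix scaled to one expected
substitution per site per unit branch length, so branch lengths are
site_rate × branch duration in Ma). Gaps and `X` are missing data, so
dash-filled α3 partitions contribute nothing to the α3 likelihood. Site
patterns are compressed before the pruning recursion; per-node scaling
guards against underflow. Rates are independent across partitions given
the fixed tree, so each is a bounded 1-D optimisation (Brent, bounds
[1e-7, 0.5] per site per Ma, xatol 1e-10); uncertainty is reported as
profile-likelihood intervals at a log-likelihood drop of 1.92 (≈95% for
one parameter). No among-site rate heterogeneity is modelled within a
partition (a +G flag is deliberately not exposed; model selection reported
only the plain Dayhoff model). An entirely-missing partition or a
zero-duration tree raises a degenerate-input error at estimation time; the
likelihood itself is still defined at total duration zero, where it
reduces to the sum of log stationary frequencies of the observed residues.

The public API follows the statistical-modelling convention:
`PartitionRateModel(alignment, chronogram, model).fit()` returns a
`PartitionRateResults` with estimates, profile CIs, per-partition
log-likelihoods, a `summary()` table and a whole-chain rate table.

## Synthetic data

The generator produces datasets with the statistical structure the
pipeline assumes, so every stage is testable without downloads.

*Time trees* are constant-rate birth–death trees conditioned on taxon
count and root age, sampled by the coalescent-point-process construction:
n−1 inter-leaf node depths drawn i.i.d. from the birth–death depth
distribution truncated at the root age, the root depth placed uniformly
among them. Defaults: birth 0.015, death 0.005 per lineage per Ma
(unstated in the source analyses; chosen once as a moderate-extinction
regime giving total tree lengths of ~2000–3000 Ma for 20 taxa), root age
430 Ma (the calibrated bony-fish scale).

*Sequences* evolve site-independently by the continuous-time Dayhoff
process (jump-chain simulation; every substitution event is logged with
its edge, site and residues, and tests replay the log from the root to
reproduce each tip exactly). Structural invariants are frozen: glycine at
every third helical position, the scaffold's K/R tryptic boundaries, and —
for α1/α3 — the full 17-residue T32/33 window, which is what guarantees
the classifier's 100% accuracy on simulator output by construction.
Default per-site rates are 0.00067/0.00088/0.00094 per Ma (α3 > α2 > α1).

*Dataset assembly*: the α1 root is the bundled reference itself (real
chains are homologous to the zebrafish reference, and this homology is
what makes alignment-based window transfer work); α3 derives from α1 by a
5% root mutation (gene duplication) plus its own descent; α2 draws its
root from the stationary frequencies. 15% of taxa (a seeded subset) lack
α3, matching the 85% prevalence of the three-chain arrangement; 10% of
taxa are tetraploid, and their B isoforms are produced by post-hoc extra
substitutions targeted uniformly in the 3–10% divergence band (the
process that generated real isoform pairs is not modelled, only the band).

*What the generator does not emulate*: within-chain rate heterogeneity
(sites outside the frozen mask evolve at one rate per chain), indels, the
taxonomic clustering of α3 loss, and hydroxyproline/PTM chemistry. One
visible consequence: the realized within-taxon α1-vs-α3 divergence comes
out at ~30–40%, somewhat above the ~25–29% observed in real fishes,
because uniform-rate sites saturate more slowly than real
rate-heterogeneous collagen positions. Passing tests therefore demonstrate
the pipeline's correctness on structurally collagen-like data, not that
the generator is a calibrated model of collagen evolution.

*Tree clouds* stand in for posterior samples: seeded random NNI walks of
configurable length around a source topology. Two clouds around distinct
sources separate in classical MDS (centroid gap exceeding within-cloud
spread), mirroring how partition-specific posterior samples occupy
distinct regions of tree space.

## Numerical choices and reproducibility

All randomness flows from explicit integer seeds (`numpy` Generators);
identical configurations produce byte-identical output files. Quartet
computations are exact integer counts; Cailliez uses a PSD guard of 1e-9
at the boundary; classical MDS rejects axes beyond the positive spectrum
at a relative tolerance of 1e-9. Every CLI run writes a `manifest.json`
with the resolved configuration, seed and SHA-256 digests of inputs and
outputs.

Problem sizes used in the test suite and the acceptance script (20–100
taxa, 30-tree clouds, 5-seed recovery studies) are chosen so the full
suite runs in a few minutes on one CPU while keeping Monte-Carlo error
well inside the asserted tolerances; the parameter-recovery study
simulates with an empty invariant mask — i.e. under the estimator's own
generative model, the only regime where "true rate" is well defined.

## Known limitations

- No Bayesian tree or divergence-time inference: topology search, relaxed
  clocks and fossil calibration are external concerns; this package
  consumes their outputs (tree samples, `.pstat` summaries).
- The α2 chain has no discriminator; its identity is taken from
  annotation.
- The fixed chain lengths assume pre-reconciled indels; only the
  classifier accepts relaxed-length fragments.
- Quartet distances are computed for every pair of trees at O(n⁴)
  per pair after an O(n²) distance pass; fine for hundreds of trees on
  tens of taxa, not tuned for thousands.
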