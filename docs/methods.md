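# Methods

`phylodissect` dissects the phylogenetic signal that a multilocus amino-acid
data set carries for one of two competing topology hypotheses, T1 and T2.
The motivating use case is the adjudication of deep, conflicted nodes —
e.g. whether a focal group is monophyletic (T2) or whether an "outpost"
lineage nests inside it (T1) — where long-branch attraction (LBA) and other
systematic errors can manufacture apparent support. The package implements
the full chain from matrix construction to diagnosis: decisiveness
filtering, saturation-based subsampling, a likelihood engine for gene- and
site-wise support scores, entropy and informativeness diagnostics, reduced
alphabet (SR4) recoding, and gene/site concordance factors, together with a
synthetic-data generator so every stage is testable without any external
data or tools.

## Models and likelihood

Substitution follows a reversible continuous-time Markov chain on the 20
amino acids (or on 4 groups after recoding): `Q_ij = S_ij * pi_j` with
symmetric exchangeabilities `S` and stationary frequencies `pi`, normalised
so the expected rate at stationarity is 1 (branch lengths are expected
substitutions per site). Bundled exchangeability sets: LG (Le & Gascuel
2008), WAG (Whelan & Goldman 2001), and Poisson (all-equal). Frequencies
can be the published ones, uniform, or pooled empirically from the scored
alignment with a 0.5 pseudocount (the "+F" convention; the pseudocount
keeps unobserved states at positive mass, which reversibility requires).

Among-site rate variation uses the standard discrete gamma: `k`
equal-probability categories (default 4) whose rates are the category means
of a mean-one gamma with shape `alpha`, computed from the regularised
incomplete-gamma identity so the rates average exactly 1. `alpha` defaults
to 0.8 throughout — a typical estimate for conserved amino-acid loci;
larger values mean less heterogeneity.

Site log-likelihoods use Felsenstein pruning with three standard
engineering choices:

- transition probabilities come from one eigendecomposition of the
  pi-symmetrised rate matrix, reused for every branch and category (exact
  for reversible `Q`);
- duplicate site patterns are collapsed before pruning and weights applied
  afterwards;
- partials are rescaled per node with accumulated per-pattern log scalers,
  so trees with hundreds of taxa do not underflow.

Branch lengths on a fixed topology are fitted coordinate-wise: for a branch
with inside partial `F` (data below, given the child state) and outside
partial `H` (everything else, given the parent state), the total likelihood
is `sum_ij H_i P_ij(t) F_j`, a cheap univariate function optimised by
bounded Brent in `[1e-8, 20]` substitutions/site. Sweeps repeat until the
total log-likelihood improves by less than `tol` (default 1e-6, at most 50
sweeps; a warning is logged on non-convergence and the best point
returned). Inside partials are maintained incrementally — updating one
branch invalidates only its root path. Each single-branch update is
accepted only if it does not lower the likelihood, so the sweep sequence is
monotone by construction. Large screening runs (the per-locus signal table,
supermatrix site scores, and the consistency experiments) use `tol=1e-3`,
`xatol=1e-6`: those consumers use only the sign or the magnitude class of a
score difference, for which the looser tolerance is far below the decision
threshold.

## Signal scores

For a locus `L`, the gene-wise score is
`dGLS = lnL(L | T1) - lnL(L | T2)`; positive values support T1. By default
branch lengths are re-optimised per topology per locus ("reoptimize" mode)
— comparing a constrained against an unconstrained topology with shared
lengths would conflate topology with length misfit. A "fixed" mode scores
supplied lengths as-is; in that mode the per-site scores
`dSLS_i = sitelnL_i(T1) - sitelnL_i(T2)` sum exactly to the matrix-level
dGLS, an algebraic identity the tests verify to 1e-8. Support classes use a
tie band `tie_eps` (default 0: sign only; ties are reported separately, not
split between classes).

Per-locus covariates recorded alongside dGLS: alignment length,
parsimony-informative site count (>= 2 states each in >= 2 taxa), missing
fraction (measured against the full taxon set of the hypothesis trees, so
unsampled taxa count as missing — with row-dropout occupancy the
within-locus fraction is identically zero and uninformative), a rate proxy
(optimised T1 tree length divided by taxon count; the package's own simple,
model-based choice since no canonical definition exists), and the
saturation slope/r² described below. Class-wise medians and IQRs plus a
two-sided Mann-Whitney flag per covariate form the property-comparison
table.

## Saturation

Each locus's uncorrected p-distances (pairwise deletion; pairs sharing
fewer than 20 columns excluded — their variance explodes) are regressed on
patristic distances from a tree with branch lengths (in pipeline runs, the
locus's own gene tree when available, otherwise T1 with re-optimised
lengths). The regression keeps a free intercept, so r² is the squared
Pearson correlation — the conventional summary of a saturation plot. A
slope near 1 means observed differences track inferred change; multiple
hits flatten the slope. Slowly evolving loci are selected by
`slope >= 0.4` and `r² >= 0.95` (configurable; these are the conventional
cutoffs for this filter).

## Entropy, trimming, recoding

Per-column Shannon entropy uses plug-in frequencies over non-missing cells
and natural log; columns with fewer than two observed residues are reported
as 0 and flagged uninformative rather than propagating NaN. Entropy/gap
trimming removes columns with `H > max_entropy` or missing fraction above
`max_gap`; it is a deliberately simple stand-in for heteropecilly-targeted
trimming — high-entropy, gappy columns are the ones most likely to violate
stationary site-profile assumptions, but no sliding-window smoothing or
similarity-matrix scoring is attempted. SR4 recoding maps the 20 amino
acids onto {AGNPST}, {CHWY}, {DEKQR}, {FILMV} (Susko & Roger 2007); it can
only merge states, so per-column entropy never increases — a data-processing
inequality the tests check.

## Concordance factors

For every internal branch of a binary reference tree (derooted internally),
the branch separates four leaf groups. A gene tree is decisive when it
samples at least one taxon from each group; the gene concordance factor
(gCF) is the percentage of decisive gene trees containing the branch's
bipartition restricted to the gene's taxa. The site concordance factor
(sCF) samples quartets (one leaf per group; exhaustive when there are at
most `n_quartets` combinations, default 100, seeded otherwise), counts
decisive sites per quartet (all four residues present, exactly two states
twice each) and averages the concordant fraction. Branches with no
decisive genes/sites are reported as NaN with counts, not silently
dropped.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular data set:

- **Species tree**: random-join (Yule-like) topology over `n_taxa` leaves,
  i.i.d. Exponential branch lengths with mean `branch_scale` (default 0.1
  subs/site — deep-but-resolvable internodes).
- **Hypothesis pair**: the outpost clade is pruned and regrafted either
  inside the focal clade (T1) or as its sister (T2); all clades disjoint
  from focal+outpost are shared, so the pair differs by exactly one
  rearrangement.
- **Long branches**: named leaves or clades get their branch lengths
  multiplied (the `lineage_rate_multipliers` map), emulating fast-evolving
  lineages prone to LBA.
- **Loci**: lengths uniform on `locus_length_range` (default 100-500
  columns), per-locus rate lognormal with sigma 0.4 (moderate rate spread
  across loci), sequences evolved under LG+G (alpha 0.8) from stationary
  root states, one discrete-gamma category per site.
- **Noise class**: a fraction of loci (default 0 — enabled per study) is
  generated on T2 at `noise_rate_multiplier` x the locus rate (default 10)
  and shorter lengths (default 60-120): short, saturated loci whose
  apparent signal is largely noise, the minority class the diagnosis is
  meant to expose.
- **Occupancy**: each (locus, taxon) pair is dropped independently with
  `dropout_prob` (default 0.2); dropped taxa are absent, not gap-padded,
  mirroring transcriptomic supermatrices.

What the generator does **not** emulate: indels and alignment error,
compositional heterogeneity and heteropecilly, within-locus heterotachy,
profile-mixture (site-heterogeneous) processes, gene-tree discordance from
coalescent or paralogy processes (gene trees equal the scaled species
tree). Passing tests therefore demonstrate correctness of the statistics
and the internal consistency of the pipeline's logic on data satisfying the
model's assumptions — they do not certify behaviour on real data violating
them.

## Pipeline report and numerical conventions

`run_pipeline` chains simulate/ingest -> decisiveness filter -> saturation
stats and slow-locus selection -> concatenation (+ RAxML-style partition
file) -> per-locus dGLS table and class comparison -> supermatrix dSLS and
per-site entropy -> gCF/sCF against both hypotheses -> optional SR4
re-scoring, writing CSVs, Newick/FASTA, a JSON results block, a
human-readable summary, and a manifest with a SHA-256 per output file. A
run is a pure function of configuration + seed; identical configs produce
byte-identical CSVs.

The site-class entropy contrast in the report is computed over
parsimony-informative columns only. At desk scale the two optimised trees
differ slightly in total length, which gives every constant column a tiny
nonzero dSLS; sign-classifying those columns floods both classes with
zero-entropy sites that carry no topology information. Restricting to
informative columns removes this artefact; full per-site scores (all
columns) are still written to `site_scores.csv`.

Other conventions: partition coordinates are 1-based inclusive (ecosystem
convention) while internal indices are 0-based half-open; `-`, `X` and `?`
are all treated as missing for likelihood, distance, and entropy purposes;
ties in support classification are an explicit third class.

## Known limitations

- No topology search: trees and hypotheses are inputs.
- Branch-length confounding at the root of a rooted input (only the sum of
  the two root-child branches is identifiable under a reversible model);
  optimisation still converges, the split between the two is arbitrary.
- gCF requires a binary reference; polytomies raise.
- The acceptance-scale experiments run at desk sizes (12 taxa, tens of
  loci, 50 replicates), chosen as the package's standard demonstration
  conditions.
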