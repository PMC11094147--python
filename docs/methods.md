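# Methods

This note records the models implemented in `beeqmp`, the assumptions they
make, the defaults and why, and what the synthetic-data generator does and
does not emulate.

## Quantitative microbiome profiling

Amplicon counts are compositional; QMP converts them to absolute profiles
by equalizing the *sampling depth* — sequencing reads per unit of microbial
load — across samples. Microbial load is estimated from qPCR as
`L = E^(ΔCt)` with `ΔCt = mean Ct_host − mean Ct_16S` over triplicates and
amplification efficiency `E = 2` (perfect doubling per cycle; `E` is a
parameter of `load_from_ct` for assays with measured efficiencies). With
`S_min = min_i N_i / L_i`, sample *i* is subsampled to
`n_i = ⌊S_min · L_i⌋` reads, which is ≤ `N_i` by construction; the floor
(rather than rounding) preserves that guarantee. Subsampling is
multivariate hypergeometric (without replacement) on integer counts and
multinomial with probabilities proportional to the corrected counts on
real-valued (copy-number-corrected) matrices, since fractional "reads"
cannot be drawn without replacement. The default 1000 replicates are
averaged at full precision. Because draws are without replacement, every
replicate total equals `n_i` exactly; the only deviation of
`total_i / L_i` from `S_min` is the floor rounding, bounded by
`1/min_i(n_i)` in relative terms. When all loads are equal the procedure
reduces to classical even-depth rarefaction.

Copy-number correction divides each ASV's count by its genus's 16S rRNA
operon copy number and rescales each sample so its total is preserved
exactly; it runs *before* rarefaction (the corrected matrix is what gets
subsampled), and zero entries stay zero. Stage order is: contaminant
removal → rare-ASV filter → copy-number correction → load estimation →
rarefaction.

## Filtering rules

*Contaminants.* For each ASV a 2×2 presence/absence table (negative
extraction controls vs bee samples, presence = count > 0) is tested with a
one-sided Fisher exact test; ASVs more prevalent in controls at p < 0.05
are removed. The one-sided orientation means an ASV absent from all
controls can never be flagged. A prevalence-threshold score statistic
would give the same decisions at this α; the exact test was chosen for
being assumption-free at control group sizes of ~8.

*Rare ASVs.* An ASV is retained iff it has **more than** `min_count = 3`
reads in at least `⌈min_prevalence · n⌉` samples (`min_prevalence = 0.2`,
boundary inclusive). The filter is idempotent and requires raw integer
counts. Both thresholds are parameters.

## Diversity and permutation statistics

Alpha diversity uses natural logarithms (the ecology-toolchain default;
the base is an option): Shannon `H = −Σ p ln p`, Simpson `D = 1 − Σ p²`
(the inverse form is deliberately not the default), Pielou
`J = H / ln S_obs` with `S_obs` the number of taxa with positive
abundance; `J` is undefined (NaN) for single-taxon samples.

Bray–Curtis is `Σ|x−y| / Σ(x+y)`; quantitative Jaccard is `2BC/(1+BC)`.
A pair of all-zero samples gets distance 0 with a warning. Weighted
UniFrac weights every branch by length times the difference in descendant
abundance *fractions*; the normalized variant (default, bounded in [0,1])
divides by `Σ l_b (p_b^A + p_b^B)`. Trees come either from data files or
from the in-package neighbor joining, which clamps negative branch lengths
to zero while transferring the deficit to the sibling edge (preserving
pairwise path lengths) and midpoint-roots the result for UniFrac.

PERMANOVA Gower-centres the squared distances (`G = −½ C D² C`) and
partitions `tr(G)` by *sequential* (Type I) projections onto the nested
dummy-coded model sequence — condition, location, condition×location in
that order, matching the design's narrative order; with an unbalanced,
partially confounded design the order matters and is the user's choice.
Rank increments give the degrees of freedom, so aliased interaction cells
(the design has no failed hives in one location) reduce the interaction df
instead of breaking the fit. p-values use unrestricted sample relabelling:
`p = (1 + #{F* ≥ F}) / (1 + n_perm)` (default 9999 permutations; the
study-scale 10⁶ is configurable), or exhaustive enumeration over all `n!`
relabelings for `n ≤ 9`. Because bees within a hive are correlated and
condition is constant within hive, unrestricted bee-level permutation is
anti-conservative for hive-level factors; the package therefore also
supports testing on hive-mean profiles, and the calibration tests evaluate
the unrestricted test in the exchangeable regime it assumes (see below).
PERMDISP follows the betadisper recipe (principal-coordinate embedding,
distances to group spatial medians, permutation F) via scikit-bio, with
the all-zero-distance degenerate case defined as F = 0, p = 1.

NMDS minimizes Kruskal stress-1 by SMACOF with monotone regression
(scikit-learn backend), best of `n_starts = 16` random initializations;
identical seeds give identical coordinates.

## Associations

ASVs are pooled to genus by column summation (totals preserved). The
"nested" two-way ANOVA treats hives, not bees, as independent units:
responses are averaged to hive means, then condition + location +
interaction are fit with the same rank-aware sequential-SS machinery as
PERMANOVA and F-tested against the hive-level residual. A bee-level
variant with hive as the error stratum (hive-within-cell mean square as
the denominator for hive-level terms) is exposed for sensitivity analysis;
neither variant claims to reproduce any particular published table, since
the exact error strata there are unstated. Per-genus condition and
location p-values are BH-adjusted across genera.

IndVal uses the group-size-corrected form (group *means* rather than sums
for the specificity component A), appropriate for the unbalanced 14:9
survived:failed hive split; fidelity B is the within-group occurrence
fraction at a configurable presence threshold (default: any positive
abundance after QMP averaging). The statistic `max_g √(A_g B_g)` is tested
by group-label permutation with BH adjustment across ASVs, with an
exhaustive mode enumerating all assignments of samples to groups of the
observed sizes.

DWV levels are `ΔCT = mean Ct_GAPDH − mean Ct_DWV` per strain (A, B, C);
higher values mean more viral template. Each strain's ΔCT feeds the same
nested ANOVA.

## Classification

Features are genus-level QMP abundances plus (optionally) one-hot location
indicators; the label is the bee's hive condition. Per seed: a stratified
80/20 train/test split (a hive-grouped split mode exists because hive
mates share labels — a leakage channel per-sample splits ignore);
standardization and the hyperparameter grid search (5-fold CV, AUROC
scoring) are fit on the training portion only. Grids: ridge-logistic
`C ∈ {10⁻³ … 10³}` (7 log-spaced values); random forest fixed at 500
trees with `max_features ∈ {√p, p/3, p}`. Test AUROC is the rank-based
Mann–Whitney statistic (ties ½) and the summary is the *median* over
seeds. Feature importance is either the median signed logistic weight per
feature across seeds or the drop in median AUROC when the protocol is
rerun with one feature omitted.

## The synthetic-data generator

The generator draws, per study: hive condition labels matching the design
(12/9/2 hives per location with 8/0/1 failures); bees per hive from
{5,…,8} weighted to mean ≈7.3 (~168 bees); genus composition through a
two-stage Dirichlet (hive concentration 60 around a condition-adjusted
base, bee concentration 250 around the hive), which creates the
within-hive correlation the nested analyses assume; fixed within-genus ASV
splits; multinomial counts at a log-normal depth (median 33 000, σ=0.35,
clipped to 9461–73 402 reads); true loads log-normal (bee σ=0.5, hive
σ=0.3 on the ln scale, failed-hive median 1.0) times a ×2 condition
multiplier; and Ct values back-computed under the same efficiency-2 model
the estimator uses, with Gaussian replicate noise (σ = 0.15 cycles), so
load recovery is exact in expectation. The condition effect is planted
twice, mirroring the two findings the pipeline must detect: on total load
(×2) and on the relative shares of *Commensalibacter* (×2.5) and
*Snodgrassella* (×2.0) — the share multipliers are the overall ~5× and ~4×
fold changes divided by the load effect. Five contaminant ASVs (classic
kitome genera) appear in negative controls at 0.9 prevalence and in bees
at 0.05; DWV ΔCT means are per strain and location, with the
between-location shift planted on strain C only (−0.94 / 0.55 / 0.42
cycles). Trees are genus-structured random coalescents. A `truth` record
stores every latent value, and `generate_worked_micro` emits an 8-bee
instance small enough for exhaustive permutation enumeration.

What the generator does **not** emulate: sequencing error and chimeras
(counts are exact multinomials), taxonomic misassignment, real 16S
sequence evolution (trees are random), compositional zero-inflation beyond
multinomial sampling, qPCR inhibition or efficiency drift, and seasonal
dynamics. Passing tests therefore demonstrate that the *statistical
machinery* recovers planted structure under the design's sampling
hierarchy — not that the biological effect sizes of any real study are
correct.

## Calibration and power checks — problem sizes and regimes

The test suite checks null calibration (rejection rate at α=0.05 within
[0.02, 0.09] over 200 replicate studies) for PERMANOVA and the nested
ANOVA, and permuted-label median AUROC within [0.4, 0.6] over 20 seeds.
PERMANOVA and the AUROC null run on a null design with the hive-level
Dirichlet stage flattened (bees exchangeable): with within-hive
correlation and hive-constant labels, *any* unrestricted per-sample
procedure is anti-conservative (PERMANOVA) or anti-generalizing (label
permutation with hive memorization), which is a property of
pseudo-replicated designs, not of the implementations. The nested ANOVA
is calibrated under the full hierarchical design, since hive-mean
aggregation is exactly what makes it valid there. Power checks use 50
replicate studies (condition detection ≥80% for total-abundance ANOVA and
PERMANOVA), 20 replicates for coefficient-ranking of the planted genera,
and 20 seeds for median AUROC; rarefaction uses 50 replicates and
PERMANOVA 99 permutations inside these loops, full scale (1000 / 9999)
elsewhere. The acceptance script runs the logistic protocol at the full
100 seeds and the random forest at 30 seeds (forest refits dominate
runtime; the median is stable well before 30).

Known limitation: with only 23 hives, chance hive-level composition
variation can hand a non-planted genus a large ridge *partial* coefficient
(a counterweight under near-separable fits) even though the planted genera
dominate every univariate comparison; the strictest coefficient-ranking
check (planted genera top-2 in ≥90% of replicates) sits at ~80–85% under
the defaults above.

## Numerical choices

- TSV canonical dialect (UTF-8, header, "." decimal); floats written at
  `%.10g`, round-trip tolerance 1e-9; newick via scikit-bio.
- One master seed; every stochastic stage draws from a named
  `SeedSequence` substream (`"synth"`, `"qmp"`, `"perm"`, `"indval"`,
  `"ml"`), so stages are replayable independently and bit-identically.
- Copy-number rescaling and genus pooling preserve sample totals to 1e-9;
  permutation p-values use a 1e-12 tie tolerance on the statistic;
  zero-variance ANOVA responses return F = 0, p = 1 via a scale-relative
  (1e-12) guard; Dirichlet draws are clipped at 1e-12 and renormalized.
- NJ agglomeration ties break on taxon name order, making the tree
  invariant to input taxon order.
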