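# Methods

This note records the models the package implements, the defaults it
ships, and the choices made where the design was genuinely open.

## Preference estimation

A competitive assay measures both products in one reaction, so each
replicate yields one ratio R = signal(MeSA)/signal(MeBA). Aggregation is
**mean-of-ratios** with the sample standard deviation across replicates,
matching the per-assay replicate structure (each replicate is its own
internally controlled experiment); ratio-of-means is deliberately not
offered. Replicates with a zero methyl-benzoate signal have an undefined
ratio and are dropped with a logged warning; a genotype losing all its
replicates is an error rather than a silent gap. Ratios are scale
invariant, so no cross-replicate signal normalisation is applied.

Competitive ratios approximate ratios of specificity constants but are not
identical to them; the package computes both and reports them side by
side.

## Michaelis–Menten kinetics

v = V_max·S/(K_M+S) is fitted by bounded nonlinear least squares
(scipy's trust-region reflective method, tolerances 1e-14). Initial values:
V_max⁰ = max observed v, K_M⁰ = the substrate concentration at half of
V_max⁰ by linear interpolation, floored at 1% of the smallest positive S.
Standard errors come from the local curvature (the covariance of the
least-squares estimate); k_cat = V_max/[E] with [E] in µM supplied by the
user, and specificity k_cat/K_M is always formed from the unrounded
internal estimates after converting K_M from µM to M. Published parameter
tables rounded to two significant figures cannot exactly reproduce the
specificity ratios computed from unrounded fits; ratios formed from
rounded entries can differ from the original by several percent, which is
why the tests assert specificity folds only to within that rounding gap.
Counts-per-minute data are converted to velocities by a user-supplied
specific-activity factor; no radiochemistry constants are hard-coded.

## Epistasis regression

Genotypes are bit vectors over the mutated sites. The design matrix uses
**reference (0/1) coding**: the column for a term T (a subset of sites) is
the product of the indicator columns in T; the intercept is the empty set.
Coefficients therefore read as effects relative to the all-ancestral
background, which is how mutation effects are naturally presented in
resurrection studies; ±1 (Walsh) coding is not offered because every
downstream quantity here (additive nulls, per-site effects) is
background-referenced. With this coding, saturated-model OLS coefficients
equal the combinatorial inclusion–exclusion epistatic coefficients, which
the tests verify against an independent oracle.

Fits are ordinary least squares through statsmodels. The response is the
raw preference ratio by default (a log scale is available); replicate-level
observations are the default fitting unit because they provide residual
degrees of freedom even under the saturated mean structure — fitting on
genotype means is allowed but the stepwise procedure then stops, with a
warning, at the last order that leaves residual df.

Per-term variance shares are **sequential (type-I) sums of squares** in the
canonical column order (term size, then lexicographic), divided by the
total mean-centred sum of squares; they sum to the model R². On a complete
balanced 2ⁿ design the ordering convention matters little for the dominant
term, but the convention is fixed and reported.

Model selection starts at the additive model and adds one full interaction
order at a time; nested models are compared by the F statistic
((RSS₀−RSS₁)/(p₁−p₀))/(RSS₁/(n−p₁)), stopping at the first non-rejection
at α = 0.05. Residual sums below 1e-12 of the total sum of squares are
treated as exact zeros so that noise-free data yield F = 0 (no
improvement) or F = ∞ (perfect complex fit) rather than ratios of
round-off error.

## Path accessibility

Accessibility operationalises "can the replacements accumulate in this
order without meaningfully losing function": a path is accessible iff at
every step the preference value does not fall by more than ε on the chosen
scale. Default ε = 0 (strict monotone non-decreasing), a single explicit
tolerance rather than per-step hypothesis tests — simpler, and it makes
the classification a deterministic function of the landscape that a
brute-force permutation check can verify exactly (the tests do, for
n ≤ 5). With ε = 0 the ratio and log-ratio scales classify identically;
they differ only for ε > 0, where ε is absolute on the chosen scale.

## Conservation vs structure

Conservation of a replaced site is counted two ways: the number of
descendant sequences retaining the focal residue at the alignment column
(a gap never counts as retained — documented because it depresses apparent
conservation at indel-prone columns), and Fitch parsimony's minimum number
of state changes across the descendant phylogeny (multifurcations folded
pairwise, equivalent to arbitrary zero-length resolution; the branch into
the ancestor itself is excluded from the count, and output metadata says
so). Structure distances are consumed from a CSV produced externally on a
crystal structure; measuring atoms in structure files is intentionally out
of scope. Correlations are Pearson r with **two-sided** p-values from the
t transform — directional claims in the literature are often one-tailed,
but two-sided is the conservative default and is stated in the output.

## Ancestral reconstruction

Likelihoods use Felsenstein pruning with per-node rescaling; posteriors at
an internal node come from the standard inside/outside decomposition with
the stationary distribution as root prior (marginal, per-node
reconstruction only — joint reconstruction is out of scope). Gaps and `?`
are missing data (partial likelihood one in every state). The engine is
exact: tests require equality with exhaustive enumeration over internal
states to 1e-10 on trees of ≤ 5 leaves, and re-rooting invariance (the
pulley principle) under reversible models.

Models are reversible CTMCs normalised to one expected substitution per
unit branch length. Built-ins: equal-exchangeability amino-acid model with
arbitrary frequencies, and the two-state GTR for presence/absence.
Empirical exchangeability matrices (JTT etc.) are loaded from plain-text
PAML-layout files rather than hard-coded. Rate heterogeneity is an
optional equal-weight discrete-gamma mixture (mean-of-bin rates,
normalised to mean one); free-rate mixtures are not implemented — a
deliberate simplification, since the engine takes branch lengths and
model parameters as given and does not optimise anything.

Length-variable regions: the alignment is recoded residue→1, gap→0 and
presence is reconstructed under the binary model. A residue is included in
an ancestral estimate where its presence posterior is ≥ 0.5 (ties toward
presence). Replacement lists between two ancestors count sites where both
have a residue present and the MAP states differ; presence flips are
reported separately as insertions/deletions.

## Synthetic data

The generators define the study conditions the tests run under.

* **Assay tables.** Genotype value = baseline + Σ effects over active
  terms, on the ratio scale by default. The methyl-benzoate signal is
  fixed at 100 units; the methyl-salicylate signal is value×100 plus
  Gaussian noise (sd on the ratio scale, i.e. noise_sd = 0.05 is a 5%
  coefficient of variation against the reference peak — a realistic
  integrated-peak-area precision). Noise is additive Gaussian on the
  declared scale, matching the regression's error model, with draws
  floored at a small positive value (lognormal noise is available via the
  log-ratio scale). The default preset plants baseline 0.09 (an ~11-fold
  benzoate preference), single effects 1.25/0.15/0.25/0.16, pairwise
  effects 0.15/0.30/0.15 of the other sites with the dominant one, and one
  third-order effect 0.30 — so the additive prediction for the quadruple
  mutant is 1.90 while its true value is 2.80, and the dominant site's
  sequential R² sits near 0.85 with 3 replicates at noise sd 0.05.
* **Alignments.** Root sequence drawn from the stationary distribution,
  evolved site-independently along the given tree; indels are a separate
  binary presence character evolved with branch lengths scaled by an indel
  rate, root fully present, absence masking the residue. True sequences at
  every labelled internal node are stored. Not emulated: among-site rate
  variation in the truth, indel length distributions (single-column
  events only), alignment error (the alignment is known, not estimated),
  and selection. Passing reconstruction tests therefore demonstrate
  correctness of the inference machinery under the generating model, not
  robustness to misalignment or model misspecification on real data.
* **Saturation curves.** v from the closed form plus Gaussian noise,
  clipped at zero.

All generators are deterministic given their seed.

## Problem sizes in tests and the acceptance script

Simulation-based checks use: 1000 replicate landscapes for the type-I
error of the order-2 test, 400 for power at 5σ planted interactions, 200
noisy curves for K_M recovery, and 50 replicate 8-leaf 200-site alignments
(mean root height 0.5 substitutions/site) for ancestral MAP recovery,
where the frozen pass threshold is 85% aggregate recovery (pilot runs gave
≈88–89%). These sizes give Monte-Carlo error comfortably below the margins
being asserted.

## Known limitations

* The epistasis model assumes homoscedastic additive error on the chosen
  response scale; strongly multiplicative noise should use the log scale.
* Sequential variance shares depend on term order off balanced complete
  designs; incomplete landscapes are rejected rather than imputed.
* The ASR engine does not estimate branch lengths, frequencies or rate
  parameters; it reconstructs under the model it is given.
* Accessibility treats each step deterministically; it does not model
  fixation probabilities or clonal interference.
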