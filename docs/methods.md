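# Methods

## The system and the data model

The package analyses serial growth–dilution coculture experiments: small
bacterial communities (pairs and trios drawn from a species pool) are grown
in batch for 48 h, diluted 1500-fold into fresh medium, and propagated for
38 such cycles. Since regrowing a 1500-fold dilution takes log₂ 1500 ≈ 10.55
doublings, each cycle corresponds to ~10.5 generations and the whole
experiment to ~400. Composition is measured only at a discrete set of
transfers (by default 0, 2, 5, 7, 10, 14, 19, 30, 38) by plating and
counting colonies, so the primary data are multinomial colony counts per
(community, replicate, transfer), converted to species fractions.

Two reference generations anchor the analysis: the *ecological* anchor
(~70 generations, transfer 7), by which compositions have converged from
their arbitrary inoculation fractions to an ecological equilibrium, and the
*evolutionary* endpoint (~400 generations, transfer 38). Target generations
resolve to the nearest sampled transfer, ties toward the earlier one; no
interpolation is attempted, because compositions exist only where plates
were counted.

## Distances, variability, and nulls

All compositional distances are Euclidean on the fraction vector and
normalized by √n for n species, following the convention of the experiments
this pipeline models. Note the true diameter of the simplex is √2 for any
n ≥ 2, so for trios the normalized distance cannot exceed √(2/3) ≈ 0.816 and
the prediction accuracy 1 − Δ/√n is bounded below by ~0.18; the
`normalization="true_max"` flag switches to √2 scaling where the absolute
scale matters.

Between-replicate variability at a generation is the mean distance of all
replicates from the medoid replicate (the replicate minimizing summed
distance to the others; ties break lexicographically on replicate id). The
medoid's zero self-distance is included in the mean by default — the
simplest convention, with `include_medoid=False` available. The
random-community null replaces the observed fractions with draws from a
flat Dirichlet (α = 1), matched per community to the observed replicate
count; observed-vs-null is a one-sided Mann–Whitney U test (midranks;
scipy's exact method for small tie-free samples; the fully degenerate
all-tied case returns p = 0.5).

The sampling noise attached to a plated fraction p with n colonies is the
standard deviation of the beta posterior, σ = √(p(1−p))/(n+1). Samples with
≤ 15 colonies are flagged during validation; the simulator never produces
them.

## Repeatability and its permutation null

For each replicate, the species whose relative abundance grew by the
largest factor between the two anchors is its maximally increasing member;
zero fractions are floored at the plating detection limit 1/(total
colonies + 1) (or a configurable pseudo-fraction, default 10⁻³, when counts
are unavailable) so fold changes stay finite. The community repeatability
score is the modal winner's frequency across replicates; communities with
fewer than three replicates present at both anchors are excluded.

The null model shuffles the individual (community, replicate, species) fold
changes of one size class — pairs and trios separately, never pooled —
reassigns them to the original slots, and recomputes every score and the
across-community mean, 2000 times. The p-value is the raw frequency of
permuted means at least as high as the observed mean (no +1 correction; a
`(b+1)/(m+1)` style estimator is deliberately not the default because the
raw frequency is the quantity defined for this analysis). The permutation is
implemented as a batched argsort of iid uniforms, so all iterations of one
size class vectorize; under a fixed seed iteration streams are reproducible.

Shuffling at the level of individual scalar values is the most literal
reading of pooling "across all samples"; it breaks the within-replicate
coupling of fold changes (which sum to ~1 in fraction space), which is
exactly what makes it a null for the *identity* of the winner rather than
for the magnitudes.

## The assembly rule

A trio's predicted composition assigns species i a fraction proportional to
the weighted geometric mean of its fractions in the two pairs containing
it; the default weights are equal (exponent 1/2 on each pairwise fraction),
which preserves the rule's fixed point (a trio equal to its prediction
scores accuracy exactly 1) and permutation equivariance, and is the only
self-contained choice — the weighting interface accepts alternatives. Zero
pairwise fractions are floored (shared configuration with the repeatability
module) before the product, so a species excluded in both its pairs is
predicted at a small positive fraction rather than exactly zero.

Accuracy is evaluated against the *mean* composition of the trio's
replicates at the resolved transfer (a per-replicate mode exists for
diagnostics). Competing predictors: pairs frozen at the ecological anchor;
species' monoculture carrying capacities normalized to sum to 1 (the
minimal proportional-abundance reading — the experiments leave the
transformation unspecified); and the uninformed barycentric guess.

The qualitative trio prediction takes each pair's winner as the species
winning the most replicates; a species winning both of its pairs is
predicted for the trio. When the three pairs have three different winners
(a transient, rock-paper-scissors-like topology) the fallback predicts the
species with the highest mean fold increase, averaged across both pairs and
replicates. Significance of the prediction accuracy is an exact one-sided
binomial tail at chance 1/3 (1/2 for the pairwise growth-based dominance
prediction); no normal approximation, since the trio counts involved are
small.

## Growth parameters

The growth rate is time-to-threshold: r = log₂(0.08/10⁻⁴)/t*, with t* the
first crossing of OD 0.08 found by linear interpolation between the
bracketing 10-min samples (interpolation removes most of the sampling
quantization; the estimator's bias for a logistic curve that decelerates
before the threshold is under 2%). Lag time is deliberately inside t*, so r
is an effective rate over the whole pre-threshold phase. Curves that never
reach the threshold yield an undefined rate and exclude their pair from the
dominance evaluation rather than being guessed. Replicate aggregation is a
two-level mean — technical replicates within an evolutionary replicate
first, then across evolutionary replicates — which differs from the flat
mean on unbalanced designs.

Carrying capacity is the end-of-cycle monoculture OD, smoothed per
replicate with a centered 3-point moving mean (truncated at the ends) and
averaged across all available cycles by default (a cycle range is
accepted); curves are assumed blank-corrected on input.

## The simulator

The latent model is competitive generalized Lotka–Volterra within each
cycle, dxᵢ/dt = xᵢrᵢ(1 − Σⱼ aᵢⱼxⱼ/Kᵢ), integrated with adaptive RK45 at
relative tolerance 10⁻⁸ (abundances below 10⁻¹² clamp to zero), followed by
division by the dilution factor. This choice produces the two-timescale
structure the analyses assume — convergence to a cycle-to-cycle fixed point
within a few transfers, then nothing, until drift is switched on — and the
analysis modules are entirely independent of it.

Evolution is phenomenological: after the onset transfer (default 7), log
growth rates and log interaction coefficients relax (rate 0.1/cycle, plus
per-cycle noise of SD 0.03) toward attractor values. Attractors are drawn
at the *species* level for rates (mean log-displacement +0.25 — most
strains get faster, as adaptation to a fixed medium produces — SD 0.4) and
at the *ordered-pair* level for interactions (SD 0.4), shared by every
community containing those species. Each community deviates from the shared
course with SD 0.1, and each replicate deviates from its community attractor
with SD 0.4/κ. κ (default 4) is the repeatability dial: large κ sends every
community's repeatability score to 1. Sharing attractors across communities
is what couples pair and trio evolution, and is the mechanism by which
same-generation pairwise outcomes remain predictive of trios throughout the
simulated coevolution.

The default design mirrors the experimental one: a 16-species pool, 44
pairs and 43 trios drawn from a 10-species clique so that every trio's
three pairs are themselves measured, 6 replicates per pair and 4 per trio
(within the experimental 3–18 range; chosen to keep a full run under a
minute on one CPU), 38 cycles. Ancestral interactions are drawn as
aᵢⱼ = c·Kᵢ/Kⱼ with c ~ U(0.25, 0.9), which guarantees stable ancestral
pairwise coexistence (both invasion conditions hold); trios and evolved
parameters may still lose species, which the coexistence filter removes
exactly as it would for real data. Observed compositions are multinomial
draws of 20–100 colonies (respecting the > 15-colony floor); sampling depth
`None` returns the latent fractions for noise-free tests.

Two shortcut generators bypass the ODE. `plant_repeatability` synthesizes
anchor-generation fraction pairs whose max-increaser is a planted species
with probability exactly q — initial fractions are flat-Dirichlet and fold
factors use disjoint log-uniform ranges (winner e^U(0.6,1.2), losers
e^U(−1.2,−0.6)), so the drawn winner is the strict argmax and q is exact.
`make_consistent_trio` returns the assembly-rule prediction verbatim as an
"observation", pinning the fixed point.

What the simulator does *not* emulate: genotype-level evolution (mutations,
sweeps, clonal interference), contamination, plate-count misidentification,
spatial structure, or multi-trophic interactions. Passing tests on
simulated data therefore certify the statistical machinery and its
calibration, not the biological fidelity of any particular gLV
parameterization.

## Numerical and design choices

- Tie-breaks are deterministic everywhere (species label order for argmax
  ties, lexicographic replicate id for medoid ties, earlier transfer for
  generation ties) and flagged where scientifically meaningful.
- All stochastic operations take explicit seeds; per-community and
  per-stage streams are derived from one master seed via seed sequences, so
  pipeline runs are byte-identical for a fixed seed (outputs carry no
  timestamps and tables are written in fixed row order).
- Counts win over an inconsistent fraction column (with a warning), since
  counts are the raw measurement.
- Problem sizes in the test-suite calibrations (500 null datasets for the
  type-I check, 200 planted communities, 10⁵–10⁶ Monte-Carlo draws for the
  Dirichlet oracle) were chosen so that three-standard-error bands are
  decisive while the whole suite stays fast.

## Known limitations

- The equal-weight geometric mean is one member of a family; fitted weights
  might do better on real data and can be supplied, but are not estimated.
- The carrying-capacity predictor is proportional-abundance by construction;
  it inherits no information about interactions.
- The shuffle null treats fold-change values as exchangeable scalars across
  communities of a size class; the alternative granularity permuting intact
  per-replicate fold-change vectors is exposed, but the scalar pool is the
  default and the calibrated path.
- Mann–Whitney switches to the normal approximation with midranks for
  larger samples; for the sample sizes here (tens of communities versus
  hundreds of null draws) this is standard but approximate.
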