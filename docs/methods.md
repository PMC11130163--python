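# Methods

## Data model

All spine and bouton analyses operate on 1-D arc-length coordinates along a
linear neurite, in micrometres, with the origin at the proximal end of the
imaged segment and positions on the closed interval [0, L]. Any consistent
origin choice preserves all inter-event distances, which is all the
statistics use. Presence is a per-session boolean; k sessions are assumed
equally spaced (3-day intervals by default). A spine that disappears and
reappears, e.g. (T, F, T), is counted as eliminated over the first interval
and newly generated over the second — re-gains are generation events, not
continuations.

Annotation-time rules (minimum spine length 0.4 µm, exclusion of headless
filopodia, splitting of "snowman" double-headed spines) belong to the image
annotation step: the package accepts already-annotated tables and enforces
only structural invariants (positions in range, ids unique, at least one
presence flag set, bouton size ratios ≥ 2). We treat all rows as fully
observed; edge-censoring of spines near the imaged segment's ends is not
modeled.

## Turnover, fates, carryover, survival

The generation percentage over an interval (s₁, s₂) is
100 · #(absent at s₁ ∧ present at s₂) / #(present at s₁); elimination
mirrors it with the roles of the sessions swapped. Dendrites with a zero
baseline count are flagged and excluded from per-dendrite means. Counting is
exact, so baseline − eliminated + generated = next-session count holds as an
identity on every dataset.

Over three sessions, spines present at session 2 (plus those eliminated over
the first interval) partition into four fate patterns: pre-existing
survived (T,T,T), pre-existing lost (T,T,F), generated survived (F,T,T) and
generated lost (F,T,F). Generated-survived spines are the *carryover*
spines. The carryover fraction divides the carryover count by the pooled
session-1 spine count of the group; published legends print these as "k of
N" pairs, and the 2×2 table for the exact test is built as (k, N − k) per
group — subtracting is required because the printed totals include the
events. The alternative reading of the totals (all-session union rather
than session-1 count) is exposed by simply passing different counts to
`table_from_counts`. Survival rates condition on session-2 presence:
100·GS/(GS+GL) for newly generated spines, and the analogue for
pre-existing ones.

## Clustering-bias inference

Events (generated or eliminated spines of one interval) are pooled across
branchlets by concatenating the branchlets end-to-end; gaps between
consecutive events on the pseudo-dendrite are the unit of analysis (n
events yield n − 1 gaps). The clustering probability at threshold d is the
fraction of gaps ≤ d ("within d" is inclusive). Because the concatenation
order is arbitrary, the observed statistic averages over 1000 random orders;
a single branchlet is order-invariant, and the exhaustive all-orders average
is used as a test oracle for up to 4 branchlets. Gaps spanning a
concatenation join are legitimate gaps; no special-casing is applied at
joins.

The null redraws n positions i.i.d. uniform on [0, ΣLᵢ] (concatenated mode)
or each branchlet's own count uniform on that branchlet with gaps pooled
within branchlets (per-dendrite mode), 100,000 iterations by default. The
empirical P is the plain fraction of iterations with null clustering
probability ≥ observed, so its resolution is 1/iterations; the
(k+1)/(n+1)-corrected variant is available as an option. The observed
average and the null use independent child RNG streams of the caller's
seed.

For n uniform points on [0, L] the joint law of the n + 1 spacings is
Dirichlet, and every spacing — including the two edge spacings — has
survival function (1 − d/L)ⁿ. The n − 1 adjacent gaps are a subset of the
spacings, so the null mean clustering probability is exactly
1 − (1 − d/L)ⁿ. (Note the exponent is n, not n − 1: the n − 1 counts the
gaps, not the Beta exponent.) The test suite checks the simulated null mean
against this closed form within 3 Monte Carlo standard errors.

The threshold sweep runs the test at several distances (3/6/9 µm by
default) and reports the threshold maximizing observed − null-mean
clustering probability — the Youden-style optimal separation of the two
distributions — with ties broken toward the smaller distance. Null draws
have no minimum inter-spine spacing (the null is plain uniform, with no
exclusion radius). Crosstalk distances are within-branchlet
nearest-neighbour distances from each generated spine to the eliminated
spines of the same interval, with "no partner" flags where a branchlet has
none.

Per-spine clustered membership (used to split carryover counts) is a
within-branchlet rule with no concatenation: a generated spine is clustered
iff another generated spine of the same interval lies within d on the same
branchlet.

## Bouton detection and matching

Candidate peaks on an axial intensity profile are local maxima with
prominence above a quarter of the profile's median intensity (a relative
floor, keeping detection invariant to global intensity scaling). The
flanking backbone of a candidate at position p is the median intensity over
[p − 2w, p − w] ∪ [p + w, p + 2w] (w = 2 µm by default), excluding samples
within 1 µm of other candidates; the median is robust to nearby bumps, which
is why it was chosen over a mean — the backbone estimator is otherwise
unconstrained by the detection rule itself. A candidate is a bouton call iff
peak/backbone ≥ 2. This threshold rule overestimates generation and
elimination when sub-threshold varicosities cross the 2× line between
sessions; the package reproduces the rule as stated and documents the bias
rather than correcting it.

Identity across sessions is greedy closest-first matching under a 1-µm
tolerance; no drift/registration correction is modeled. Matching conserves
counts (|a| − eliminated = |b| − generated = matched) and swapping the
sessions swaps the generated and eliminated labels. Rates are reported per
µm of axon (events/length) and as percentages (per-length rate ÷ mean of
the two sessions' densities × 100); the two-session mean matches the
interval over which the events are counted. Projection stratification
groups per-axon rate vectors by (group, projection) and reports mean ±
s.e.m. with counts; between-stratum hypothesis tests are delegated to
standard statistical routines and are not re-implemented here.

## Volume quantification

Spine volumes near the diffraction limit are approximated by partial z-sums:
a 5-plane moving average along z (2 µm at 0.5-µm plane spacing) of the
stack, truncated at the boundary planes — truncation avoids fabricating
intensity outside the stack, and the window must be odd and no larger than
the plane count. The normalized volume V is the maximum of the averaged
stack over the spine ROI divided by the maximum over the adjacent shaft ROI
(ROIs are axis-aligned boxes, 0-based half-open); the ratio cancels global
intensity scale. A nonpositive shaft peak raises a "degenerate shaft ROI"
error. The small/large split at V = 0.15 uses V ≤ 0.15 for the small group
(ties assigned small, documented).

## Exact statistics

Fisher's exact test enumerates the hypergeometric support of the 2×2 table
with fixed margins and sums the probabilities of all outcomes whose
probability does not exceed the observed table's (the standard two-sided
"small-p" rule), with a 1e−7 relative guard against floating-point ties.
The implementation is cross-checked in the tests against an exact-rational
brute-force enumerator and against scipy's implementation.

Module concordance is the percentage of genes whose two logFC values share a
sign (first/third quadrants); genes with either logFC exactly zero are
excluded from the denominator, since the quadrant rule is undefined on the
axes (measure-zero on real data). The one-sided P against chance is the
exact binomial tail P(X ≥ k), X ~ Bin(n, ½), computed as a rational
Σ C(n,i)/2ⁿ (ties counted in the tail, i.e. ≥ observed); a log₁₀ tail is
also reported for modules where the P underflows. Modules with fewer than 8
analyzable genes are skipped and reported as such. No multiple-testing
adjustment is applied across modules; per-module P-values are reported
individually. Gene selection keeps genes with adjusted P strictly below the
threshold in *both* comparisons (0.1 by default, 0.05 as the stricter
preset), and Pearson's r on the selected paired logFC values comes from the
standard t transform.

## Synthetic-data generators

All generators derive child RNG streams from a single root seed, so outputs
are reproducible and independent of the order in which modules are invoked.

**Spine datasets.** Branchlet lengths are Normal(31.7, 5.9) µm — the
reported mean span per branchlet; the spread is exposed as a free parameter
since the printed ± may be read as s.d. or s.e.m. Session-1 spine counts
are Poisson(density·L) at 0.6 spines/µm (a typical adult tuft-dendrite
density), placed uniformly. Per interval, each spine dies with probability
sigmoid(logit(p_elim) + β·(µ_logV − log V)) — β = 0 gives the group preset
exactly; β > 0 biases elimination toward small spines — and new spines
number Binomial(n_present, p_gen), the minimal model consistent with rates
reported as percentages of the prior session's count. Group presets are the
reported 3-day rates: generation/elimination 5.3%/8.0% (unexposed controls)
and 10.2%/12.5% (VPA-exposed). Each new spine is placed, with probability
π_c (the clustering bias), uniformly within δ_c (3 µm default) of a
uniformly chosen earlier new spine of the same interval, clipped to [0, L];
otherwise uniformly on [0, L]. Positions are continuous; volumes are
log-normal(−1.2, 0.8) (median normalized volume ≈ 0.30) and fixed at birth.
The generator emits single linear branchlets only — no branching topology —
and uniform placement with no refractory spacing, which is exactly the
clustering test's null when π_c = 0.

**Axon profiles.** Boutons follow the same binomial birth/death scheme per
axon (densities 0.12/0.08 per µm for ipsilateral/contralateral axons, so
the control group shows the ipsilateral > contralateral density ordering).
Profiles are baseline 1 plus Gaussian bumps (σ = 0.5 µm) at bouton
positions, sampled every 0.1 µm, with peak-to-backbone amplitude ratios
drawn uniform on [2.2, 3.5] for true boutons and [1.2, 1.8] for decoy
varicosities, plus i.i.d. Gaussian noise (σ = 0.05 by default). True bouton
and decoy positions keep a 2-µm minimum spacing by rejection sampling:
varicosities closer than the bump width merge into a single intensity peak
and are not resolvable as separate ground-truth objects at the emulated
resolution.

**Z-stacks.** 51 planes at 0.5 µm, built from isotropic Gaussian blobs over
an optional cylindrical shaft running along x, plus seeded noise. Because
spine and shaft blobs share the same σ in the oracle constructions, the
moving average attenuates both equally and the normalized-volume ratio is
analytically known.

**Paired logFC tables.** Each gene's concordance indicator is
Bernoulli(f_c); its (model, human) logFC pair is rejection-sampled from a
bivariate normal with correlation ρ conditioned on the assigned sign
pattern. When f_c equals the natural sign-agreement probability
½ + arcsin(ρ)/π the mixture is exactly bivariate normal and the sample
correlation recovers ρ; other f_c values trade correlation fidelity for the
configured concordance, which is the quantity the concordance statistic
consumes. Adjusted-P columns make a configurable fraction of genes pass the
0.1 threshold.

**What the generators do not emulate.** No imaging noise or registration
error on spine positions; no observer mis-tracking of identity; no spatial
heterogeneity of turnover along a branchlet beyond the injected clustering;
no correlation between spine volume and clustering; modules are independent
in the logFC generator. Passing tests therefore demonstrate the estimators'
correctness and calibration under the stated stochastic model, not
robustness to annotation error in real images.

## Problem sizes and numerical choices

The test suite and the acceptance script scale the Monte Carlo work to
what the inferences need: calibration and power use 200 generated datasets
of 12 branchlets with 1000 null iterations and 150 concatenation orders
each (the empirical-P resolution of 10⁻³ is ample for testing uniformity
and a 0.05 criterion), the closed-form check uses 10,000–20,000 iterations,
and production defaults remain 100,000 iterations / 1000 permutations as
used in the clustering result objects. Calibration of the false-positive
rate is checked with a Kolmogorov–Smirnov test against uniform at α = 0.01
over the seed sweep; power at π_c = 0.8, δ_c = 3 µm exceeds 90%, and the
threshold sweep recovers δ_c = 3 µm as the optimal cut-off.

Known limitations: the clustering probability treats gaps, not spine pairs,
as the unit (the all-pairs alternative is inconsistent with n − 1 pair
counts); the empirical P cannot resolve below 1/iterations; greedy bouton
matching is not guaranteed optimal when calls are denser than twice the
tolerance; and the per-dendrite null conditions on observed per-branchlet
event counts, so branchlets with fewer than two events contribute no gaps.
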