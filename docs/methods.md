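# Methods

This note records the statistical models implemented in `otucensus`, the
assumptions they make, the parameters that matter, and the choices taken
where the methodology was genuinely open.

## Data model and filtering

The unit of input is an OTU-by-sample table of nonnegative integer read
counts, with every sample assigned to exactly one study.  Studies are the
sampling units of all incidence statistics: studies differ in environment,
primers and protocol, so samples within a study are not independent draws
from the global pool, but distinct studies approximately are.

The **detection filter** retains an OTU only if it was detected (at least one
read) in at least two samples of the same study.  This is an aggressive
guard against spurious OTUs (sequencing errors, PCR chimeras), which
dominate the singleton tail of raw amplicon clusterings.  Because the rule
is applied separately per study, each study remains an independent sampling
unit afterwards, and study-level presence in the incidence matrix uses the
same two-samples rule.  The filter trades sensitivity for specificity: it
also removes genuinely rare biological OTUs, which is exactly what the
downstream estimators are designed to add back.

## Incidence-based richness estimators

From the binary OTU-by-study matrix we tally the frequency counts Q_i
(number of OTUs present in exactly i of T studies), with
S_obs = Σ Q_i.  All estimators return S ≥ S_obs; mass conservation
(Σ Q_i = S_obs, Σ i·Q_i = total incidences) is asserted on every tally.

- **Chao2** — S_obs + ((T−1)/T)·Q₁²/(2Q₂); when Q₂ = 0 the bias-corrected
  form S_obs + ((T−1)/T)·Q₁(Q₁−1)/2.
- **iChao2** — adds ((T−3)/(4T))·(Q₃/Q₄)·max(Q₁ − ((T−3)/(2(T−1)))·Q₂Q₃/Q₄, 0).
  When Q₄ = 0 the conventional substitution Q₄ ← 1 is applied and flagged in
  the diagnostics.
- **ICE** — cutoff k = 10: frequent OTUs (incidence > k) are counted as is;
  for the infrequent set, sample coverage C = 1 − Q₁/N_infr and a
  coefficient of variation correction γ² are computed, with T_infr the
  number of studies containing at least one infrequent OTU.  When every
  infrequent OTU is a unique (C = 0) the estimator is flagged inestimable
  rather than returning a number.
- **tWLRM** — regression of y_i = log((i+1)Q_{i+1}/Q_i) on log(i+1) over the
  contiguous nonzero run Q₁…Q_τ (τ ≥ 3 required), extrapolated to i = 0;
  Q̂₀ = Q₁/exp(ŷ₀).  Weights are inverse delta-method variances
  w_i = (1/Q_i + 1/Q_{i+1})⁻¹ — the source literature leaves the weighting
  unspecified, so this is a documented package choice.  For geometrically
  decaying counts Q_i = c·ρ^i the extrapolation is exact (Q̂₀ = c), which is
  the oracle used in the tests.
- **Breakaway-style ratio regression** — models y_i = (i+1)Q_{i+1}/Q_i with
  rational functions of i of orders (0,1), (1,1), (1,2), (2,2), fitted by
  iteratively reweighted least squares (3 IRLS passes, delta-method
  variances).  The lowest order whose weighted lack-of-fit χ² has p > 0.05
  and whose y(0) > 0 is selected; Q̂₀ = Q₁/y(0); the SE comes from the delta
  method on the fitted intercept.  If no order qualifies, the estimator
  falls back to Chao2 with a diagnostic flag.  This is an approximation to
  the published method of the same spirit; digit-exact agreement with other
  implementations is not expected.
- **iChao2split** — studies are randomly assigned to four near-equal groups
  (sizes differing by at most one, uniform assignment), group presence is
  presence in any member study, and iChao2 is computed with T = 4; the mean
  over 100 random splits is the estimate and their SD the standard error.
  This deliberately discards the per-study resolution to blunt the
  unequal-effort problem: individual studies are far from equivalent
  sampling units, but four random pools of ~T/4 studies are nearly
  exchangeable.
- **Coverage-ratio richness** — S = N_census/ρ with ρ the fraction of an
  independent reference collection recaptured by the census; per-taxon
  fractions are supported.

A CatchAll-style mixed-exponential estimator is deliberately not
implemented; the CLI reserves the method name and reports it as such.
Standard errors for the closed-form estimators default to a seeded
studies-bootstrap (resampling study columns with replacement) rather than
closed-form variance formulas.

## Good–Turing abundances, MRA and coverage

Per sample, α = ((r+1)/N)·(N_{r+1}/N_r).  The estimator's empty-class
problem (N_{r+1} = 0, always true for the largest count class) is handled by
falling back to the maximum-likelihood frequency r/N; smoothing schemes
would add structure the data cannot verify.  A useful exact identity: when
the occupied count classes are contiguous 1…R, the non-fallback abundances
sum to (N − N₁)/N, which the tests assert to 1e-12.

The MRA averages per-sample α over **all** samples, zeros included — an OTU
detected in 1 of 100 samples at α = 10⁻³ has MRA 10⁻⁵.  Per-sample
estimation before averaging avoids biasing MRAs toward OTUs that happen to
occur in deeply sequenced samples; pooling reads across samples or within
studies is deliberately not offered.

Good's coverage uses the rarest retained class — doubletons, since
single-read OTUs are filtered out: P₁ = 2N₂/N estimates the probability that
a fresh read hits a one-read-class OTU, and P ≥ 1 − 2P₁ follows from
assuming the unseen mass P₀ does not exceed P₁.  Two caveats are worth
stating plainly.  First, the P₀ ≤ P₁ step is heuristic.  Second, the bound
concerns the probability of hitting an OTU *observed* by sequencing; it does
not account for genuine abundance carried by OTUs removed by the detection
filter.  In a real census the removed OTUs are presumed artifacts, so this
distinction vanishes; in a synthetic census every OTU is real, the filter
removes real mass of order 10⁻³, and the bound (whose slack is ~4N₂/N, order
10⁻⁵) is anticonservative with respect to the retained set.  The test suite
therefore checks conservativeness against the detected-OTU universe, with
the doubleton class tallied before filtering — the form in which the
guarantee actually holds (20/20 replicate censuses).

## Discovery model and log-normal reconstruction

MRAs are histogrammed on an equal-width log10 grid (default width 0.25
decades, aligned to integer multiples of the width; zero-MRA OTUs are
excluded and counted).  The same grid is applied to a half-depth rarefied
twin of the census, regenerated through the same filter.

Per bin, reads are modeled as Poisson(λ) and discovery as ≥2 reads:
P(λ) = 1 − e^(−λ) − λe^(−λ), evaluated as the regularized incomplete gamma
function γ-form Pr[Poisson(λ) ≥ 2] to stay accurate at small λ (the literal
expression loses all precision below λ ~ 10⁻⁷).  The full/rarefied count
ratio f/f_r identifies λ via P(λ)/P(λ/2), strictly decreasing from 4 to 1;
the root is found by Brent bracketing on [10⁻¹², 10³].  Bins with
f/f_r ≤ 1 are treated as completely detected (F = f); bins with ratio ≥ 4
are unresolved and excluded; bins where either census holds fewer than 5
OTUs are flagged insufficient-counts and excluded, because the ratio of two
small Poisson counts can imply detection corrections of several orders of
magnitude from pure noise.  At real-census scale (hundreds to thousands of
OTUs per bin) the floor is inactive.

The log-normal fit uses natural logs: F_bin = S·Δ·φ((ln α − μ)/σ)/σ with Δ
the bin width in ln units, fitted by unweighted least squares (a
Poisson-weighted option exists behind a flag).  This parameterization makes
the fitted amplitude S equal the model's integral over the whole real axis,
so the total-richness step is an identity, not a quadrature.  Initial values
come from the F-weighted moments of ln α; at least 4 resolved bins are
required.

## Neutral steady-state bound

S = 2rN/d for global cell count N, neutral per-site drift rate r
(substitutions/site/generation) and OTU divergence radius d (0.03 for 97%
clusters, 0.01 for 99%).  Only this closed-form bound is implemented; no
refinement terms.  S is homogeneous of degree 1 in r and N and −1 in d, and
with N = 10³⁰, r = 5×10⁻¹⁰–4×10⁻⁹, d = 0.03 it spans 10²²–10²³ — 16–17
orders of magnitude above empirical richness estimates of 0.8–1.6 million.

## Consensus taxonomy

Hits below 60% identity never vote.  If any hit is a perfect match, exactly
the perfect matches vote; otherwise all hits within 5 percentage points of
the best hit vote (inclusive at exactly best−5; all identity gates use a
10⁻⁹ tolerance).  The assignment is the deepest rank prefix shared by all
voters, comparing ranks positionally on semicolon-split paths; disagreement
at the domain rank, or no qualifying hits, leaves the query unidentified.
Widening the voting band can only shorten the consensus path.  A distance
histogram (100 − best identity, default 2-point bins) summarizes how far
queries sit from the reference.

## Synthetic census generator

The generator emulates the count-level structure the analysis assumes, and
nothing more: S_true OTUs with global relative abundances drawn log-normally
(natural-log μ, σ; renormalized to sum to 1), a study/sample hierarchy,
per-sample abundances perturbed by an independent multiplicative
log-normal factor exp(N(0, sample_noise_sigma)) and renormalized (the
minimal structure that makes MRAs differ from single-sample abundances —
there is no canonical between-sample model), and reads drawn as independent
Poisson(depth × per-sample abundance) — matching the discovery model's
Poisson assumption exactly, and differing from multinomial sampling only at
O(1/depth).  One seed drives a hierarchical RNG stream
(census → study → sample), so subsets are reproducible.  A binomial thinner
produces the half-depth twin.

Defaults — S_true = 5,000, σ = 1.5, 40 studies × 10 samples, depth 5×10⁴,
sample_noise_sigma = 0.5 — are desk-scale study conditions: large enough for
the estimators' asymptotics to be meaningful, small enough that the full
chain runs in seconds.  The validation suites and acceptance script run at
S_true up to 10,000 and depth 2×10⁴.  What the generator does **not**
emulate: sequences and sequencing error (so "spurious OTUs" do not exist in
synthetic data — every filtered OTU is a real one), primer bias,
between-study environmental structure (studies are exchangeable draws around
one global composition), and the real census's scale (~7×10⁵ OTUs across
~3×10⁴ samples, with abundances reaching 10⁻¹⁰).  Passing tests therefore
demonstrate the correctness and internal consistency of the statistical
machinery under its own assumptions — not robustness to the violations real
data brings (unequal study effort, non-Poisson overdispersion, artifact
OTUs).

## Numerical choices and known limitations

- Bisection tolerance 10⁻¹² on λ; ratio residuals below 10⁻¹⁰ at the root.
- Good–Turing per-OTU abundances are jumpy for high count classes (where
  N_r ∈ {0, 1, 2}): individual MRAs can be off by ~20% even at depth 10⁵,
  though medians are within a few percent.  The log-binned histogram (0.25
  decades ≈ 78% width) absorbs this.
- The discovery model degrades when the abundance distribution is so wide
  (σ ≳ 2) that resolved bins hold few OTUs; the insufficient-counts floor
  protects the fit, but tail mass beyond the resolved bins is then
  extrapolated purely by the log-normal assumption.
- Estimator standard errors are approximations (delta method or bootstrap);
  between-estimator spread is a more honest uncertainty assessment than any
  single SE.
- The breakaway-style estimator is a reimplementation of the ratio
  regression idea, not a port; on heavy-tailed frequency counts its model
  selection can differ from other implementations.
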