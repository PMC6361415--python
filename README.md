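# otucensus

Statistical estimation of global microbial (16S OTU) richness from
multi-study incidence data.

Large composite amplicon surveys pool hundreds of independent sequencing
studies to census bacterial and archaeal diversity: reads are clustered into
operational taxonomic units (OTUs), spurious clusters are filtered out, and
the question becomes *how many OTUs exist globally, given how many each study
discovered?*  `otucensus` implements the statistical layer of such a census:
everything downstream of the OTU table.

## What it computes

**Incidence-based richness.**  Treating each study as a sampling unit, let
Q_i be the number of OTUs detected in exactly *i* of *T* studies
(an OTU counts as "detected in a study" only if found in at least two samples
of that study, a guard against sequencing-error and chimera artifacts).
The suite estimates total richness S = S_obs + Q_0 via:

- **Chao2**: S_obs + ((T−1)/T) · Q₁²/(2Q₂), the classical lower bound;
- **iChao2**: Chao2 plus a Q₃/Q₄ correction term;
- **ICE**: coverage-based estimation over the infrequent OTUs (Q₁–Q₁₀);
- **tWLRM**: weighted linear regression of log-transformed consecutive
  count ratios, extrapolated to predict Q₀;
- **breakaway-style ratio regression**: nested rational-function models of
  the ratios (i+1)Q_{i+1}/Q_i fitted by IRLS;
- **iChao2split**: studies pooled into four random global sampling units,
  iChao2 on the resulting Q₁–Q₄, averaged over 100 random splits;
- **coverage-ratio richness**: S = N_census/ρ, where ρ is the fraction of an
  independent reference collection recaptured by the census.

**Good–Turing abundances and coverage.**  Within a sample of N reads, an OTU
seen r times gets relative abundance α = ((r+1)/N)·(N_{r+1}/N_r); its mean
relative abundance (MRA) is the average over all samples (zeros included).
Census coverage is bounded by Good's formula from the rarest retained class:
P₁ = 2N₂/N and P ≥ 1 − 2P₁.

**Rarefaction-calibrated discovery model.**  Detection of an OTU requires at
least two reads, so under Poisson sampling the discovery probability is
P(λ) = 1 − e^(−λ) − λe^(−λ).  Comparing per-MRA-bin OTU counts between the
census and a half-depth rarefied twin identifies λ bin by bin (the count
ratio P(λ)/P(λ/2) falls strictly from 4 to 1), giving the extant count
F(α) = f(α)/P(λ) per bin.  A log-normal model
F(α) ≈ S·Δ·N(ln α; μ, σ²) is then fitted by least squares; its amplitude S
is exactly the model's integral over the real axis — the total extant
richness.

**Neutral null bound.**  A steady-state model with constant global cell
count N, phylogeny-independent turnover and neutral per-site drift at rate r
predicts about 2rN/d OTUs at divergence radius d — with N ≈ 10³⁰ and
r ≈ 5×10⁻¹⁰–4×10⁻⁹ that is 10²²–10²³, some 16–17 orders of magnitude above
empirical estimates.

**Also included:** sample-based accumulation curves, the expected overlap of
a new study with the existing census, consensus taxonomy assignment from
alignment hit tables (60% identity floor, top-hit band voting, deepest
shared rank), and a synthetic census generator (log-normal abundances,
study/sample hierarchy, Poisson read sampling, binomial rarefaction) so the
whole chain can be validated against known ground truth.

## Worked example

```python
from otucensus import *

cfg = CensusConfig(s_true=10_000, sigma=1.5, n_studies=40,
                   samples_per_study=10, depth_per_sample=20_000, seed=1)
table, truth = generate_census(cfg)          # OTU x sample read counts
filtered, removed = detection_filter(table)  # >=2 samples per study rule
m = incidence_from_counts(filtered)          # OTU x study presence
fc = frequency_counts(m)                     # Q_1 ... Q_T

print("observed OTUs:", fc.s_obs)
print("iChao2:   %.0f" % ichao2(fc).s_hat)
print("tWLRM:    %.0f" % twlrm(fc).s_hat)
print("breakaway:%.0f" % breakaway_ratio_regression(fc).s_hat)

rarefied, _ = detection_filter(rarefy_census(table, 0.5, seed=2))
hist = bin_mra_histogram(mean_relative_abundance(filtered),
                         mean_relative_abundance(rarefied))
ln = fit_lognormal(extant_histogram(hist))
print("log-normal total: %.0f (mu=%.2f, sigma=%.2f)" % (ln.s_total, ln.mu, ln.sigma))
```

Output:

```
observed OTUs: 9887
iChao2:   9986
tWLRM:    10300
breakaway:10090
log-normal total: 9936 (mu=-10.41, sigma=1.46)
```

Of 10,000 true OTUs the census observed 9,887; every estimator adds back
unseen richness and lands within a few percent of the truth, and the
reconstructed abundance distribution recovers the generating log-normal
(true post-normalization parameters here: μ ≈ −10.3, σ ≈ 1.49).

The same steps are available from the shell via the `otucensus` CLI
(`simulate`, `filter`, `incidence`, `freqs`, `richness`, `coverage`, `mra`,
`lognormal`, `accumulate`, `nullmodel`, `taxonomy`, `recapture`).

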