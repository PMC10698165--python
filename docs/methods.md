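# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish about real data.

## Trophic metrics from amino-acid δ¹⁵N

Food chain length (FCL) for a single specimen is
`FCL = (δ¹⁵N_Trp − δ¹⁵N_Scr − β)/TDF + 1`, where the trophic side uses
glutamic acid, alanine and proline and the source side phenylalanine and
glycine. Two estimators are exposed:

- **Glu–Phe**: the canonical single-pairing estimate.
- **Multi-AA**: δ¹⁵N_Trp and δ¹⁵N_Scr are inverse-variance weighted means
  over the amino acids present, with weights 1/σ² from the per-AA
  procedural reproducibility SDs (defaults: Glu 0.24, Ala 0.08, Pro 0.25,
  Phe 0.13, Gly 0.19 ‰). β and TDF are likewise replaced by
  1/SD²-weighted means over the calibrated pairings available among the
  amino acids present.

Calibration constants live in `CalibrationConstants` and are loadable
from YAML, never hard-coded in the operations. The Glu–Phe pairing uses
the canonical teleost values β = 3.6 ± 0.5 ‰ and TDF = 5.7 ± 0.3 ‰; the
remaining pairings carry representative defaults and should be replaced
with a study-specific calibration where one exists. The weighting of β
and TDF by their calibration SDs mirrors the 1/σ² form of the δ¹⁵N
weighted mean; this is a design choice, as is keeping the protist-index
residuals in ‰ (a z-scored variant is available via `standardize=True`).

Choices worth knowing:

- FCL estimates below 1 are returned unclamped with a `TrophicWarning`;
  a negative number of trophic steps indicates a data problem the caller
  must see, not hide.
- Partial amino-acid profiles renormalise weights over the amino acids
  present and are flagged `partial` rather than dropped, so a pipeline
  can reproduce a complete-profiles-only analysis by filtering on the
  flag.
- Energy transfer efficiency is `GGE^(FCL−1)` with GGE = 0.20 per step by
  default; efficiency of a primary consumer (FCL = 1) is 1 by convention,
  and log₁₀(efficiency) is linear in FCL with slope log₁₀(GGE).
- The heterotrophic-protist index is the OLS residual of δ¹⁵N_Ala on
  δ¹⁵N_Glu over a cohort (≥3 specimens, with intercept). Alanine is the
  one trophic amino acid that also enriches through protistan grazers, so
  positive residuals suggest a longer protistan pathway.

## Random-walk state-space model

Annual series are modelled as a local level observed with replicate
noise: `x_t = x_{t−1} + w_t, w_t ~ N(0, Q)`;
`y_{i,t} = x_t + v_{i,t}, v_{i,t} ~ N(0, R)`. Years without observations
stay on the latent grid and are interpolated by the model; the posterior
variance at a missing year always exceeds that of its observed
neighbours.

Because the model is linear-Gaussian, it is sampled exactly by conjugate
Gibbs: a joint forward-filter backward-sampling draw of `x_{1:T}` given
(Q, R), then inverse-gamma full-conditional draws of Q (from state
increments) and R (from observation residuals). No generic MCMC engine is
involved; correctness is checked against an independent Kalman
filter/smoother (itself verified against hand-worked three-year
recursions and against statsmodels' local-level smoother).

Defaults and priors (all overridable in `SSMConfig`):

- Priors: inverse-gamma(0.01, 0.01) on Q and R (weakly informative,
  conjugate); x₁ ~ N(mean of the first observed year's values, 10 ×
  sample variance of all observations).
- Sampler: 3 chains, 20,000 iterations, burn-in 5,000, thinning 5. On the
  reference design (45 years, 5 replicates/year, 40% missing) this takes
  ~10 s on one CPU and reaches split-chain R̂ ≤ 1.01 comfortably; the
  convergence criterion is R̂ ≤ 1.05 for every state and variance, and a
  `ConvergenceWarning` plus `converged=False` is raised otherwise —
  never a silent pass. Chains are initialised with overdispersed
  variances so R̂ is meaningful.
- The observation family is normal; replicate observations within a year
  enter through their sufficient statistics.
- `fixed_q`/`fixed_r` pin a variance instead of sampling it (used for
  exact-inference tests, degenerate all-identical series, and
  known-measurement-variance fits). A series whose observed values are
  all identical cannot separate Q from R and is rejected with advice to
  set `fixed_r`.
- MAP per year is the mode of a Gaussian-kernel density estimate over
  pooled post-burn-in draws (Silverman bandwidth `0.9·min(sd, IQR/1.34)·
  n^{−1/5}`, 512-point grid, draws thinned to ≤4,000 for evaluation);
  the posterior median is reported alongside, and the 95% interval is the
  central 2.5–97.5 percentile band. A point-mass posterior returns that
  point.
- Reproducibility is exact: one integer seed spawns per-chain PCG64
  streams, and identical seed + config + data give bit-identical draws.
- An optional log-scale switch fits strictly positive series on the log
  scale and reports summaries back on the natural scale.

## Cross-correlation

The cross-correlation at lag k is the Pearson correlation of
`(x_{t+k}, y_t)` over overlapping years — positive k means x leads y.
This orientation is fixed and written into every output header.
Correlations are computed pairwise-complete per lag; lags with fewer than
3 overlapping pairs are reported missing, never zero. The ±1.96/√n band
(n = lag-0 overlap) is the two-sided 5% bound for white noise; for 45
years it is 0.292, i.e. ~±0.30.

The band is descriptive only. Two caveats are deliberate: no p-values are
attached (model-interpolated series are not a valid basis for
significance tests), and for integrated (random-walk-like) series the
band does not calibrate level correlations at all — independent walks
routinely show |r| far above it (spurious regression). Where the tests
assert band calibration or lag placement they therefore do so on
differenced series, whose innovations are white under the model; level
correlations are still reported, as is conventional, but only their sign
and magnitude are interpreted, not their band exceedance.

## Community change detection

Taxon abundance matrices are transformed elementwise by ln(a + 1) (the +1
offset handles true zeros and is configurable), converted to Bray–Curtis
dissimilarities `Σ|a−b|/Σ(a+b)`, and clustered agglomeratively under a
chronological-contiguity constraint: only temporally adjacent clusters
may merge, and each merge minimises the increase in within-cluster
dispersion computed from squared dissimilarities
(`Σ_{i<j} d²_ij / |C|`) — standard stratigraphic practice. The full
merge-height sequence is returned; zone boundaries for any zone count are
recovered by undoing the last merges. A largest-gap heuristic suggests a
zone count, but the final choice is left to the user: break depth is a
judgement the analyst should make on the full profile, not something to
automate away. A pair of all-zero years has dissimilarity 0 by convention
(with a warning). Z-scores use the sample SD (denominator n−1).

## Synthetic data: what it emulates, and what it does not

`simulate_coupled_system` builds a complete study-like dataset: latent
random walks for FCL (start 3.0, Q = 0.04) and the source-δ¹⁵N baseline
(start 8 ‰), ~45% of years sampled with 3–15 specimens each, per-specimen
amino-acid values from the forward model with procedural noise, companion
series (log₁₀ size ratio, log₁₀ spawning stock biomass) observed with 5
replicates/year at variance 0.25, and an 8-taxon lognormal community
matrix. Couplings are constructive: the size-ratio walk's innovations
load on the FCL innovations to target a lag-0 correlation of +0.8, and
the SSB walk loads on the previous year's size-ratio innovation at −0.6;
targets therefore hold in expectation on the innovations (measured means
0.785 and −0.60 over 200 replicates), while level correlations of the
integrated walks scatter widely around them, as real trending series do.
An optional boom-bust step enters as an extra innovation at the step year
(default ΔFCL +0.5, Δsource −2.5 ‰) and so propagates through the
couplings; the community matrix shifts at the same year, dominated by a
collapse of the large calanoid taxon. Default magnitudes not tied to a
stated design choice are arbitrary-but-realistic and documented here
once; they are study conditions, not tuning knobs.

The forward model generates trophic amino acids with the same pooled
weighted β̄/TDF̄ the multi-AA estimator uses, and zero per-AA source
offsets by default, so the noiseless forward→inverse round trip is exact
by construction; this validates the estimator algebra, not the field
accuracy of any particular calibration. Likewise, passing tests on this
generator show the pipeline recovers signals under its own model
assumptions (Gaussian noise, a single shared baseline across source AAs,
constant calibration constants over time); they do not establish
robustness to preservation artefacts, spatial heterogeneity among
stations, diet-dependent TDF variation, or non-Gaussian observation
error, none of which are simulated.

## Verification problem sizes

The test suite runs the full stack at deliberately modest sizes: default
sampler settings on one 45-year reference fit; 50 reduced-iteration
replicate fits for the Q-coverage check (≥42/50 intervals must cover
truth); a 10-year fixed-variance fit against the exact smoother (per-year
Monte-Carlo standard errors from the effective sample size, with
multiplicity headroom: at least 9 of 10 years within 2 SE and all within
4); 1,000 white-noise pairs for band calibration; and one boom-bust
scenario fit at 3 × 6,000 iterations for end-to-end recovery. The whole
suite completes in about two minutes on a single CPU.
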