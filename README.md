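# trophlink

Trophic time-series analysis for larval fish: from amino-acid nitrogen
isotopes to food chain length, energy transfer efficiency, and their
relationship to population dynamics.

## The scientific problem

Boom-and-bust cycles of small pelagic fishes (anchovy, sardine) are poorly
predicted by spawning-stock models. One candidate driver is the trophic
environment met by young larvae: when the food chain between phytoplankton
and larva is long, little of the primary production energy reaches the
larva, and survival through the critical early weeks drops.

Compound-specific isotope analysis of amino acids (CSIA-AA) makes this
testable on archived larvae. "Source" amino acids (Phe, Gly) record the
δ¹⁵N baseline at the bottom of the food chain; "trophic" amino acids
(Glu, Ala, Pro) additionally enrich by a trophic discrimination factor
(TDF) with every transfer. Food chain length for one larva is

    FCL = (δ¹⁵N_Trp − δ¹⁵N_Scr − β) / TDF + 1

with β the trophic–source offset in primary producers. A multi-amino-acid
variant replaces each side with an inverse-variance weighted mean
(weights 1/σ² from per-AA procedural SDs) and β/TDF with uncertainty-
weighted means over calibrated pairings. Assuming a constant gross growth
efficiency (GGE ≈ 0.2) per step, the energy transfer efficiency from the
food-web base to the larva is GGE^(FCL−1), so log₁₀(efficiency) is linear
in FCL.

Annual series built from such specimens are sparse (many unsampled years)
and noisy (few specimens per year). `trophlink` models each series with a
Bayesian random-walk state-space model

    x_t = x_{t−1} + w_t,   w_t ~ N(0, Q)        (state)
    y_{i,t} = x_t + v_{i,t},   v_{i,t} ~ N(0, R)  (observation)

sampled by an exact conjugate Gibbs scheme (forward-filter backward-
sampling for the state path, inverse-gamma draws for Q and R), with
split-chain Gelman–Rubin R̂ diagnostics, per-year MAP values (KDE mode)
and 95% credible intervals. MAP series are then related by lagged
cross-correlation with descriptive ±1.96/√n white-noise bands, and
zooplankton community matrices are screened for regime breaks with
Bray–Curtis dissimilarity and chronologically constrained (CONISS-style)
clustering. A synthetic-data module generates full study-like datasets
with known truth, so every stage is testable end to end.

## Worked example

```python
from trophlink import (AAProfile, CalibrationConstants, fcl_glu_phe,
                       fcl_trp_scr, transfer_efficiency)

calib = CalibrationConstants.default()     # Glu–Phe: β=3.6‰, TDF=5.7‰
fcl = fcl_glu_phe(25.0, 8.0, calib)
print(f"FCL(Glu-Phe)  = {fcl:.4f}")

larva = AAProfile("L1", 1990, {"Glu": 25.0, "Ala": 24.2, "Pro": 24.6,
                               "Phe": 8.0, "Gly": 8.6})
fcl_m = fcl_trp_scr(larva, calib)
print(f"FCL(multi-AA) = {fcl_m:.4f}")
print(f"efficiency    = {transfer_efficiency(fcl_m, calib.gge):.5f}")
```

prints

```
FCL(Glu-Phe)  = 3.3509
FCL(multi-AA) = 3.4219
efficiency    = 0.02028
```

i.e. this larva sits ~3.4 trophic steps above the nitrogen baseline, and
about 2% of primary-production energy reaches it. A full simulated
study runs from the shell:

```
trophlink simulate --outdir demo --seed 1 --boom-bust-year 1988
trophlink fit-ssm demo/size_ratio_log10.csv --seed 1
trophlink cluster demo/community.csv
```

The `cluster` command on that fixture reports the deepest community break
at 1988, the planted regime-shift year. The `run` subcommand executes the
whole pipeline (specimens → state-space fits → cross-correlations →
zonation → period contrasts) from a YAML config and writes a manifest
with input hashes and the seed.

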