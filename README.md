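# isoniche

Bivariate stable-isotope niche statistics for community ecology: standard
ellipse areas (SEA, SEAc and their Bayesian posterior SEA_b), geometric
ellipse overlaps, Layman community-wide metrics and δ15N-based trophic
positions — packaged with a compiled isotope summary table for three
glacier-impacted Antarctic soft-sediment assemblages (Potter Cove, King
George Island) and a seeded synthetic-community generator so every analysis
is reproducible end to end.

It is written for trophic ecologists who compare the isotopic niches of
communities or size classes from δ13C/δ15N biplots, and for anyone who needs
a tested, scriptable Python implementation of SIBER-style ellipse statistics.

## The statistics

For a consumer community with points x_i = (δ13C_i, δ15N_i) and unbiased
sample covariance **S**:

- **SEA** = π·√det(**S**) — the area of the 1-SD Mahalanobis contour,
  containing ≈ 40 % of a bivariate-normal community's spread (the bivariate
  analogue of the standard deviation), in ‰².
- **SEAc** = SEA·(n−1)/(n−2) — the small-sample-corrected point estimate.
- **SEA_b** — the posterior distribution of π·√det(Σ) under a vague conjugate
  Normal–Inverse-Wishart prior; i.i.d. exact draws, no MCMC. Pairwise niche
  comparisons are index-paired exceedance probabilities P(SEA_b^A > SEA_b^B).
- **Overlap** — the intersection area of two SEAc-scaled ellipses, by polygon
  clipping.
- **Layman metrics** — NR, CR, CD, MNND, SDNND (+ convex-hull total area TA)
  over community points or group centroids, deterministic or with posterior
  uncertainty propagated through the group means.
- **Trophic position** — TP = λ + (δ15N − δ15N_base)/Δn with a long-lived
  first-consumer baseline (λ = 2) and Δn = 1.8 ‰ per level; discrete trophic
  levels are Δn-wide bands stacked above the empirically derived TL2 band.

## Worked example

`examples/site_ellipses.py` simulates one replicate-level realisation of the
packaged summary table (seed 1) and compares the three sites:

```text
site    n   SEA     SEAc    hull (all in permil^2)
IslaD   24   22.49   23.51   63.41
Faro    52   17.76   18.12   76.72
Creek   27   15.20   15.81   35.99

pairwise SEAc ellipse overlap (permil^2):
  IslaD ~ Faro: 8.79
  IslaD ~ Creek: 5.31
  Faro ~ Creek: 9.37
```

The most recently ice-free site (Isla D) has the widest isotopic niche
(largest SEAc) although it is the site with the fewest points, and the two
older sites overlap most — the niche-width gradient follows time since
glacier retreat. The other examples cover Bayesian comparison
(`bayesian_comparison.py`), community-wide metrics (`community_metrics.py`),
trophic levels (`trophic_levels.py`) and generator-based parameter recovery
(`synthetic_recovery.py`); each prints a short interpretation with its
numbers.

A thin CLI wraps the same pipeline:

```bash
isoniche analyze --input fixture --variant complete --seed 1 --draws 10000 --out report/
isoniche fixture --out table.csv
isoniche simulate --seed 1 --out replicates.csv
isoniche metrics --input replicates.csv --grouping site
```

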