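# Methods

## Data model

The packaged fixture (`src/isoniche/fixtures/potter_cove.csv`) is a compiled
summary table of δ13C/δ15N measurements (mean ± SD, ‰) for food sources and
consumers of three Antarctic soft-sediment assemblages sampled at 15 m depth
in Potter Cove: Creek (ice-free since the 1950s), Faro (ice-free since the
1990s) and Isla D (ice-free 2003–2006). Each row carries a replicate count R
(the number of measured samples) and a pooled-individual count N (individuals
per sample), a size class (meiofauna, small macrofauna < 1 cm, large
macrofauna > 1 cm, or not applicable for food sources and unassigned
zooplankton), a trophic group, and a storage flag. Values are stored as
published, i.e. δ13C of formalin-stored consumers already includes the +2 ‰
preservation correction, and the rows are flagged accordingly so
`apply_formalin_correction` (idempotent by construction) does not re-apply it.

Two polychaetes are recorded with the dual site label `Creek+IslaD`: they
were collected at Creek but are known members of the Isla D assemblage, so
the *complete* dataset variant places their points in both communities. The
*reduced* variant drops, from Isla D only, these two predators plus the
ectosymbiont-bearing harpacticoid morphotype whose chemosynthetic signal
(δ13C −34.9 ‰, δ15N −2.6 ‰) makes it an extreme outlier. Unassigned
zooplankton (mysid, calanoid copepods) never enter ellipse analyses but are
kept for the trophic-level summary.

## Standard ellipses

The standard ellipse of a community is the 1-SD Mahalanobis contour of the
fitted bivariate normal; its area is SEA = π√det(S) with S the unbiased
sample covariance, and SEAc = SEA·(n−1)/(n−2) corrects the small-sample bias
of the determinant. Ellipse boundaries are polygonised on the eigenbasis of
S; the SEAc ellipse is the SEA ellipse scaled radially by √(SEAc/SEA), which
preserves shape and matches the corrected area exactly. Overlaps are
intersection areas of 1024-gon approximations (Shapely polygon clipping);
at 1024 vertices the polygonisation error is below 0.1 %, which is orders of
magnitude below the sampling noise of the data. Degenerate inputs (n < 3,
collinear points, covariance determinant ≤ 1e−12) raise errors rather than
returning silent zeros; the convex hull alone degrades continuously and
returns area 0 with a warning for collinear input.

## Bayesian ellipse areas

The posterior of (μ, Σ) uses the conjugate Normal–Inverse-Wishart family
with vague hyperparameters μ₀ = 0, κ₀ = 10⁻³, ν₀ = 3, Λ₀ = 10⁻³·I. Because
the family is conjugate, draws are i.i.d. exact samples from the posterior
(default 10⁴ draws, burn-in 0); each covariance draw yields one
SEA_b = π√det(Σ). This targets the same vague-prior posterior that
simulation-based samplers approximate, deterministically for a given seed.
With the sample sizes used here (n ≥ 5) the data terms dominate all four
posterior parameters; the only situation where the prior is noticeably
informative is a group with near-zero variance placed far from the origin,
which does not arise in isotope data at natural scales.

Posterior summaries report central (equal-tail) intervals at 0.50/0.75/0.95
and a mode taken as the peak of a Gaussian KDE (Silverman-type bandwidth,
512-point grid); a constant sample short-circuits to zero-width intervals.
Pairwise comparisons are index-paired exceedance fractions with ties counted
as ½, so P(A>B) + P(B>A) = 1 exactly and P(A>A) = ½. The model sanity gate
used throughout the pipeline is that the data's SEAc must fall inside the
95 % interval of SEA_b.

The Bayesian Layman metrics replace group centroids with the groups'
posterior mean draws (independent samplers paired by draw index) and compute
the five metrics per draw; site-level grouping uses the three size-class
centroids, the grouping under which the cross-site metric comparisons are
made.

## Trophic positions

TP = λ + (δ15N − δ15N_base)/Δn with λ = 2 and Δn = 1.8 ‰, an
invertebrate/plant-diet fractionation step chosen over the classic 3 ‰. The
baseline is the pooled mean δ15N of the long-lived deposit/suspension-feeding
bivalve *Yoldia eightsi* across its two sites ((8.75 + 8.12)/2 = 8.435 ‰).
A published variant of this equation divides the whole bracket (λ + Δδ15N)
by Δn; that form is inconsistent with the convention that the baseline
itself sits at TP = λ, so the standard form is the default and the bracketed
variant is available behind `printed_form=True` for comparison.

Discrete trophic levels are δ15N bands: TL2 spans the observed range of the
designated first consumers (filter/suspension feeders plus the baseline
bivalve, giving [3.52, 8.75] ‰ on the packaged table), and TL3, TL4, …
are consecutive Δn-wide bands above the TL2 upper edge. A value exactly on
a boundary belongs to the lower band — this keeps the band-defining baseline
at TL2 — implemented with a 10⁻⁹ ‰ tolerance against float representation
error. Consumers below the TL2 band (the ectosymbiont-bearing copepod) are
kept at TL2 with a `below_band` flag rather than rejected, so outliers stay
representable. Under these defaults the packaged consumer set occupies four
levels (TL2–TL5).

## Synthetic communities

`simulate_from_summaries` draws, for every summary row, R independent
bivariate-normal replicates with the row's means and SDs. Within-group
δ13C–δ15N correlation defaults to 0 because summary tables report no
covariance; this is a documented limitation, not an estimate. Rows with
R = 1 reproduce their mean exactly — the single published measurement is the
datum, and adding noise would double-count uncertainty. Randomness uses one
`SeedSequence` substream per group spawned from the top-level seed, so
appending groups never perturbs existing draws. `simulate_parametric`
accepts arbitrary means, SDs, correlations and replicate counts for
parameter-recovery and power studies.

What the generator emulates is the between-taxon structure plus printed
within-group noise; what it cannot recover is the exact replicate-level
configuration of the original data. Community SEAc is dominated by
between-taxon spread, so site-level statistics reproduce well, but
small-group statistics (e.g. a 12-point meiofauna class) are sensitive to
the particular replicate values and may deviate from originally reported
numbers even when the summaries match. Passing tests therefore demonstrate
correctness of the estimators and fidelity at the summary level, not
recovery of unpublished raw data.

## Problem sizes and numerical choices

The reference study (`isoniche.reference`, also behind
`scripts/acceptance.py`) uses 100 simulated communities and 10⁴ posterior
draws per group — enough that Monte-Carlo error on every reported mean is
well below the tolerances at which the results are read, while completing in
well under a minute on one CPU. Other defaults: ellipse polygonisation 1024
vertices; SDNND uses the sample SD (ddof = 1, switchable); nearest-neighbour
ties share the minimum distance; validation bounds δ13C ∈ [−60, 0] ‰ and
δ15N ∈ [−10, 25] ‰ are configurable.

## Known limitations

- Ellipse statistics assume approximate bivariate normality per community;
  heavy-tailed or multimodal communities inflate SEA relative to robust
  alternatives. No normality diagnostics are bundled; the simulation checks
  play that role here.
- The within-group correlation default (ρ = 0) slightly misstates groups
  whose replicates co-vary in both isotopes.
- Axis-aligned metrics (CR, NR) are not rotation invariant by design.
- Overlap areas between highly eccentric near-tangent ellipses are the
  quantities most sensitive to small covariance differences, and therefore
  reconstruct least precisely from summary-level data.
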