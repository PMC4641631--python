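"""Bayesian ellipse-area comparison between sites.

Fits the Normal-Inverse-Wishart posterior to each site's consumer points,
summarises the SEA_b distribution (mode + credible intervals), checks that
the data's SEAc falls inside the 95% interval, and prints pairwise
exceedance probabilities P(SEA_b of A > SEA_b of B).
"""

from itertools import combinations

from isoniche import (
    COMPLETE,
    Site,
    check_seac_in_ci,
    fit_standard_ellipse,
    load_reference_summaries,
    prob_larger,
    sample_posterior,
    select_community,
    simulate_from_summaries,
    summarize_posterior,
)

records = simulate_from_summaries(load_reference_summaries(), seed=1)

draws = {}
for i, site in enumerate((Site.ISLA_D, Site.FARO, Site.CREEK)):
    pts = select_community(records, site, COMPLETE)
    fit = fit_standard_ellipse(pts)
    d = sample_posterior(pts, n_draws=10_000, seed=100 + i, group=site.value)
    draws[site.value] = d
    s = summarize_posterior(d)
    lo, hi = s.intervals[0.95]
    ok = "yes" if check_seac_in_ci(fit, d) else "NO"
    print(
        f"{site.value:7s} SEAc={fit.seac:6.2f}  SEA_b mode={s.mode:6.2f}"
        f"  95% CI=[{lo:6.2f}, {hi:6.2f}]  SEAc in CI: {ok}"
    )

print("\nP(SEA_b of A > SEA_b of B), index-paired over 10^4 draws:")
for a, b in combinations(draws, 2):
    print(f"  P({a} > {b}) = {prob_larger(draws[a], draws[b]):.3f}")

print(
    "\nProbabilities near 1 mean site A's isotopic niche is almost certainly"
    "\nwider than B's once sampling uncertainty is accounted for."
)
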