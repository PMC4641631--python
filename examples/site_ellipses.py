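"""Whole-community standard ellipses for the three Potter Cove sites.

Simulates one replicate-level realisation of the packaged summary table,
selects each site's consumer community (complete dataset) and prints SEA,
SEAc, convex hull area and the pairwise SEAc ellipse overlaps.
"""

from itertools import combinations

from isoniche import (
    COMPLETE,
    Site,
    convex_hull_area,
    ellipse_overlap,
    fit_standard_ellipse,
    load_reference_summaries,
    select_community,
    simulate_from_summaries,
)

records = simulate_from_summaries(load_reference_summaries(), seed=1)

fits = {}
print("site    n   SEA     SEAc    hull (all in permil^2)")
for site in (Site.ISLA_D, Site.FARO, Site.CREEK):
    pts = select_community(records, site, COMPLETE)
    fit = fit_standard_ellipse(pts)
    fits[site.value] = fit
    print(f"{site.value:7s} {fit.n:2d}  {fit.sea:6.2f}  {fit.seac:6.2f}  {convex_hull_area(pts):6.2f}")

print("\npairwise SEAc ellipse overlap (permil^2):")
for a, b in combinations(fits, 2):
    print(f"  {a} ~ {b}: {ellipse_overlap(fits[a], fits[b], use_seac=True):.2f}")

print(
    "\nSEAc is the small-sample-corrected standard ellipse area (~40% of the"
    "\ncommunity's isotopic spread); larger SEAc = wider isotopic niche."
    "\nThe youngest ice-free site (Isla D) shows the widest, most elongated niche."
)
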