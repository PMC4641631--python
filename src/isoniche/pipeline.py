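"""End-to-end orchestration: seeded, re-runnable niche analyses.

The pipeline ties the stages together the way the site comparison is meant to
be read: load (or simulate) replicate-level data, select each site's consumer
community under a dataset variant, fit standard ellipses, sample ellipse-area
posteriors, compute overlaps, exceedance probabilities and Layman metrics
(deterministic and Bayesian), and emit a JSON-serialisable report plus CSV
tables.  All randomness flows from one seed through ``SeedSequence``
substreams, so re-running a config reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bayes, ellipse, layman, trophic
from .data import (
    COMPLETE,
    REDUCED,
    DatasetVariant,
    GroupSummary,
    IsotopeRecord,
    Site,
    SizeClass,
    load_isotope_table,
    load_reference_summaries,
    records_to_points,
    select_community,
)
from .simulate import simulate_from_summaries

__all__ = ["AnalysisConfig", "run_site_comparison", "run_size_by_site", "save_report"]

log = logging.getLogger("isoniche.pipeline")

ANALYSIS_SITES = (Site.CREEK, Site.FARO, Site.ISLA_D)
SIZE_CLASSES = (SizeClass.MEIOFAUNA, SizeClass.SMALL_MACROFAUNA, SizeClass.LARGE_MACROFAUNA)

_VARIANTS = {"complete": COMPLETE, "reduced": REDUCED}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a re-runnable analysis needs; the seed is mandatory."""

    seed: int
    input: str = "fixture"  # "fixture", a summary CSV, or a replicate CSV
    input_level: str = "summary"  # replicate tables are analysed as-is
    variants: tuple[str, ...] = ("complete", "reduced")
    n_draws: int = 10_000
    burn_in: int = 0
    min_group_n: int = 3
    n_vertices: int = 1024
    formalin_offset: float = 2.0
    trophic: trophic.TrophicConfig = field(default_factory=trophic.TrophicConfig)

    def resolve_variants(self) -> list[DatasetVariant]:
        return [_VARIANTS[name] for name in self.variants]


def _load_records(config: AnalysisConfig, rng_stream: np.random.SeedSequence) -> list[IsotopeRecord]:
    """Replicate-level records: loaded directly, or simulated from summaries."""
    if config.input == "fixture":
        summaries = load_reference_summaries()
    elif config.input_level == "replicate":
        return load_isotope_table(config.input, level="replicate")
    else:
        summaries = load_isotope_table(config.input, level="summary")
    seed = int(rng_stream.generate_state(1)[0] % (2**31))
    return simulate_from_summaries(summaries, seed=seed)


def _fit_block(points: np.ndarray) -> dict:
    fit = ellipse.fit_standard_ellipse(points)
    return {
        "n": fit.n,
        "centroid": [float(v) for v in fit.centroid],
        "covariance": [[float(v) for v in row] for row in fit.covariance],
        "SEA": fit.sea,
        "SEAc": fit.seac,
        "TA": ellipse.convex_hull_area(points),
    }


def _posterior_block(fit, draws, level: float = 0.95) -> dict:
    summ = bayes.summarize_posterior(draws)
    return {
        "mode": summ.mode,
        "median": summ.median,
        "intervals": {str(k): list(v) for k, v in summ.intervals.items()},
        "seac_in_95ci": bayes.check_seac_in_ci(fit, draws, level),
    }


def run_site_comparison(config: AnalysisConfig) -> dict:
    """Whole-community ("by site") comparison across the three sites.

    Per variant and site: ellipse fit (SEA, SEAc, hull area), SEA_b posterior
    summary with the SEAc-in-CI check; per site pair: SEAc ellipse overlap and
    P(SEA_b row > column); Layman metrics over size-class centroids, both
    deterministic and Bayesian (with cross-site exceedance probabilities).
    """
    base = np.random.SeedSequence(config.seed)
    data_stream, *post_streams = base.spawn(1 + 2 * len(config.variants) * len(ANALYSIS_SITES))
    records = _load_records(config, data_stream)
    post_iter = iter(post_streams)
    report: dict = {"config": _config_dict(config), "variants": {}}
    for variant in config.resolve_variants():
        vrep: dict = {"sites": {}, "pairwise": {}, "layman": {}}
        site_points: dict[str, np.ndarray] = {}
        site_fits = {}
        site_draws = {}
        class_draws: dict[str, dict] = {}
        for site in ANALYSIS_SITES:
            pts = select_community(records, site, variant, scope="all_consumers")
            site_points[site.value] = pts
            fit = ellipse.fit_standard_ellipse(pts)
            draws = bayes.sample_posterior(
                pts,
                n_draws=config.n_draws,
                burn_in=config.burn_in,
                rng=np.random.default_rng(next(post_iter)),
                group=f"{variant.name}:{site.value}",
            )
            site_fits[site.value] = fit
            site_draws[site.value] = draws
            block = _fit_block(pts)
            block["posterior"] = _posterior_block(fit, draws)
            vrep["sites"][site.value] = block
            # size-class groups for the Bayesian community metrics
            by_class = select_community(records, site, variant, scope="by_size_class")
            stream = next(post_iter)
            substreams = stream.spawn(len(SIZE_CLASSES))
            class_draws[site.value] = {}
            for sc, sub in zip(SIZE_CLASSES, substreams):
                if sc not in by_class or by_class[sc].shape[0] < config.min_group_n:
                    continue
                class_draws[site.value][sc.value] = bayes.sample_posterior(
                    by_class[sc],
                    n_draws=config.n_draws,
                    rng=np.random.default_rng(sub),
                    group=f"{variant.name}:{site.value}:{sc.value}",
                )
            # deterministic Layman metrics over size-class centroids
            centroids = np.array([v.mean(axis=0) for v in by_class.values()])
            if centroids.shape[0] >= 2:
                vrep["layman"].setdefault("deterministic", {})[site.value] = asdict(
                    layman.layman_metrics(centroids, include_hull=centroids.shape[0] >= 3)
                )
        # pairwise overlap and exceedance
        names = [s.value for s in ANALYSIS_SITES]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                vrep["pairwise"][f"{a}-{b}"] = {
                    "seac_overlap": ellipse.ellipse_overlap(
                        site_fits[a], site_fits[b], use_seac=True, n_vertices=config.n_vertices
                    ),
                    "p_larger": bayes.prob_larger(site_draws[a], site_draws[b]),
                }
        # Bayesian Layman metrics over size-class centroid posteriors
        bl: dict[str, dict] = {}
        for site_name, groups in class_draws.items():
            if len(groups) >= 2:
                bl[site_name] = bayes.bayesian_layman(list(groups.values()))
        vrep["layman"]["bayesian"] = {
            site_name: {
                metric: asdict(bayes.summarize_posterior(vals))
                for metric, vals in metrics.items()
            }
            for site_name, metrics in bl.items()
        }
        vrep["layman"]["exceedance"] = {
            f"{a}-{b}": {
                metric: bayes.prob_larger(bl[a][metric], bl[b][metric])
                for metric in bl[a]
            }
            for i, a in enumerate(bl)
            for b in list(bl)[i + 1 :]
        }
        report["variants"][variant.name] = vrep
        log.info("site comparison done for variant %s", variant.name)
    return report


def run_size_by_site(config: AnalysisConfig) -> dict:
    """Per-(site, size class) ellipses and the meio/macro exceedance comparisons.

    Groups with fewer than ``min_group_n`` points are excluded with a logged
    warning; SEAc overlap between size classes is suppressed (with a note)
    whenever any group at the site is below the minimum, since small-sample
    ellipse overlaps are not comparable.
    """
    base = np.random.SeedSequence(config.seed)
    data_stream, post_stream = base.spawn(2)
    records = _load_records(config, data_stream)
    substreams = iter(post_stream.spawn(len(config.variants) * len(ANALYSIS_SITES) * len(SIZE_CLASSES)))
    report: dict = {"config": _config_dict(config), "variants": {}}
    for variant in config.resolve_variants():
        vrep: dict = {"sites": {}, "comparisons": {}}
        for site in ANALYSIS_SITES:
            by_class = select_community(records, site, variant, scope="by_size_class")
            site_rep: dict = {"groups": {}, "excluded": [], "overlap_note": None}
            draws_by_class = {}
            for sc in SIZE_CLASSES:
                stream = next(substreams)
                pts = by_class.get(sc)
                n_pts = 0 if pts is None else pts.shape[0]
                if n_pts < config.min_group_n:
                    site_rep["excluded"].append({"size_class": sc.value, "n": n_pts})
                    log.warning(
                        "%s/%s/%s: %d point(s) < min_group_n=%d, excluded",
                        variant.name, site.value, sc.value, n_pts, config.min_group_n,
                    )
                    continue
                try:
                    fit = ellipse.fit_standard_ellipse(pts)
                except ellipse.DegenerateDataError:
                    site_rep["excluded"].append({"size_class": sc.value, "n": n_pts})
                    continue
                draws = bayes.sample_posterior(
                    pts,
                    n_draws=config.n_draws,
                    rng=np.random.default_rng(stream),
                    group=f"{variant.name}:{site.value}:{sc.value}",
                )
                draws_by_class[sc.value] = draws
                block = _fit_block(pts)
                block["posterior"] = _posterior_block(fit, draws)
                site_rep["groups"][sc.value] = block
            if site_rep["excluded"]:
                site_rep["overlap_note"] = (
                    "size-class SEAc overlaps suppressed: "
                    f"{len(site_rep['excluded'])} group(s) below min_group_n"
                )
            comp = {}
            pairs = (
                ("meiofauna", "small_macrofauna"),
                ("large_macrofauna", "small_macrofauna"),
            )
            for a, b in pairs:
                if a in draws_by_class and b in draws_by_class:
                    comp[f"p_{a}>{b}"] = bayes.prob_larger(draws_by_class[a], draws_by_class[b])
            vrep["sites"][site.value] = site_rep
            vrep["comparisons"][site.value] = comp
        report["variants"][variant.name] = vrep
    return report


def _config_dict(config: AnalysisConfig) -> dict:
    d = asdict(config)
    return d


def save_report(report: dict, out_dir: str | Path, stem: str = "report") -> Path:
    """Write the JSON report plus flat CSV tables of fits and pairwise results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{stem}.json"
    json_path.write_text(json.dumps(report, indent=2, default=_jsonify))
    rows = []
    for vname, vrep in report.get("variants", {}).items():
        for scope_key in ("sites",):
            for site_name, block in vrep.get(scope_key, {}).items():
                blocks = block.get("groups", {site_name: block}) if "groups" in block else {"": block}
                for gname, gblock in blocks.items():
                    if "SEAc" not in gblock:
                        continue
                    rows.append(
                        {
                            "variant": vname,
                            "site": site_name,
                            "group": gname,
                            "n": gblock["n"],
                            "SEA": gblock["SEA"],
                            "SEAc": gblock["SEAc"],
                            "TA": gblock.get("TA"),
                        }
                    )
    if rows:
        pd.DataFrame(rows).to_csv(out / f"{stem}_ellipses.csv", index=False)
    return json_path


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "value"):
        return obj.value
    raise TypeError(f"not JSON serialisable: {type(obj)}")
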