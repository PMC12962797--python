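"""End-to-end drivers for the two headline analyses.

``diversity_meta`` runs Hill-number partitioning per district and the
paired meta-analysis over sites (18 cases: TD/FD x gamma/alpha/beta x
q = 0, 1, 2).  ``beta_deviation_analysis`` runs the individual-shuffle
null model, joins the resulting pairwise beta-deviations to structural,
abiotic and spatial pair distances, and fits the treatment-specific
mixed models; ``ses_analysis`` runs the trait-shuffle SES and its
treatment comparison.  The command-line interface is a thin wrapper
around these functions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .distances import pair_predictors
from .hill import DiversityEstimate, gower_distance
from .inference import compare_ses, fit_beta_deviation_model, table_one
from .io import RunConfig
from .meta import run_all_cases
from .nulls import NullConfig, beta_deviation, functional_ses
from .partition import decompose, shared_coverage_target

logger = logging.getLogger(__name__)

__all__ = ["diversity_meta", "beta_deviation_analysis", "ses_analysis"]


def _site_pairs(assemblages: dict) -> dict:
    """Group districts into (site -> {treatment: AssemblageSet})."""
    sites: dict = {}
    for (site, _district), a in sorted(assemblages.items()):
        sites.setdefault(site, {})[a.treatment] = a
    return sites


def diversity_meta(assemblages: dict, traits: pd.DataFrame | None,
                   config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage-standardized partitioning + paired meta-analysis.

    Returns ``(meta_table, district_table)``: the combined 18-case table
    and the per-district estimates behind it.  Both districts of a site
    share one coverage target so their difference is not a sampling-depth
    artefact.
    """
    rng = np.random.default_rng(config.seed)
    distance = None
    if "FD" in config.facets:
        if traits is None:
            raise ValueError("FD requested but no trait table provided")
        distance = gower_distance(traits)
    sites = _site_pairs(assemblages)
    records = []
    district_rows = []
    for site, by_treatment in sorted(sites.items()):
        target = shared_coverage_target(list(by_treatment.values()),
                                        config.coverage_multiplier,
                                        config.cap_factor)
        for treatment, A in sorted(by_treatment.items()):
            for facet in config.facets:
                for q in config.q_values:
                    res = decompose(A, q, facet, coverage=target,
                                    distance=distance, B=config.bootstrap,
                                    rng=rng, cap_factor=config.cap_factor,
                                    fd_mc=config.fd_mc)
                    beta_est = DiversityEstimate(
                        value=res.dissimilarity, facet=facet, scale="beta",
                        q=q, coverage=target, se=res.diss_se,
                        ci_low=res.diss_ci[0], ci_high=res.diss_ci[1],
                        n_boot=config.bootstrap,
                        replicates=res.replicates.get("diss"))
                    for est in (res.gamma, res.alpha, beta_est):
                        records.append({"site": site, "treatment": treatment,
                                        "estimate": est})
                        district_rows.append({
                            "site": site, "district": A.district,
                            "treatment": treatment, "facet": facet,
                            "scale": est.scale, "q": q, "value": est.value,
                            "se": est.se, "coverage": target})
    meta_table = run_all_cases(records)
    return meta_table, pd.DataFrame(district_rows)


def beta_deviation_analysis(assemblages: dict, env: pd.DataFrame,
                            traits: pd.DataFrame | None,
                            config: RunConfig):
    """Null-model beta-deviation, distance join and mixed-model z-table.

    Returns ``(ztable, deviations, fits)``: the six-coefficient z-value
    table per (facet, q) case with the conditional R-squared row, the
    joined pair-level table, and the ModelFit objects.
    """
    preds = pair_predictors(env, scope=config.standardization_scope)
    preds["pmin"] = preds[["patch_a", "patch_b"]].min(axis=1)
    preds["pmax"] = preds[["patch_a", "patch_b"]].max(axis=1)
    distance = None
    if "FD" in config.facets:
        if traits is None:
            raise ValueError("FD requested but no trait table provided")
        distance = gower_distance(traits)
    sites = _site_pairs(assemblages)
    dev_frames = []
    for facet in config.facets:
        for q in config.q_values:
            for si, (site, by_treatment) in enumerate(sorted(sites.items())):
                sets = list(by_treatment.values())
                species = sorted(set().union(*[set(a.species) for a in sets]))
                cols = {}
                districts = {}
                for a in sets:
                    sub = a.counts.reindex(species, fill_value=0)
                    for patch in a.patches:
                        cols[patch] = sub[patch]
                    districts[a.district] = {"patches": a.patches,
                                             "treatment": a.treatment}
                site_counts = pd.DataFrame(cols)
                nc = NullConfig("individual_shuffle", config.null_replicates,
                                seed=config.seed + 1000 * si + 17)
                dev = beta_deviation(site_counts, districts, nc, q,
                                     facet=facet, distance=distance,
                                     site=site, fd_mc=config.fd_mc)
                dev_frames.append(dev)
    deviations = pd.concat(dev_frames, ignore_index=True)
    deviations["pmin"] = deviations[["patch_a", "patch_b"]].min(axis=1)
    deviations["pmax"] = deviations[["patch_a", "patch_b"]].max(axis=1)
    joined = deviations.merge(
        preds[["site", "district", "pmin", "pmax",
               "structural", "abiotic", "spatial"]],
        on=["site", "district", "pmin", "pmax"], how="left", validate="m:1")
    if joined[["structural", "abiotic", "spatial"]].isna().any().any():
        raise ValueError("patch keys in community and environment tables "
                         "do not match")
    fits = {}
    for (facet, q), g in joined.groupby(["facet", "q"]):
        fits[(facet, q)] = fit_beta_deviation_model(g)
    ztable = table_one(fits)
    return ztable, joined, fits


def ses_analysis(assemblages: dict, traits: pd.DataFrame,
                 config: RunConfig, q: float = 0):
    """Trait-shuffle SES per district and its treatment contrast."""
    rng = np.random.default_rng(config.seed + 7)
    rows = []
    for (_site, _district), a in sorted(assemblages.items()):
        rows.append(functional_ses(a, traits.loc[a.species],
                                   R=config.null_replicates, q=q, rng=rng))
    ses = pd.DataFrame(rows)
    fit = compare_ses(ses)
    return ses, fit
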