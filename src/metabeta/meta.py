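"""Paired meta-analysis of treatment-control diversity differences.

Each site contributes one paired difference (treated district minus
control district) per diversity case -- a case being a combination of
facet (TD/FD), scale (alpha/beta/gamma) and order q (0/1/2), 18 cases in
all.  Site differences are combined by fixed-effect inverse-variance
weighting, with standard errors propagated from the district-level
bootstrap replicate streams where available.  Positive combined values
mean higher diversity in the treated (ESBC) districts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hill import DiversityEstimate

__all__ = ["PairedDifference", "MetaResult", "pair_difference", "combine",
           "run_all_cases", "CASES"]

Z_95 = 1.959963984540054

#: the 18 diversity cases: facet x scale x q
CASES = [(f, s, q) for f in ("TD", "FD") for s in ("gamma", "alpha", "beta")
         for q in (0, 1, 2)]


@dataclass
class PairedDifference:
    """ESBC-minus-control difference for one site and one diversity case."""

    site: str
    facet: str
    scale: str
    q: float
    difference: float
    se: float
    n_boot: int = 0
    replicates: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MetaResult:
    """Combined difference for one diversity case across sites."""

    facet: str
    scale: str
    q: float
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    n_sites: int
    weights: np.ndarray
    significant: bool
    flags: tuple = ()


def pair_difference(est_e: DiversityEstimate, est_c: DiversityEstimate,
                    site: str = "") -> PairedDifference:
    """Difference between a treated and a control estimate of one case.

    When both estimates carry bootstrap replicate streams the SE of the
    difference is the SD of replicate-wise differences; otherwise it
    falls back to sqrt(SE_E^2 + SE_C^2).
    """
    if (est_e.facet, est_e.scale, est_e.q) != (est_c.facet, est_c.scale, est_c.q):
        raise ValueError("estimates belong to different diversity cases")
    delta = est_e.value - est_c.value
    reps = None
    if est_e.replicates is not None and est_c.replicates is not None \
            and len(est_e.replicates) == len(est_c.replicates):
        reps = np.asarray(est_e.replicates) - np.asarray(est_c.replicates)
        se = float(reps.std(ddof=1))
    else:
        se = float(np.sqrt(np.nan_to_num(est_e.se) ** 2
                           + np.nan_to_num(est_c.se) ** 2))
    return PairedDifference(site=site, facet=est_e.facet, scale=est_e.scale,
                            q=est_e.q, difference=delta, se=se,
                            n_boot=0 if reps is None else len(reps),
                            replicates=reps)


def combine(diffs: list[PairedDifference], se_floor: float = 1e-6,
            method: str = "fixed") -> MetaResult:
    """Inverse-variance combination of site differences.

    The default is the fixed-effect model: weights proportional to
    1/SE^2, combined SE = (sum 1/SE^2)^(-1/2), 95% CI by the normal
    approximation.  ``method="random"`` adds a DerSimonian-Laird
    between-site variance to every weight.  Sites reporting SE = 0 are
    floored at ``se_floor`` with a warning.  A single site is returned
    as-is, flagged "single_site".
    """
    if method not in ("fixed", "random"):
        raise ValueError(f"unknown method {method!r}")
    if not diffs:
        raise ValueError("no differences to combine")
    cases = {(d.facet, d.scale, d.q) for d in diffs}
    if len(cases) > 1:
        raise ValueError(f"cannot combine across cases: {sorted(cases)}")
    facet, scale, q = next(iter(cases))
    flags = ()
    d = np.array([x.difference for x in diffs], dtype=float)
    se = np.array([x.se for x in diffs], dtype=float)
    if np.any(se <= 0):
        warnings.warn("zero bootstrap SE floored for meta-analysis weighting",
                      stacklevel=2)
        flags = flags + ("se_floored",)
        se = np.maximum(se, se_floor)
    if len(diffs) == 1:
        est, s = float(d[0]), float(se[0])
        w = np.array([1.0])
        flags = flags + ("single_site",)
    else:
        w_raw = 1.0 / se ** 2
        if method == "random":
            # DerSimonian-Laird between-site variance
            mu_fe = np.sum(w_raw * d) / w_raw.sum()
            q_stat = float(np.sum(w_raw * (d - mu_fe) ** 2))
            denom = w_raw.sum() - np.sum(w_raw ** 2) / w_raw.sum()
            tau2 = max(0.0, (q_stat - (len(d) - 1)) / denom) if denom > 0 else 0.0
            w_raw = 1.0 / (se ** 2 + tau2)
        w = w_raw / w_raw.sum()
        est = float(np.sum(w * d))
        s = float(1.0 / np.sqrt(w_raw.sum()))
    lo, hi = est - Z_95 * s, est + Z_95 * s
    return MetaResult(facet=facet, scale=scale, q=q, estimate=est, se=s,
                      ci_low=lo, ci_high=hi,
                      z=est / s if s > 0 else np.inf * np.sign(est),
                      n_sites=len(diffs), weights=w,
                      significant=bool(lo > 0 or hi < 0), flags=flags)


def run_all_cases(estimates: list[dict], cases: list[tuple] | None = None,
                  treatment_col: str = "treatment",
                  treated: str = "ESBC", control: str = "control") -> pd.DataFrame:
    """Meta-analysis for every facet x scale x q case.

    Parameters
    ----------
    estimates
        Records with keys site, treatment, and a DiversityEstimate per
        entry under key "estimate" (carrying facet/scale/q).  One record
        per (site, treatment, case).
    cases
        The (facet, scale, q) cases expected; defaults to every case
        present in the input (the full design yields the 18 cases of
        :data:`CASES`).  A case missing for some site raises with an
        explicit gap report rather than being silently dropped.

    Returns
    -------
    One tidy row per case (facet, scale, q, estimate, ci_low, ci_high,
    significant, n_sites).
    """
    by_key: dict = {}
    for rec in estimates:
        e = rec["estimate"]
        by_key[(rec["site"], rec[treatment_col], e.facet, e.scale, e.q)] = e
    sites = sorted({rec["site"] for rec in estimates})
    if cases is None:
        seen = {(e.facet, e.scale, e.q)
                for e in (rec["estimate"] for rec in estimates)}
        cases = [c for c in CASES if c in seen] \
            + sorted(seen - set(CASES), key=str)
    gaps = []
    rows = []
    results = []
    for facet, scale, q in cases:
        diffs = []
        for site in sites:
            ke = (site, treated, facet, scale, q)
            kc = (site, control, facet, scale, q)
            if ke not in by_key or kc not in by_key:
                gaps.append((site, facet, scale, q))
                continue
            diffs.append(pair_difference(by_key[ke], by_key[kc], site))
        if not diffs:
            gaps.append(("<all sites>", facet, scale, q))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.append(combine(diffs))
    if gaps:
        raise ValueError(f"incomplete input; missing (site, facet, scale, q): {gaps[:10]}")
    for r in results:
        rows.append({"facet": r.facet, "scale": r.scale, "q": r.q,
                     "estimate": r.estimate, "se": r.se, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "z": r.z,
                     "significant": r.significant, "n_sites": r.n_sites})
    return pd.DataFrame(rows)
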