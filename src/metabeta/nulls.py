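"""Null models: individual shuffling and trait shuffling.

Two randomization schemes isolate different assembly signals:

* individual shuffle -- every sampled individual of a site is randomly
  reassigned to one of the site's patches, holding each patch's total
  abundance fixed.  Site-level species totals (hence site gamma and the
  species' relative abundances) are preserved exactly.  The difference
  between observed pairwise dissimilarity and its null expectation is
  the beta-deviation: positive values mean patches differ more in
  composition than random reallocation of individuals predicts.

* trait shuffle -- species labels are permuted across the rows of the
  trait table while the abundance matrix is untouched.  Standardized
  effect sizes (SES) compare observed functional turnover with the
  distribution under trait-label permutation; |SES| > 1.96 flags a
  significant departure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hill import TraitDistanceMatrix, gower_distance
from .partition import AssemblageSet, pairwise_beta

logger = logging.getLogger(__name__)

__all__ = ["NullConfig", "shuffle_individuals", "beta_deviation",
           "trait_shuffle", "functional_ses"]


@dataclass(frozen=True)
class NullConfig:
    """Configuration of a null-model run."""

    scheme: str = "individual_shuffle"   # or "trait_shuffle"
    replicates: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.scheme not in ("individual_shuffle", "trait_shuffle"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def shuffle_individuals(counts: pd.DataFrame, rng: np.random.Generator,
                        method: str = "hypergeometric") -> pd.DataFrame:
    """Randomly redistribute all individuals among the patches.

    ``counts`` is a species-by-patch matrix covering all patches of a
    site (both districts).  The default preserves patch totals and
    per-species site totals exactly; conditional on those margins every
    assignment of individuals to patches is equally likely (multivariate
    hypergeometric allocation patch by patch).  ``method="multinomial"``
    frees the patch totals: each individual picks a patch independently
    with probability proportional to the observed patch total.
    """
    Z = counts.to_numpy().astype(np.int64)
    if Z.sum() < 1:
        raise ValueError("site has no individuals")
    n_patch = Z.sum(axis=0)
    out = np.zeros_like(Z)
    n_cols = Z.shape[1]
    if method == "multinomial":
        p = n_patch / n_patch.sum()
        for i, total in enumerate(Z.sum(axis=1)):
            if total > 0:
                out[i] = rng.multinomial(int(total), p)
    elif method == "hypergeometric":
        remaining = Z.sum(axis=1).copy()
        for k in range(n_cols - 1):
            out[:, k] = rng.multivariate_hypergeometric(remaining,
                                                        int(n_patch[k]))
            remaining -= out[:, k]
        out[:, n_cols - 1] = remaining
    else:
        raise ValueError(f"unknown shuffle method {method!r}")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def beta_deviation(site_counts: pd.DataFrame, districts: dict,
                   config: NullConfig, q: float, facet: str = "TD",
                   distance: TraitDistanceMatrix | None = None,
                   coverage: float | str | None = "auto",
                   site: str = "", fd_mc: int = 15,
                   scope: str = "site") -> pd.DataFrame:
    """Pairwise beta-deviation for one site.

    Parameters
    ----------
    site_counts
        Species-by-patch matrix spanning all patches of the site; the
        shuffle redistributes individuals across both districts.
    districts
        Mapping district id -> dict(patches=[...], treatment=str)
        selecting which patch pairs are evaluated (within-district only).
    config
        ``individual_shuffle`` scheme; ``replicates`` null draws.  With
        a single replicate the output is flagged "single-replicate null".

    scope
        "site" (default) shuffles individuals across both districts of
        the site; "district" restricts the shuffle to each district's
        own patches (sensitivity mode).

    Returns
    -------
    One row per within-district patch pair: observed 1-S, null mean,
    null SD and deviation = observed - null mean.  The null replicates
    are standardized to the same coverage target as the observed pair.
    """
    if config.scheme != "individual_shuffle":
        raise ValueError("beta_deviation requires the individual_shuffle scheme")
    if scope not in ("site", "district"):
        raise ValueError(f"unknown shuffle scope {scope!r}")
    rng = np.random.default_rng(config.seed)
    R = config.replicates

    observed = {}
    targets = {}
    for d_id, info in districts.items():
        A = AssemblageSet(site_counts[info["patches"]], site=site,
                          district=d_id, treatment=info.get("treatment", ""))
        obs = pairwise_beta(A, q, facet, coverage, distance, rng=rng,
                            fd_mc=fd_mc)
        observed[d_id] = obs
        # freeze the pair-level coverage target for the null replicates
        targets[d_id] = obs["coverage"].iloc[0] if len(obs) else None

    null_acc = {d: [] for d in districts}
    for _ in range(R):
        if scope == "site":
            shuffled = shuffle_individuals(site_counts, rng)
        else:
            parts = [shuffle_individuals(site_counts[info["patches"]], rng)
                     for info in districts.values()]
            shuffled = pd.concat(parts, axis=1)
        for d_id, info in districts.items():
            A = AssemblageSet(shuffled[info["patches"]], site=site,
                              district=d_id,
                              treatment=info.get("treatment", ""))
            nb = pairwise_beta(A, q, facet, targets[d_id], distance,
                               rng=rng, fd_mc=fd_mc)
            null_acc[d_id].append(nb.set_index(["patch_a", "patch_b"])["dissimilarity"])

    rows = []
    for d_id, info in districts.items():
        obs = observed[d_id]
        nulls = pd.concat(null_acc[d_id], axis=1)
        for _, r in obs.iterrows():
            key = (r["patch_a"], r["patch_b"])
            vals = nulls.loc[key].to_numpy(dtype=float)
            row = {"site": site, "district": d_id,
                   "treatment": info.get("treatment", ""),
                   "patch_a": r["patch_a"], "patch_b": r["patch_b"],
                   "facet": facet, "q": q,
                   "observed": r["dissimilarity"],
                   "null_mean": float(vals.mean()),
                   "null_sd": float(vals.std(ddof=1)) if R > 1 else 0.0,
                   "deviation": r["dissimilarity"] - float(vals.mean()),
                   "n_null": R}
            if R == 1:
                row["flag"] = "single-replicate null"
            rows.append(row)
    return pd.DataFrame(rows)


def trait_shuffle(traits: pd.DataFrame, rng: np.random.Generator,
                  exclude_identity: bool = False) -> pd.DataFrame:
    """Permute species labels across whole trait rows.

    The multiset of trait rows is unchanged; only the species-to-trait
    assignment is randomized.  The identity permutation is a legitimate
    draw unless ``exclude_identity`` is set.
    """
    if len(traits) < 2:
        raise ValueError("need at least two species")
    s = len(traits)
    perm = rng.permutation(s)
    if exclude_identity:
        while np.all(perm == np.arange(s)):
            perm = rng.permutation(s)
    out = traits.iloc[perm].copy()
    out.index = traits.index
    return out


def functional_ses(A: AssemblageSet, traits: pd.DataFrame, R: int = 100,
                   q: float = 0, rng: np.random.Generator | None = None,
                   coverage: float | None = None,
                   tau: str | float = "dmean") -> dict:
    """Trait-shuffle SES of mean pairwise functional dissimilarity.

    Observed mean pairwise functional 1-S for the district, normalized
    by the mean and SD over ``R`` trait-label permutations:
    SES = (obs - null_mean) / null_sd.  Because the shuffle leaves the
    abundance matrix untouched, sampling-depth artefacts affect observed
    and null identically; the default therefore evaluates functional
    dissimilarity on the reference sample (``coverage=None``).

    Returns a record with observed, null mean/SD, SES and a significance
    flag (|SES| > 1.96); SES is flagged undefined when the null SD is 0.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    missing = set(A.species) - set(traits.index)
    if missing:
        raise KeyError(f"traits missing for species: {sorted(missing)[:5]}")
    traits = traits.loc[A.species]
    D = gower_distance(traits, tau=tau)

    def mean_pairwise(dist: TraitDistanceMatrix) -> float:
        tab = pairwise_beta(A, q, "FD", coverage, dist, rng=rng)
        return float(tab["dissimilarity"].mean())

    obs = mean_pairwise(D)
    # a trait-row permutation is a simultaneous row/column permutation of
    # the Gower matrix, so the matrix is computed once
    dm = D.distances.to_numpy()
    null_vals = np.empty(R)
    for r in range(R):
        perm = rng.permutation(len(traits))
        dperm = pd.DataFrame(dm[np.ix_(perm, perm)], index=D.distances.index,
                             columns=D.distances.columns)
        null_vals[r] = mean_pairwise(TraitDistanceMatrix(dperm, D.tau))
    mu, sd = float(null_vals.mean()), float(null_vals.std(ddof=1))
    if sd > 0:
        ses = (obs - mu) / sd
        flag = ""
    else:
        ses = np.nan
        flag = "undefined: null SD = 0"
        logger.warning("SES undefined for district %s: null SD is zero",
                       A.district)
    return {"site": A.site, "district": A.district, "treatment": A.treatment,
            "q": q, "observed": obs, "null_mean": mu, "null_sd": sd,
            "ses": ses, "significant": bool(sd > 0 and abs(ses) > 1.959964),
            "n_null": R, "flag": flag}
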