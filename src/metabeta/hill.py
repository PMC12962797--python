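"""Hill-number diversity with coverage-based standardization.

This module is the numerical core of the package: Hill numbers of order
``q`` for taxonomic (TD) and functional (FD) diversity, the sample-coverage
estimator, rarefaction/extrapolation of both coverage and diversity along
the sample-size axis, inversion of the coverage curve so estimates can be
standardized to a common coverage level, and a Chao-style bootstrap for
standard errors.

Notation
--------
For an assemblage with species counts ``x_i`` and ``n = sum(x_i)``
individuals, ``p_i = x_i / n`` and ``f_k`` is the number of species
observed exactly ``k`` times.  The Hill number of order ``q`` is

    qD = (sum_i p_i**q) ** (1 / (1 - q)),   q != 1
    1D = exp(-sum_i p_i * log(p_i))

i.e. species richness at q=0, the exponential of Shannon entropy at q=1
and the inverse Simpson concentration at q=2.  Sample coverage is the
estimated proportion of the community's total abundance that belongs to
species detected in the sample; it is the standardization axis used in
place of raw sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

__all__ = [
    "AbundanceVector",
    "DiversityEstimate",
    "TraitDistanceMatrix",
    "hill_number",
    "sample_coverage",
    "coverage_profile",
    "expected_hill",
    "standardize_to_coverage",
    "functional_hill_number",
    "fd_at_size",
    "gower_distance",
    "augmented_probabilities",
    "bootstrap_estimate",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceVector:
    """Species counts for a single assemblage.

    Parameters
    ----------
    counts
        Nonnegative integer abundances, one entry per species.  Zeros are
        allowed (species absent from this assemblage but present in the
        shared species list).
    species
        Optional species labels aligned with ``counts``.
    """

    counts: np.ndarray
    species: tuple | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if self.species is not None and len(self.species) != c.size:
            raise ValueError("species labels do not match counts length")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int((self.counts > 0).sum())

    def f(self, k: int) -> int:
        """Number of species observed exactly ``k`` times."""
        return int((self.counts == k).sum())

    @property
    def f1(self) -> int:
        return self.f(1)

    @property
    def f2(self) -> int:
        return self.f(2)


@dataclass(frozen=True)
class TraitDistanceMatrix:
    """Pairwise functional distances between species with a threshold tau.

    Distances are expected on the Gower scale (0 to 1, zero diagonal,
    symmetric).  ``tau`` is the level of distinctness at which two species
    are treated as belonging to fully distinct functional groups.
    """

    distances: pd.DataFrame
    tau: float

    def __post_init__(self):
        d = self.distances
        if not isinstance(d, pd.DataFrame):
            d = pd.DataFrame(np.asarray(d))
            object.__setattr__(self, "distances", d)
        a = d.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def submatrix(self, species) -> np.ndarray:
        missing = [s for s in species if s not in self.distances.index]
        if missing:
            raise KeyError(f"species missing from trait distance matrix: {missing[:5]}")
        return self.distances.loc[list(species), list(species)].to_numpy(dtype=float)


@dataclass
class DiversityEstimate:
    """A single diversity estimate with its standardization context."""

    value: float
    facet: str = "TD"          # "TD" or "FD"
    scale: str = "gamma"       # "alpha" | "beta" | "gamma"
    q: float = 0
    coverage: float | None = None
    m_star: float | None = None
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_boot: int = 0
    flags: tuple = ()
    replicates: np.ndarray | None = field(default=None, repr=False)


def _counts(v) -> np.ndarray:
    if isinstance(v, AbundanceVector):
        c = v.counts
    else:
        c = np.asarray(v)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
    if c.sum() < 1:
        raise ValueError("assemblage must contain at least one individual")
    return c.astype(np.int64)


# --------------------------------------------------------------------------
# Hill numbers at the reference sample
# --------------------------------------------------------------------------

def hill_number(v, q: float) -> float:
    """Hill number (effective species number) of order ``q``.

    ``q=0`` counts species regardless of abundance, ``q=1`` weights each
    species by its frequency (exponential Shannon), ``q=2`` emphasises
    dominant species (inverse Simpson).
    """
    x = _counts(v)
    if q < 0:
        raise ValueError("q must be nonnegative")
    p = x[x > 0] / x.sum()
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p ** q) ** (1.0 / (1.0 - q)))


def sample_coverage(v) -> float:
    """Estimated sample coverage of the reference sample.

    C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]; returns 1 when
    the sample has no singletons.
    """
    x = _counts(v)
    n = int(x.sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    a = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    return float(1.0 - (f1 / n) * a)


def _f0_hat(n: int, f1: int, f2: int) -> float:
    """Chao1-style estimate of the number of undetected species."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


# --------------------------------------------------------------------------
# coverage rarefaction / extrapolation
# --------------------------------------------------------------------------

def _coverage_rarefied(x: np.ndarray, m: int) -> float:
    # estimator of the coverage of a size-m subsample: equals
    # 1 - P(the (m+1)-th individual drawn without replacement is new)
    n = int(x.sum())
    xx = x[(x > 0) & (n - x >= m)]
    if xx.size == 0:
        return 1.0
    lg = gammaln(n - xx + 1) - gammaln(n - xx - m + 1) - gammaln(n) + gammaln(n - m)
    return float(1.0 - np.sum(xx / n * np.exp(lg)))


def _coverage_at_int(x: np.ndarray, m: int) -> float:
    n = int(x.sum())
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < n:
        return _coverage_rarefied(x, m)
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    c_ref = sample_coverage(x)
    if m == n or f1 == 0:
        return c_ref if m == n else 1.0 if f1 == 0 else c_ref
    f0 = _f0_hat(n, f1, f2)
    if f0 <= 0:
        return 1.0
    a_ext = n * f0 / (n * f0 + f1)
    return float(1.0 - (1.0 - c_ref) * a_ext ** (m - n))


def coverage_profile(v, m) -> float:
    """Expected sample coverage at sample size ``m``.

    Interpolates (hypergeometric subsampling) for ``m <= n`` and
    extrapolates with the Chao1-style undetected-species estimate for
    ``m > n``.  Fractional ``m`` is handled by linear interpolation
    between adjacent integers.  Nondecreasing in ``m``.
    """
    x = _counts(v)
    m = float(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    lo = int(np.floor(m))
    if lo == m:
        return _coverage_at_int(x, lo)
    hi = lo + 1
    w = m - lo
    return (1 - w) * _coverage_at_int(x, lo) + w * _coverage_at_int(x, hi)


# --------------------------------------------------------------------------
# diversity rarefaction / extrapolation
# --------------------------------------------------------------------------

def _entropy_asymptotic(x: np.ndarray) -> float:
    """Chao-Wang-Jost asymptotic estimator of Shannon entropy."""
    x = x[x > 0]
    n = int(x.sum())
    h = float(np.sum(x / n * (digamma(n) - digamma(x))))
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return h
    if f2 > 0:
        a = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 1:
        a = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        a = 1.0
    if a < 1.0:
        r = np.arange(1, n)
        h += f1 / n * (1 - a) ** (1 - n) * (-np.log(a) - np.sum((1 - a) ** r / r))
    return h


def _hill_rarefied(x: np.ndarray, q: float, m: int) -> float:
    x = x[x > 0]
    n = int(x.sum())
    if q == 0:
        keep = x[n - x >= m]
        if keep.size == 0:
            return float(x.size)
        lg = gammaln(n - keep + 1) - gammaln(n - keep - m + 1) \
            - gammaln(n + 1) + gammaln(n - m + 1)
        return float(x.size - np.sum(np.exp(lg)))
    if abs(q - 1.0) < 1e-12:
        # expected frequency counts E[f_k(m)] via hypergeometric probabilities
        xu, mult = np.unique(x, return_counts=True)
        kmax = min(int(xu.max()), m)
        k = np.arange(1, kmax + 1, dtype=float)
        X = xu[:, None].astype(float)
        K = k[None, :]
        valid = (K <= X) & (n - X >= m - K)

        def lg(a):  # gammaln with placeholder args where invalid
            return gammaln(np.where(valid, a, 1.0))

        lgn = gammaln(n + 1) - gammaln(m + 1) - gammaln(n - m + 1)
        lp = (lg(X + 1) - lg(K + 1) - lg(X - K + 1)
              + lg(n - X + 1) - lg(m - K + 1) - lg(n - X - m + K + 1) - lgn)
        w = -(k / m) * np.log(k / m)
        h = float(np.sum(mult[:, None] * np.where(valid, np.exp(lp), 0.0)
                         * w[None, :]))
        return float(np.exp(h))
    if abs(q - 2.0) < 1e-12:
        return _hill_q2(x, m)
    raise NotImplementedError("rarefaction implemented for q in {0, 1, 2}")


def _hill_q2(x: np.ndarray, m: float) -> float:
    # closed form, valid for interpolation and extrapolation alike
    n = int(x.sum())
    s2 = float(np.sum(x * (x - 1.0)) / (n * (n - 1.0))) if n > 1 else 0.0
    denom = 1.0 / m + (m - 1.0) / m * s2
    if denom <= 0:
        return float((x > 0).sum())
    return float(1.0 / denom)


def _hill_extrapolated(x: np.ndarray, q: float, m: float) -> float:
    x = x[x > 0]
    n = int(x.sum())
    t = m - n
    if q == 0:
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        f0 = _f0_hat(n, f1, f2)
        if f0 <= 0 or f1 == 0:
            return float(x.size)
        return float(x.size + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** t))
    if abs(q - 1.0) < 1e-12:
        h_obs = float(np.log(hill_number(x, 1.0)))
        h_inf = max(_entropy_asymptotic(x), h_obs)
        return float(np.exp(n / m * h_obs + t / m * h_inf))
    if abs(q - 2.0) < 1e-12:
        return _hill_q2(x, m)
    raise NotImplementedError("extrapolation implemented for q in {0, 1, 2}")


def expected_hill(v, q: float, m) -> float:
    """Expected Hill number of order ``q`` at sample size ``m``.

    Rarefaction below the reference size ``n`` uses exact hypergeometric
    expectations of the frequency counts; extrapolation above ``n`` uses
    the standard asymptotic forms.  At ``m = n`` this equals the observed
    Hill number.  Fractional ``m`` is linearly interpolated.
    """
    x = _counts(v)
    n = int(x.sum())
    m = float(m)
    if m < 1:
        raise ValueError("m must be >= 1")

    def at_int(mi):
        if mi <= n:
            return _hill_rarefied(x, q, int(mi))
        return _hill_extrapolated(x, q, float(mi))

    lo = int(np.floor(m))
    if lo == m:
        return at_int(lo)
    if lo >= n:  # extrapolation formulas are continuous in real m
        return _hill_extrapolated(x, q, m)
    w = m - lo
    return (1 - w) * at_int(lo) + w * at_int(lo + 1)


# --------------------------------------------------------------------------
# coverage standardization
# --------------------------------------------------------------------------

def size_for_coverage(v, target: float, cap_factor: float = 2.0):
    """Invert the coverage curve: smallest (fractional) m with coverage >= target.

    Returns ``(m_star, flags)``; when the target exceeds the coverage
    attainable at the extrapolation cap ``cap_factor * n`` the cap is
    returned with the ``"coverage_unreachable"`` flag.
    """
    x = _counts(v)
    x = x[x > 0]
    n = int(x.sum())
    if not 0 < target < 1:
        raise ValueError("target coverage must lie in (0, 1)")
    # precompute the pieces of the coverage curve once
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    c_ref = sample_coverage(x)
    f0 = _f0_hat(n, f1, f2)
    a_ext = n * f0 / (n * f0 + f1) if f1 > 0 and f0 > 0 else 0.0
    lg_n = gammaln(n)
    xf = x.astype(float)

    def cov(m: int) -> float:
        if m < n:
            xx = xf[n - x >= m]
            if xx.size == 0:
                return 1.0
            lgr = gammaln(n - xx + 1) - gammaln(n - xx - m + 1) \
                - lg_n + gammaln(n - m)
            return float(1.0 - np.sum(xx / n * np.exp(lgr)))
        if m == n or f1 == 0:
            return c_ref if m == n else 1.0
        return float(1.0 - (1.0 - c_ref) * a_ext ** (m - n))

    m_cap = float(cap_factor) * n
    lo_cap = int(np.floor(m_cap))
    w_cap = m_cap - lo_cap
    c_cap = cov(lo_cap) if w_cap == 0 else \
        (1 - w_cap) * cov(lo_cap) + w_cap * cov(lo_cap + 1)
    if target >= c_cap:
        if target > c_cap + 1e-12:
            return m_cap, ("coverage_unreachable",)
        return m_cap, ()
    if cov(1) >= target:
        return 1.0, ()
    # integer bisection on the nondecreasing coverage curve, then linear
    # interpolation between the bracketing integers (the fractional-m rule)
    lo, hi = 1, int(np.ceil(m_cap))
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cov(mid) >= target:
            hi = mid
        else:
            lo = mid
    c_lo = cov(lo)
    c_hi = cov(hi)
    if c_hi <= c_lo:
        return float(hi), ()
    return min(lo + (target - c_lo) / (c_hi - c_lo), m_cap), ()


def standardize_to_coverage(v, target: float, q: float,
                            cap_factor: float = 2.0,
                            facet: str = "TD",
                            scale: str = "gamma") -> DiversityEstimate:
    """Diversity of order ``q`` standardized to coverage ``target``.

    Solves for the sample size whose expected coverage equals the target
    (bisection over a continuous size axis) and evaluates the expected
    Hill number there.  Unreachable targets are computed at the
    extrapolation cap and flagged rather than silently truncated.
    """
    x = _counts(v)
    m_star, flags = size_for_coverage(x, target, cap_factor)
    if flags:
        warnings.warn(
            f"target coverage {target:.4f} unreachable at cap {cap_factor}n; "
            "estimate computed at the cap", stacklevel=2)
    value = expected_hill(x, q, m_star)
    return DiversityEstimate(value=value, facet=facet, scale=scale, q=q,
                             coverage=target, m_star=m_star, flags=flags)


# --------------------------------------------------------------------------
# functional (trait-based) diversity
# --------------------------------------------------------------------------

def functional_hill_number(v, D, q: float, tau: float | None = None) -> float:
    """Effective number of distinct functional groups of order ``q``.

    Attribute-diversity form: each species i has functional "abundance"
    a_i = sum_j (1 - min(d_ij, tau)/tau) * p_j, the total abundance of
    species within its functional neighbourhood, and

        FD_q = (sum_i (p_i / a_i) * a_i**q) ** (1 / (1 - q))

    with the analytic q -> 1 limit.  When all between-species distances
    reach tau this reduces to the taxonomic Hill number; when all
    distances are zero it equals 1.
    """
    if isinstance(D, TraitDistanceMatrix):
        tau = D.tau if tau is None else tau
        if isinstance(v, AbundanceVector) and v.species is not None:
            x = v.counts
            present = x > 0
            dmat = D.submatrix([s for s, keep in zip(v.species, present) if keep])
            x = x[present]
        else:
            x = _counts(v)
            if len(D.distances) != x.size:
                raise ValueError("distance matrix does not cover the abundance vector")
            present = x > 0
            dmat = D.distances.to_numpy(dtype=float)[np.ix_(present, present)]
            x = x[present]
    else:
        x = _counts(v)
        dmat = np.asarray(D, dtype=float)
        if dmat.shape != (x.size, x.size):
            raise ValueError("distance matrix does not cover the abundance vector")
        present = x > 0
        dmat = dmat[np.ix_(present, present)]
        x = x[present]
        if tau is None:
            raise ValueError("tau is required when passing a raw distance matrix")
    return _fd_from_parts(x / x.sum(), dmat, tau, q)


def _fd_from_parts(p: np.ndarray, dmat: np.ndarray, tau: float, q: float) -> float:
    sim = 1.0 - np.minimum(dmat, tau) / tau
    a = sim @ p
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(a))))
    return float(np.sum((p / a) * a ** q) ** (1.0 / (1.0 - q)))


def fd_at_size(v, D: TraitDistanceMatrix, q: float, m: float,
               rng: np.random.Generator, n_mc: int = 30,
               species=None) -> float:
    """Monte-Carlo expected functional Hill number at sample size ``m``.

    For ``m <= n`` draws hypergeometric subsamples of the reference
    sample; for ``m > n`` draws multinomial samples of size m from the
    observed relative abundances (undetected species carry no trait
    information, so FD extrapolation stays within the detected pool).
    """
    if isinstance(v, AbundanceVector):
        species = v.species if species is None else species
        x = v.counts
    else:
        x = _counts(v)
    if species is None:
        raise ValueError("species labels are required for FD standardization")
    present = x > 0
    x = x[present]
    dmat = D.submatrix([s for s, keep in zip(species, present) if keep])
    n = int(x.sum())
    mi = int(round(m))
    if mi >= n:
        if mi == n:
            return _fd_from_parts(x / n, dmat, D.tau, q)
        p = x / n
        vals = []
        for _ in range(n_mc):
            y = rng.multinomial(mi, p)
            keep = y > 0
            vals.append(_fd_from_parts(y[keep] / mi, dmat[np.ix_(keep, keep)], D.tau, q))
        return float(np.mean(vals))
    vals = []
    for _ in range(n_mc):
        y = rng.multivariate_hypergeometric(x, mi)
        keep = y > 0
        vals.append(_fd_from_parts(y[keep] / mi, dmat[np.ix_(keep, keep)], D.tau, q))
    return float(np.mean(vals))


def gower_distance(traits: pd.DataFrame, tau: str | float = "dmean") -> TraitDistanceMatrix:
    """Gower distance over a mixed-type species trait table.

    Numeric columns contribute range-normalized absolute differences,
    categorical/boolean columns contribute 0/1 mismatch; each pairwise
    distance averages over the traits observed for both species.  ``tau``
    defaults to the mean off-diagonal distance ("dmean" convention).
    """
    if len(traits) < 2:
        raise ValueError("need at least two species")
    s = len(traits)
    num = np.zeros((s, s))
    den = np.zeros((s, s))
    any_observed = np.zeros(s, dtype=bool)
    for col in traits.columns:
        vals = traits[col]
        obs = vals.notna().to_numpy()
        any_observed |= obs
        both = np.outer(obs, obs)
        if pd.api.types.is_numeric_dtype(vals) and not pd.api.types.is_bool_dtype(vals):
            v = vals.to_numpy(dtype=float)
            rng_ = np.nanmax(v) - np.nanmin(v)
            if rng_ > 0:
                d = np.abs(np.subtract.outer(v, v)) / rng_
            else:
                d = np.zeros((s, s))
            d = np.where(both, np.nan_to_num(d), 0.0)
        else:
            codes = pd.factorize(vals, use_na_sentinel=True)[0]
            d = np.where(both, (codes[:, None] != codes[None, :]).astype(float), 0.0)
        num += d
        den += both
    if not any_observed.all():
        bad = traits.index[~any_observed].tolist()
        raise ValueError(f"species with all traits missing: {bad[:5]}")
    with np.errstate(invalid="ignore", divide="ignore"):
        dmat = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    np.fill_diagonal(dmat, 0.0)
    dmat = 0.5 * (dmat + dmat.T)
    df = pd.DataFrame(dmat, index=traits.index, columns=traits.index)
    if tau == "dmean":
        off = dmat[~np.eye(s, dtype=bool)]
        tau_val = float(off.mean()) if off.size else 1.0
        if tau_val <= 0:
            tau_val = 1.0  # all species functionally identical
    else:
        tau_val = float(tau)
    return TraitDistanceMatrix(df, tau_val)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def augmented_probabilities(v) -> np.ndarray:
    """Chao-calibrated bootstrap probabilities.

    Detected species probabilities are shrunk to account for the chance
    they were over-represented, and the estimated undetected species are
    appended with equal shares of the coverage deficit.  With no
    singletons this reduces to the observed relative abundances.
    """
    x = _counts(v)
    x = x[x > 0]
    n = int(x.sum())
    p = x / n
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f1 == 0:
        return p
    c_hat = sample_coverage(x)
    w = p * (1 - p) ** n
    lam = (1 - c_hat) / w.sum() if w.sum() > 0 else 0.0
    p_adj = np.maximum(p * (1 - lam * (1 - p) ** n), 0.0)
    f0 = max(int(np.ceil(_f0_hat(n, f1, f2))), 1)
    p0 = (1 - c_hat) / f0
    out = np.concatenate([p_adj, np.full(f0, p0)])
    return out / out.sum()


def bootstrap_estimate(v, statistic, B: int = 200,
                       rng: np.random.Generator | None = None):
    """Bootstrap SE and percentile CI of ``statistic(counts)``.

    Resamples ``n`` individuals multinomially from the Chao-augmented
    probabilities ``B`` times.  Returns ``(se, (lo, hi), replicates)``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    x = _counts(v)
    x = x[x > 0]
    n = int(x.sum())
    p = augmented_probabilities(x)
    reps = np.empty(B)
    for b in range(B):
        reps[b] = statistic(rng.multinomial(n, p))
    se = float(reps.std(ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return se, (float(lo), float(hi)), reps
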