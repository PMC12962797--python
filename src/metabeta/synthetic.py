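"""Synthetic metacommunity landscapes under mixed assembly archetypes.

Generates paired-district forest landscapes with the statistical
structure the analysis pipeline assumes: a number of sites, each with a
structurally heterogenized (ESBC) district and a homogeneous control
district, each district a grid of 50 m x 50 m patches (~20 ha
footprint).  Patch communities are drawn from an additive mixture of
four assembly archetypes acting on latent Poisson intensities:

* species sorting   -- Gaussian match between species niche optima and
                       the patch environment (strong where the
                       environment varies, i.e. in ESBC districts);
* mass effect       -- source-patch suitability diffused over an
                       exponential dispersal kernel;
* patch dynamics    -- occupancy from a seeded colonization-extinction
                       process with distance-decaying colonization;
* neutral           -- equal expected shares in every patch of a site.

Each archetype's intensity profile is normalized at the district level
(total intensity matches the regional abundance mass) before mixing, so
mixture weights act on expected composition, absolute habitat filtering
between species is preserved, and a pure-neutral landscape has exactly
homogeneous expectations.  Observed counts arise by Poisson draws from the mixture
intensity followed by binomial thinning (the detection step), which at
realistic sampling fractions (<= 0.3) leaves many singletons, so the
coverage machinery downstream is genuinely exercised.

All randomness flows from a single seed; identical seeds give
bit-identical landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .partition import AssemblageSet

__all__ = ["ArchetypeConfig", "SyntheticLandscape", "generate_species_pool",
           "generate_landscape", "assemble_communities", "sample_communities"]

# environmental axis scales used to express niche breadth in native units
CANOPY_SCALE = 0.25     # canopy density is a proportion
DEADWOOD_SCALE = 25.0   # m^3 per patch
ELL_SCALE = 3.0         # Ellenberg indicator units (broad niches)
N_ELL = 5


@dataclass(frozen=True)
class ArchetypeConfig:
    """Mixture weights and scales of the assembly process generator.

    Weights need not sum to one; they are normalized internally.  The
    default is an even mixture of the four archetypes.  ``niche_breadth``
    is a dimensionless multiplier of the per-axis environmental scales
    (1 = moderate filtering); ``dispersal_scale`` is the e-folding
    distance of the exponential kernel in meters.  The species-abundance
    distribution is lognormal in expected per-patch intensity;
    ``sampling_fraction`` is the binomial detection probability.
    ``treatment_effect`` scales the extra structural heterogeneity of
    ESBC districts (0 = no treatment, used for null calibration).
    """

    w_sorting: float = 0.25
    w_mass: float = 0.25
    w_patchdyn: float = 0.25
    w_neutral: float = 0.25
    niche_breadth: float = 1.0
    dispersal_scale: float = 200.0
    sad_meanlog: float = -0.7
    sad_sdlog: float = 1.5
    n_species: int = 1308
    sampling_fraction: float = 0.2
    trait_correlation: float = 0.7
    treatment_effect: float = 1.0
    seed: int = 0

    def __post_init__(self):
        w = (self.w_sorting, self.w_mass, self.w_patchdyn, self.w_neutral)
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("mixture weights must be nonnegative, sum > 0")
        if self.niche_breadth <= 0 or self.dispersal_scale <= 0:
            raise ValueError("scales must be strictly positive")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")
        if self.sad_sdlog <= 0:
            raise ValueError("sad_sdlog must be positive")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([self.w_sorting, self.w_mass, self.w_patchdyn,
                      self.w_neutral], dtype=float)
        return w / w.sum()


@dataclass
class SyntheticLandscape:
    """A generated landscape: environment, species pool and communities.

    ``latent`` and ``sampled`` map (site, district) to species-by-patch
    count matrices; ``env`` holds one row per patch.
    """

    config: ArchetypeConfig
    pool: pd.DataFrame
    traits: pd.DataFrame
    env: pd.DataFrame
    latent: dict = field(default_factory=dict)
    sampled: dict = field(default_factory=dict)

    @property
    def sites(self) -> list:
        return sorted(self.env["site"].unique())

    def districts(self) -> list[tuple]:
        return sorted(self.sampled.keys())

    def assemblage_set(self, site: str, district: str) -> AssemblageSet:
        counts = self.sampled[(site, district)]
        tr = self.env.loc[(self.env["site"] == site)
                          & (self.env["district"] == district),
                          "treatment"].iloc[0]
        return AssemblageSet(counts, site=site, district=district, treatment=tr)

    def assemblage_sets(self) -> dict:
        return {k: self.assemblage_set(*k) for k in self.sampled}

    def community_long(self, which: str = "sampled") -> pd.DataFrame:
        """Long-format (site, district, treatment, patch, species, abundance)."""
        store = self.sampled if which == "sampled" else self.latent
        frames = []
        tr_map = self.env.drop_duplicates(["site", "district"]).set_index(
            ["site", "district"])["treatment"]
        for (site, district), counts in sorted(store.items()):
            long = counts.stack()
            long = long[long > 0].rename("abundance").reset_index()
            long.columns = ["species", "patch", "abundance"]
            long.insert(0, "treatment", tr_map.loc[(site, district)])
            long.insert(0, "district", district)
            long.insert(0, "site", site)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# species pool
# --------------------------------------------------------------------------

def generate_species_pool(config: ArchetypeConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Regional species pool: abundances, niches, dispersal and traits.

    Each species gets a lognormal expected per-patch intensity, a niche
    optimum on every environmental axis, a dispersal ability (meters)
    and a trait vector correlated with niche position and dispersal at
    ``config.trait_correlation`` (two numeric traits tied to niche and
    dispersal, one free numeric trait, one categorical guild).
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    s = config.n_species
    species = [f"sp{i:04d}" for i in range(s)]
    abundance = rng.lognormal(config.sad_meanlog, config.sad_sdlog, s)
    niche_canopy = rng.uniform(0.25, 0.95, s)
    niche_deadwood = rng.uniform(0.0, 60.0, s)
    niche_ell = rng.normal(5.0, 1.0, (s, N_ELL))
    dispersal = rng.lognormal(np.log(config.dispersal_scale), 0.6, s)

    r = float(config.trait_correlation)
    if not -1 <= r <= 1:
        raise ValueError("trait_correlation must lie in [-1, 1]")

    def mix(signal):
        z = (signal - signal.mean()) / (signal.std() or 1.0)
        return r * z + np.sqrt(max(1 - r * r, 0.0)) * rng.normal(size=s)

    trait_niche = mix(niche_canopy)
    trait_disp = mix(np.log(dispersal))
    trait_size = rng.normal(size=s)
    bins = np.quantile(niche_canopy, [1 / 3, 2 / 3])
    guild_true = np.digitize(niche_canopy, bins)
    keep = rng.random(s) < abs(r)
    guild = np.where(keep, guild_true, rng.integers(0, 3, s))
    guild_names = np.array(["gap", "intermediate", "canopy"])[guild]

    pool = pd.DataFrame({
        "species": species,
        "abundance": abundance,
        "niche_canopy": niche_canopy,
        "niche_deadwood": niche_deadwood,
        "dispersal": dispersal,
        "trait_niche": trait_niche,
        "trait_dispersal": trait_disp,
        "trait_size": trait_size,
        "guild": guild_names,
    }).set_index("species")
    for j in range(N_ELL):
        pool[f"niche_ell{j + 1}"] = niche_ell[:, j]
    return pool


def pool_traits(pool: pd.DataFrame) -> pd.DataFrame:
    """The mixed-type trait table (two+ numeric, one categorical)."""
    tr = pool[["trait_niche", "trait_dispersal", "trait_size", "guild"]].copy()
    tr["guild"] = tr["guild"].astype("category")
    return tr


# --------------------------------------------------------------------------
# landscape: environment and coordinates
# --------------------------------------------------------------------------

def _patch_grid(n_patches: int, rng) -> np.ndarray:
    if n_patches == 9:
        rows, cols = 3, 3
    elif n_patches == 15:
        rows, cols = 3, 5
    else:
        raise ValueError("patches_per_district must be 9 or 15")
    xs, ys = np.meshgrid(np.arange(cols) * 100.0, np.arange(rows) * 100.0)
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return coords + rng.uniform(-10, 10, coords.shape)


def _district_env(n_patches: int, treatment: str, cfg: ArchetypeConfig, rng):
    """Canopy, deadwood and indicator values for one district's patches."""
    eff = cfg.treatment_effect if treatment == "ESBC" else 0.0
    if eff > 0:
        # gaps: a deterministic spread of canopy targets plus jitter
        targets = np.linspace(0.35, 0.92, n_patches)
        canopy = 0.88 + eff * (targets[rng.permutation(n_patches)] - 0.88)
        canopy = np.clip(canopy + rng.normal(0, 0.02, n_patches), 0.0, 1.0)
        deadwood = np.clip(eff * rng.uniform(0, 60, n_patches)
                           + np.abs(rng.normal(4, 2, n_patches)), 0, None)
    else:
        canopy = np.clip(rng.normal(0.88, 0.02, n_patches), 0.0, 1.0)
        deadwood = np.abs(rng.normal(4, 2, n_patches))
    ell_site = rng.normal(5.0, 1.0, N_ELL)
    ell = ell_site + rng.normal(0, 0.3, (n_patches, N_ELL))
    # canopy gaps shift understorey conditions (light axis excluded)
    ell[:, 0] += 0.8 * (0.88 - canopy)
    return canopy, deadwood, ell


def generate_landscape(n_sites: int = 11, patches_per_district: int = 9,
                       config: ArchetypeConfig | None = None) -> SyntheticLandscape:
    """Generate a full landscape and its sampled communities.

    Control districts have low between-patch variance in canopy and
    deadwood; ESBC districts have gaps and elevated, variable deadwood
    (the variance contrast is enforced for every site whenever
    ``treatment_effect > 0``).  Patches lie on a jittered 100-m grid
    within a ~20 ha footprint.  Deterministic given ``config.seed``.
    """
    config = ArchetypeConfig() if config is None else config
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if patches_per_district not in (9, 15):
        raise ValueError("patches_per_district must be 9 or 15 "
                         f"(got {patches_per_district})")
    rng = np.random.default_rng(config.seed)
    pool = generate_species_pool(config, rng)

    rows = []
    for i in range(n_sites):
        site = f"S{i + 1:02d}"
        origin = np.array([i * 10_000.0, 0.0])
        for j, (district_suffix, treatment) in enumerate(
                [("C", "control"), ("E", "ESBC")]):
            district = f"{site}{district_suffix}"
            coords = _patch_grid(patches_per_district, rng) \
                + origin + np.array([0.0, j * 3_000.0])
            canopy, deadwood, ell = _district_env(
                patches_per_district, treatment, config, rng)
            for k in range(patches_per_district):
                rec = {"site": site, "district": district,
                       "treatment": treatment, "patch": f"{district}p{k + 1:02d}",
                       "canopy": canopy[k], "deadwood": deadwood[k],
                       "x": coords[k, 0], "y": coords[k, 1]}
                for a in range(N_ELL):
                    rec[f"ell{a + 1}"] = ell[k, a]
                rows.append(rec)
    env = pd.DataFrame(rows)

    if config.treatment_effect > 0:
        env = _enforce_variance_contrast(env)

    latent = assemble_communities(env, pool, config, rng)
    sampled = sample_communities(latent, config.sampling_fraction, rng=rng)
    return SyntheticLandscape(config=config, pool=pool,
                              traits=pool_traits(pool), env=env,
                              latent=latent, sampled=sampled)


def _enforce_variance_contrast(env: pd.DataFrame) -> pd.DataFrame:
    """Guarantee var(canopy) and var(deadwood) are larger in ESBC per site."""
    env = env.copy()
    for site, g in env.groupby("site"):
        for col in ("canopy", "deadwood"):
            ctl = g.loc[g["treatment"] == "control", col]
            esbc = g.loc[g["treatment"] == "ESBC", col]
            v_c, v_e = ctl.var(), esbc.var()
            if v_e <= v_c:
                centre = esbc.mean()
                scale = np.sqrt((v_c * 1.5 + 1e-12) / (v_e + 1e-12))
                newvals = centre + (esbc - centre) * scale
                if col == "canopy":
                    newvals = newvals.clip(0.0, 1.0)
                else:
                    newvals = newvals.clip(0.0, None)
                env.loc[esbc.index, col] = newvals
    return env


# --------------------------------------------------------------------------
# community assembly
# --------------------------------------------------------------------------

def _norm_district(x: np.ndarray, abundance: np.ndarray) -> np.ndarray:
    """Scale a species-by-patch profile so the abundance-weighted total
    intensity of the district equals the regional abundance mass.

    Unlike per-species normalization this keeps absolute habitat
    filtering: a species whose niche matches nowhere in the district
    stays rare everywhere.  A constant profile (the neutral term) is
    left exactly unchanged.
    """
    tot = float((abundance[:, None] * x).sum())
    if tot <= 0:
        return x
    target = abundance.sum() * x.shape[1]
    return x * (target / tot)


def _mass_profile(phi_raw: np.ndarray, dist: np.ndarray,
                  dispersal: np.ndarray) -> np.ndarray:
    """Source suitability diffused by an exponential dispersal kernel."""
    # kernel per species: exp(-d / dispersal_s); (species, patch, patch)
    kern = np.exp(-dist[None, :, :] / dispersal[:, None, None])
    return np.einsum("skj,sj->sk", kern, phi_raw)


def _patchdyn_profile(dist: np.ndarray, dispersal: np.ndarray, rng,
                      steps: int = 30, colonization: float = 0.35,
                      extinction: float = 0.15) -> np.ndarray:
    """Occupancy from distance-decaying colonization and random extinction."""
    s, p = dispersal.size, dist.shape[0]
    kern = np.exp(-dist[None, :, :] / dispersal[:, None, None])
    log_miss = np.log1p(-np.clip(colonization * kern, 0, 0.999))
    occ = np.zeros((s, p), dtype=bool)
    occ[np.arange(s), rng.integers(0, p, s)] = True
    for _ in range(steps):
        pressure = np.einsum("skj,sj->sk", log_miss, occ.astype(float))
        p_col = 1.0 - np.exp(pressure)
        colonize = (~occ) & (rng.random((s, p)) < p_col)
        go_extinct = occ & (rng.random((s, p)) < extinction)
        occ = (occ | colonize) & ~go_extinct
        # a species extinct everywhere recolonizes from the region
        dead = ~occ.any(axis=1)
        if dead.any():
            occ[np.flatnonzero(dead), rng.integers(0, p, int(dead.sum()))] = True
    return occ.astype(float)


def assemble_communities(env: pd.DataFrame, pool: pd.DataFrame,
                         config: ArchetypeConfig,
                         rng: np.random.Generator | None = None) -> dict:
    """Latent per-patch communities for every district.

    Expected composition is the weighted mixture of the four archetype
    intensity profiles (each normalized at the district level so the
    mixture preserves the regional abundance mass), scaled by the
    species' regional abundance; realized latent counts are Poisson
    draws from the mixture intensity.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    w = config.weights
    abundance = pool["abundance"].to_numpy()
    dispersal = pool["dispersal"].to_numpy()
    latent = {}
    for (site, district), envd in env.groupby(["site", "district"], sort=True):
        envd = envd.set_index("patch")
        coords = envd[["x", "y"]].to_numpy()
        dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        phi = np.exp(-0.5 * (
            ((envd["canopy"].to_numpy()[None, :]
              - pool["niche_canopy"].to_numpy()[:, None])
             / (config.niche_breadth * CANOPY_SCALE)) ** 2
            + ((envd["deadwood"].to_numpy()[None, :]
                - pool["niche_deadwood"].to_numpy()[:, None])
               / (config.niche_breadth * DEADWOOD_SCALE)) ** 2
            + sum(((envd[f"ell{a + 1}"].to_numpy()[None, :]
                    - pool[f"niche_ell{a + 1}"].to_numpy()[:, None])
                   / (config.niche_breadth * ELL_SCALE)) ** 2
                  for a in range(N_ELL))))
        profiles = np.zeros((4,) + phi.shape)
        if w[0] > 0:
            profiles[0] = _norm_district(phi, abundance)
        if w[1] > 0:
            profiles[1] = _norm_district(
                _mass_profile(phi, dist, dispersal), abundance)
        if w[2] > 0:
            profiles[2] = _norm_district(
                _patchdyn_profile(dist, dispersal, rng), abundance)
        if w[3] > 0:
            profiles[3] = 1.0
        lam = abundance[:, None] * np.einsum("a,ask->sk", w, profiles)
        counts = rng.poisson(lam)
        latent[(site, district)] = pd.DataFrame(
            counts, index=pool.index, columns=envd.index)
    return latent


def sample_communities(latent: dict, sampling_fraction: float,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> dict:
    """Binomial thinning of latent counts: the detection step.

    Every latent individual is observed independently with probability
    ``sampling_fraction``; a fraction of 1 reproduces the latent counts
    exactly.
    """
    if not 0 < sampling_fraction <= 1:
        raise ValueError("sampling_fraction must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {}
    for key, counts in sorted(latent.items()):
        if sampling_fraction == 1:
            out[key] = counts.copy()
        else:
            out[key] = pd.DataFrame(
                rng.binomial(counts.to_numpy(), sampling_fraction),
                index=counts.index, columns=counts.columns)
    return out
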