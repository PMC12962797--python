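"""Synthetic metacommunity generator: contracts and archetype behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, pearsonr, spearmanr
from scipy.spatial.distance import pdist

from metabeta.synthetic import (ArchetypeConfig, assemble_communities,
                                generate_landscape, generate_species_pool,
                                sample_communities)


def cfg(**kw):
    base = dict(n_species=80, seed=1, sampling_fraction=0.25)
    base.update(kw)
    return ArchetypeConfig(**base)


# ------------------------------------------------------------- validation

def test_config_validation():
    with pytest.raises(ValueError):
        ArchetypeConfig(w_sorting=-1)
    with pytest.raises(ValueError):
        ArchetypeConfig(niche_breadth=0)
    with pytest.raises(ValueError):
        ArchetypeConfig(sampling_fraction=0)
    with pytest.raises(ValueError):
        ArchetypeConfig(n_species=1)
    assert ArchetypeConfig(w_sorting=3, w_mass=1, w_patchdyn=0,
                           w_neutral=0).weights == pytest.approx(
        [0.75, 0.25, 0, 0])


def test_invalid_patch_count_rejected():
    with pytest.raises(ValueError, match="9 or 15"):
        generate_landscape(2, 10, cfg())


# ----------------------------------------------------------- landscape

def test_design_arithmetic():
    land = generate_landscape(11, 9, cfg(n_species=40))
    assert len(land.sampled) == 22
    assert len(land.env) == 198
    assert land.env["patch"].is_unique


def test_determinism_same_seed():
    c = cfg(seed=123)
    l1 = generate_landscape(2, 9, c)
    l2 = generate_landscape(2, 9, c)
    assert l1.env.equals(l2.env)
    assert l1.pool.equals(l2.pool)
    assert all(l1.sampled[k].equals(l2.sampled[k]) for k in l1.sampled)


def test_treatment_variance_contrast_every_site():
    land = generate_landscape(5, 9, cfg(seed=9))
    for col in ("canopy", "deadwood"):
        v = land.env.groupby(["site", "treatment"])[col].var().unstack()
        assert (v["ESBC"] > v["control"]).all()


def test_grid_layout_within_footprint():
    land = generate_landscape(1, 15, cfg())
    for _, g in land.env.groupby("district"):
        span_x = g["x"].max() - g["x"].min()
        span_y = g["y"].max() - g["y"].min()
        assert span_x < 600 and span_y < 600  # ~20 ha footprint
        d = pdist(g[["x", "y"]].to_numpy())
        assert d.min() > 0  # coordinates distinct


def test_sampled_leq_latent():
    land = generate_landscape(2, 9, cfg())
    for key in land.latent:
        assert (land.sampled[key].to_numpy()
                <= land.latent[key].to_numpy()).all()


def test_sorting_composition_tracks_environment():
    """Pure sorting: composition dissimilarity correlates with
    environmental distance across ESBC patches (Mantel-type r > 0)."""
    land = generate_landscape(3, 9, cfg(
        w_sorting=1, w_mass=0, w_patchdyn=0, w_neutral=0, n_species=150))
    rs = []
    for (site, d), Z in land.sampled.items():
        sub = land.env[land.env.district == d].set_index("patch")
        if sub["treatment"].iloc[0] != "ESBC":
            continue
        comm = pdist(Z.T.to_numpy(), "braycurtis")
        envd = pdist(sub.loc[Z.columns, ["canopy"]].to_numpy() / 0.25
                     + 0 * sub.loc[Z.columns, ["deadwood"]].to_numpy())
        rs.append(pearsonr(comm, envd).statistic)
    assert np.mean(rs) > 0


# ----------------------------------------------------------- species pool

def test_pool_rank_abundance_nonincreasing():
    pool = generate_species_pool(cfg(n_species=500, sad_sdlog=1.5))
    ranked = np.sort(pool["abundance"].to_numpy())[::-1]
    assert (np.diff(ranked) <= 0).all()


def test_pool_trait_correlation_zero():
    pool = generate_species_pool(cfg(n_species=2000, trait_correlation=0.0))
    r = pearsonr(pool["trait_niche"], pool["niche_canopy"]).statistic
    assert abs(r) < 0.1


def test_pool_trait_correlation_positive():
    pool = generate_species_pool(cfg(n_species=2000, trait_correlation=0.8))
    r = pearsonr(pool["trait_niche"], pool["niche_canopy"]).statistic
    assert r > 0.6


def test_pool_mixed_trait_schema():
    pool = generate_species_pool(cfg())
    traits = pool[["trait_niche", "trait_dispersal", "trait_size", "guild"]]
    numeric = traits.select_dtypes("number").columns
    assert len(numeric) >= 2
    assert "guild" in traits.columns and traits["guild"].dtype == object


def test_pool_seed_reproducible():
    p1 = generate_species_pool(cfg(seed=5))
    p2 = generate_species_pool(cfg(seed=5))
    assert p1.equals(p2)


def test_pool_rejects_undersized():
    with pytest.raises(ValueError):
        ArchetypeConfig(n_species=1)


# ------------------------------------------------------ assembly archetypes

def test_neutral_homogeneous_expectations():
    """Pure neutral: chi-square homogeneity across a site's patches is
    non-significant in >= 90% of replicates."""
    nonsig = 0
    reps = 60
    for seed in range(reps):
        c = cfg(w_sorting=0, w_mass=0, w_patchdyn=0, w_neutral=1,
                seed=seed, n_species=40, sad_meanlog=1.5)
        land = generate_landscape(1, 9, c)
        Z = land.latent[("S01", "S01C")].to_numpy()
        keep = Z.sum(axis=1) >= 45  # expected count >= 5 per cell
        if keep.sum() < 5:
            continue
        _, p, *_ = chi2_contingency(Z[keep])
        nonsig += p > 0.05
    assert nonsig / reps >= 0.90


def test_mass_effect_source_patch_dominates():
    """One high-suitability source patch has the largest expected total."""
    c = cfg(w_sorting=0, w_mass=1, w_patchdyn=0, w_neutral=0, seed=3,
            n_species=200)
    pool = generate_species_pool(c)
    env = generate_landscape(1, 9, c).env
    ctl = env[env.district == "S01C"].copy().reset_index(drop=True)
    # make patch 0 the single high-resource source for most species
    ctl.loc[0, "canopy"] = float(pool["niche_canopy"].median())
    ctl.loc[0, "deadwood"] = float(pool["niche_deadwood"].median())
    ctl.loc[1:, "canopy"] = 0.05
    ctl.loc[1:, "deadwood"] = 120.0
    latent = assemble_communities(ctl, pool, c, np.random.default_rng(0))
    totals = latent[("S01", "S01C")].sum(axis=0)
    source = ctl["patch"].iloc[0]
    assert totals.idxmax() == source
    assert (totals.drop(source) < totals[source]).all()


def test_patch_dynamics_distance_decay():
    """Pure patch dynamics: similarity decays with distance (negative
    Spearman correlation, pooled over landscapes)."""
    rs = []
    for seed in range(20):
        c = cfg(w_sorting=0, w_mass=0, w_patchdyn=1, w_neutral=0, seed=seed,
                n_species=100, dispersal_scale=80.0, sad_meanlog=1.0)
        land = generate_landscape(1, 9, c)
        for (site, d), Z in land.sampled.items():
            sub = land.env[land.env.district == d].set_index("patch")
            sim = 1 - pdist(Z.T.to_numpy(), "braycurtis")
            dd = pdist(sub.loc[Z.columns, ["x", "y"]].to_numpy())
            rs.append(spearmanr(sim, dd).statistic)
    from scipy.stats import wilcoxon
    stat = wilcoxon(rs, alternative="less")
    assert np.mean(rs) < 0
    assert stat.pvalue < 0.05


# ------------------------------------------------------------- sampling

def test_sampling_identity_at_one():
    land = generate_landscape(1, 9, cfg(sampling_fraction=1.0))
    for key in land.latent:
        assert land.sampled[key].equals(land.latent[key])


def test_sampling_binomial_mean(rng):
    latent = {("S", "D"): pd.DataFrame({"p": [10] * 10000})}
    out = sample_communities(latent, 0.5, rng=rng)
    mean = out[("S", "D")]["p"].mean()
    se = np.sqrt(10 * 0.25 / 10000)
    assert abs(mean - 5.0) < 3 * se


def test_sampling_fraction_validated():
    with pytest.raises(ValueError):
        sample_communities({}, 0.0)


def test_low_fraction_leaves_singletons():
    land = generate_landscape(3, 9, cfg(sampling_fraction=0.1,
                                        n_species=200))
    for key, Z in land.sampled.items():
        f1 = int((Z.sum(axis=1) == 1).sum())
        assert f1 > 0


def test_neutral_landscape_beta_deviation_centred():
    """Pure-neutral landscapes run through the null-model pipeline give
    beta-deviations centred on zero (grand mean within 2 MC-SE over
    independent landscapes, > 200 pairs in total)."""
    import warnings
    from metabeta.nulls import NullConfig, beta_deviation
    warnings.filterwarnings("ignore", category=UserWarning)
    means = []
    n_pairs = 0
    for seed in range(6):
        c = cfg(w_sorting=0, w_mass=0, w_patchdyn=0, w_neutral=1,
                n_species=120, seed=seed + 60, sampling_fraction=0.3,
                sad_meanlog=0.5)
        land = generate_landscape(2, 9, c)
        devs = []
        for site in land.sites:
            sets = [land.assemblage_set(site, d)
                    for (s, d) in land.sampled if s == site]
            species = sorted(set().union(*[set(a.species) for a in sets]))
            counts = pd.concat([a.counts.reindex(species, fill_value=0)
                                for a in sets], axis=1)
            districts = {a.district: {"patches": a.patches,
                                      "treatment": a.treatment}
                         for a in sets}
            tab = beta_deviation(
                counts, districts,
                NullConfig("individual_shuffle", 20, seed=seed), 0,
                site=site)
            devs.append(tab["deviation"])
        devs = pd.concat(devs)
        n_pairs += len(devs)
        means.append(float(devs.mean()))
    assert n_pairs >= 200
    means = np.asarray(means)
    mc_se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean()) < 2 * max(mc_se, 1e-3)
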