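"""Patch-pair predictors: structural, abiotic and spatial distance.

Structural distance is the Euclidean distance between two patches in
z-standardized (canopy density, deadwood volume) space -- the two
attributes the heterogenization treatment manipulates.  Abiotic distance
is the Euclidean distance across z-standardized Ellenberg indicator
means (light excluded upstream).  Spatial distance is the planar
Euclidean distance in meters from projected coordinates.  Standardization
is pooled across all patches of the analysis set by default so that
effect sizes are comparable across sites; per-site scaling is available.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = ["structural_distance", "abiotic_distance", "spatial_distance",
           "pair_predictors"]

STRUCTURE_COLS = ("canopy", "deadwood")


def _zscore(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            bad = df.index[np.isnan(v)].tolist()
            raise ValueError(f"missing value in column {c!r} for patches {bad[:5]}")
        sd = v.std(ddof=0)
        out[c] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def structural_distance(env_a, env_b) -> float:
    """Euclidean distance on (already standardized) canopy and deadwood."""
    a = np.array([env_a["canopy"], env_a["deadwood"]], dtype=float)
    b = np.array([env_b["canopy"], env_b["deadwood"]], dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing structural attribute")
    return float(np.linalg.norm(a - b))


def abiotic_distance(vec_a, vec_b) -> float:
    """Euclidean distance across (already standardized) indicator means."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("indicator vectors differ in length")
    return float(np.linalg.norm(a - b))


def spatial_distance(xy_a, xy_b) -> float:
    """Planar Euclidean distance in meters."""
    a = np.asarray(xy_a, dtype=float)
    b = np.asarray(xy_b, dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("missing coordinate")
    return float(np.linalg.norm(a - b))


def pair_predictors(env: pd.DataFrame, scope: str = "pooled") -> pd.DataFrame:
    """Distance predictors for every within-district patch pair.

    Parameters
    ----------
    env
        One row per patch with columns site, district, treatment, patch,
        canopy, deadwood, x, y and one or more ``ell*`` indicator
        columns.
    scope
        "pooled" z-standardizes structure and indicators across all
        patches; "site" standardizes within each site.

    Returns a frame keyed like the beta-deviation tables
    (site, district, treatment, patch_a, patch_b) with columns
    structural, abiotic, spatial (plus raw canopy/deadwood differences).
    """
    required = {"site", "district", "treatment", "patch", "canopy",
                "deadwood", "x", "y"}
    missing = required - set(env.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    ell_cols = [c for c in env.columns if c.startswith("ell")]
    zcols = list(STRUCTURE_COLS) + ell_cols
    if scope == "pooled":
        z = _zscore(env, zcols)
    elif scope == "site":
        z = env.groupby("site", group_keys=False)[env.columns.tolist()].apply(
            lambda g: _zscore(g, zcols))
    else:
        raise ValueError(f"unknown standardization scope {scope!r}")

    rows = []
    for (site, district), g in z.groupby(["site", "district"], sort=True):
        g = g.set_index("patch")
        for pa, pb in itertools.combinations(sorted(g.index), 2):
            ra, rb = g.loc[pa], g.loc[pb]
            rows.append({
                "site": site, "district": district,
                "treatment": ra["treatment"],
                "patch_a": pa, "patch_b": pb,
                "structural": structural_distance(ra, rb),
                "abiotic": abiotic_distance(ra[ell_cols], rb[ell_cols])
                if ell_cols else 0.0,
                "spatial": spatial_distance((ra["x"], ra["y"]),
                                            (rb["x"], rb["y"])),
                "d_canopy": abs(float(ra["canopy"] - rb["canopy"])),
                "d_deadwood": abs(float(ra["deadwood"] - rb["deadwood"])),
            })
    return pd.DataFrame(rows)
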