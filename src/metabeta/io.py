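"""Readers, writers and run configuration.

Long-format community tables (site, district, treatment, patch, species,
abundance) are the canonical on-disk representation; traits, patch
environments and coordinates travel as separate CSVs.  Readers tolerate
comma- and tab-delimited files and validate keys, labels and counts with
line-level error messages; writers emit RFC-4180 CSV.  Every pipeline
run records a provenance block (configuration, seeds, package version)
sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .partition import AssemblageSet

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_community", "write_community", "read_table",
           "read_traits", "read_environment", "write_provenance"]

COMMUNITY_COLS = ["site", "district", "treatment", "patch", "species",
                  "abundance"]
TREATMENTS = {"ESBC", "control"}


@dataclass
class RunConfig:
    """Settings of a pipeline run; defaults follow the study design.

    Coverage standardization targets 0.95 of the maximum reachable
    coverage; bootstrap uses 200 replicates; null models use 100.
    """

    coverage_multiplier: float = 0.95
    cap_factor: float = 2.0
    q_values: tuple = (0, 1, 2)
    facets: tuple = ("TD", "FD")
    bootstrap: int = 200
    null_replicates: int = 100
    fd_mc: int = 30
    seed: int = 0
    standardization_scope: str = "pooled"   # distance z-scoring
    community: str | None = None
    traits: str | None = None
    environment: str | None = None
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("q_values", "facets"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["q_values"] = list(self.q_values)
        d["facets"] = list(self.facets)
        return d


def read_table(path) -> pd.DataFrame:
    """CSV/TSV reader with delimiter sniffing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep=None, engine="python")


def read_community(path) -> dict:
    """Read a long-format community table into AssemblageSets per district.

    Returns a mapping (site, district) -> AssemblageSet with the species
    union harmonized within each site.  Zero-abundance rows are dropped
    (and counted in the log); duplicate keys, negative abundances and
    unknown treatment labels raise with the offending line numbers.
    """
    df = read_table(path)
    missing = set(COMMUNITY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"community table missing columns: {sorted(missing)}")
    lines = df.index + 2  # header is line 1
    bad = df["abundance"] < 0
    if bad.any():
        raise ValueError(
            f"negative abundance at line(s) {lines[bad].tolist()[:5]}")
    bad = ~df["treatment"].isin(TREATMENTS)
    if bad.any():
        raise ValueError(
            f"unknown treatment label at line(s) {lines[bad].tolist()[:5]} "
            f"(expected one of {sorted(TREATMENTS)})")
    keys = df[["site", "district", "patch", "species"]]
    dup = keys.duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (site, district, patch, species) keys at line(s) "
            f"{lines[dup].tolist()[:5]}")
    tr_per_district = df.groupby(["site", "district"])["treatment"].nunique()
    if (tr_per_district > 1).any():
        bad_d = tr_per_district[tr_per_district > 1].index.tolist()
        raise ValueError(f"treatment not constant within district: {bad_d}")

    n_zero = int((df["abundance"] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-abundance rows", n_zero)
    df = df[df["abundance"] > 0]

    out = {}
    for site, site_df in df.groupby("site"):
        species = sorted(site_df["species"].unique())
        for (district,), d_df in site_df.groupby(["district"]):
            wide = d_df.pivot_table(index="species", columns="patch",
                                    values="abundance", aggfunc="sum",
                                    fill_value=0)
            wide = wide.reindex(species, fill_value=0)
            out[(site, district)] = AssemblageSet(
                wide.astype(np.int64), site=site, district=district,
                treatment=d_df["treatment"].iloc[0])
    return out


def write_community(sets_or_frame, path) -> None:
    """Write AssemblageSets (or an already-long frame) as long-format CSV."""
    if isinstance(sets_or_frame, pd.DataFrame):
        long = sets_or_frame[COMMUNITY_COLS]
    else:
        frames = []
        for (site, district), a in sorted(sets_or_frame.items()):
            long = a.counts.stack()
            long = long[long > 0].rename("abundance").reset_index()
            long.columns = ["species", "patch", "abundance"]
            long.insert(0, "treatment", a.treatment)
            long.insert(0, "district", district)
            long.insert(0, "site", site)
            frames.append(long)
        long = pd.concat(frames, ignore_index=True)[COMMUNITY_COLS]
    long.to_csv(path, index=False, lineterminator="\r\n")


def read_traits(path) -> pd.DataFrame:
    """Species trait table indexed by species; mixed types preserved."""
    df = read_table(path)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in trait table")
    return df.set_index("species")


def read_environment(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"site", "district", "treatment", "patch", "canopy",
                "deadwood", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"environment table missing columns: {sorted(missing)}")
    return df


def write_provenance(path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable record of the settings that produced a run."""
    from . import __version__
    block = {"package": "metabeta", "version": __version__,
             "config": config.to_dict()}
    if extra:
        block.update(extra)
    with open(path, "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True)
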