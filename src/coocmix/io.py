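"""Readers, writers and input cross-validation.

Standard plain-text inputs: occurrence matrix (CSV/TSV, sites as rows,
species as columns), site metadata (site_id, habitat_category), guild
table (species_id, primary_guild, secondary_guild) and a Newick tree whose
tip labels match species IDs after a configurable normalization
(underscores vs spaces). Species missing from the guild table or the tree
are excluded before pairing and listed in the bundle's exclusion manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data import SpeciesInfo, collapse_habitat

log = logging.getLogger(__name__)


@dataclass
class AssemblageBundle:
    """Cross-validated inputs ready for pairing."""

    matrix: pd.DataFrame  # sites x species (only retained species)
    site_habitat: pd.Series  # site_id -> altered/intact
    species_info: dict  # species_id -> SpeciesInfo
    tree: dendropy.Tree
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _normalize_label(label: str, mode: str = "underscore") -> str:
    s = str(label).strip()
    return s.replace(" ", "_") if mode == "underscore" else s.replace("_", " ")


def read_matrix(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    m = pd.read_csv(path, sep=sep, index_col=0)
    m.index = m.index.astype(str)
    m.columns = [str(c) for c in m.columns]
    return m


def read_site_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"site_id", "habitat_category"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: site metadata missing columns {sorted(missing)}")
    return df


def read_guilds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species_id", "primary_guild"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: guild table missing columns {sorted(missing)}")
    if "secondary_guild" not in df.columns:
        df["secondary_guild"] = ""
    return df


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_inputs(
    matrix_path,
    sites_path,
    guilds_path,
    tree_path,
    *,
    label_normalization: str = "underscore",
) -> AssemblageBundle:
    """Read and cross-validate the four standard inputs.

    Retains the species present in matrix, guild table and tree (after tip
    label normalization); everything else lands in the exclusion manifest
    with a reason. Habitat categories are collapsed to altered/intact.
    """
    matrix = read_matrix(matrix_path)
    sites = read_site_metadata(sites_path)
    guilds = read_guilds(guilds_path)
    tree = read_tree(tree_path)

    hab = pd.Series(
        [collapse_habitat(c) for c in sites["habitat_category"]],
        index=sites["site_id"].astype(str),
        name="habitat",
    )
    missing_sites = [s for s in matrix.index if s not in hab.index]
    if missing_sites:
        raise ValueError(f"sites missing from metadata: {missing_sites}")

    tip_lookup = {}
    for leaf in tree.leaf_node_iter():
        raw = leaf.taxon.label
        tip_lookup[_normalize_label(raw, label_normalization)] = raw

    guild_map = {}
    for row in guilds.itertuples():
        sec = row.secondary_guild if isinstance(row.secondary_guild, str) else ""
        guild_map[str(row.species_id)] = (str(row.primary_guild), sec.strip() or None)

    info, excl = {}, []
    for sp in matrix.columns:
        norm = _normalize_label(sp, label_normalization)
        if sp not in guild_map or not guild_map[sp][0].strip():
            excl.append({"species_id": sp, "reason": "missing dietary guild"})
            continue
        if norm not in tip_lookup:
            excl.append({"species_id": sp, "reason": "tip absent from tree"})
            continue
        primary, secondary = guild_map[sp]
        info[sp] = SpeciesInfo(sp, primary, secondary, tip_lookup[norm])
    if not info:
        raise ValueError("no species retained after cross-validation")
    if excl:
        log.info("excluded %d species: %s", len(excl), [e["species_id"] for e in excl])

    return AssemblageBundle(
        matrix=matrix[list(info)],
        site_habitat=hab,
        species_info=info,
        tree=tree,
        exclusions=pd.DataFrame(excl, columns=["species_id", "reason"]),
    )


def write_bundle(bundle_dir, matrix, site_metadata, guilds, tree) -> dict:
    """Write the four standard input files; returns their paths."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": d / "matrix.csv",
        "sites": d / "sites.csv",
        "guilds": d / "guilds.csv",
        "tree": d / "tree.nwk",
    }
    matrix.to_csv(paths["matrix"])
    site_metadata.to_csv(paths["sites"], index=False)
    guilds.to_csv(paths["guilds"], index=False)
    tree.write(path=str(paths["tree"]), schema="newick")
    return {k: str(v) for k, v in paths.items()}


def provenance_block(config: dict, seed: int) -> dict:
    """Reproducibility metadata: config hash, seed, library versions."""
    import scipy

    from . import __version__

    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest()[:16],
        "config": config,
        "seed": int(seed),
        "versions": {
            "coocmix": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
    }
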