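"""Pair-level records with covariates from raw assemblage inputs.

Turns a binary site-by-species matrix, site habitat metadata, a dietary
guild table and a phylogeny into one record per unordered species pair per
habitat, carrying the 2x2 occupancy counts plus the covariates used by the
hierarchical model: dietary-guild overlap (low/medium/high), diet pairing,
standardized (binned) phylogenetic node distance, habitat, occupancy
pairing ``{min(n_A, n_B), max(n_A, n_B)}`` and a co-occurrence-set ID.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HABITAT_CATEGORIES = {
    "none",
    "cropland",
    "pasture",
    "plantation",
    "secondary forest",
    "fragment",
    "disturbed forest",
    "inhabited area",
    "combined",
}

SET_DEFINING_VARS = (
    "phylo_bin",
    "guild_overlap",
    "diet_pairing",
    "habitat",
    "occupancy_pairing",
)


@dataclass(frozen=True)
class SpeciesInfo:
    """Dietary-guild and tree-tip information for one species."""

    species_id: str
    primary_guild: str
    secondary_guild: str | None = None
    tree_tip: str | None = None

    @property
    def guild_set(self) -> frozenset:
        g = {self.primary_guild}
        if self.secondary_guild:
            g.add(self.secondary_guild)
        return frozenset(g)

    @property
    def guild_label(self) -> str:
        if self.secondary_guild:
            return f"{self.primary_guild}-{self.secondary_guild}"
        return self.primary_guild


def collapse_habitat(category: str, *, synonyms: dict | None = None) -> str:
    """Collapse the nine register disturbance categories to altered/intact.

    Sites with no recorded alteration ("none") are intact; every other
    category is altered. Case and surrounding whitespace are ignored.
    """
    norm = str(category).strip().lower()
    if synonyms and norm in synonyms:
        norm = synonyms[norm]
    if norm not in HABITAT_CATEGORIES:
        raise ValueError(
            f"unrecognized habitat category {category!r}; "
            f"allowed: {sorted(HABITAT_CATEGORIES)}"
        )
    return "intact" if norm == "none" else "altered"


def coerce_binary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Abundances > 0 become presence; the method is presence-absence."""
    vals = matrix.to_numpy()
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValueError("occurrence matrix must be non-negative and finite")
    return pd.DataFrame(
        (vals > 0).astype(np.int8), index=matrix.index, columns=matrix.columns
    )


def build_pair_counts(matrix: pd.DataFrame, sites=None) -> pd.DataFrame:
    """One row of 2x2 occupancy counts per unordered pair of present species.

    ``sites`` restricts the matrix to a habitat subset first. Species with
    zero occupancy within the subset appear in no pair; for k species
    present the result has exactly C(k, 2) rows. Species are ordered
    lexically so each unordered pair appears once (species_a < species_b).
    """
    sub = matrix if sites is None else matrix.loc[list(sites)]
    if sub.shape[0] == 0:
        raise ValueError("habitat subset contains no sites")
    sub = coerce_binary(sub)
    occ = sub.sum(axis=0)
    present = sorted(occ.index[occ > 0])
    if len(present) < 2:
        warnings.warn("fewer than two species present; no pairs built")
        return pd.DataFrame(
            columns=["species_a", "species_b", "n_a", "n_nota", "n_b", "n_ab"]
        )
    x = sub[present].to_numpy(dtype=np.int64)
    n_sites = x.shape[0]
    co = x.T @ x
    occv = np.diag(co)
    ia, ib = np.triu_indices(len(present), k=1)
    names = np.asarray(present, dtype=object)
    return pd.DataFrame(
        {
            "species_a": names[ia],
            "species_b": names[ib],
            "n_a": occv[ia],
            "n_nota": n_sites - occv[ia],
            "n_b": occv[ib],
            "n_ab": co[ia, ib],
        }
    )


def classify_guild_overlap(a: SpeciesInfo, b: SpeciesInfo) -> str:
    """Dietary-guild overlap level for a pair: low / medium / high.

    High: identical {primary, secondary} guild multisets (order may be
    reversed). Medium: some but not all guilds shared, or either species is
    an omnivore (omnivory overrides everything else). Low: no shared guilds.
    """
    ga, gb = a.guild_set, b.guild_set
    if not ga or not gb:
        raise ValueError("both species must carry guild assignments")
    if "omnivore" in ga or "omnivore" in gb:
        return "medium"
    if ga == gb:
        return "high"
    if ga & gb:
        return "medium"
    return "low"


def diet_pairing_label(a: SpeciesInfo, b: SpeciesInfo) -> str:
    """Canonical unordered diet-pairing label, e.g. 'frugivore|nectarivore'."""
    return "|".join(sorted((a.guild_label, b.guild_label)))


# ---------------------------------------------------------------------------
# Phylogenetic node distances
# ---------------------------------------------------------------------------


def _tip_paths(tree) -> dict:
    """Map taxon label -> list of ancestor node ids from tip's parent to root."""
    paths = {}
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf.parent_node
        while node is not None:
            path.append(id(node))
            node = node.parent_node
        paths[leaf.taxon.label] = path
    return paths


def phylo_node_distance(tree, a: str, b: str, *, convention: str = "internal") -> int:
    """Node distance between two tips of a (dendropy) tree.

    ``convention="internal"`` counts the internal nodes strictly between
    the two tips on the tip-to-tip path, so sister tips have distance 1.
    ``convention="edges"`` counts path edges instead (sister tips: 2). The
    source definition ("number of branch nodes separating the pair") admits
    either reading; the choice only shifts/stretches the standardized scale.
    """
    paths = _tip_paths(tree)
    return _path_distance(paths, a, b, convention)


def _path_distance(paths: dict, a: str, b: str, convention: str) -> int:
    for tip in (a, b):
        if tip not in paths:
            raise KeyError(f"tip {tip!r} not found in tree")
    if a == b:
        return 0
    pa, pb = paths[a], paths[b]
    seen = {nid: depth for depth, nid in enumerate(pa)}
    for depth_b, nid in enumerate(pb):
        if nid in seen:
            edges = (seen[nid] + 1) + (depth_b + 1)  # tip-to-MRCA edge counts
            if convention == "edges":
                return edges
            if convention == "internal":
                return edges - 1
            raise ValueError(f"unknown node-distance convention {convention!r}")
    raise ValueError(f"tips {a!r} and {b!r} share no ancestor (disconnected tree?)")


def node_distance_table(tree, tips, *, convention: str = "internal") -> pd.DataFrame:
    """All pairwise node distances for the given tips (species_a < species_b)."""
    paths = _tip_paths(tree)
    tips = sorted(tips)
    rows = [
        (a, b, _path_distance(paths, a, b, convention))
        for a, b in itertools.combinations(tips, 2)
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "node_distance"])


@dataclass
class PhyloDistanceTable:
    """Log-standardized, binned phylogenetic distances for a set of pairs."""

    raw: np.ndarray
    standardized: np.ndarray
    bin_index: np.ndarray  # 1..n_bins
    std_value: np.ndarray  # bin mean of standardized values, per pair
    bin_edges: np.ndarray
    bin_means: np.ndarray


def standardize_and_bin(distances, n_bins: int = 5) -> PhyloDistanceTable:
    """Log, centre and scale node distances, then bin into equal-width intervals.

    The standardized values have mean 0 and variance 1 (population sd);
    ``n_bins`` equal-width bins span [min, max] of the standardized values
    (left-closed, last bin right-closed) and every pair in a bin is assigned
    that bin's mean standardized distance.
    """
    raw = np.asarray(distances)
    if np.any(raw < 1):
        raise ValueError("node distances must be >= 1")
    logd = np.log(raw.astype(float))
    sd = logd.std()
    if sd == 0:
        raise ValueError("all distances identical; standardization degenerate")
    z = (logd - logd.mean()) / sd
    edges = np.linspace(z.min(), z.max(), n_bins + 1)
    idx = np.clip(np.digitize(z, edges, right=False), 1, n_bins)
    means = np.array(
        [z[idx == k].mean() if np.any(idx == k) else np.nan for k in range(1, n_bins + 1)]
    )
    return PhyloDistanceTable(raw, z, idx, means[idx - 1], edges, means)


# ---------------------------------------------------------------------------
# Co-occurrence sets and pipeline
# ---------------------------------------------------------------------------


def occupancy_pairing(n_a, n_b) -> pd.Series:
    """Unordered occupancy pairing label '{min}-{max}'."""
    lo = np.minimum(n_a, n_b)
    hi = np.maximum(n_a, n_b)
    return pd.Series([f"{a}-{b}" for a, b in zip(lo, hi)])


def assign_cooc_sets(
    records: pd.DataFrame,
    defining_vars=("occupancy_pairing", "phylo_bin", "diet_pairing", "habitat"),
    *,
    allow_missing_occupancy_pairing: bool = False,
) -> pd.DataFrame:
    """Assign each pair a co-occurrence-set ID from its levels on defining_vars.

    Pairs with identical levels on every defining variable share a set; the
    partition is exhaustive and disjoint. Occupancy pairing must be among
    the defining variables (occupancy is the primary determinant of the
    probability of co-occurrence) unless explicitly overridden.
    """
    defining_vars = tuple(defining_vars)
    if len(defining_vars) < 2:
        raise ValueError("at least two set-defining variables are required")
    unknown = set(defining_vars) - set(SET_DEFINING_VARS)
    if unknown:
        raise ValueError(f"unknown set-defining variables: {sorted(unknown)}")
    if "occupancy_pairing" not in defining_vars:
        if not allow_missing_occupancy_pairing:
            raise ValueError(
                "occupancy_pairing must be among the set-defining variables "
                "(pass allow_missing_occupancy_pairing=True to override)"
            )
        log.warning("co-occurrence sets defined without occupancy_pairing")
    out = records.copy()
    parts = [
        var + "=" + out[var].astype(str) for var in defining_vars
    ]
    set_id = parts[0]
    for p in parts[1:]:
        set_id = set_id + "|" + p
    out["set_id"] = set_id
    return out


def restrict_species_pool(matrix: pd.DataFrame, site_habitat: pd.Series):
    """Keep only species present in both altered and intact site subsets.

    Returns ``(matrix_subset, retained_fraction)``. Used to separate
    compositional turnover between habitats from changed spatial
    relationships of a shared species pool.
    """
    bin_m = coerce_binary(matrix)
    hab = site_habitat.reindex(matrix.index)
    occ_by_hab = {}
    for h in ("altered", "intact"):
        sites = hab.index[hab == h]
        if len(sites) == 0:
            raise ValueError(f"no sites in habitat {h!r}")
        occ_by_hab[h] = bin_m.loc[sites].sum(axis=0)
    keep = (occ_by_hab["altered"] > 0) & (occ_by_hab["intact"] > 0)
    if not keep.any():
        raise ValueError("no species occur in both habitat types")
    frac = float(keep.mean())
    return matrix.loc[:, keep.index[keep]], frac


def assemble_pair_records(
    matrix: pd.DataFrame,
    site_habitat: pd.Series,
    species_info: dict,
    tree,
    *,
    defining_vars=("occupancy_pairing", "phylo_bin", "diet_pairing", "habitat"),
    node_convention: str = "internal",
    n_bins: int = 5,
    habitat_mode: str = "separate",
) -> pd.DataFrame:
    """Full pipeline: pair counts per habitat + covariates + set IDs.

    ``habitat_mode="separate"`` (default) enumerates pairs within each
    habitat subset, so a pair occurring in both habitats yields two records
    with habitat-specific counts; ``"pooled"`` enumerates pairs once over
    all sites, labelling every record with the reference level (intact) —
    habitat must then appear in neither the fixed terms nor the
    set-defining variables of downstream models.

    Phylogenetic standardization is computed over the pooled set of analysed
    pair records (both habitats), so the covariate scale — and hence the
    meaning of a shared slope — is common to the two habitat subsets.
    """
    species = [s for s in matrix.columns if s in species_info]
    dropped = [s for s in matrix.columns if s not in species_info]
    if dropped:
        log.info("dropping %d species without guild/tree info: %s", len(dropped), dropped)
    matrix = matrix[species]

    hab = site_habitat.reindex(matrix.index)
    if hab.isna().any():
        raise ValueError(f"sites missing habitat metadata: {list(hab.index[hab.isna()])}")

    if habitat_mode == "pooled":
        records = build_pair_counts(matrix, list(hab.index))
        records["habitat"] = "intact"
    elif habitat_mode == "separate":
        frames = []
        for h in ("altered", "intact"):
            sites = hab.index[hab == h]
            if len(sites) == 0:
                continue
            rec = build_pair_counts(matrix, sites)
            rec["habitat"] = h
            frames.append(rec)
        records = pd.concat(frames, ignore_index=True)
    else:
        raise ValueError(f"unknown habitat_mode {habitat_mode!r}")

    info = {s: species_info[s] for s in species}
    pair_cov = {}
    for a, b in {(r.species_a, r.species_b) for r in records.itertuples()}:
        ia, ib = info[a], info[b]
        pair_cov[(a, b)] = (
            classify_guild_overlap(ia, ib),
            diet_pairing_label(ia, ib),
        )
    records["guild_overlap"] = [
        pair_cov[(a, b)][0] for a, b in zip(records.species_a, records.species_b)
    ]
    records["diet_pairing"] = [
        pair_cov[(a, b)][1] for a, b in zip(records.species_a, records.species_b)
    ]

    tip_of = {s: (info[s].tree_tip or s) for s in species}
    paths = _tip_paths(tree)
    dist = np.array(
        [
            _path_distance(paths, tip_of[a], tip_of[b], node_convention)
            for a, b in zip(records.species_a, records.species_b)
        ]
    )
    pt = standardize_and_bin(dist, n_bins=n_bins)
    records["node_distance"] = pt.raw
    records["phylo_bin"] = pt.bin_index
    records["std_phylo_distance"] = pt.std_value

    records["occupancy_pairing"] = occupancy_pairing(
        records.n_a.to_numpy(), records.n_b.to_numpy()
    ).to_numpy()
    return assign_cooc_sets(records, defining_vars)
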