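"""Spatial clustering metrics: SPDV and EDC.

SPDV_K (Spatial Proximity to Disease Variants) of a residue is the mean of
the K smallest Euclidean Cα–Cα distances from that residue to the unique
sites of known disease variants. A residue that is itself a disease site is
excluded from its own calculation, so scoring a known pathogenic position is
never influenced by its own label. SPDV is oriented *lower = more
pathogenic*: residues close to existing disease sites are the suspicious
ones.

EDC (Extent of Disease Clustering) is the ratio of the mean nearest-site
distance taken over all residues to the same mean taken over the disease
sites themselves. Randomly dispersed sites give EDC ≈ 1; spatially clustered
sites give EDC > 1.

Both metrics support an intra-chain mode (distances within one chain) and an
interchain mode (sites pooled across all chains of a complex, nearest taken
across chains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from spdvkit.structures import ResidueKey, StructureModel

logger = logging.getLogger(__name__)

SPDV_ORIENTATION = "lower_pathogenic"


@dataclass
class SiteSet:
    """A labelled set of disease-variant sites (unique residue keys)."""

    label: str
    keys: frozenset[ResidueKey]

    def __post_init__(self) -> None:
        self.keys = frozenset(self.keys)
        if not self.keys:
            raise ValueError(f"site set {self.label!r} is empty")

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class SpdvProfile:
    """Per-residue SPDV_K values for one disease-set model and one K.

    ``values`` maps residue key → SPDV_K in Å; keys with fewer than K
    eligible sites are in ``undefined`` and absent from ``values``.
    """

    model_label: str
    K: int
    mode: str
    values: dict[ResidueKey, float]
    undefined: set[ResidueKey] = field(default_factory=set)
    orientation: str = SPDV_ORIENTATION


@dataclass
class EdcResult:
    edc: float
    n_sites: int
    n_residues: int
    numerator_mean: float
    denominator_mean: float


def _site_coords(
    structure: StructureModel, sites: SiteSet, chain_id: str | None
) -> tuple[list[ResidueKey], np.ndarray]:
    keys = []
    for k in sites.keys:
        if k not in structure:
            raise KeyError(f"site {k} not in structure")
        if chain_id is not None and k[0] != chain_id:
            continue
        if structure[k].ca is not None:
            keys.append(k)
    keys.sort()
    if not keys:
        return [], np.empty((0, 3))
    return keys, np.vstack([structure[k].ca for k in keys])


def _k_smallest_mean(dists: np.ndarray, K: int) -> float:
    """Mean of the K smallest values; NaN when fewer than K remain.

    Ties never expand K: exactly the K smallest values (stable order) enter
    the mean.
    """
    if dists.size < K:
        return float("nan")
    if dists.size == K:
        return float(np.mean(dists))
    part = np.partition(dists, K - 1)[:K]
    return float(np.mean(part))


def spdv(
    structure: StructureModel,
    sites: SiteSet,
    query: ResidueKey,
    K: int,
    mode: str = "intra",
) -> float:
    """SPDV_K of one residue, in Å.

    Distances run from the query Cα to every eligible site Cα (the query
    itself is removed from the site set if present); the K smallest are
    averaged. Returns NaN when fewer than K eligible sites remain.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    if query not in structure:
        raise KeyError(f"query residue {query} not in structure")
    q = structure[query]
    if q.ca is None:
        raise ValueError(f"query residue {query} has no Cα")
    chain = query[0] if mode == "intra" else None
    keys, coords = _site_coords(structure, sites, chain)
    eligible = np.array([k != query for k in keys], dtype=bool)
    coords = coords[eligible] if len(keys) else coords
    if coords.shape[0] == 0:
        logger.warning("no eligible sites for query %s (mode=%s)", query, mode)
        return float("nan")
    dists = np.linalg.norm(coords - q.ca, axis=1)
    return _k_smallest_mean(dists, K)


def spdv_profile(
    structure: StructureModel,
    sites: SiteSet,
    K_set: Iterable[int],
    mode: str = "intra",
) -> dict[int, SpdvProfile]:
    """SPDV_K for every residue with a Cα, for each K, sharing one distance
    computation.

    In intra mode each residue sees only the sites on its own chain; in inter
    mode all sites are pooled and the nearest are taken across chains.
    """
    K_list = sorted(set(int(k) for k in K_set))
    if not K_list:
        raise ValueError("K_set must be non-empty")
    if any(k < 1 for k in K_list):
        raise ValueError("all K must be positive")
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")

    profiles = {k: SpdvProfile(sites.label, k, mode, {}) for k in K_list}
    chains = structure.chain_ids if mode == "intra" else [None]
    for chain in chains:
        res_keys, res_xyz = structure.ca_coords(
            [r.key for r in (structure.chain(chain) if chain else structure.residues)]
        )
        site_keys, site_xyz = _site_coords(structure, sites, chain)
        if not res_keys:
            continue
        if not site_keys:
            for prof in profiles.values():
                prof.undefined.update(res_keys)
            continue
        D = cdist(res_xyz, site_xyz)
        site_col = {k: j for j, k in enumerate(site_keys)}
        for i, rk in enumerate(res_keys):
            row = D[i]
            j = site_col.get(rk)
            if j is not None:  # leave-self-out at site residues
                row = np.delete(row, j)
            for k in K_list:
                val = _k_smallest_mean(row, k)
                if np.isnan(val):
                    profiles[k].undefined.add(rk)
                else:
                    profiles[k].values[rk] = val
    return profiles


def spdv_1d(seq_length: int, sites: Iterable[int], query: int, K: int) -> float:
    """Sequence-distance analog of SPDV: mean of the K smallest |query − site|
    separations in residues, with self-exclusion. NaN when fewer than K
    eligible sites exist.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    if not (1 <= query <= seq_length):
        raise KeyError(f"query {query} outside sequence 1..{seq_length}")
    pos = sorted(set(int(p) for p in sites))
    if not pos:
        raise ValueError("site set is empty")
    if any(p < 1 or p > seq_length for p in pos):
        raise ValueError("site positions outside sequence range")
    dists = np.array([abs(query - p) for p in pos if p != query], dtype=float)
    if dists.size == 0:
        logger.warning("no eligible sites for 1D query %d", query)
        return float("nan")
    return _k_smallest_mean(dists, K)


def edc(structure: StructureModel, sites: SiteSet, mode: str = "inter") -> EdcResult:
    """Extent of Disease Clustering.

    numerator_mean: mean over all residues (with a Cα) of the distance to the
    nearest site other than the residue itself.
    denominator_mean: the same mean restricted to the site residues (nearest
    *other* site).
    EDC = numerator / denominator; ≈1 for randomly dispersed sites, >1 for
    clustered sites.
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    chains = structure.chain_ids if mode == "intra" else [None]
    num_terms: list[np.ndarray] = []
    den_terms: list[np.ndarray] = []
    n_sites_total = 0
    for chain in chains:
        res_keys, res_xyz = structure.ca_coords(
            [r.key for r in (structure.chain(chain) if chain else structure.residues)]
        )
        site_keys, site_xyz = _site_coords(structure, sites, chain)
        if not site_keys:
            continue
        n_sites_total += len(site_keys)
        D = cdist(res_xyz, site_xyz)
        site_col = {k: j for j, k in enumerate(site_keys)}
        for i, rk in enumerate(res_keys):
            j = site_col.get(rk)
            row = D[i] if j is None else np.delete(D[i], j)
            if row.size == 0:
                continue
            nearest = row.min()
            num_terms.append(nearest)
            if j is not None:
                den_terms.append(nearest)
    if n_sites_total < 2:
        raise ValueError("EDC requires at least 2 sites with Cα coordinates")
    numerator = float(np.mean(num_terms))
    denominator = float(np.mean(den_terms))
    return EdcResult(
        edc=numerator / denominator,
        n_sites=n_sites_total,
        n_residues=len(num_terms),
        numerator_mean=numerator,
        denominator_mean=denominator,
    )


def profile_table(profiles: Mapping[int, SpdvProfile], residue_map=None):
    """Tidy DataFrame of SPDV profiles: one row per (residue, model, K).

    When a :class:`~spdvkit.structures.ResidueMap` is given, structure keys
    are translated to human positions and unmapped residues dropped.
    """
    import pandas as pd

    rows = []
    for k, prof in sorted(profiles.items()):
        for key, val in sorted(prof.values.items()):
            if residue_map is not None:
                try:
                    pos = residue_map.pos_for(key)
                except KeyError:
                    continue
                ident = pos
            else:
                ident = f"{key[0]}/{key[1]}{key[2]}"
            rows.append(
                {"human_pos": ident, "model_label": prof.model_label, "K": k,
                 "spdv": val, "orientation": prof.orientation}
            )
    return pd.DataFrame(rows, columns=["human_pos", "model_label", "K", "spdv", "orientation"])
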