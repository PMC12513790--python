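"""Shared fixtures and independent brute-force oracles.

The oracle functions deliberately use naive enumeration (python loops,
explicit sorts) so they stay independent of the vectorised implementations
they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from spdvkit.structures import Residue, StructureModel

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.100   0.200   0.300  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.900   0.100   0.200  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.000   1.000   0.000  1.00  0.00           C
ATOM      5  CA  SER A   3       8.000   0.000   1.500  1.00  0.00           C
END
"""

MISSING_CA_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


def structure_from_coords(xyz, chain_id: str = "A", start: int = 1) -> StructureModel:
    """Single-chain structure with given Cα coordinates."""
    residues = [
        Residue(chain_id, start + i, "", "ALA", np.asarray(c, dtype=float))
        for i, c in enumerate(xyz)
    ]
    return StructureModel("test", residues)


def multichain_structure(coords_by_chain: dict) -> StructureModel:
    residues = []
    for chain_id, xyz in coords_by_chain.items():
        for i, c in enumerate(xyz):
            residues.append(Residue(chain_id, i + 1, "", "ALA", np.asarray(c, dtype=float)))
    return StructureModel("test", residues)


# ---------------------------------------------------------------- oracles


def brute_spdv(coords: dict, site_keys, query, K: int) -> float:
    """Exhaustive SPDV: all distances listed, sorted, mean of K smallest."""
    q = coords[query]
    dists = []
    for s in site_keys:
        if s == query:
            continue
        dists.append(math.dist(q, coords[s]))
    dists.sort()
    if len(dists) < K:
        return float("nan")
    return sum(dists[:K]) / K


def brute_spdv_1d(sites, query: int, K: int) -> float:
    dists = sorted(abs(query - p) for p in sites if p != query)
    if len(dists) < K:
        return float("nan")
    return sum(dists[:K]) / K


def brute_edc(coords: dict, site_keys) -> float:
    """EDC by direct enumeration of nearest-site distances."""
    sites = list(site_keys)
    num = []
    den = []
    for key, xyz in coords.items():
        ds = [math.dist(xyz, coords[s]) for s in sites if s != key]
        if not ds:
            continue
        nearest = min(ds)
        num.append(nearest)
        if key in site_keys:
            den.append(nearest)
    return (sum(num) / len(num)) / (sum(den) / len(den))


def brute_auc(pos_scores, neg_scores) -> float:
    """Pair-counting AUC: concordant pairs + half ties."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def missing_ca_pdb(tmp_path):
    path = tmp_path / "gap.pdb"
    path.write_text(MISSING_CA_PDB)
    return path
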