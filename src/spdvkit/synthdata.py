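"""Synthetic structures, planted disease sites and score distributions.

The generator produces the controlled regimes the metrics are designed to
separate: site sets planted uniformly at random (no clustering, EDC ≈ 1)
versus sites concentrated around spatial cluster centers (EDC > 1, low SPDV
near the cluster), and two-component Gaussian score distributions for
exercising ROC evaluation and likelihood-ratio calibration.

Generated structures are serialised to minimal PDB text and parsed back
through the ordinary structure reader, so the file-reading code path is
exercised rather than bypassed. All randomness flows from the single seed of
the :class:`SyntheticSpec` via independent child streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from spdvkit.metrics import SiteSet
from spdvkit.structures import StructureModel, read_pdb_string, Residue, pdb_text

CA_SPACING = 3.8          # Å, consecutive Cα along a chain
HELIX_RISE = 1.5          # Å per residue, ideal α-helix
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # Å
GLOBULE_DENSITY = 0.6e-3  # residues per Å³ (0.6 per nm³)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic instance; ``seed`` is mandatory."""

    n_residues: int
    seed: int
    geometry: str = "random_globule"  # line | helix | random_globule
    site_count: int = 0
    cluster_centers: list[int] | None = None  # residue indices (1-based); None ⇒ one random center
    cluster_spread: float = math.inf          # Å; inf ⇒ uniform planting
    path_mean: float = 2.0
    path_sd: float = 1.0
    benign_mean: float = 0.0
    benign_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("n_residues must be ≥ 2")
        if self.site_count > self.n_residues:
            raise ValueError("site_count cannot exceed n_residues")
        if not (self.cluster_spread > 0):
            raise ValueError("cluster_spread must be positive (or inf for uniform)")
        if self.geometry not in ("line", "helix", "random_globule"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, stream])


def _coordinates(spec: SyntheticSpec) -> np.ndarray:
    n = spec.n_residues
    if spec.geometry == "line":
        xyz = np.zeros((n, 3))
        xyz[:, 0] = CA_SPACING * np.arange(n)
        return xyz
    if spec.geometry == "helix":
        i = np.arange(n)
        theta = np.deg2rad(HELIX_TWIST) * i
        return np.column_stack(
            [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
        )
    # random_globule: uniform points in a sphere at protein-like packing
    rng = spec.rng(0)
    radius = (3 * n / (4 * math.pi * GLOBULE_DENSITY)) ** (1 / 3)
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got), 3))
        cand = cand[np.linalg.norm(cand, axis=1) <= radius]
        take = min(len(cand), n - got)
        pts[got : got + take] = cand[:take]
        got += take
    return pts


def make_structure(spec: SyntheticSpec, chain_id: str = "A") -> StructureModel:
    """Deterministic synthetic single-chain structure for the seed.

    Coordinates are serialised to PDB text and re-read through
    :func:`spdvkit.structures.read_pdb_string`.
    """
    xyz = _coordinates(spec)
    residues = [
        Residue(chain_id, i + 1, "", "ALA", xyz[i]) for i in range(spec.n_residues)
    ]
    text = pdb_text(StructureModel(f"synthetic-{spec.geometry}-{spec.seed}", residues))
    return read_pdb_string(text, structure_id=f"synthetic-{spec.geometry}-{spec.seed}")


def plant_sites(structure: StructureModel, spec: SyntheticSpec, label: str = "planted") -> SiteSet:
    """Plant ``site_count`` disease sites on the structure.

    With infinite spread, sites are sampled uniformly without replacement.
    Otherwise residues are sampled without replacement with probability
    proportional to a Gaussian kernel of the distance to the nearest cluster
    center.
    """
    if spec.site_count < 1:
        raise ValueError("site_count must be ≥ 1 to plant sites")
    keys, xyz = structure.ca_coords()
    n = len(keys)
    if spec.site_count > n:
        raise ValueError("site_count exceeds residues with coordinates")
    rng = spec.rng(1)
    if math.isinf(spec.cluster_spread):
        idx = rng.choice(n, size=spec.site_count, replace=False)
    else:
        centers = spec.cluster_centers
        if centers is None:
            centers = [int(rng.integers(1, n + 1))]
        center_xyz = xyz[[c - 1 for c in centers]]
        d2 = ((xyz[:, None, :] - center_xyz[None, :, :]) ** 2).sum(-1).min(axis=1)
        logw = -d2 / (2 * spec.cluster_spread**2)
        # Gumbel-max trick: weighted sampling without replacement
        idx = np.argsort(-(logw + rng.gumbel(size=n)))[: spec.site_count]
    return SiteSet(label, frozenset(keys[i] for i in idx))


def sites_to_variant_table(sites: SiteSet, label: str = "MH") -> pd.DataFrame:
    """Variant table with one alanine→valine variant per planted site."""
    rows = [
        {"human_pos": num, "ref_aa": "A", "alt_aa": "V", "label": label, "source": "synthetic"}
        for (_, num, _) in sorted(sites.keys)
    ]
    return pd.DataFrame(rows)


def simulate_scores(
    n_path: int,
    n_benign: int,
    seed: int,
    path_mean: float = 2.0,
    path_sd: float = 1.0,
    benign_mean: float = 0.0,
    benign_sd: float = 1.0,
    predictor: str = "synthetic",
    orientation: str = "higher_pathogenic",
) -> pd.DataFrame:
    """Two-component Gaussian score table with truth labels.

    Returns a tidy DataFrame (variant, predictor, score, orientation, truth)
    with ``truth`` ∈ {pathogenic, benign}; deterministic per seed.
    """
    if n_path < 1 or n_benign < 1:
        raise ValueError("n_path and n_benign must be positive")
    if path_sd <= 0 or benign_sd <= 0:
        raise ValueError("standard deviations must be positive")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 2])
    path = rng.normal(path_mean, path_sd, n_path)
    benign = rng.normal(benign_mean, benign_sd, n_benign)
    rows = [
        {"variant": f"path_{i:05d}", "predictor": predictor, "score": s,
         "orientation": orientation, "truth": "pathogenic"}
        for i, s in enumerate(path)
    ] + [
        {"variant": f"benign_{i:05d}", "predictor": predictor, "score": s,
         "orientation": orientation, "truth": "benign"}
        for i, s in enumerate(benign)
    ]
    return pd.DataFrame(rows)


def write_instance(spec: SyntheticSpec, outdir: str | Path, n_scores: tuple[int, int] = (200, 200)) -> dict[str, Path]:
    """Write a full synthetic instance (PDB + variants.tsv + scores.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    structure = make_structure(spec)
    paths = {"structure": outdir / "structure.pdb"}
    paths["structure"].write_text(pdb_text(structure))
    if spec.site_count:
        sites = plant_sites(structure, spec)
        variants = sites_to_variant_table(sites)
        paths["variants"] = outdir / "variants.tsv"
        variants.to_csv(paths["variants"], sep="\t", index=False)
    scores = simulate_scores(
        n_scores[0], n_scores[1], spec.seed,
        spec.path_mean, spec.path_sd, spec.benign_mean, spec.benign_sd,
    )
    paths["scores"] = outdir / "scores.tsv"
    scores.to_csv(paths["scores"], sep="\t", index=False)
    return paths
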