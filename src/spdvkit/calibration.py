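"""Gene-specific ACMG/AMP PP3/BP4 evidence calibration.

A predictor score is converted to clinical evidence through its positive
likelihood ratio lr⁺(s): the ratio of the score density among reference
pathogenic (P/LP) variants to the density among reference benign (B/LB)
variants, both estimated by Gaussian kernel density estimation. Bootstrap
resampling of the two reference sets yields a percentile band around the lr
curve; evidence assignment uses the conservative band edge (lower for PP3,
upper for BP4) so that evidence strength is never overstated.

Evidence thresholds follow the Bayesian odds-of-pathogenicity framework: the
odds required for *very strong* pathogenic evidence, op_vs, is the posterior
odds of a near-certain call (default posterior 0.99) divided by the prior
odds; successive square roots of op_vs give the strong, moderate and
supporting thresholds, and the benign (BP4) thresholds are their exact
reciprocals. With the 10% prior used for genes of mixed inheritance,
op_vs = 891 and supporting evidence starts at lr⁺ ≈ 2.34.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATHOGENIC_LEVELS = ("very_strong", "strong", "moderate", "supporting")
EVIDENCE_LEVELS = (
    "PP3_very_strong", "PP3_strong", "PP3_moderate", "PP3_supporting",
    "indeterminate",
    "BP4_supporting", "BP4_moderate", "BP4_strong", "BP4_very_strong",
)


@dataclass
class EvidenceLadder:
    """Prior-derived likelihood-ratio thresholds for PP3/BP4 levels."""

    prior: float
    posterior_vs: float
    op_vs: float
    pathogenic: dict[str, float]  # level -> lr threshold (call when lr ≥)
    benign: dict[str, float]      # level -> lr threshold (call when lr ≤)


def evidence_ladder(prior: float = 0.1, posterior_vs: float = 0.99) -> EvidenceLadder:
    """Build the evidence ladder for a given prior probability of pathogenicity.

    op_vs = posterior odds / prior odds; thresholds for strong, moderate and
    supporting are op_vs^(1/2), op_vs^(1/4), op_vs^(1/8); benign thresholds
    are the reciprocals.
    """
    if not (0.0 < prior < 1.0):
        raise ValueError(f"prior must be in (0, 1), got {prior}")
    if not (prior < posterior_vs < 1.0):
        raise ValueError(f"posterior_vs must be in (prior, 1), got {posterior_vs}")
    op_vs = (posterior_vs / (1.0 - posterior_vs)) / (prior / (1.0 - prior))
    pathogenic = {
        "very_strong": op_vs,
        "strong": op_vs ** 0.5,
        "moderate": op_vs ** 0.25,
        "supporting": op_vs ** 0.125,
    }
    benign = {level: 1.0 / thr for level, thr in pathogenic.items()}
    return EvidenceLadder(prior, posterior_vs, op_vs, pathogenic, benign)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread <= 0:
        raise ValueError("reference scores are degenerate (zero spread)")
    return 0.9 * spread * n ** (-0.2)


def kde_density(samples: np.ndarray, grid: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    """Gaussian KDE evaluated on ``grid``; Silverman bandwidth by default."""
    samples = np.asarray(samples, dtype=float)
    h = silverman_bandwidth(samples) if bandwidth is None else float(bandwidth)
    z = (grid[:, None] - samples[None, :]) / h
    return np.exp(-0.5 * z * z).sum(axis=1) / (len(samples) * h * np.sqrt(2 * np.pi))


@dataclass
class LrModel:
    """Fitted lr⁺ curve for one predictor with a bootstrap percentile band.

    ``grid`` spans the pooled reference scores; beyond the span lr⁺ is
    clamped to its boundary value (KDE tails are unreliable, so the curve is
    never extrapolated).
    """

    predictor: str
    orientation: str
    path_scores: np.ndarray
    benign_scores: np.ndarray
    bandwidth: str | float
    n_boot: int
    seed: int
    grid: np.ndarray
    lr_point: np.ndarray
    lr_lower: np.ndarray
    lr_upper: np.ndarray
    lr_ceiling: float = 1e6

    def lr(self, scores) -> np.ndarray:
        return np.interp(np.asarray(scores, dtype=float), self.grid, self.lr_point)

    def lr_band(self, scores) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(scores, dtype=float)
        return (np.interp(s, self.grid, self.lr_lower),
                np.interp(s, self.grid, self.lr_upper))


def _class_rng(seed: int, samples: np.ndarray) -> np.random.Generator:
    # bootstrap stream keyed by the data, not by the class role, so that
    # swapping the reference sets reflects the lr curves exactly
    digest = zlib.crc32(np.ascontiguousarray(samples, dtype=float).tobytes())
    return np.random.default_rng([seed & 0x7FFFFFFF, digest])


def _lr_from_densities(dp: np.ndarray, db: np.ndarray, ceiling: float) -> np.ndarray:
    tiny = 1e-300
    return np.clip((dp + tiny) / (db + tiny), 1.0 / ceiling, ceiling)


def fit_lr_curve(
    path_scores,
    benign_scores,
    predictor: str = "score",
    orientation: str = "higher_pathogenic",
    bandwidth: str | float = "silverman",
    n_boot: int = 1000,
    seed: int = 0,
    n_grid: int = 256,
    band: tuple[float, float] = (5.0, 95.0),
    min_ref: int = 10,
    lr_ceiling: float = 1e6,
) -> LrModel:
    """Fit a bootstrap-stabilised KDE likelihood-ratio curve.

    Parameters
    ----------
    path_scores, benign_scores
        Reference scores of expert-curated pathogenic / benign variants; each
        set must contain at least ``min_ref`` finite values.
    bandwidth
        ``"silverman"`` (per reference set, per bootstrap resample) or a
        fixed numeric bandwidth.
    band
        Percentiles of the bootstrap lr curves forming the conservative band.
    """
    p = np.asarray(path_scores, dtype=float)
    b = np.asarray(benign_scores, dtype=float)
    p, b = p[np.isfinite(p)], b[np.isfinite(b)]
    if len(p) < min_ref or len(b) < min_ref:
        raise ValueError(
            f"each reference set needs ≥ {min_ref} scores (got {len(p)} pathogenic, {len(b)} benign)"
        )
    pooled = np.concatenate([p, b])
    grid = np.linspace(pooled.min(), pooled.max(), n_grid)
    bw = None if bandwidth == "silverman" else float(bandwidth)

    dp = kde_density(p, grid, bw)
    db = kde_density(b, grid, bw)
    if np.any(db <= 0):
        logger.warning("zero benign density inside the score span; lr capped at %g", lr_ceiling)
    lr_point = _lr_from_densities(dp, db, lr_ceiling)

    rng_p = _class_rng(seed, p)
    rng_b = _class_rng(seed, b)
    boot_lr = np.empty((n_boot, n_grid))
    for i in range(n_boot):
        bp = p[rng_p.integers(0, len(p), len(p))]
        bb = b[rng_b.integers(0, len(b), len(b))]
        boot_lr[i] = _lr_from_densities(kde_density(bp, grid, bw), kde_density(bb, grid, bw), lr_ceiling)
    # floor/ceiling order statistics keep the band conservative and make the
    # band of the swapped fit the exact reciprocal of this one
    lr_lower = np.percentile(boot_lr, band[0], axis=0, method="lower")
    lr_upper = np.percentile(boot_lr, band[1], axis=0, method="higher")

    return LrModel(
        predictor=predictor,
        orientation=orientation,
        path_scores=p,
        benign_scores=b,
        bandwidth=bandwidth,
        n_boot=n_boot,
        seed=seed,
        grid=grid,
        lr_point=lr_point,
        lr_lower=lr_lower,
        lr_upper=lr_upper,
        lr_ceiling=lr_ceiling,
    )


@dataclass
class EvidenceCall:
    variant: str
    score: float
    lr: float
    lr_lower: float
    lr_upper: float
    level: str


def assign_level(lr_lower: float, lr_upper: float, ladder: EvidenceLadder) -> str:
    """Strongest pathogenic level whose threshold the conservative lr meets,
    else the strongest benign level, else indeterminate."""
    for level in PATHOGENIC_LEVELS:
        if lr_lower >= ladder.pathogenic[level]:
            return f"PP3_{level}"
    for level in PATHOGENIC_LEVELS:
        if lr_upper <= ladder.benign[level]:
            return f"BP4_{level}"
    return "indeterminate"


def classify_variants(
    model: LrModel,
    ladder: EvidenceLadder,
    scores: pd.DataFrame,
) -> list[EvidenceCall]:
    """Assign PP3/BP4 evidence levels to scored variants.

    ``scores`` needs columns ``variant`` and ``score``; when ``predictor`` /
    ``orientation`` columns are present they must match the model. Scores
    outside the fitted span are clamped to the boundary lr (logged).
    """
    if "predictor" in scores.columns:
        other = set(scores["predictor"].unique()) - {model.predictor}
        if other:
            raise ValueError(f"score table contains other predictors: {sorted(other)}")
    if "orientation" in scores.columns:
        other = set(scores["orientation"].unique()) - {model.orientation}
        if other:
            raise ValueError(f"orientation mismatch with model: {sorted(other)}")
    s = scores["score"].to_numpy(dtype=float)
    outside = (s < model.grid[0]) | (s > model.grid[-1])
    if outside.any():
        logger.warning("%d scores outside the fitted span; lr clamped at the boundary", int(outside.sum()))
    lr = model.lr(s)
    lo, hi = model.lr_band(s)
    return [
        EvidenceCall(v, float(sc), float(l), float(a), float(c), assign_level(a, c, ladder))
        for v, sc, l, a, c in zip(scores["variant"], s, lr, lo, hi)
    ]


def calls_frame(calls: Sequence[EvidenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"variant": c.variant, "score": c.score, "lr": c.lr,
          "lr_lower": c.lr_lower, "lr_upper": c.lr_upper, "level": c.level}
         for c in calls]
    )


def summarise_calls(
    calls: Sequence[EvidenceCall],
    categories: Mapping[str, str],
) -> pd.DataFrame:
    """Composition of evidence classes per variant category.

    Returns a DataFrame indexed by evidence level with one column per
    category; each column's fractions sum to 1. Every call's variant must
    belong to exactly one category.
    """
    missing = [c.variant for c in calls if c.variant not in categories]
    if missing:
        raise ValueError(f"variants without a category: {missing[:5]}")
    df = pd.DataFrame({"category": [categories[c.variant] for c in calls],
                       "level": [c.level for c in calls]})
    counts = df.groupby(["category", "level"]).size().unstack(0, fill_value=0)
    frac = counts / counts.sum(axis=0)
    return frac.reindex([lv for lv in EVIDENCE_LEVELS if lv in frac.index])
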