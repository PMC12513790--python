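"""Discrimination analysis: ROC AUC and rank-sum comparisons.

The AUC is computed through its Mann–Whitney identity — the probability that
a randomly chosen pathogenic variant outscores a randomly chosen benign one,
with ties counted one half — which makes it robust to class-size imbalance
and to monotone rescaling of predictor scores.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from spdvkit.scores import DOMINANT

logger = logging.getLogger(__name__)


def roc_auc(scores, labels, orientation: str = "higher_pathogenic") -> float:
    """ROC AUC of ``scores`` against binary ``labels`` (1 = pathogenic).

    Equals the Mann–Whitney U statistic normalised by n1·n0, ties ½. Pairs
    with a missing score are dropped. For a ``lower_pathogenic`` predictor
    (such as SPDV) the score order is reversed, so a well-behaved predictor
    always yields AUC > 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if orientation == "lower_pathogenic":
        s = -s
    elif orientation != "higher_pathogenic":
        raise ValueError(f"unknown orientation {orientation!r}")
    y = y.astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be represented")
    ranks = rankdata(s, method="average")
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def ranksum_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns (U statistic for sample a, p-value) using the normal
    approximation with tie correction. When every pooled value is identical
    the statistic carries no information and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    z = (u - n1 * n2 / 2) / math.sqrt(var)
    p = math.erfc(abs(z) / math.sqrt(2))
    return float(u), float(min(p, 1.0))


def evaluate_predictors(
    score_table: pd.DataFrame,
    variants: pd.DataFrame,
    comparisons: Sequence[tuple[str, Sequence[str]]] | None = None,
) -> pd.DataFrame:
    """One ROC AUC per predictor per comparison.

    ``comparisons`` is a list of (label, pathogenic phenotype subset); each
    subset is compared against the benign class. The default follows the
    dominant-disease design: MH+CCD+RRD pooled, then each dominant phenotype
    separately (recessive variants are excluded, as they are common in a
    heterozygous state in healthy populations). Missing scores are removed
    per predictor (pairwise deletion), so each AUC uses every variant that
    predictor actually scored.
    """
    if comparisons is None:
        comparisons = [("dominant vs benign", DOMINANT)] + [
            (f"{ph} vs benign", (ph,)) for ph in DOMINANT
        ]
    v = variants.set_index("variant")["label"]
    rows = []
    for predictor, sub in score_table.groupby("predictor", sort=False):
        sub = sub.drop_duplicates(subset="variant").set_index("variant")
        orientation = sub["orientation"].iloc[0]
        labels = v.reindex(sub.index)
        for comp_label, phenos in comparisons:
            is_path = labels.isin(phenos)
            is_benign = labels == "benign"
            mask = (is_path | is_benign) & sub["score"].notna()
            n1 = int((is_path & mask).sum())
            n0 = int((is_benign & mask).sum())
            if n1 == 0 or n0 == 0:
                logger.warning("skipping %s for %s: empty class", comp_label, predictor)
                continue
            auc = roc_auc(
                sub.loc[mask, "score"].to_numpy(),
                is_path[mask].to_numpy(),
                orientation,
            )
            rows.append(
                {"predictor": predictor, "comparison": comp_label,
                 "n_pathogenic": n1, "n_benign": n0, "roc_auc": auc}
            )
    return pd.DataFrame(rows, columns=["predictor", "comparison", "n_pathogenic", "n_benign", "roc_auc"])


def roc_curve_points(scores, labels, orientation: str = "higher_pathogenic") -> pd.DataFrame:
    """(fpr, tpr) points of the ROC curve, for plotting/export."""
    from sklearn.metrics import roc_curve as _sk_roc_curve

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if orientation == "lower_pathogenic":
        s = -s
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})
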