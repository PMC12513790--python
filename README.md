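# spdvkit

Structure-based spatial-clustering metrics and clinical evidence calibration
for missense variant interpretation.

In many dominant disorders — RyR1-related disease (malignant hyperthermia,
central core disease) being a prominent example — pathogenic missense
variants act through gain-of-function mechanisms that sequence-based variant
effect predictors (VEPs) capture poorly, yet the variants cluster strongly in
the three-dimensional structure of the protein. `spdvkit` turns that
clustering into a usable predictor and into calibrated ACMG/AMP PP3/BP4
clinical evidence:

- **SPDV_K** (Spatial Proximity to Disease Variants): for a residue *r*,
  the mean of the *K* smallest Cα–Cα Euclidean distances from *r* to the
  unique sites of known pathogenic variants,

  SPDV_K(r) = (1/K) Σ_{i=1..K} d₍ᵢ₎(r, S \ {r}),

  where d₍₁₎ ≤ d₍₂₎ ≤ … are the sorted distances to the site set *S* and *r*
  is always excluded from its own calculation (so scoring a known pathogenic
  residue is never circular). Lower SPDV ⇒ more suspicious. Intra-chain,
  interchain (sites pooled across a complex) and a 1D sequence-distance
  analog are provided.
- **EDC** (Extent of Disease Clustering): the mean nearest-site distance
  over all residues divided by the mean nearest-other-site distance over
  the site residues themselves. EDC ≈ 1 for randomly dispersed sites,
  EDC > 1 for spatial clustering.
- **Evaluation**: ROC AUC through its Mann–Whitney identity (ties ½,
  pairwise deletion of missing scores, per-phenotype comparisons) and
  Wilcoxon rank-sum comparisons.
- **PP3/BP4 calibration**: gene-specific positive likelihood ratios
  lr⁺(s) = f_P(s)/f_B(s) estimated by Gaussian KDE from reference
  pathogenic and benign score distributions, bootstrap percentile bands,
  and an evidence ladder derived from a prior probability of pathogenicity
  (prior 0.1, posterior 0.99 ⇒ odds for *very strong* = 891; successive
  square roots give strong / moderate / supporting; benign thresholds are
  the exact reciprocals).

Supporting machinery includes PDB/mmCIF reading (via gemmi), pairwise
alignment-based mapping of human sequence positions onto structure
residues, variant dataset assembly, predictor-score segmentation/merging
for very long proteins, rank normalisation, and a synthetic-data generator
(line / helix / random-globule structures with uniformly or cluster-planted
disease sites and two-component Gaussian score distributions).

## Worked example

Plant 25 clustered disease sites on a 250-residue synthetic globule, score
every residue with SPDV_4, and calibrate the scores into PP3/BP4 evidence:

```python
import numpy as np, pandas as pd
from spdvkit import (SyntheticSpec, make_structure, plant_sites, spdv_profile,
                     edc, roc_auc, fit_lr_curve, evidence_ladder, classify_variants)

spec = SyntheticSpec(n_residues=250, seed=23, site_count=25,
                     cluster_spread=6.0, cluster_centers=[60])
st = make_structure(spec)
sites = plant_sites(st, spec)

r = edc(st, sites)
print(f"EDC = {r.edc:.2f}  ({r.n_sites} sites, {r.n_residues} residues)")

prof = spdv_profile(st, sites, K_set=[4])[4]
site_keys = set(sites.keys)
scores = np.array(list(prof.values.values()))
labels = np.array([k in site_keys for k in prof.values])
print(f"SPDV_4 ROC AUC = {roc_auc(scores, labels, orientation='lower_pathogenic'):.3f}")

model = fit_lr_curve(scores[labels], scores[~labels], predictor="SPDV_4",
                     orientation="lower_pathogenic", n_boot=200, seed=23)
calls = classify_variants(model, evidence_ladder(prior=0.1),
                          pd.DataFrame({"variant": [f"site{i}" for i in range(labels.sum())],
                                        "score": scores[labels]}))
```

which prints

```
EDC = 4.26  (25 sites, 250 residues)
SPDV_4 ROC AUC = 0.988
```

and assigns `PP3_moderate` to 19 and `PP3_supporting` to 6 of the 25
planted sites: tightly clustered sites give a large EDC, low SPDV values at
and near the cluster, near-perfect site/non-site discrimination, and
moderate-strength pathogenic evidence after conservative (lower bootstrap
band) likelihood-ratio calibration. With uniformly planted sites the same
pipeline returns EDC ≈ 1 and AUC ≈ 0.5.

A `spdvkit` console script exposes the same steps
(`simulate`, `map`, `spdv`, `edc`, `assemble`, `rank-norm`,
`merge-segments`, `evaluate`, `calibrate`); see `spdvkit --help`.

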