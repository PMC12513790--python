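# Methods

## Spatial proximity to disease variants (SPDV)

For a residue *r* with a resolved Cα and a set *S* of unique
pathogenic-variant sites, SPDV_K(r) is the mean of the K smallest Euclidean
Cα–Cα distances from *r* to members of *S*, with *r* removed from *S* when
it is itself a site. Self-exclusion makes the score non-circular: a known
pathogenic residue is evaluated purely by its proximity to *other* disease
sites. Cα atoms are used as the residue reference point because backbone
positions are reliably placed even at moderate (≈3–4 Å) cryo-EM
resolution, where side-chain placement is noisy.

Modes:

- **intra**: only sites on the query's own chain are eligible;
- **inter**: sites on all chains of the complex are pooled and the nearest
  K are taken across chains (relevant for homotetrameric channels, where a
  site's closest disease neighbour may sit on the adjacent protomer);
- **1D analog**: distance is |i − j| in sequence positions; it serves as the
  structure-free baseline, and its lower discrimination performance is what
  demonstrates the value of the 3D metric.

Numerical choices: distances are ranked with a stable sort and exactly the
K smallest enter the mean — ties at the K-th position never expand K, so
results are deterministic. A residue with fewer than K eligible sites gets
an undefined (missing) value, never an imputed one; imputation would
silently distort downstream AUCs. Residues without a Cα are skipped in
profiles. SPDV is oriented *lower = more pathogenic*; the orientation is
carried as a flag on the profile rather than by negating values, so
exported tables remain in Å.

## Extent of disease clustering (EDC)

EDC = (mean over all residues of the distance to the nearest site other
than the residue itself) ÷ (the same mean restricted to the site residues).
If sites are dispersed like any other residue, the two means agree and
EDC ≈ 1; if sites huddle together, sites see a much closer nearest
neighbour than a typical residue does, and EDC > 1. The numerator includes
the site residues themselves (with self-exclusion), which pulls the
statistic mildly toward 1 but keeps it a ratio of like-for-like means. At
least two sites with coordinates are required (the denominator is undefined
otherwise).

There is a small finite-size bias: non-site residues choose the nearest of
|S| sites while site residues choose among |S|−1, so under uniform planting
the expected EDC sits slightly below 1 (nearest-neighbour distance scales
like |S|^(−1/3)); with 20 sites this is ≈2% and the Monte-Carlo acceptance
envelope [0.95, 1.05] absorbs it.

## Sequence↔structure mapping

All cross-referencing between 1-based human sequence numbering and author
numbering of the deposited structure goes through a `ResidueMap` built from
a two-record FASTA pairwise alignment (human row first). Any alignment
program may produce it; the reader validates that the ungapped rows
reproduce the human sequence and the modelled chain sequence exactly, and
reports the first offending column otherwise. Aligned ortholog
substitutions are mapped but flagged; human positions aligned to gaps
(unmodelled/disordered residues), to residues without a Cα, or to
nonstandard residues with no parent amino acid are listed as unmapped with
the reason. Nonstandard residues with a known parent (MSE → M) participate
normally. For altLoc Cα records the first-listed location is kept —
deterministic and standard practice at moderate resolution. Insertion codes
are part of the residue key.

## Score handling

- **Segmentation**: very long proteins exceed what some predictors accept
  in one pass; `segment_sequence(length, 800, 50)` produces 800-residue
  windows overlapping by 50 (a 5038-residue sequence gives seven segments,
  the last 538 long) and `merge_segment_scores` averages scores where
  windows overlap, ignoring missing values.
- **Rank normalisation**: ascending midranks over the finite values divided
  by their count, mapping any score to (0, 1] and making downstream
  comparisons invariant to monotone rescaling. Midranks for ties keep the
  operation consistent with rank-sum testing.
- **Dataset assembly**: population variants also present in the disease set
  are removed from the benign side, keeping the classes mutually exclusive;
  duplicate records collapse; conflicting phenotype annotations for one
  variant raise an error rather than being silently resolved. No allele
  frequency filter is applied to the population set — rare benign variants
  are exactly what a predictor must separate from rare pathogenic ones in
  practice.

## Evaluation

ROC AUC is computed through the Mann–Whitney identity (rank sum of the
pathogenic class, ties ½), which is exactly the probability that a random
pathogenic variant outscores a random benign one and is robust to class
imbalance. Missing scores are deleted pairwise per predictor, so every
predictor is evaluated on the variants it actually scored. Default
comparisons pit the pooled dominant phenotypes, and each dominant phenotype
separately, against the benign class; recessive variants are excluded from
discrimination analyses because they circulate heterozygously in healthy
populations. Rank-sum p-values use the normal approximation with tie
correction (adequate at the sample sizes involved; no continuity
correction); no multiple-testing correction is applied and p-values are
reported raw.

## PP3/BP4 calibration

The positive likelihood ratio of a score s is lr⁺(s) = f_P(s)/f_B(s), the
ratio of Gaussian-KDE density estimates over reference pathogenic and
benign score sets (expert-curated labels supplied by the user; the tool
never labels its own references). Defaults and rationale:

- **Bandwidth**: Silverman's rule of thumb, 0.9·min(sd, IQR/1.34)·n^(−1/5),
  per reference set and per bootstrap resample — standard, deterministic,
  robust to heavy tails via the IQR guard. A fixed numeric bandwidth can be
  supplied instead.
- **Bootstrap**: 1000 resamples of each reference set, percentile band at
  5%/95% using floor/ceiling order statistics. Evidence assignment uses the
  conservative band edge — the lower edge for pathogenic (PP3) and the
  upper edge for benign (BP4) calls — so evidence strength is never
  overstated by KDE sampling noise. Each reference set's bootstrap stream
  is keyed by the seed and the data themselves, which makes swapping the
  two reference sets invert every lr curve exactly (PP3 and BP4 calls swap
  one-for-one), a symmetry the test suite asserts.
- **Support**: the lr curve is evaluated on a 256-point grid spanning the
  pooled reference scores; outside the span lr⁺ is clamped to its boundary
  value because KDE tails are unreliable. Zero benign density inside the
  span caps lr⁺ at a configured ceiling (default 10⁶) with a logged
  warning. Each reference set must contain at least 10 scores
  (configurable floor).
- **Evidence ladder**: with prior π and a very-strong posterior of 0.99,
  the odds of pathogenicity for very strong evidence is
  op_vs = (0.99/0.01)/(π/(1−π)); strong, moderate and supporting thresholds
  are op_vs^(1/2), op_vs^(1/4), op_vs^(1/8), and the benign thresholds are
  their exact reciprocals. With the default π = 0.1 (a pragmatic choice for
  genes with mixed inheritance and high VUS rates), op_vs = 891 and
  supporting evidence begins at lr⁺ ≈ 2.34. The posterior is configurable
  rather than hard-coded because different calibration conventions exist.
- **Assignment**: a variant receives the strongest pathogenic level whose
  threshold its lower-band lr⁺ meets; failing that, the strongest benign
  level whose threshold its upper-band lr⁺ undercuts; otherwise
  *indeterminate*. Whether published calibrations use the band edge or the
  point estimate is often unstated; the band edge was chosen here as the
  defensible conservative option, and the point estimate is also reported
  per variant.

## Synthetic data

The generator emulates the regimes the metrics must separate, not protein
physics:

- **Geometries**: a 3.8 Å-spaced line (the mean Cα–Cα distance of a trans
  peptide), an ideal α-helix (1.5 Å rise, 100° twist, 2.3 Å radius), and a
  random globule — uniform points in a sphere at 0.6 residues/nm³, a
  protein-like packing density.
- **Site planting**: uniform sampling without replacement (null regime,
  EDC ≈ 1) or weighted sampling with probability ∝ a Gaussian kernel
  (default spread 5 Å in the envelope checks) of the distance to the
  nearest cluster center (clustered regime, EDC > 1). Weighted sampling
  without replacement uses the Gumbel-max trick for determinism and speed.
- **Scores**: two-component Gaussian mixtures; the default Δμ = 2, sd = 1
  separation gives an analytic ROC AUC of Φ(2/√2) ≈ 0.921 and an analytic
  likelihood ratio exp(2s−2), both used as closed-form oracles.

All randomness derives from the single mandatory seed through independent
child streams, and generated structures are serialised to minimal PDB text
and re-read through the ordinary structure reader so the parsing code path
is exercised.

What passing on synthetic data does *not* show: real pathogenic variants
cluster with irregular geometry (multiple anisotropic clusters along
functional domains), real score distributions are skewed and multimodal,
and real structures have disordered regions and ortholog substitutions.
The structure/mapping layer handles those features and is unit-tested on
crafted fixtures, but quantitative performance numbers on synthetic
instances do not transfer to any particular protein.

## Problem sizes

Default verification runs use 200-residue globules with 20 planted sites
(100 Monte-Carlo seeds for EDC envelopes), 250-residue instances for the
SPDV→AUC pipeline, 1000 scores per class for AUC checks and 2000 per class
with 1000 bootstraps for likelihood-ratio recovery — sizes at which every
brute-force oracle is still exact and the full suite runs in well under a
minute.

## Known limitations

- EDC and SPDV use Cα positions only; side-chain or all-atom variants,
  solvent accessibility and domain annotations are out of scope.
- The lr⁺ curve is not constrained to be monotone in the score; strongly
  non-monotone calibrations (possible with multimodal references) are
  legitimate output but should be inspected before clinical use.
- PP3/BP4 outputs are single ACMG/AMP evidence items; combining them with
  other criteria into a final classification is intentionally out of scope.
- Structure-based scoring requires the variant position to be resolved in
  the structure; variants at disordered positions are reported as unmapped
  rather than scored.
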