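# Methods

## Pipeline

`mplexcov` analyses group-level dual-layer covariance networks built
from regional cortical thickness (CTH, mm) and FDG-PET SUVR tables. The
stages, in order:

1. **Residualization.** Per region and modality, ordinary least squares
   of the subject values on intercept, age (years), sex (coded M=1,
   F=0) and education (years), via QR decomposition. Residuals feed all
   later stages; raw values are never correlated. The fit requires at
   least 5 subjects and a full-rank design; a collinear covariate is
   reported by name. When two groups are compared, the regression is
   fitted once on the pooled pair, not per group: the permutation test
   assumes subjects are exchangeable under the null, and per-group
   fitting would absorb part of any group difference into the nuisance
   model. For descriptive per-group measure tables the fit instead
   pools all subjects of the input cohort.
2. **Layers.** Pearson correlation between all region pairs across the
   subjects of a group, one weighted layer per modality. Diagonal fixed
   at 0; zero-variance regions are an error (named).
3. **Binarization.** Default *density* semantics: at density d exactly
   `round_half_away_from_zero(d·E)` strongest positive edges are kept
   (E = n(n−1)/2). Negative correlations are zeroed first — binarized
   covariance analyses conventionally discard negative edges. Ties are
   broken by a stable sort on (−weight, i, j), i < j, so results are
   platform-independent. An *absolute* mode (edge iff r > d) is
   provided. The default sweep is d = 0.40…0.70 in 0.05 steps.
4. **Supra-adjacency.** Binary layers on the diagonal blocks, replica
   coupling C = c·I (default c = 1) on the off-diagonal blocks. The
   coupling is structural: degrees and all derived measures count
   intralayer edges only, as the participation-coefficient formula
   presumes, so measure values are invariant to c.
5. **Measures.** Intralayer degrees k_i^α, overlapping degree
   o_i = Σ_α k_i^α, nodal multiplex participation coefficient
   p_i = M/(M−1)(1 − Σ_α (k_i^α/o_i)²), and global means over all
   nodes. An isolated node (o_i = 0) gets p_i = 0 — it participates in
   no layer, resolving the 0/0 downward. Note this biases global MPC
   downward at sparse densities; keeping isolated nodes in the global
   mean holds the node count constant across thresholds and groups.
6. **Inference.** Group-level networks have no subject-level values, so
   differences are tested by relabelling subjects into pseudo-groups of
   the original sizes and recomputing the full pipeline per relabelling
   (default 5,000 permutations; at least 100 enforced). The two-tailed
   p uses the add-one estimator p = (#{|Δ_null| ≥ |Δ_obs|}+1)/(B+1), so
   p is never 0 on finite permutations; the null's 2.5 %/97.5 %
   quantiles are reported alongside. The FDR family is the set of
   regions within one (comparison, measure, threshold) triple,
   Benjamini–Hochberg step-up at q = 0.05; global measures are single
   tests per threshold and carry no correction. Families are *not*
   pooled across thresholds; each threshold is reported separately, and
   the manifest echoes this convention.

Seeding: one master seed; independent per-comparison generators are
spawned from it (`numpy` SeedSequence), so adding or removing a
comparison never perturbs another comparison's permutation stream.
Reruns of the same config are bit-identical.

## Cohort statistics

Demographics tables are tested with classical one-way ANOVA (a
summary-statistics path reconstructs SSB/SSW from published mean/SD/n
rows and is algebraically exact given exact summaries; no Welch
correction), Pearson chi-square without continuity correction for sex
ratios, a tie-corrected Kruskal–Wallis H computed directly from ordinal
severity counts via category mid-ranks, and Bonferroni-corrected
pairwise t tests as post hocs. SDs follow the sample (n−1) convention;
p-values come from the asymptotic F and chi-square references.
Statistics recomputed from 2-dp rounded published summaries can only be
expected to match printed F values to within a few percent.

## Synthetic cohorts

The generator's control knob is the *population* correlation matrix per
(group, modality), because the analysis object is the group-level
covariance network. Subjects are i.i.d. multivariate normal draws
around a linear covariate term (age ~ U(50, 80), sex ~ Bernoulli(1/2),
education ~ U(8, 22); default slopes of plausible sign and size for
thickness and SUVR; residual scale 0.15, the order of regional SDs in
surface-extracted ROI tables).

Targets use a two-factor model, PSD by construction:

* a **global factor** whose loadings are spread ±15 % around
  `sqrt(base_correlation − community_loading²)` by a golden-ratio
  low-discrepancy sequence — node strengths are distinct (density
  thresholding is decided by structure, not tie-breaking) yet
  uncorrelated with node index;
* a **community factor** with loading 0.45 on ordinary nodes and 0.80
  on the epicenter subset, making the epicenter a strongly covarying
  hub module in *both* groups' background, consistent with the
  disease-epicenter-as-hub picture.

Defaults: mean background correlation 0.55, n = 60 per group, 34
regions, 6 epicenter nodes. The relatively high correlation level is
deliberate: the sampling noise of a correlation falls as (1−r²)/√n, and
at lower background levels group-level degree estimates at n = 60 are
too noisy for any Δr = 0.3 effect to separate from the permutation
null.

The planted group difference shifts the epicenter's community loading
in one layer of the second group so that each epicenter/non-epicenter
edge changes by exactly `epicenter_delta_by_layer[modality]` (default
−0.3 on the FDG layer only; edges inside the epicenter module change
more, as both endpoints lose loading). This creates layer imbalance:
after thresholding, epicenter FDG degrees collapse while CTH degrees
persist, lowering nodal MPC in the affected group by an amount
computable from the target matrices before any sampling (the
population-level oracle used in tests). A `repair_psd` projection
(eigenvalue clipping at 1e-8, rescale to unit diagonal, logged; error
if any entry moves by more than 0.25) guards hand-crafted
configurations; factor-model targets never trigger it.

What the generator does **not** emulate: site effects, missing data,
non-Gaussian regional distributions, spatial autocorrelation on the
cortical sheet, subject-level network structure, and longitudinal
change. Passing tests therefore demonstrate correctness and calibration
of the *pipeline*, not robustness to those real-data features.

## Calibration and power, as measured

* Type-I error of the global-MPC permutation test on 500 null cohort
  pairs (n = 30/group, 8 regions, 200 permutations — sizes chosen to
  keep the 500-replicate harness fast): empirical rejection rate ≈
  0.044–0.046 at α = 0.05, consistent with the add-one estimator's
  nominal level 10/201 ≈ 0.0498.
* Planted-effect recovery (Δr = −0.3 on the FDG layer of 6/34 nodes,
  n = 60/group, d = 0.5, 1,000 permutations, FDR 0.05): at the default
  seed all six planted nodes are detected with zero false positives;
  across independent seeds the per-node power is high but not
  unfailing — typically 5–6 of 6 detected, occasionally 4, with false
  positives at most ~2 of 28. The dominant failure mode is a whole-row
  sampling fluctuation of one epicenter node's correlations.
* A structural caveat worth knowing: density thresholding is relative,
  so suppressing a large set of strong edges drags the cutoff after
  them and partially absorbs the planted contrast; effects planted near
  the cutoff are intrinsically harder to detect than the same Δr
  planted across it.

## Design choices where the convention was open

* **Threshold semantics.** "0.4–0.7" is read as edge density (the
  common convention for group covariance networks); absolute mode is a
  flag away. All outputs record the mode used.
* **Interlayer coupling value.** Never printed in this literature;
  replica coupling with strength 1 is the multiplex-topology default,
  and no measure here depends on it.
* **Permutation count and p estimator.** Add-one, so 5,000 permutations
  yield a minimum attainable p of ~2×10⁻⁴; both the tail-count p and
  the null 95 % interval are reported because "significant by 95 %
  interval" and "tail-count p < 0.05" differ in edge cases.
* **FDR family.** Regions within one (comparison, measure, threshold);
  spanning thresholds as well would roughly septuple the family and is
  not what per-threshold reporting implies.
* **Sex coding.** M=1/F=0, recorded in the run manifest.
* **Missing values.** Rejected outright; no imputation.

## Limitations

* Group-level networks preclude subject-level inference or correlation
  of measures with clinical scores.
* The bundled parcellation lists cover cortex only (68-region
  gyral and 148-region gyral/sulcal); subcortex and cerebellum are out
  of scope, though any custom region list is accepted.
* Weighted-graph multiplex measures and multiplex clustering are not
  implemented; layers are binarized before measuring.
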