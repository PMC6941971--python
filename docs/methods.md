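# Methods

## Model and estimation

The pipeline assumes a linear-Gaussian relation between a cohort's disease
annotations and its landmark-gene expression. With **Y** (p_disease × n,
risk factors by patients) and **Z** (p_genes × n, log-scale expression
restricted to the landmark set and row-centred),

    Y = H F + ε_Y,    Z = B F + ε_Z,

the latent features **F** (k × n) are extracted by truncated SVD of the
standardized factor matrix and the signatures **B** by ordinary least
squares, B̂ = Z Fᵀ(FFᵀ)⁻¹. The residual Z − B̂F is orthogonal to every
feature row (normal equations); this is asserted at 1e-8 on every fit.

Conventions, chosen where the model itself is indifferent:

* **Factor standardization.** Continuous factor rows are z-scored
  (population sd); binary 0/1 rows are centred only, so rare aberrations
  keep proportionally small leverage. Missing factor values are masked
  during standardization and then set to 0 (the factor mean), which keeps
  all patients in the decomposition.
* **Scale split.** H = U_k Σ_k carries all scale; F = V_kᵀ has unit-norm
  rows. Signature magnitudes are then comparable across cohorts of
  different size.
* **Sign orientation.** Each feature is flipped so that the
  largest-|loading| entry of its H column is positive. Without a fixed
  orientation the suppressor/enhancer directions of the match score would
  be undefined. Across cohorts, signatures are additionally sign-aligned to
  the first cohort before the consistency screen, and the flips are carried
  through to scoring.
* **Supervised mode.** With user loadings H, F is the per-patient least
  squares solution on its natural scale (H = I returns F = Y exactly; pass
  `unit_norm=True` to renormalize). With signed marker gene sets, each
  feature row is mean(z-scored expression of up markers) − mean(down
  markers), unit-normed. Both entry points exist because practitioners
  provide supervision sometimes in factor space, sometimes as gene sets.
* **Survival mode.** The extra feature row is the Cox log-partial-hazard
  per patient (lifelines, Efron ties), with a ridge penalty of 1e-4 for
  stability, covariates standardized, right censoring. The returned row is
  unit-normed.

## Cross-cohort consistency

A feature is retained when the mean pairwise Pearson correlation of its
signature vectors across cohorts exceeds 0.4 — the screen that separates
reproducible risk axes from cohort-specific noise. For permutation or
shuffle controls the sign alignment must be disabled
(`align_signs=False`): a signature fitted to a shuffled feature is still a
random mixture of the cohort-shared expression components, so aligning by
the observed correlation selects |r| and gives the null a positive mean
(≈ 0.3 under the generator defaults) even though the unaligned null is
symmetric about 0. Shuffle controls therefore report the sign-free mean
over replicates.

## Compendium processing

Replicate-level profiles are reduced to one fold-change profile per
(drug, cell line): the plate's mean vehicle (DMSO) profile is subtracted
from its treated profiles, replicates are grouped by (dose, time), and each
group's mean profile enters a precision-weighted mean with weight n/s²
(s² = mean per-gene sample variance within the group; groups with fewer
than 3 replicates get weight n). This vehicle-centring + pooling is the
package's documented stand-in for heavier batch-correction pipelines;
externally pooled profiles can be supplied unchanged through
`compendium.from_pooled`. Profiles are then z-scored per cell line — each
gene to mean 0, sd 1 across drugs, population (ddof=0) sd for bit
reproducibility; genes constant within a cell line are set to 0 and logged.
Cell lines carrying fewer than a configurable number of unique drugs
(default 1000, matching large public compendia; far smaller for synthetic
runs) are dropped.

## Match score

σ(g, h) is the cosine between profile and signature divided by ρ_same, the
mean cosine among profile pairs whose drugs share a high-confidence protein
link (score > 900) in that cell line, clipped to [0, 1]. It is 0 at or
below orthogonality and 1 at the similarity level expected of two drugs
with the same target. Cell lines with fewer than 30 same-target pairs fall
back to the pooled estimate across lines; all calibration scales are
floored at 0.05 so a signal-free calibration set cannot produce a
degenerate divisor (the fallback is logged). σ̄(r) is the analogously
calibrated mean cosine between the drug's profiles in different cell
lines; drugs observed in a single line get the neutral value 0.5. The
score multiplies σ across cohorts (a drug must match consistently in every
cohort to score high), averages over the cell lines where the drug is
present with weights normalized to mean 1, and multiplies by σ̄.

Missing (drug, cell line) entries are simply omitted from the average —
compendium coverage is sparse in practice. All of σ, σ̄ and S are in
[0, 1] by construction, and σ(g, −B) = σ(−g, B) exactly.

## Permutation control

Null scores are generated by permuting the signature's gene labels — the
same permutation applied across cohorts, a fresh one per iteration — and
rescoring all drugs, which preserves the drug–drug correlation structure of
the compendium (drug-label permutation is available behind a flag). The
default per-drug p-value is the deterministic add-one rule
(1 + #{null ≥ S})/(1 + n_perm). Because the score is clipped, its null
distribution has an atom at 0 and the deterministic rule is conservative
there (ties push p toward 1). For calibration studies
`randomized=True` returns the tie-randomized p-value
(#{null > S} + U·(1 + #{null = S}))/(1 + n_perm) with U ~ U(0,1) drawn from
the same seeded generator; it is exactly uniform under the null for any
discrete statistic.

## Target enrichment

Per protein target, R+ holds the compendium drugs with a link score
strictly above 900 and R− every other compendium drug, including those
with sub-threshold links. Targets with |R+| < 4 are skipped (too few
drugs to estimate a distribution shift). The one-sided two-sample KS
statistic D = sup_x [ecdf_{R−}(x) − ecdf_{R+}(x)] detects an upward shift
of R+ scores; the p-value is computed by exhaustive enumeration of all
C(n, n_plus) splits when the pooled size is at most 16 (exact under the
permutation null, tie-safe), and by the asymptotic one-sided bound
exp(−2D²·mn/(m+n)) above (the switchover is configurable). q-values are
Benjamini–Hochberg within each (feature, direction) family — the default,
deterministic and safe at small target counts — with Storey's fixed-λ
(λ = 0.5) π̂₀ estimate and pooled-family correction available behind flags.
The significance flag defaults to q < 1e-4.

Reporting helpers: the minimum spanning forest of significant targets over
a protein-link graph (edge distance 1000 − score, Kruskal with edges
pre-sorted lexicographically so ties break deterministically), and ROC
curves of direction calls (match scores as confidences) against observed
signature modulation, with AUC by trapezoid rule.

## Synthetic data

The generators emulate exactly the statistical structure the estimators
assume — they are the test harness, not a model of any real assay:

* **Cohorts.** Shared H_true and B_true, independent latent features and
  Gaussian noise per cohort. Defaults: 978 genes, 16 disease factors,
  noise sd 1, signal scale 1. H_true is block-structured the way clustered
  risk annotations look: each latent axis loads positively on its own
  disjoint set of factors with one dominant anchor (strength 4, supporting
  loadings uniform in [0.8, 2]), and earlier axes have more supporting
  factors. Disjoint positive blocks make the axes orthogonal and their
  order and sign identifiable, so fitted and planted features can be
  compared one-to-one. Latent feature rows are centred and orthogonalized
  (norm √n), so the noiseless model is exactly identifiable.
* **Compendium.** Causal drugs respond as direction · effect_size ·
  unit(B_true column) · √p plus unit noise (per-gene signal amplitude ≈
  effect_size); inert drugs are pure noise; every causal or decoy target is
  linked to its drugs at score 950, so the link table itself carries no
  signal beyond the planted response. Defaults: 300 drugs, 3 cell lines,
  20 targets, 10 drugs per target, effect size 5 = 5 × noise sd, one
  suppressor target on feature 1. Optional Bernoulli(0.7) coverage
  exercises the sparse-entry averaging.
* **Survival.** Exponential event times with rate exp(xβ), independent
  exponential censoring tuned to the requested censoring fraction.
* **Protrusions.** Poisson(A_true) counts per image of Exp(k_true) lengths.

What the generator does **not** emulate: real L1000 noise spectra and
probe-level artifacts, realistic STITCH score distributions and target
promiscuity, batch/plate structure beyond a single vehicle offset, and
heavy-tailed expression noise (a t(df=3) option exists for robustness
checks). Passing tests demonstrate correctness of the estimators under the
assumed model, not performance on any particular public dataset.

## Morphology

The count of protrusions longer than d is fitted as A·e^{−k·d} on a
log-count scale by linear least squares — deterministic and
initialization-free, unlike a nonlinear fit on raw counts — over a grid of
50 thresholds from 0 to the 99th percentile length, using only bins with
at least 3 protrusions. Y_np = A/N_bp and Y_md = −1000·k follow exactly
from the fit; higher (less negative) Y_md means longer protrusions. Group
contrasts use a percentile bootstrap over images (default 1000 resamples,
seeded). Length units are pass-through metadata; the scores are
unit-dependent.

## Reproducibility and problem sizes

A pipeline run writes a manifest (config, seed, version, output SHA-256
checksums); re-running from the same config or manifest reproduces every
output byte for byte. The single global seed fans out to per-stage seeds
as BLAKE2b("seed:stage") mod 2³¹. Floats are written at 6 significant
digits with LF endings.

The test suite and the acceptance script use deliberately small problem
sizes chosen to exercise every code path at negligible cost: recovery
studies at 3 cohorts × 200 patients × 978 genes over 20 seeds; the
end-to-end planted-target study at the generator defaults over 20 seeds;
KS and BH exactness against enumeration oracles (all splits of pooled size
≤ 10; 1000 random p-vectors); permutation calibration on 100-drug null
compendia over 40 seeds; morphology recovery at 10⁵ sampled lengths.

## Known limitations

The exact similarity and consistency normalizations used by large public
analyses are not re-derivable from first principles; the calibrated clipped
cosine here satisfies the documented contract (bounded, 0 = no match,
1 = same-target level, function of the scalar product) but will not
reproduce third-party score values numerically. GCT support is dense 1.2/1.3
only (no GCTX/HDF5). Survival handling is right-censoring only. No
probe-to-gene collapsing, no normalization of raw counts, and no network
download of any external resource.
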