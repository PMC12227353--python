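# Methods

## The question the pipeline addresses

Correlating a regional brain measure across observations yields a
"connectivity-like" matrix: inter-individual correlations of gray-matter
volume (structural covariance), of FDG-PET uptake (metabolic connectivity),
or of resting-state summaries such as ReHo. What drives those correlations —
stable between-person traits, slow within-person aging, or session-to-session
state fluctuation — is ambiguous in a cross-sectional sample. Dense
longitudinal designs can separate the sources: within-subject across-session
correlations isolate within-person variability (aging + state), age-binned
across-subject correlations isolate trait variability, and a cubic age fit
splits within-person series into a smooth age component and residuals.

`connocorr` implements that analysis as a reusable pipeline and pairs it with
a generative model in which the three sources are explicit and separable, so
every stage has a parameter-recovery test without requiring any imaging
download.

## Generative model

For subject *s*, session *t* at age *a*, ROI *i*:

```
y_sti = c_si(a_st) + trait_si + state_sti + eps_sti
```

* **Age component** `c_si(a)`: a cubic polynomial. A shared mean coefficient
  vector (optional, default zero) plus subject-level perturbations of the
  linear/quadratic/cubic coefficients, drawn jointly across ROIs from the age
  source's correlation target. Coefficients act on the design-scaled age
  `u = (a − mid)/half ∈ ~[−1, 1]`; per-power standard deviations are weighted
  (0.5, 0.3, 0.2) and divided by Var(u^k) for u ~ U(−1, 1), so the
  component's expected across-session variance equals the source's
  `variance_scale`. Units: measure units; `variance_scale` is in measure
  units squared.
* **Trait** `trait_si`: drawn once per subject from the trait target; exactly
  constant across sessions (it cancels from all within-subject correlations).
* **State** `state_sti`: drawn independently per session from the state
  target — the "sustained activity" fluctuation that also underlies
  functional connectivity, which is why the pipeline's FC simulations share
  the state target by default.
* **Noise**: i.i.d. Gaussian, `noise_sd` in measure units.

Sampling design: first-session age uniform over the design range;
inter-session gaps uniform within ±20% of `follow_up/(n_sessions − 1)`
(published session schedules give ranges, not spacings). Randomness is
hierarchical (`numpy` `SeedSequence.spawn`): one root seed, one independent
stream per subject, so enlarging a cohort never perturbs existing subjects,
and identical inputs reproduce tables bit for bit.

Default study structures: a "single dense subject" (1 subject, 70 sessions,
first age ~30, 16-year follow-up) and an "aging cohort" (70 subjects, 5–9
sessions each, first ages 62–86, ~8-year follow-up; the inter-individual
analysis bins integer ages 70–89 and requires ≥ 10 subjects per bin).

### Correlation targets: block vs graded

Two target families are provided:

* **Block targets** (`CovSpec` + `make_network_covariance`): one value for
  same-network pairs, one for homotopic left/right pairs, one for everything
  else, on a 114-ROI atlas (2 × 50 cortical regions in seven mirror-ordered
  networks + 14 bilateral subcortical structures). Indefinite constructions
  are repaired by clipping negative eigenvalues at zero and re-normalizing
  the diagonal, so requested entries may shrink slightly; an unrepairable
  spec fails loudly with the offending eigenvalue.
* **Graded targets** (`random_factor_correlation` + `ExplicitCov`): a random
  k-factor correlation matrix whose entries are continuously distributed.

The distinction matters for validation design. With a block target, ~88% of
ROI pairs share the single between-network value; any estimation noise then
randomizes the ranks inside that tied block, and the Spearman correlation
between even an excellent estimate and the target is capped near 0.55. Block
targets are therefore used for Frobenius-norm convergence tests, and graded
targets for every rank-agreement (Spearman) recovery test. Empirical
connectivity matrices are themselves continuously graded, so the graded
family is also the more realistic emulation.

### Modality presets

Declared defaults expressing the qualitative contrast the pipeline exposes,
not estimates of real variance shares (no published decomposition of age vs
state vs trait magnitudes exists for these measures):

| preset        | age var | trait var | state var | noise sd |
|---------------|--------:|----------:|----------:|---------:|
| `volume-like` |     1.0 |      0.08 |      0.08 |     0.05 |
| `reho-like`   |    0.08 |      0.08 |      1.0  |     0.1  |
| `pet-like`    |     0.1 |      0.5  |      0.6  |     0.1  |

Volume-like data are dominated by slow, coupled age trajectories; ReHo-like
and PET-like data by state fluctuation, with PET carrying a larger trait
share. The dominated sources sit at ≤ 10% of the dominant variance.

### What the generator does not emulate

Scanner/site effects (the main suspected source of residual structural
correlations in multi-site data), head motion, hemodynamics, spatial
autocorrelation beyond the voxel fixture's smoothed noise, realistic
anatomy, and non-Gaussian tails. Passing recovery tests therefore shows the
*estimators* are correct, not that real data meet the model's assumptions —
in particular, near-zero raw-vs-residual similarity for noise-only residuals
is expected here even though scanner variability makes that similarity high
in real structural data.

## Regional measures

* **ROI means**: plain voxel averages within integer-labelled atlas regions;
  an ROI absent from a volume is NaN (flagged), never silently zero.
* **ReHo**: Kendall's coefficient of concordance of each voxel's series with
  its 7/19/27-neighborhood (default 27, exposed as a flag since the original
  toolbox setting is not documented),
  `W = 12 Σ_t (R_t − R̄)² / (K²(n³ − n) − K ΣT)` with mid-rank ties and the
  standard tie correction ΣT. At mask edges the neighborhood shrinks to the
  available in-mask voxels (per-voxel K returned); an all-constant
  neighborhood is flagged NaN rather than propagated. Inputs are assumed
  already smoothed if smoothing is wanted; an optional flag divides the map
  by its in-mask mean before ROI averaging (off by default — whether the
  original analysis standardized ReHo maps is unstated).
* **Confound regression**: ordinary least-squares residualization against a
  t × q design (Friston-24 motion expansion — parameters, one-lag copies,
  and both squared — plus the first five principal components of
  white-matter/CSF signals and an intercept, q = 30 when full). Collinear
  columns are pruned by pivoted QR and logged. Residuals are orthogonal to
  every retained column and the operation is idempotent.
* **Global scaling**: division by the mean within an intracranial mask
  (PET-style intensity normalization); scale-invariant by construction.

## Correlation matrices

Pearson correlations throughout, matching the convention of the analyses
being reproduced:

* **within-subject**: across one subject's sessions (≥ 3 required);
* **intra-individual**: unweighted element-wise mean of within-subject
  matrices over subjects with ≥ 5 sessions;
* **inter-individual**: sessions binned to floor(age); within a bin each
  subject contributes the mean of its same-bin sessions; Pearson across
  subjects per bin with ≥ 10 subjects; qualifying bins averaged. Session age
  (not baseline age) defines the bin. The per-bin census is included in any
  failure message and in provenance;
* **time-series FC**: per-session Pearson over timepoints, averaged across
  sessions.

Averaging is the plain mean of r; a Fisher-z averaging mode exists but is
off by default to match the source convention. Zero-variance ROIs are
flagged as NaN rows/columns and excluded pairwise from averages. Tables
canonicalize row order at construction, making every matrix bitwise
invariant under input row permutations.

## Cubic age decomposition

Per ROI and subject, OLS on a cubic polynomial of age, fit on a centered and
standardized age basis for conditioning (a raw cubic over a multi-decade age
range is severely ill-conditioned; the design's condition number is checked
and reported on failure) with coefficients mapped back to the raw-age basis.
Requirements: ≥ 5 sessions, ≥ 4 distinct ages. Fitted + residual equals the
input exactly; residuals below solver precision (relative 1e-10) are snapped
to exact zero so that noise-free data yield flagged, not spurious, residual
correlations. Fits are per-ROI independent and unweighted. Series are fit on
raw values (z-scoring in the source figures is presentational only).

## Matrix similarity

* **Vectorization**: strict upper triangle, row-major
  (`numpy.triu_indices(n, 1)` order), n(n−1)/2 values — 6,441 at 114 ROIs.
* **Spearman ρ** with mid-rank ties; p from the large-n t approximation.
  With thousands of ROI pairs, tiny ρ are "significant"; the ρ values are
  the informative output.
* **Williams' test** for two dependent correlations sharing one variable:
  `t = (r_jk − r_jh) √[(n−1)(1+r_kh) / (2·((n−1)/(n−3))·|R| + r̄²(1−r_kh)³)]`
  with `|R| = 1 − r_jk² − r_jh² − r_kh² + 2 r_jk r_jh r_kh`, df = n − 3,
  two-tailed p, direction reported alongside. Applied to matrix comparisons
  with n = number of ROI pairs, mirroring the source usage; the entries of a
  correlation matrix are not independent observations, so these p-values are
  anti-conservative — a label-permutation alternative
  (`williams_permutation`) is provided as the stricter check. Literature
  variants of the statistic differ slightly across citations; the variant
  above is fixed and unit-tested against its own closed form.
* **PCA**: each matrix's upper-triangle vector standardized (sample sd,
  n − 1), SVD of the stacked pairs × matrices array; variance fractions from
  squared singular values; component sign fixed so each component's mean
  loading is non-negative; score vectors reshaped to symmetric ROI × ROI
  matrices (zero diagonal — scores are not correlations).

## Pipeline and problem sizes

`run_simon_like` / `run_adni_like` / `run_combined` orchestrate the
experiments into deterministic artifact directories (TSV matrices with JSON
provenance sidecars, a similarity report, a manifest of content hashes; the
configuration hash excludes the output path so identical analyses hash
identically anywhere). All randomness descends from the single config seed.

Default problem sizes mirror the study structures (70 sessions; 70 subjects
× 5–9 sessions; 58 and 17 FC sessions). The test suite and the acceptance
script run these at full 114-ROI scale — the estimators are cheap — with FC
sessions of 200 timepoints; Monte-Carlo convergence checks use reduced
atlases (4–10 ROIs) where tight Frobenius bounds are attainable, and voxel
fixtures use 4³–12³ grids. These sizes are the package's validation design
choices.

## Known limitations

* The single-subject age component spans a rank-3 smooth function space, so
  its correlation matrix cannot converge to an arbitrary target; recovery is
  assessed against the realized latent age series (which
  `simulate_measures(..., return_components=True)` returns), and the
  dominated-source orderings are the meaningful single-subject claims.
* Williams' test on matrix entries inherits the non-independence caveat
  above; no spatial-autocorrelation-preserving (spin-test) null is
  implemented.
* No model selection over polynomial order, no splines/GAMs, no site-effect
  regression.
* The ADNI-style experiment applies no age decomposition (the decomposition
  operation accepts any single-subject table, but 5–9 sessions leave a cubic
  fit with 1–5 residual degrees of freedom).
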