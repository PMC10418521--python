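# Methods

## Generative model

A cohort of N subjects with m scans each is simulated directly at the
level of per-scan target correlation matrices. All components add in
Fisher-z (arctanh) space, which keeps the back-transformed correlations
in (−1, 1) by construction:

```
Z_is = Z_base + α·F_i + β·y_i·W + σ·E_is        (subject i, scan s)
```

- **Backbone** `Z_base`: hollow symmetric matrix with upper-triangle
  entries drawn once per cohort from N(0.25, 0.15²) in z-units,
  emulating the positive-mean edge distribution of resting-state FC.
  It is common to every scan, so it affects raw similarity values but no
  ranking or prediction after standardization.
- **Fingerprint** `F_i = Σ_k u_k u_kᵀ − diag`, with each `u_k` an
  i.i.d. normal vector scaled to unit ℓ2 norm, so each rank-1 term has
  unit Frobenius norm and a rank-k fingerprint has norm ≈ √k. The
  per-term normalization makes α comparable across ROI counts. `F_i` is
  redrawn per subject and fixed across that subject's scans — it is
  exactly what makes scans identifiable.
- **Phenotype loading** `W`: the same construction with rank 1, drawn
  once per cohort. The continuous phenotype is `y_i ~ N(0,1)`; the
  binary label thresholds it at zero so one generative path serves both
  regression and classification.
- **Session noise** `E_is`: hollow symmetric with i.i.d. normal upper
  triangle, normalized to unit Frobenius norm, redrawn per scan. The
  normalization puts σ on the same scale as α and β: the three
  parameters are directly the Fisher-z magnitudes of their components,
  and e.g. α/σ is the fingerprint-to-noise ratio. (An unnormalized
  per-edge noise convention would make σ's meaning depend on the ROI
  count and, at the default settings, bury the fingerprint entirely.)

After `tanh`, the matrix is projected to the nearest valid correlation
matrix: symmetrize, eigen-decompose, clip eigenvalues at 1e−8,
reconstruct, renormalize to unit diagonal. At the default scales the
projection is a near-no-op; it exists so extreme parameter choices fail
softly into valid correlation matrices (or raise if the diagonal
degenerates).

Two output paths share one draw of targets: `generate_fc_cohort`
vectorizes the target matrices directly (no FC estimation noise — the
"infinite-T" limit), while `generate_cohort` samples T timepoints from
a zero-mean multivariate normal with the target as covariance, giving
realistic correlation-estimation noise of order 1/√T per edge.
Randomness is split into substreams (structure / cohort / timeseries)
from the config seed, so the two paths agree on targets and a
`structure_seed` can be shared between cohorts that must have the same
backbone and phenotype pattern (the cross-cohort experiment) while their
subjects differ.

### Defaults and what they represent

50 subjects × 2 scans, P = 30 ROIs, T = 200 TRs at TR = 2 s, α = 1.0,
β = 0.5, σ = 0.5, fingerprint rank 3. These are desk-scale study
conditions: strong but not degenerate identifiability (fast-path
identification is at ceiling; through the T = 200 estimation noise it
drops to roughly 0.2–0.3 against a 0.01 chance level), a phenotype
signal a linear model can partly recover (legitimate accuracy ≈ 0.8),
and headroom for the double-dip arm to inflate toward 1.0. Real
cohorts' fingerprint-to-noise ratios are not published quantities; the
defaults are chosen to bracket the qualitative regime, not to match any
dataset.

### What the generator does not emulate

Hemodynamics, scanner drift, motion, physiological artifacts, spatial
ROI geometry, site effects, family structure, non-Gaussian phenotypes,
and nonstationarity within a scan (windows differ only by sampling
noise). Consequently, passing tests show that the *pipeline* measures
fingerprint-driven leakage correctly under a stationary Gaussian model;
they do not certify effect sizes on real data.

## Connectivity

Bandpass: order-4 Butterworth, 0.01–0.15 Hz, applied forward-backward
(`sosfiltfilt`, zero phase) to each ROI column of the full series;
series must exceed the filter's padding length (27 samples). Filtering
precedes any windowing — estimating a bandpass on 50-TR windows
independently is numerically fragile. FC is the Pearson correlation
matrix vectorized over the strict upper triangle in row-major
(`numpy.triu_indices`) order; this single convention is shared by every
module. dFC uses non-overlapping windows anchored at TR 0, discarding a
trailing partial window. Zero-variance columns and windows raise rather
than propagate NaNs.

## Fingerprinting

Identification is per-query nearest-neighbor matching: a query vector
succeeds iff its best same-subject cosine similarity strictly exceeds
its best other-subject similarity; exact ties fail, making the statistic
deterministic. Window-level vectors of one subject count as same-subject
matches — that is precisely the mechanism the window exploit leverages.
The analytic chance level for structureless vectors is
(m−1)/(N·m−1). Euclidean distance is available as an alternative
metric, stored negated so "higher = more similar" holds uniformly; on
unit-normalized vectors its ranking coincides with cosine.

## Experiments

- **Splits.** Subject-disjoint: random 80/20 partition of subjects, all
  units of a subject on one side. Scan double-dip: first scan
  (lexicographic) to train, second to test, extras to train —
  deterministic, maximizing the per-subject train/test pairing. Window
  double-dip: even window indices train, odd test. Random scan split:
  unit-level 80/20, landing between the extremes.
- **Models.** Logistic regression (accuracy) and ridge (RMSE) from
  scikit-learn; features standardized with train statistics only, with
  the scaler inside the CV pipeline so inner folds are clean too.
  Regularization from the grid 10⁻⁴…10⁴ by inner 5-fold CV on the
  training set (folds shrink automatically only when a class has fewer
  than 5 training samples, which occurs only in deliberately tiny test
  cohorts).
- **Aggregation.** "Bootstrap" means Monte-Carlo re-splitting: 20
  independent re-splits with seeds base+iteration; deterministic split
  makers vary only the inner-CV shuffle. Means and SDs are over
  iterations.
- **Inflation.** Classification: double-dip minus legitimate mean
  accuracy, in percentage points. Regression: RMSE reduction relative
  to the null-model RMSE, `100·(legit − dd)/null` — the convention that
  reproduces published improvement percentages from their printed RMSEs;
  reporting relative to the null scale keeps the number comparable
  across phenotypes with different units.
- **Cross-cohort mitigation.** Train on all of cohort A, test on all of
  cohort B, with shared backbone and phenotype pattern but disjoint
  subjects. Fingerprints cannot transfer, so accuracy should match the
  within-cohort subject-disjoint level — and does, within iteration
  noise.

## Numerical and design notes

- Problem sizes in the test and acceptance runs (50×2 cohorts at P=30;
  window experiments at 10 iterations; chance-level checks over 50
  seeds) were chosen as the smallest cohorts at which the statistical
  assertions have comfortable margins; everything scales up by config.
- Scan-level leakage experiments run on the fast FC path (exact
  targets); the window exploit necessarily runs through timeseries, and
  does so without bandpass filtering, since the simulated signal is
  spectrally flat and filtering would only discard degrees of freedom
  from 50-TR correlation estimates. The filter has its own
  frequency-response oracle tests.
- Ties in identification fail; argmax-based alternatives would be
  order-dependent.
- The binary task's classes are as balanced as N(0,1) thresholding
  makes them; the null model reports the realized majority frequency
  rather than assuming 0.5.
- Determinism: identical configs give bit-identical cohorts, FC tables
  and reports (same-architecture NumPy/BLAS); all artifacts carry the
  config hash.

## Limitations

Linear models only; no overlapping/tapered windows or partial
correlations; no similarity-enhancing preprocessing of FC residuals
(which would raise identifiability further and likely widen the leakage
gap); effect sizes are functions of the synthetic α/β/σ regime and
should be read qualitatively, not as predictions for any real cohort.
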