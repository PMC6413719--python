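# Methods

## Study design model

The design is a categorical grid of (block, absolute time) cells on a 24-h
clock anchored at dusk (the moment the temperature shift is applied).  The
default layout is:

- `control20`: the last warm day, 8 harvests at 3-h spacing (hours 0–21);
- `cold_day1`: the first cold day, harvested from its dusk through the
  following dusk inclusive, 9 harvests (hours 24–48);
- `cold_day4`: the fourth cold day, likewise 9 harvests (hours 96–120);

giving 26 time-points, and with 3 replicate batches, 78 samples.  Each cold
time-point is contrasted against the warm time-point at the same time of
day (24-h wrap allowed), so both dusk harvests of a cold day map to the
single warm dusk; this yields 18 contrast groups.  "Consecutive" contrasts
are adjacent sampling times within one cold day: runs never span the
day-1/day-4 boundary, which is three days wide in real time.  Within each
cold block two of the nine sampled cells share a time of day (the two
dusks), so cells are keyed by absolute time, not clock time.

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with known truth:

- **Baseline**: gene expectation `baseline_tpm · (1 + A·cos(2π(t_day − φ)/24))`
  with amplitude `A ∈ [0, 1)` and phase `φ` in hours.  Cohort baselines are
  log-normal (median 30 TPM, log-SD 0.8), amplitudes uniform on [0, 0.4],
  phases uniform on the clock.
- **Cold archetypes** modify the expectation after the switch. Sustained
  (`de_up`/`de_down`/`adaptive`) scale by `2^(log2FC·w(t))`; `transient`
  applies the effect only in the first cold day; `late` only in the
  acclimated day; `rhythm_damped`/`rhythm_gained` scale the amplitude in
  cold (×0.25 / ×3 capped at 0.9); `phase_shift` advances the phase 6 h.
  The onset ramp `w(t)` is logistic with half-time `onset_h` (default 3 h,
  slope scale `onset_h/4`), reaching ~1 within two half-times — the
  simulated responses are therefore fully developed by 6 h of cold.
- **Isoform switches** (`das_switch`): the gene total is left untouched
  while usage flows between the first two isoforms, `f₁ = f₁⁰ − δ·w(t)`,
  `f₂ = f₂⁰ + δ·w(t)` (`δ = das_delta_ps`, default 0.3).  Base fractions
  `(0.5 + δ/2, 0.5 − δ/2)` make the isoform ranking reverse exactly at the
  onset half-time, giving a well-defined true switch time for recovery
  tests.  This is the "DAS-only" category: splicing regulation with no
  gene-level expression change.
- **Noise**: expected TPM is converted to expected reads through effective
  lengths (length − 200, floored at 1), scaled to a per-sample library size
  (uniform 0.8–1.2 M reads), multiplied by a per-(gene, batch) effect
  (log₂-normal, SD 0.1), and counts are drawn gamma–Poisson with dispersion
  φ in Var = μ + φμ² (default 0.05).  φ = 0 selects the exact noise-free
  limit (counts = rounded expectations) used by deterministic tests.  TPM
  is recomputed from the drawn counts so the two columns of each quant
  table are mutually consistent, as a real quantifier's output would be.

What the generator does **not** emulate: positional/sequence biases,
mapping ambiguity between isoforms (counts are drawn independently per
transcript), correlated gene networks, varying per-gene dispersions, and
partial cells or missing samples.  Passing recovery tests therefore
demonstrate the correctness and calibration of the decision rules under
the design's statistical model, not robustness to quantification artifacts.

## Analysis pipeline

- **Counts**: scaled-TPM counts, kept as non-negative reals (rounding is a
  lossy choice nothing downstream needs).
- **Filtering**: CPM ≥ 1 in ≥ 3 samples, computed with unit normalization
  factors, since filtering precedes factor estimation in the workflow
  order.  Filtering is idempotent.
- **TMM**: reference sample = upper-quartile closest to the mean upper
  quartile; 30 % two-sided trim on M, 5 % on A; weights are inverse
  asymptotic variances of M; zero counts excluded pairwise; factors
  rescaled to geometric mean 1.  The implementation agrees with the
  reference R implementation to ≤ 1e-6 (tested).
- **Batch factors**: an unweighted first-pass fit of log₂-CPM on the
  design, SVD of the residuals, top-k right singular vectors as sample
  covariates.  Default k = 1: three replicate batches suggest one dominant
  nuisance direction; k is configurable.  Weights are not yet defined at
  this stage, hence the unweighted first pass.
- **Voom weights**: log₂-CPM with prior count 0.5 over effective library
  size + 1; sqrt residual SD is smoothed against mean log-count by lowess
  (span 0.5, 3 robustness iterations) and evaluated at each observation's
  fitted log-count; weights are the fourth-power inverse.  At least 10
  features are required to fit a trend.
- **Model**: cell-means coding (one indicator per time-point cell) plus
  batch columns; time is categorical because the contrasts are defined
  between matched cells, not on a periodic basis.  Per-feature WLS with
  residual df n − p.
- **Moderation**: moment estimation of the inverse-chi-square prior on log
  sample variances (trigamma inversion by Newton iteration); posterior
  variance `(d₀s₀² + df·s²)/(d₀ + df)`; moderated t with df d₀ + df.
  Degenerate inputs: identical variances give d₀ = ∞ (all posteriors equal
  the bias-corrected prior); d₀ = 0 leaves sample variances untouched.
- **Contrasts**: log₂FC = treatment-cell coefficient − matched control-cell
  coefficient; BH adjustment within each contrast across features (the
  family the thresholds are stated per contrast group).
- **Divergence**: gene log₂FC = inverse-variance weighted mean of member
  transcript log₂FCs (keeping transcript and gene estimates on a single
  weighting scheme; separate gene-level fits are still used for DE calls).
  Var(divergence) = Var(transcript) − 1/ΣW under independence.  A per-gene
  F statistic (Σwᵢdᵢ²/(k−1)) is also reported.  Single-transcript genes
  are excluded — they cannot be DAS.  Shared within-gene components (e.g.
  batch wiggle common to isoforms) cancel in the divergence but not in its
  variance estimate, so the test is mildly conservative, never
  anticonservative (verified on null simulations).
- **PS**: computed from replicate-mean TPM per cell (abundance scale, the
  simplest auditable choice — not from fitted values); NaN where the gene
  mean is zero.  ΔPS is two-sided (|ΔPS|): both isoform gains and losses
  count.
- **Decision rules**: DE = ≥ 2 consecutive contrasts with adjusted
  p < 0.01 and |log₂FC| ≥ 1 each; DAS = some transcript with adjusted
  divergence p < 0.01 and |ΔPS| ≥ 0.1 in ≥ 2 consecutive contrasts.  All
  four thresholds are configurable; these defaults define the categories
  DE-only / DE+DAS / DAS-only / not-regulated, which partition the
  expressed genes.  The transcript-level DE rule is identical to the
  gene-level rule applied to transcript statistics.

## Isoform switches

Candidates are strict sign changes of the replicate-mean difference of an
isoform pair between adjacent time-points (exact ties are treated as no
crossing, avoiding zero-width events).  The switch time is the linear
interpolation of the zero crossing.  The score is the mean of the fraction
of individual samples where the pre-switch isoform dominates before and
the post-switch isoform dominates after; flanking intervals run to the
previous/next crossing or the series ends, need ≥ 2 time-points each, and
are tested with Welch t-tests on per-time-point means.  Defaults
(score ≥ 0.5, both p ≤ 0.05) are configurable; only pairwise events are
reported.  `filter_rapid` keeps events within a window (default 3 h, one
sampling interval) after the cold transition.

## Numerical choices and degenerate inputs

- Zero-residual features get σ = 0 and are carried through moderation
  (their posterior variance is pulled to the prior).
- All-zero TPM columns produce a warning and zero counts.
- The lowess trend is floored at 1e-6 to keep weights finite.
- Contrast standard errors of exactly 0 yield t = 0 (not ±∞).
- Derived sub-seeds are drawn below 2³¹ from a single generator, so every
  run is reproducible from one integer seed.

## Problem sizes

The test suite and the acceptance script run the full chain on cohorts of
200–500 genes under the default 78-sample design: large enough for stable
trend estimation, moderation and calibration checks (≈ 1250 transcripts
pass filtering at 500 genes), small enough that a complete analysis takes
about a second.  Null calibration uses five independent cohorts of 500
null genes; recovery uses three cohorts of 200 genes with 20 sustained-up,
10 transient and 10 isoform-switch genes against 160 nulls.

## Known limitations

- Calibration of the divergence test is slightly conservative in the
  presence of shared within-gene variance components (see above).
- The moment estimator of the prior df is noisy below a few hundred
  features; the pipeline is intended for cohorts of ≥ ~100 genes.
- PS from replicate-mean TPM is undefined for genes expressed in only some
  cells; such cells are NaN and never satisfy the |ΔPS| gate.
- The switch detector assumes profiles are comparable across the day-1 /
  day-4 gap; a crossing interpolated inside that 48-h unsampled span is
  reported at the interpolated time but is not biologically localizable.
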