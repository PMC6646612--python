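# Methods

This note documents the models behind `enisim`, the defaults and why they
were chosen, and what the simulation can and cannot say about real
electrode-neuron interfaces.

## Generative model of a virtual ear

Each subject `s` has a duration of deafness `D_s ~ Uniform(3, 53)` years and
an electrode array drawn from the mix 5/11 lateral (1J), 2/11 helix, 4/11
mid-scala. Per electrode site `e` (1 = apical, 16 = basal):

* **Neural status.** Two latent fractions decline logistically with
  duration: peripheral-process survival
  `p_se = clamp01(logistic(2.0 − 0.08·D_s) + η_se)` and spiral-ganglion
  density with the same form. Site noise `η` (SD 0.15) is smoothed by a
  3-point moving average so that neighbouring electrodes face correlated
  neural tissue; the window is configurable. The two fractions are separate
  because peripheral-process integrity is the quantity the polarity effect
  is thought to index, while overall ganglion density shifts absolute
  thresholds — keeping them distinct lets tests vary them independently.
* **Geometry.** EMD is Gaussian around 1.5 mm (lateral arrays) or 0.9 mm
  (pre-curved), SD 0.25–0.3 mm, smoothed along the array and clipped to
  [0.1, 2.2] mm. Scalar location is iid categorical with marginals
  0.59 ST / 0.36 intermediate / 0.05 SV. Optionally
  (`extracochlear_prob`) the two most basal contacts sit outside the
  cochlea: they then have no geometry estimate and no auditory percept.
* **Resistances.** A ladder network with log-normal parameters: medians
  300 Ω (transversal) and 120 Ω (longitudinal), site log-SD 0.4, and a
  subject-level log-SD 0.5 shared by both parameter sets (subjects differ
  in overall cochlear impedance far more than sites within a subject).
  An electrode's "local" longitudinal resistance is the geometric mean of
  its adjacent ladder segments.
* **Thresholds (dB re 1 μA).** The polarity effect is
  `PE = −0.5 + 4.0·(1 − p_se) + ε(0.8)`; the monopolar base is
  `M = 38 + 8·(1 − sgn) + 2·EMD + u_s(3) + ε(1)`, with
  `T_ACA = M + PE/2`, `T_CAC = M − PE/2` (so ACA − CAC reproduces PE
  bit-exactly). Focused thresholds on channels 2–15 follow
  `T_sQP = 38 + 5.46·EMD − 1.18·[intermediate] + 3.52·[SV]
  − 2.42·(log10 R_local − cohort median) + 0.73·PE + u′_s(4) + ε(2.5)`.
  The four slope magnitudes on the sQP line are the study-condition
  anchors; the subject SD of 4 dB against a residual SD of 2.5 dB makes the
  conditional variance explained far exceed the marginal share, as intended
  for clustered threshold data. All other magnitudes (intercepts, noise
  SDs, subject SDs, the dynamic-range distribution Normal(12, 2) dB with a
  6 dB floor) are package defaults selected once to give realistic dB and
  Ohm scales — per-subject sQP means in the mid-40s dB, polarity effects of
  a few dB, resistances spanning roughly 50–2000 Ω — not empirical claims.

By construction the site-level regressors (EMD, scalar location,
resistance) are generated independently of `p_se`, so the polarity effect
is statistically unrelated to electrode position and impedance while
focused thresholds load on all three influences. Mild between-subject
associations remain (array type and duration shift subject means), which is
why independence checks are performed within subject.

## Simulated listener and threshold procedures

A trial is an atomic yes/no detection with probability
`γ + (1 − γ − λ)·Φ((L − T)/s)`; slope `s = 0` yields a deterministic step
observer (ties detect) that makes the procedure oracles unambiguous.
Response timing, inter-stimulus delays and loudness growth are not
modelled; the most-comfortable level is `threshold + dynamic range` and
caps every presented level.

The staircase starts at 90 % of MCL **on the dB scale** (the procedure's
step sizes are dB, so the fraction is interpreted there; a linear-μA
reading would only shift the starting point). Steps are 0.5 dB until the
first reversal, then 0.2 dB; the track ends after eight reversals and
returns the mean of the last six. Two runs are averaged, or four when the
first two differ by ≥ 1 dB. A listener who never detects near MCL (e.g. an
extracochlear site) yields a flagged missing estimate rather than a number.

The sweep presents sQP stimuli with σ = 0.9 while α advances 0→1 in 0.1
steps, two presentations per α, the level moving ±1 dB per presentation
(down after a press). Channel `c` uses active electrodes `(c−1, c)` with
fractions `(1−α, α)` and returns `(c−2, c+1)` at `−σ/2` each; channel 2
reuses the channel-3 electrode set with α forced to 0. Runs start 6 dB
below the local MCL; two forward and two reverse runs are collected. Each
press/release transition contributes a local threshold sample (mean of the
two straddling levels at their mean array position); integer-channel
thresholds are triangular-weighted averages (weight `1 − |position − c|`)
of these samples, averaged over runs. The exact reconstruction kernel used
with this sweep in practice is not standardized, so the kernel is isolated
behind one function and its half-width is the natural swap point. A
consequence worth remembering: the kernel smooths along the array, so on
deliberately jagged threshold profiles (the default cohort) sweep estimates
are regression-diluted relative to the latent per-channel truth; accuracy
statements (≤ 1 dB) apply to smooth or flat profiles.

The listener's true threshold for a steered stimulus is linearly
interpolated between integer-channel values at position `(c−1) + α`.

## EFI forward model and inversion

Node `i` couples to ground through `r_trans[i]` and to neighbours through
`r_long`. Injecting unit current at node `j` and solving the nodal system
gives column `j` of the model matrix; reciprocity (symmetry) and monotone
column decay are structural properties and are property-tested. Inversion
minimizes `Σ w(i,j)·(z_model − z)²` with `w = exp(−|i−j|/τ)`, τ = 3, over
log-resistances (positivity by construction), Levenberg–Marquardt from a
median-based initial guess, tolerances 1e-14, max 500 iterations.

Whether the matrix diagonal belongs in the objective is genuinely open:
real diagonals include electrode-contact polarization that a resistive
ladder cannot represent. The package default **includes** the diagonal
because excluding it leaves one exactly flat direction in the objective at
each end of the array (verified by the Jacobian's two zero singular
values): the end triplet `r_trans[1], r_trans[2], r_long[1]` (and its basal
mirror) is then only identified up to a one-parameter family. With the
diagonal included, a noiseless round trip recovers all 31 parameters to
machine precision. `include_diagonal=False` remains available for matrices
with substantial contact impedance; `r_total` is always the peak of the
reconstructed profile, never the raw diagonal.

## Statistics

* **rmcorr** is computed by within-subject centring, algebraically equal to
  the ANCOVA with subject as factor and a common slope:
  `r_rm = sign(b)·sqrt(SS_x/(SS_x + SS_err))` on `N − k − 1` df, p from the
  covariate F test, confidence interval by Fisher z on the error df. With a
  single subject it degenerates to the ordinary Pearson correlation.
* **Mixed models** are random-intercept only (no random slopes, matching
  the design). The likelihood is profiled over `ψ = σ²_u/σ²_e` using the
  closed-form blockwise inverse, optimized on log ψ by bounded scalar
  search (xatol 1e-13) with an explicit boundary check at ψ = 0; boundary
  fits are flagged, not raised. Per-term F statistics use a
  Satterthwaite-type denominator df: numerical gradients of the contrast
  variance with respect to `(σ²_u, σ²_e)` against the inverse numeric
  Hessian of the REML log-likelihood, pooled over eigen-contrasts for
  multi-df terms; when the fit is at the boundary the residual df is used.
  The df values are reported for orientation only — no test in this package
  keys on them.
* **AICc** `= −2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` counting fixed effects
  plus both variance components. Cross-model comparisons in the nested
  sequence (empty → +EMD → +scalar location → +log10 R_long → +PE) use
  **ML** likelihoods, because candidate models differ in fixed effects and
  REML likelihoods are not comparable across mean structures; the selected
  model is refit by REML for coefficient reporting, and both likelihoods
  are retained on every fit. Scalar location enters as a three-level
  factor with ST as reference. All models in a sequence share the same
  complete-case rows (dropped-row counts are reported).
* **Pseudo-R²** follows the fixed/random variance decomposition:
  `marginal = var(Xβ)/(var(Xβ)+σ²_u+σ²_e)`, conditional adds `σ²_u` to the
  numerator.
* **Per-subject correlations** use Pearson for threshold–EMD and
  threshold–PE and Spearman for threshold–R_long (resistances are skewed;
  R_long is log-transformed before entering any linear model for the same
  reason). Subjects are split at a strict `r > 0.70` threshold–EMD cutoff,
  and the PE–threshold rmcorr is computed within each group. The duration
  regression is OLS of subject-mean PE (all channels with a valid PE; a
  flag restricts to channels 2–15) on duration, with R², adjusted R², and
  F on (1, n−2) df.
* Missing data are handled complete-case per analysis, mirroring
  extracochlear and inaudible channels.

## Problem sizes and determinism

Replicate analyses use 50 default cohorts (11 × 16); the staircase bias
study uses 200 tracks; EFI property checks use 100 random networks. A
single global seed fans out to per-stage, per-subject `SeedSequence`
substreams, so any stage can be re-run without perturbing the others and
identical seeds give byte-identical outputs.

## What passing tests do and do not show

The generator reproduces the *statistical structure* assumed for the real
paradigm — not cochlear anatomy, current spread, or loudness psychophysics.
Passing recovery tests show the estimation pipeline is faithful: unbiased
staircases, identifiable ladder inversion, correct mixed-model arithmetic,
and detection of the generating pattern at realistic effect sizes. They do
not validate the biological hypothesis linking polarity sensitivity to
peripheral degeneration, and effect attenuation through the measurement
layer (sweep smoothing, staircase noise) means statistics computed on
measured tables are systematically weaker than on latent tables — a real
phenomenon the simulation makes visible rather than a defect.
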