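# enisim

Simulation and multilevel analysis of the **cochlear-implant
electrode-neuron interface (ENI)**.

Cochlear-implant outcomes depend on how well each electrode stimulates
nearby spiral ganglion neurons. Three per-electrode measurements probe this
interface:

* the **polarity effect** `PE = T_ACA − T_CAC` (dB), the difference between
  detection thresholds for cathodic-centred (ACA) and anodic-centred (CAC)
  triphasic pulses — large positive values are a putative marker of
  peripheral-process degeneration, because degenerated fibres are more
  sensitive to anodic current;
* **focused (steered-quadrupolar, sQP) thresholds**, measured with a highly
  focused four-electrode configuration (σ = 0.9) that is sensitive to local
  neural health, electrode position, and tissue impedance at once;
* **electrical field imaging (EFI)**, a stimulation-by-recording resistance
  matrix summarized by a lumped resistor ladder network (16 transversal,
  15 longitudinal resistances).

No per-electrode human dataset is publicly available for this paradigm, so
`enisim` provides the entire chain as a reproducible simulation study:

1. **`synthetic_cochlea`** — virtual implanted ears. Duration of deafness
   degrades two latent neural fractions through a logistic decline; array
   type sets electrode-to-modiolus distance (EMD); scalar location and
   ladder-network resistances are sampled per site. By construction the
   polarity effect depends *only* on peripheral survival, while sQP
   thresholds follow
   `T_sQP = q0 + 5.46·EMD − 1.18·[intermediate] + 3.52·[SV] − 2.42·(log10 R − median) + 0.73·PE + u_s + ε`.
2. **`psychophysics`** — the behavioural procedures: a one-up/one-down
   adaptive staircase (0.5 dB steps shrinking to 0.2 dB after the first
   reversal, eight reversals, threshold = mean of the last six, two runs
   with a four-run fallback) and a Bekesy-style continuous threshold sweep
   (1 dB steps, α steered 0→1 in 0.1 steps, two presentations per α, two
   forward + two reverse runs, triangular-weighted integer-channel
   reconstruction for channels 2–15).
3. **`efi`** — the ladder-network forward model (nodal solve) and its
   weighted least-squares inversion in log-resistance space, with the
   localized weighting `w = exp(−|i−j|/τ)`.
4. **`stats`** — repeated-measures correlations (ANCOVA common slope,
   `r_rm`, df = N − k − 1), random-intercept mixed models fit by REML/ML via
   a profiled likelihood over the variance ratio, AICc-ordered nested model
   building, marginal/conditional pseudo-R², per-subject Pearson/Spearman
   correlations with a 0.70 grouping cutoff, the duration-of-deafness
   regression, and Bonferroni/Tukey adjustments.
5. **`pipeline` / `enisim` CLI** — simulate → measure → efi → analyze with
   YAML config, seeded substreams, and a JSON manifest.

## Worked example

```bash
enisim --log-level warning report --seed 7 --outdir runs/demo --noise 0.02
cat runs/demo/analysis/report.txt
```

which prints (abridged):

```
Repeated-measures correlations (3 planned comparisons, Bonferroni adjusted alpha = 0.017):
  sqp_vs_emd: r_rm(142) = 0.453, p = 1.193e-08
  ...
AICc model sequence (ML likelihoods):
  empty: AICc = 714.26
  emd_mm: AICc = 680.01
  emd_mm + scalar_location: AICc = 653.14
  emd_mm + scalar_location + log_r_long: AICc = 655.29
  emd_mm + scalar_location + log_r_long + pe_db: AICc = 651.79 <- selected

Full model (REML): R2_marginal = 0.20, R2_conditional = 0.89
  emd_mm: F(1, 145.0) = 49.64, p = 6.892e-11
  pe_db: F(1, 144.3) = 5.58, p = 0.01948
Duration of deafness vs mean PE: R2 = 0.98, ..., slope = 0.069
```

Reading this: focused thresholds rise with electrode-to-modiolus distance
(r_rm = 0.45) and retain a significant polarity-effect contribution after
position and resistance are controlled (F test on `pe_db`), the
full model attains the lowest AICc, and subjects deaf for longer show larger
mean polarity effects. Measurement noise from the staircase/sweep layer and
the sweep's along-array smoothing attenuate site-level effects relative to
the latent tables (see `docs/methods.md`).

Library use mirrors the CLI:

```python
from enisim import CohortConfig, generate_cohort, cohort_to_table
from enisim import stats as st

table = cohort_to_table(generate_cohort(CohortConfig(seed=0)))
comparison = st.build_model_sequence(table)
print(comparison.as_frame())
```

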