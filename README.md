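# preyjnd

Avian-vision contrast modelling and predation/defence statistics for
weakly conspicuous, chemically defended prey.

Many chemically defended insects — pine sawfly larvae among them — are not
classically aposematic: their green-black-grey coloration looks cryptic to
humans, yet they live in conspicuous aggregations and deploy costly
defensive fluid. Asking whether such "weak warning signals" are visible to
the predators that matter, and whether conspicuousness predicts survival
or defence behaviour, takes three connected pieces of machinery:

1. **A receptor-noise-limited (RNL) vision model.** Reflectance spectra
   R(λ) are turned into cone quantum catches Q_i = ∫R·S_i·I dλ for a
   tetrachromatic viewer (default: a blue-tit-like eye under D65-like
   daylight), von Kries normalised, and compared between stimuli in
   just-noticeable differences: chromatic contrast ΔS from the four single
   cones with Weber fractions ω_i = 0.05·√(η_max/η_i), and luminance
   contrast ΔL = |ln(Q_D^a/Q_D^b)|/ω_D from the double cone. Values < 1
   JND are likely indistinguishable, 1–3 distinguishable only in optimal
   light, > 3 distinguishable.
2. **Survival models for a field predation experiment.** Five days of
   daily checks on painted (yellow vs green) solitary or grouped larvae:
   a first-attack filter (each branch contributes only its first predation
   event; replacement larvae excluded), Cox proportional hazards with
   Efron ties stratified by transect, and binomial mesh-bag (predator
   exclusion) comparisons.
3. **Behaviour–colour models.** Logistic regression of defensive display
   (U-posture) and fluid deployment on centred JND contrasts with a family
   random intercept fitted by adaptive Gauss–Hermite quadrature, and a
   gamma log-link model of fluid volume (zeros replaced by 0.001, length
   as allometry covariate).

A synthetic-data module generates all three kinds of input with known
ground truth — preset reflectance spectra, discrete-day proportional-
hazards predation records over the eight-cell field design, and
family-clustered behaviour records — so every stage is testable end to
end without external data. See `docs/methods.md` for models, assumptions
and numerical choices.

## Worked example

```python
import numpy as np
from preyjnd import bluetit_d65
from preyjnd.contrast_pipeline import build_contrast_table, paint_verification
from preyjnd.synthetic_data import gen_spectrum_set, ExperimentDesign, gen_predation
from preyjnd.survival import first_attack_filter, cox_fit

vs, illuminant = bluetit_d65()

# Is a yellow paint patch conspicuous against the larval dorsal surface?
yellow = gen_spectrum_set("yellow_paint", n=3, seed=2)
dorsal = gen_spectrum_set("larva_dorsal_green", n=3, seed=1)
r = paint_verification(yellow, dorsal, vs, illuminant)
print(f"yellow vs dorsal: dS={r.delta_s:.1f} JND ({r.class_s.value}), "
      f"dL={r.delta_l:.1f} JND")

# Contrasts of larval surfaces and defence fluid against mean needle background
table = build_contrast_table(
    {"dorsal": dorsal,
     "ventral": gen_spectrum_set("larva_ventral_pale", n=3, seed=3),
     "fluid": gen_spectrum_set("defense_fluid", n=1, noise_sd=0.0, seed=4)},
    gen_spectrum_set("needle_green", n=6, seed=5), vs, illuminant)
print(table[["stimulus_label", "reference_label", "delta_s", "delta_l"]]
      .round(1).to_string(index=False))

# Simulated field experiment -> first-attack filter -> Cox fit
records = gen_predation(ExperimentDesign(seed=7))
fit = cox_fit(first_attack_filter(records), covariates=["color", "group"])
print(fit.summary().round(3))
```

prints

```
yellow vs dorsal: dS=19.6 JND (distinguishable), dL=37.4 JND
stimulus_label reference_label  delta_s  delta_l
        dorsal    needles_mean      2.6      4.9
       ventral    needles_mean     17.6     23.4
         fluid    needles_mean      8.7     16.1
         fluid          dorsal      6.7     21.0
         fluid         ventral      8.9      7.3
              coefficient  hazard_ratio  std_error  z_value  p_value
color_yellow        0.602         1.825      0.270    2.232    0.026
group10            -0.357         0.700      0.331   -1.078    0.281
```

The yellow patch is far above the 3-JND discriminability threshold while
the larval dorsal surface sits near it against needles — the weak-signal
situation — and the pale ventral surface (revealed during the defensive
display) and the defence fluid are both clearly discriminable. In the
simulated field experiment the yellow-marked larvae carry an elevated
death hazard (the generator's truth is hazard ratio 1.64; this single
realisation estimates 1.8 ± 0.5), while grouping shows no reliable effect
at this sample size.

A thin CLI mirrors the library: `preyjnd simulate ...`,
`preyjnd contrast-table ...`, `preyjnd cox ...`, `preyjnd mesh ...`,
`preyjnd behavior ...` (see `--help`).

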