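# Methods

`preyjnd` models how an avian predator perceives the coloration of weakly
conspicuous, chemically defended prey, and provides the statistical stages
that connect perception to field survival and to individual defence
behaviour. This note records the models, their assumptions, the numerical
choices, and what the synthetic data generators do and do not emulate.

## Receptor-noise-limited discrimination

The perceptual core is the receptor-noise-limited (RNL) model of colour
discrimination for a tetrachromatic bird. For a surface with reflectance
R(λ) viewed under illuminant I(λ), receptor class *i* with spectral
sensitivity S_i(λ) captures the quantum catch

    Q_i = ∫ R(λ) S_i(λ) I(λ) dλ,

integrated by the trapezoidal rule on the canonical 1-nm grid, 300–750 nm
(451 points). Spectrophotometer exports at ~0.47 nm (three samples per
nanometre) are first decimated to one sample per integer-nm bin (the first
in ascending order) and/or linearly resampled onto the canonical grid.

Catches are von Kries normalised — divided channelwise by the catch of the
adapting field — which makes every contrast exactly invariant to the
illuminant's overall scale. The adapting field defaults to an ideal white
under the illuminant; adapting to the mean background reflectance is
available via configuration (`adapt="background"`), since both conventions
occur in practice.

Receptor signals are logarithmic (Fechner), f_i = ln Q_i, the standard
choice for reflective surfaces in bright light. Channel noise is a Weber
fraction scaled by relative cone abundance η_i:

    ω_i = ω_ref · sqrt(η_max / η_i),

anchored so the most abundant single cone has ω = ω_ref = 0.05. Chromatic
contrast between stimuli a and b uses Δf_i = ln(Q_i^a / Q_i^b); ΔS is the
noise-weighted distance of Δf after discarding the achromatic direction.
The implementation uses the published closed forms for 2, 3 and 4 receptor
classes; for other channel counts it evaluates the equivalent quadratic
form Δf'WΔf − (Δf'W1)²/(1'W1) with W = diag(1/ω²), which the test suite
also uses as an independent oracle against the closed forms. Achromatic
(luminance) contrast uses the double cone alone: ΔL = |Δf_D| / ω_D with
ω_D = 0.05 by default.

Both contrasts are in just-noticeable differences (JND). Classification:
below 1 JND likely indistinguishable, 1–3 JND (boundaries inclusive)
distinguishable only under optimal light, above 3 JND likely
distinguishable.

### The packaged viewer is a synthetic stand-in

The default viewer (`bluetit_d65`) is built from the Govardovskii A1
visual-pigment template at nominal blue tit peaks (UVS 371, SWS 448,
MWS 503, LWS 563 nm; LWS-based double cone), multiplied by logistic
ocular-media and oil-droplet long-pass filters, with abundance ratios
UVS:SWS:MWS:LWS = 1 : 1.92 : 2.68 : 2.7 (LWS most abundant, so it anchors
the 0.05 Weber fraction). The illuminant is a 6504 K Planck curve
normalised to 100 at 560 nm. These are *not* measured whole-eye tables;
absolute JND values depend on them, which is why the viewer is plain CSV +
YAML configuration that users can replace wholesale (`load_viewer`).
Relative orderings and all engine-correctness properties are insensitive to
this choice.

### Pipeline conventions

Two aggregation conventions coexist deliberately. The background reference
is the *mean reflectance spectrum* of the needle replicates; paint
verification instead computes catch vectors per measured spectrum and
averages *catches* within each set before one JND comparison
(mean-of-catches). Since the catch integral is linear in reflectance the
two coincide for noiseless inputs, but the pipeline keeps the measurement
protocol's asymmetry explicit rather than unifying it. Contrast tables can
be emitted per individual spectrum (feeding the behaviour models) or as
mean-catch rows; the two row kinds are distinguishable by construction
(`n_spectra_averaged`, labels) and never substituted for each other.

## Survival analyses

The field experiment exposes painted larvae (yellow = conspicuous,
green = cryptic control), solitary or in groups of ten, on branches along
two transects for five days with daily checks; eaten larvae are replaced to
keep group sizes constant; mesh-bagged branches control for non-predation
mortality and are scored only at the end.

**First-attack filter.** Replacement larvae have different exposure
histories, so they are excluded, and each branch contributes only its first
predation event: deaths after a branch's first attack day are recoded as
censored at that day, and the whole branch's follow-up is truncated there.
Branches with no attack keep all larvae censored at day 5. The alternative
reading that keeps every original larva's full history is available
(`mode="keep_all_originals"`) for sensitivity checks.

**Cox model.** Daily death times (days 1–5, administrative censoring at 5)
enter a Cox proportional-hazards model with 0/1 covariates for colour
(green reference) and group (solitary reference), stratified by transect.
Stratification stands in for the transect "random factor": with two
transects a stratified baseline absorbs between-transect heterogeneity
without a frailty fit; a gamma-frailty variant is noted as future work.
The partial likelihood supports Efron (default — daily checks produce many
ties) and Breslow tie handling and left truncation for delayed entry. It is
maximised by damped Newton iteration from β = 0 (step halving on
likelihood decrease), converging when max |score| < 1e−8; standard errors
come from the observed information; Wald z and two-sided normal p-values
are reported. A monotone likelihood (complete separation) is flagged as a
non-convergent result. Known behaviour: with the first-attack recoding the
Wald test is mildly conservative (measured type-I ≈ 0.03 at ~40 events
over ~80 branches) because censoring whole branches at their first event
leaves roughly one event per branch; on iid records the test is nominal
(measured 0.046–0.055 at n = 200, 1000 replicates).

**Mesh comparisons.** Death (1/0) on exposure (mesh reference) is a
binomial model with a transect random intercept (falling back to a plain
GLM with a note when only one transect is present), and within mesh bags a
fixed-effects binomial model of death on group and colour checks that
neither matters where predation is excluded. With only ~2% background
mortality, the mesh-only model is frequently separated or degenerate; such
fits are flagged, never silently reported.

## Behaviour–colour models

Per-larva defence phenotypes (U-posture display, defensive-fluid
deployment, fluid volume) are modelled against the larva's own JND
contrasts. All contrast predictors are centred (mean subtracted; the
constant is kept in the fit metadata), so intercepts are log-odds at the
average contrast.

**Binary traits** use logistic regression with a Gaussian random intercept
for larval family, fitted by maximum likelihood. The marginal likelihood
integrates the family effect by adaptive Gauss–Hermite quadrature: per
family the integrand's mode is found by Newton iteration (the integrand is
strictly log-concave, curvature ≤ −1), the quadrature grid is recentred
and rescaled at the mode, and 15 nodes are used by default (1 node
reproduces the Laplace approximation exactly; estimates change by < 1e−6
beyond 15 nodes on the test fixtures). The outer optimisation is BFGS with
a Nelder–Mead polish; standard errors come from the numerically
differentiated observed information. When the variance estimate hits the
boundary (σ̂ < 1e−3) the fit is reported as the plain GLM with σ = 0 and a
boundary note — the same behaviour `glmer` signals as a singular fit. The
implementation agrees with `lme4::glmer` (nAGQ = 15) to all printed digits
on the cross-check fixture. Without a grouping factor (or with fewer than
two families) the model is a plain IRLS GLM. By convention the
U-posture ~ dorsal colour model is fitted as a plain GLM (the mixed
variant is the one that historically fails to converge at this sample
size).

**Fluid volume** is gamma with a log link. Because the gamma density
excludes zero, volumes of exactly 0 (no fluid produced) are replaced by a
configurable constant, default 0.001, before fitting; larval length is
always included as an allometry covariate. Dispersion is the Pearson
estimator; the shape is not profiled. A constant response is returned as
the exact degenerate fit (intercept = log c, zero slopes) since IRLS
cannot start there. Inference is Wald throughout; no multiple-testing
correction is applied, matching the analysis convention the pipeline
reproduces.

Small-sample caveat: at the field scale (≈ 51 larvae in 12 families,
~85% positive responses) ML logistic estimates carry a noticeable
away-from-zero bias (measured ≈ +0.1 on a slope of 0.3 over 500 simulated
replicates) and the family SD is biased slightly down. This is intrinsic
to ML at this size — the implementation is exact against independent
oracles and consistent at large n — and should be kept in mind when
interpreting field-scale coefficient magnitudes.

## Synthetic data generators

The generators define the study conditions under which everything is
tested; they are first-class, tested code.

**Spectra** are smooth recipe curves (flat, Gaussian peak, sigmoid edge,
mixtures) with optional additive Gaussian noise clipped to [0, 1] — no
wavelength-correlated noise model. Presets emulate the study's stimuli:
chlorophyll-type needle green with a red-edge rise, a dimmer dorsal green,
a brighter flat-grey ventral side, a long-pass yellow paint edge, a
dorsal-matched green paint, and a pale needle-tinted defence fluid. Preset
amplitudes were calibrated once, against the packaged viewer, so that the
qualitative and approximate quantitative orderings of the real stimuli
hold (yellow paint ≈ 19 chromatic JND vs dorsal, green paint < 3, fluid vs
needles ≈ 8.7/16.1, ventral brighter than dorsal against needles); the
resulting values are frozen as regression tests.

**Predation** follows the field layout: eight treatment cells with
replicate counts (20, 20, 22, 19, 9, 10, 10, 9), groups of ten, two
transects (round-robin branch assignment, shared lognormal frailty per
transect, SD 0.2 by default), five days. Deaths are discrete-day
(geometric waiting times from a grouped continuous proportional-hazards
model: p_day = 1 − exp(−h0·e^η)), so Cox with Efron ties estimates the
generating log hazard ratio consistently; default truth is the field-scale
yellow effect ln 1.64 and group effect −0.429. The default baseline day
hazard 0.06 gives ≈ 26% five-day reference mortality; mesh bags draw an
independent ~2% background mortality scored only at day 5. Dead larvae are
replaced the next day (replacement rows flagged).

**Behaviour** draws 12 families of 3–5 larvae with the draw adjusted to a
51-individual total by default; lognormal JND contrasts in the weak-signal
4–8 range; latent logistic U-posture with a Gaussian family intercept
(defaults at the fitted field scale: intercept ≈ 1.7, colour slope ≈ −0.43,
luminance slope ≈ +0.29, family SD 0.5); fluid deployment is modelled the
same way but gated on the U-posture (the display precedes deployment, so
non-displayers never deploy); gamma fluid volumes (shape 2) with log-mean
in length and contrast, exactly zero for non-producers. All generators
thread `numpy.random.default_rng` seeds; nothing touches global state.

What the generators do *not* emulate: measured reflectance texture and
instrument noise structure, predator behaviour and learning, spatial
correlation between branches beyond the transect frailty, and any
correlation between coloration and defence chemistry (absent by default,
matching the field finding). Passing tests therefore demonstrate engine
correctness and recoverability under the stated generating models, not
fidelity to any particular measured dataset.

## Problem sizes used by the checks

The validation suites use: 1000 random catch/Weber instances for the RNL
oracle; 1000 null datasets of 200 iid individuals for the Cox type-I
check; 500 replicates at 400 exposed individuals for hazard-ratio
recovery through the full generate → filter → fit path; 500 replicates of
the 51-larva behaviour draw for GLMM recovery; a 20-row fixture for the
gamma ML oracle. The acceptance script averages Cox coefficients over 50
and behaviour coefficients over 30 replicate experiments. These sizes give
Monte-Carlo standard errors well below the effects of interest while
keeping the default runs desk-scale.

## Known limitations

- No spatial or pattern vision, no distance-dependent acuity, no
  photon-shot-noise (dim light) variant: contrasts describe uniform
  measured patches only.
- The packaged viewer and illuminant are template-based stand-ins (above);
  absolute JNDs should not be compared across viewers.
- Transect heterogeneity is handled by stratification, not a frailty term.
- The gamma volume model is fixed-effects only; a family grouping argument
  is accepted for interface symmetry but noted, not fitted.
- Zero-inflation in fluid volume is handled by the 0.001 replacement
  convention rather than a mixture model, reproducing the analysis being
  modelled rather than improving on it.
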