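"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to the pipeline are (a) spectrophotometer reflectance curves of
larvae, pine needles, paint patches and defence fluid, (b) five-day field
predation records over eight treatment cells on two transects, and (c)
per-larva defence-behaviour records from a dozen full-sib families.  The
generators here emulate all three with explicit generating parameters, so
every analysis stage can be tested for parameter recovery without any
external data.

* :func:`gen_spectrum` builds smooth reflectance curves from simple recipes
  (flat, Gaussian peak, sigmoid edge, mixtures) plus named presets for the
  study's stimuli (needles, larval dorsal/ventral, yellow/green paint,
  defence fluid).  Preset amplitudes are calibrated so the qualitative
  orderings of the real stimuli hold under the default viewer: the yellow
  paint patch is clearly discriminable from the dorsal surface, the green
  paint is not, and the pale ventral side has a higher luminance contrast
  against needles than the dorsal side.
* :func:`gen_predation` simulates the field experiment: per-individual
  discrete-day death hazards h0*exp(beta_color*yellow + beta_group*group +
  transect frailty) (geometric waiting times from a grouped continuous
  proportional-hazards model, matching the daily-check design), optional
  replacement of eaten larvae, and independent low background mortality in
  the mesh-bag cells scored only at the end of the experiment.
* :func:`gen_behavior` simulates family-clustered defence behaviour:
  lognormal JND contrasts, logistic U-posture/fluid probabilities with a
  Gaussian family intercept, and gamma-distributed fluid volumes (zero for
  non-producers) whose log mean depends on length and contrast.

All generators thread a seed through ``numpy.random.default_rng``; nothing
touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral_io import CANONICAL_GRID, Spectrum, SpectrumError, SpectrumSet
from .survival import SURVIVAL_COLUMNS

__all__ = [
    "SpectrumRecipe",
    "SPECTRUM_PRESETS",
    "gen_spectrum",
    "gen_spectrum_set",
    "ExperimentDesign",
    "gen_predation",
    "BehaviorParams",
    "gen_behavior",
]


# ---------------------------------------------------------------------------
# reflectance spectra


@dataclass
class SpectrumRecipe:
    """Recipe for one smooth synthetic reflectance curve.

    ``kind`` is one of ``flat`` (constant ``amplitude``), ``gaussian_peak``
    (``base`` + ``amplitude`` * Gaussian at ``peak_nm`` with SD
    ``width_nm``), ``sigmoid_edge`` (``low`` rising to ``high`` around
    ``edge_nm`` over scale ``width_nm``) or ``mixture`` (pointwise sum of
    ``components``, clipped to [0, 1]).  ``noise_sd`` adds independent
    Gaussian measurement noise, clipped back into [0, 1].
    """

    kind: str
    amplitude: float = 0.3
    base: float = 0.0
    peak_nm: float = 550.0
    width_nm: float = 40.0
    edge_nm: float = 500.0
    low: float = 0.05
    high: float = 0.8
    noise_sd: float = 0.0
    components: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        for amp in (self.amplitude, self.base, self.low, self.high):
            if not (0.0 <= amp <= 1.0):
                raise SpectrumError(f"recipe amplitudes must lie in [0, 1], got {amp}")
        if self.noise_sd < 0:
            raise SpectrumError("noise_sd must be nonnegative")


def _recipe_curve(recipe: SpectrumRecipe, w: np.ndarray) -> np.ndarray:
    if recipe.kind == "flat":
        return np.full_like(w, recipe.amplitude)
    if recipe.kind == "gaussian_peak":
        return recipe.base + recipe.amplitude * np.exp(
            -0.5 * ((w - recipe.peak_nm) / recipe.width_nm) ** 2)
    if recipe.kind == "sigmoid_edge":
        return recipe.low + (recipe.high - recipe.low) / (
            1.0 + np.exp(-(w - recipe.edge_nm) / recipe.width_nm))
    if recipe.kind == "mixture":
        if not recipe.components:
            raise SpectrumError("mixture recipe needs components")
        return np.sum([_recipe_curve(c, w) for c in recipe.components], axis=0)
    raise SpectrumError(f"unknown recipe kind {recipe.kind!r}")


def gen_spectrum(recipe: SpectrumRecipe, grid=CANONICAL_GRID,
                 seed: int | None = 0) -> Spectrum:
    """Deterministically generate one reflectance spectrum from a recipe."""
    w = np.asarray(grid, dtype=float)
    v = _recipe_curve(recipe, w)
    if recipe.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, recipe.noise_sd, size=w.size)
    v = np.clip(v, 0.0, 1.0)
    return Spectrum(w, v, label=recipe.label or recipe.kind, role="reflectance",
                    meta={"recipe": recipe.kind, "seed": seed})


#: Named stimulus presets.  Green vegetation is a chlorophyll-type peak near
#: 550 nm with a red-edge rise beyond 700 nm; the larval dorsal surface is a
#: dimmer green; the ventral side is a brighter, flatter grey; yellow paint
#: is a long-pass edge near 500 nm; green paint matches the dorsal surface
#: closely; the pooled defence fluid is a pale broadband reflector.
SPECTRUM_PRESETS = {
    "needle_green": SpectrumRecipe(
        kind="mixture", label="needle_green",
        components=[
            SpectrumRecipe(kind="gaussian_peak", base=0.03, amplitude=0.14,
                           peak_nm=552.0, width_nm=40.0),
            SpectrumRecipe(kind="sigmoid_edge", low=0.0, high=0.35,
                           edge_nm=712.0, width_nm=12.0),
        ]),
    "larva_dorsal_green": SpectrumRecipe(
        kind="mixture", label="larva_dorsal_green",
        components=[
            SpectrumRecipe(kind="gaussian_peak", base=0.025, amplitude=0.10,
                           peak_nm=548.0, width_nm=45.0),
            SpectrumRecipe(kind="sigmoid_edge", low=0.0, high=0.18,
                           edge_nm=705.0, width_nm=14.0),
        ]),
    "larva_ventral_pale": SpectrumRecipe(
        kind="mixture", label="larva_ventral_pale",
        components=[
            SpectrumRecipe(kind="flat", amplitude=0.32),
            SpectrumRecipe(kind="sigmoid_edge", low=0.0, high=0.12,
                           edge_nm=560.0, width_nm=90.0),
        ]),
    "yellow_paint": SpectrumRecipe(
        kind="sigmoid_edge", label="yellow_paint",
        low=0.04, high=0.75, edge_nm=505.0, width_nm=14.0),
    "green_paint": SpectrumRecipe(
        kind="mixture", label="green_paint",
        components=[
            SpectrumRecipe(kind="gaussian_peak", base=0.03, amplitude=0.11,
                           peak_nm=545.0, width_nm=42.0),
            SpectrumRecipe(kind="sigmoid_edge", low=0.0, high=0.17,
                           edge_nm=706.0, width_nm=14.0),
        ]),
    "defense_fluid": SpectrumRecipe(
        kind="mixture", label="defense_fluid",
        components=[
            SpectrumRecipe(kind="flat", amplitude=0.105),
            SpectrumRecipe(kind="gaussian_peak", base=0.02, amplitude=0.205,
                           peak_nm=552.0, width_nm=45.0),
            SpectrumRecipe(kind="sigmoid_edge", low=0.0, high=0.40,
                           edge_nm=710.0, width_nm=13.0),
        ]),
}


def gen_spectrum_set(preset: str, n: int = 3, noise_sd: float = 0.01,
                     seed: int = 0, grid=CANONICAL_GRID) -> SpectrumSet:
    """A set of ``n`` noisy replicates of a named preset."""
    if preset not in SPECTRUM_PRESETS:
        raise SpectrumError(f"unknown preset {preset!r}; "
                            f"options: {sorted(SPECTRUM_PRESETS)}")
    base = SPECTRUM_PRESETS[preset]
    spectra = []
    for i in range(n):
        r = replace(base, noise_sd=noise_sd, label=f"{preset}_{i:02d}")
        spectra.append(gen_spectrum(r, grid=grid, seed=(seed * 1000 + i) % (2 ** 31)))
    return SpectrumSet(spectra, group_key=preset)


# ---------------------------------------------------------------------------
# predation experiment


#: The eight treatment cells (colour, group, exposure) in the field
#: layout's order; default replicate counts pair with these positionally.
TREATMENT_CELLS = [
    ("yellow", "solitary", "exposed"),
    ("yellow", "group10", "exposed"),
    ("green", "solitary", "exposed"),
    ("green", "group10", "exposed"),
    ("yellow", "solitary", "mesh"),
    ("yellow", "group10", "mesh"),
    ("green", "solitary", "mesh"),
    ("green", "group10", "mesh"),
]


@dataclass
class ExperimentDesign:
    """Design and generating truth of a simulated predation experiment.

    Defaults follow the field layout: eight treatment cells with replicate
    counts (20, 20, 22, 19, 9, 10, 10, 9), groups of 10, a five-day
    horizon, two transects, and replacement of eaten larvae.  The true log
    hazard ratios default to the fitted field effects (yellow paint
    ln 1.64 = 0.494; group -0.429).  ``baseline_day_hazard`` is the daily
    death hazard of a green solitary larva (0.06 gives ~26% five-day
    mortality at the reference); mesh-bag mortality is background only
    (~2% over five days).
    """

    replicates: tuple = (20, 20, 22, 19, 9, 10, 10, 9)
    group_size: int = 10
    horizon_days: int = 5
    n_transects: int = 2
    beta_color: float = 0.494
    beta_group: float = -0.429
    transect_frailty_sd: float = 0.2
    baseline_day_hazard: float = 0.06
    mesh_day_hazard: float = 0.004
    replace_dead: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.replicates) != 8 or any(r <= 0 for r in self.replicates):
            raise ValueError("replicates must be 8 positive counts")
        if self.horizon_days < 1:
            raise ValueError("horizon must be >= 1 day")


def _death_prob(day_hazard: float, log_rate: float) -> float:
    """Daily death probability from a grouped continuous-time PH hazard."""
    return 1.0 - np.exp(-day_hazard * np.exp(log_rate))


def gen_predation(design: ExperimentDesign, seed: int | None = None) -> pd.DataFrame:
    """Simulate the five-day field predation experiment.

    Returns a survival-record table (one row per individual, replacements
    included when ``design.replace_dead``).  Branches are assigned to the
    two transects round-robin; each transect carries a lognormal frailty
    shared by all its branches.  Mesh-bag individuals die only of
    background causes and are scored at the end of the experiment
    (``event_day`` = horizon regardless of the unobserved death day).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    frailty = (rng.normal(0.0, design.transect_frailty_sd, size=design.n_transects)
               if design.transect_frailty_sd > 0 else np.zeros(design.n_transects))
    rows = []
    branch_no = 0
    for cell, n_rep in zip(TREATMENT_CELLS, design.replicates):
        color, group, exposure = cell
        n_ind = design.group_size if group == "group10" else 1
        for _ in range(n_rep):
            transect = branch_no % design.n_transects + 1
            tree = f"t{transect}_b{branch_no:03d}"
            branch_no += 1
            if exposure == "mesh":
                p5 = 1.0 - (1.0 - _death_prob(design.mesh_day_hazard, 0.0)) ** design.horizon_days
                for i in range(n_ind):
                    died = rng.random() < p5
                    rows.append((f"{tree}_i{i:02d}", transect, tree, color, group,
                                 "mesh", 0, design.horizon_days,
                                 "died" if died else "survived", False))
                continue
            eta = (design.beta_color * (color == "yellow")
                   + design.beta_group * (group == "group10")
                   + frailty[transect - 1])
            p_day = _death_prob(design.baseline_day_hazard, eta)
            # alive holds (individual_id, entry_day, replacement flag)
            alive = [(f"{tree}_i{i:02d}", 0, False) for i in range(n_ind)]
            n_spawned = n_ind
            for day in range(1, design.horizon_days + 1):
                survivors = []
                for ind_id, entry, is_repl in alive:
                    if rng.random() < p_day:
                        rows.append((ind_id, transect, tree, color, group,
                                     "exposed", entry, day, "died", is_repl))
                        if design.replace_dead and day < design.horizon_days:
                            survivors.append((f"{tree}_r{n_spawned:02d}", day, True))
                            n_spawned += 1
                    else:
                        survivors.append((ind_id, entry, is_repl))
                alive = survivors
            for ind_id, entry, is_repl in alive:
                rows.append((ind_id, transect, tree, color, group, "exposed",
                             entry, design.horizon_days, "survived", is_repl))
    return pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)


# ---------------------------------------------------------------------------
# behaviour records


@dataclass
class BehaviorParams:
    """Generating truth for family-clustered defence behaviour.

    Latent logistic models on centred contrasts: U-posture uses
    ``uposture_intercept + uposture_slope_color * (color - E[color]) +
    uposture_slope_luminance * (lum - E[lum]) + family effect`` and
    analogously for fluid deployment.  Defaults sit at the scale of the
    fitted behaviour-colour models (intercepts ~1.2-1.7, slopes ~|0.2-0.4|,
    family SD 0.5).  Fluid volume is gamma with shape ``gamma_shape`` and
    log mean ``volume_intercept + volume_slope_length * (length - 22) +
    volume_slope_contrast * (color - E[color])``; non-producers get volume
    exactly 0.  Contrasts are lognormal in the weakly-conspicuous JND 4-8
    range.
    """

    uposture_intercept: float = 1.7
    uposture_slope_color: float = -0.433
    uposture_slope_luminance: float = 0.289
    fluid_intercept: float = 1.2
    fluid_slope_color: float = -0.18
    fluid_slope_luminance: float = 0.25
    family_sd: float = 0.5
    gamma_shape: float = 2.0
    volume_intercept: float = 0.5
    volume_slope_length: float = 0.05
    volume_slope_contrast: float = 0.0
    color_log_mean: float = np.log(5.0)
    color_log_sd: float = 0.35
    luminance_log_mean: float = np.log(6.0)
    luminance_log_sd: float = 0.35
    length_mean_mm: float = 22.0
    length_sd_mm: float = 2.0


def _family_sizes(rng, n_families: int, per_family: tuple, total_target) -> np.ndarray:
    lo, hi = per_family
    sizes = rng.integers(lo, hi + 1, size=n_families)
    if total_target is not None:
        guard = 0
        while sizes.sum() != total_target and guard < 1000:
            i = int(rng.integers(n_families))
            if sizes.sum() < total_target and sizes[i] < hi:
                sizes[i] += 1
            elif sizes.sum() > total_target and sizes[i] > lo:
                sizes[i] -= 1
            guard += 1
    return sizes


def gen_behavior(n_families: int = 12, per_family: tuple = (3, 5),
                 params: BehaviorParams | None = None, seed: int = 0,
                 total_target: int | None = 51) -> pd.DataFrame:
    """Simulate family-clustered defence-behaviour records.

    By default 12 families of 3-5 female larvae with the draw adjusted to a
    total of 51 individuals.  Pass ``total_target=None`` for a plain
    uniform draw of family sizes.
    """
    p = params or BehaviorParams()
    rng = np.random.default_rng(seed)
    sizes = _family_sizes(rng, n_families, per_family, total_target)
    fam_effects = rng.normal(0.0, p.family_sd, size=n_families)

    rows = []
    k = 0
    for j in range(n_families):
        fam = f"fam{j:02d}"
        for _ in range(int(sizes[j])):
            length = rng.normal(p.length_mean_mm, p.length_sd_mm)
            vc = rng.lognormal(p.color_log_mean, p.color_log_sd)
            vl = rng.lognormal(p.luminance_log_mean, p.luminance_log_sd)
            dc = rng.lognormal(p.color_log_mean - 0.2, p.color_log_sd)
            dl = rng.lognormal(p.luminance_log_mean + 0.1, p.luminance_log_sd)
            # expected value of lognormal(mu, sd) is exp(mu + sd^2/2)
            vc_c = vc - np.exp(p.color_log_mean + p.color_log_sd ** 2 / 2)
            vl_c = vl - np.exp(p.luminance_log_mean + p.luminance_log_sd ** 2 / 2)
            eta_u = (p.uposture_intercept + p.uposture_slope_color * vc_c
                     + p.uposture_slope_luminance * vl_c + fam_effects[j])
            eta_f = (p.fluid_intercept + p.fluid_slope_color * vc_c
                     + p.fluid_slope_luminance * vl_c + fam_effects[j])
            u_post = rng.random() < 1.0 / (1.0 + np.exp(-eta_u))
            # the U-posture precedes fluid deployment; non-displayers never deploy
            fluid = bool(u_post) and (rng.random() < 1.0 / (1.0 + np.exp(-eta_f)))
            if fluid:
                log_mu = (p.volume_intercept
                          + p.volume_slope_length * (length - p.length_mean_mm)
                          + p.volume_slope_contrast * vc_c)
                vol = rng.gamma(p.gamma_shape, np.exp(log_mu) / p.gamma_shape)
            else:
                vol = 0.0
            rows.append((f"ind{k:03d}", fam, length, bool(u_post), bool(fluid),
                         vol, vc, vl, dc, dl))
            k += 1
    return pd.DataFrame(rows, columns=[
        "individual_id", "family_id", "length_mm", "u_posture", "fluid",
        "fluid_volume", "ventral_color_jnd", "ventral_luminance_jnd",
        "dorsal_color_jnd", "dorsal_luminance_jnd",
    ])
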