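"""Stimulus-comparison pipeline: larval colour elements vs background vs fluid.

Reproduces the study-style comparisons on top of :mod:`preyjnd.vision_model`:

* per-individual or mean-catch contrasts of larval dorsal and ventral
  surfaces against the pine-needle background (the background reference is
  always the *mean reflectance* of the needle replicates),
* defence-fluid contrasts against dorsal, ventral and needles,
* paint-patch verification, which averages *cone catches* across the
  measured larvae within each paint set and compares the mean catch vectors
  (mean-of-catches, deliberately not catch-of-mean-spectrum).

The background/paint asymmetry (mean reflectance for needles, mean catches
for paint verification) mirrors the measurement protocol and is preserved
rather than unified.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .spectral_io import Spectrum, SpectrumError, SpectrumSet, mean_spectrum
from .vision_model import (
    ContrastResult,
    QuantumCatches,
    VisualSystem,
    catch_vector,
    contrast,
)

__all__ = ["TABLE_COLUMNS", "mean_catches", "paint_verification", "build_contrast_table"]

#: Output schema of :func:`build_contrast_table`.
TABLE_COLUMNS = [
    "stimulus_label",
    "reference_label",
    "delta_s",
    "delta_l",
    "class_s",
    "class_l",
    "n_spectra_averaged",
]


def _adapting_background(vs: VisualSystem, illuminant: Spectrum,
                         background: Spectrum | None, adapt: str) -> Spectrum | None:
    """Resolve the von Kries adapting field.

    ``adapt='illuminant'`` (default) adapts to an ideal white under the
    illuminant; ``adapt='background'`` adapts to the mean background
    reflectance instead.  Both conventions occur in practice.
    """
    if adapt == "illuminant":
        return Spectrum(vs.grid.copy(), np.ones_like(vs.grid), label="ideal_white",
                        role="reflectance")
    if adapt == "background":
        if background is None:
            raise SpectrumError("adapt='background' requires a background spectrum")
        return background
    raise SpectrumError(f"unknown adaptation convention {adapt!r}")


def mean_catches(sset: SpectrumSet, vs: VisualSystem, illuminant: Spectrum,
                 adapting: Spectrum | None = None, label: str = "") -> QuantumCatches:
    """Channelwise mean of the catch vectors of every spectrum in a set."""
    singles, doubles = [], []
    normalized = adapting is not None
    for s in sset:
        qc = catch_vector(s, vs, illuminant, background=adapting)
        singles.append(qc.single)
        doubles.append(qc.double)
    return QuantumCatches(np.mean(singles, axis=0), float(np.mean(doubles)),
                          normalized=normalized,
                          stimulus_label=label or f"mean_catch({len(sset)})",
                          background_label=adapting.label if adapting else "")


def paint_verification(painted: SpectrumSet, unpainted: SpectrumSet,
                       vs: VisualSystem, illuminant: Spectrum,
                       adapt: str = "illuminant") -> ContrastResult:
    """JND contrast between a paint patch and the natural surface.

    Catch vectors are computed per measured spectrum, averaged channelwise
    within the painted and unpainted sets, and a single Delta S / Delta L is
    computed between the two mean catch vectors.
    """
    adapting = _adapting_background(vs, illuminant, None, adapt)
    qa = mean_catches(painted, vs, illuminant, adapting, label="painted")
    qb = mean_catches(unpainted, vs, illuminant, adapting, label="unpainted")
    return contrast(qa, qb, vs)


def _row(result: ContrastResult, n_averaged: int) -> dict:
    return {
        "stimulus_label": result.stimulus_label,
        "reference_label": result.reference_label,
        "delta_s": result.delta_s,
        "delta_l": result.delta_l,
        "class_s": result.class_s.value,
        "class_l": result.class_l.value,
        "n_spectra_averaged": n_averaged,
    }


def build_contrast_table(stimuli: Mapping[str, SpectrumSet], background: SpectrumSet,
                         vs: VisualSystem, illuminant: Spectrum,
                         per_individual: bool = False,
                         adapt: str = "illuminant") -> pd.DataFrame:
    """Contrast table of every stimulus set against the mean needle background.

    With ``per_individual=True`` each stimulus spectrum gets its own row
    against the mean background (``n_spectra_averaged=1``; labels carry the
    individual spectrum label) — the form consumed by the behaviour-colour
    models.  With ``per_individual=False`` one mean-catch row per stimulus
    set is emitted.  When a ``fluid`` set is present, fluid-vs-dorsal,
    fluid-vs-ventral and fluid-vs-needles rows are always included
    (mean-catch rows; the fluid sample is pooled).

    The two row kinds are distinct (per-individual rows always have
    ``n_spectra_averaged == 1`` and individual labels); they are never
    merged or substituted for one another.
    """
    for key in stimuli:
        if not isinstance(stimuli[key], SpectrumSet):
            raise SpectrumError(f"stimulus {key!r} is not a SpectrumSet")
    bg_mean = mean_spectrum(background, label="needles_mean")
    adapting = _adapting_background(vs, illuminant, bg_mean, adapt)
    q_bg = catch_vector(bg_mean, vs, illuminant, background=adapting)
    q_bg.stimulus_label = "needles_mean"

    rows = []
    for key, sset in stimuli.items():
        if per_individual:
            for s in sset:
                qs = catch_vector(s, vs, illuminant, background=adapting)
                qs.stimulus_label = f"{key}:{s.label}" if s.label else key
                rows.append(_row(contrast(qs, q_bg, vs), 1))
        else:
            qs = mean_catches(sset, vs, illuminant, adapting, label=key)
            rows.append(_row(contrast(qs, q_bg, vs), len(sset)))

    if "fluid" in stimuli:
        q_fluid = mean_catches(stimuli["fluid"], vs, illuminant, adapting, label="fluid")
        for ref_key in ("dorsal", "ventral"):
            if ref_key in stimuli:
                q_ref = mean_catches(stimuli[ref_key], vs, illuminant, adapting,
                                     label=ref_key)
                rows.append(_row(contrast(q_fluid, q_ref, vs), len(stimuli["fluid"])))
        if per_individual:
            # the mean-catch fluid-vs-needles row otherwise already exists
            rows.append(_row(contrast(q_fluid, q_bg, vs), len(stimuli["fluid"])))

    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
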