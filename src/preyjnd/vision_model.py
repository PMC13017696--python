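"""Receptor-noise-limited (RNL) discriminability model for avian vision.

The model asks whether a tetrachromatic bird (default viewer: blue tit,
*Cyanistes caeruleus*) can tell two surfaces apart under a given illuminant.
Each photoreceptor class i captures a quantum catch

    Q_i = integral R(lambda) S_i(lambda) I(lambda) d lambda

(reflectance x sensitivity x illuminant, trapezoidal rule on the shared
grid).  Catches are von Kries normalised by the catch of the adapting
background, receptor signals are logarithmic (Fechner), f_i = ln Q_i, and
discriminability is limited only by receptor noise: channel i has a Weber
fraction

    omega_i = omega_ref * sqrt(eta_max / eta_i)

anchored so the most abundant single-cone class has omega = omega_ref
(default 0.05).  Chromatic contrast Delta S between stimuli a and b is the
noise-weighted distance between the signal differences
Delta f_i = ln(Q_i^a / Q_i^b) after discarding the achromatic (all-channels-
equal) direction; achromatic (luminance) contrast uses the double cone
alone, Delta L = |ln(Q_D^a / Q_D^b)| / omega_D.  Both are expressed in
just-noticeable differences (JND): below 1 JND two stimuli are likely
indistinguishable, 1-3 JND distinguishable only under optimal light, above
3 JND distinguishable.

The packaged default viewer is a synthetic stand-in: sensitivity curves are
built from the Govardovskii et al. (2000) A1 visual-pigment template with
logistic ocular-media and oil-droplet filters at nominal blue tit peak
wavelengths, not from the measured whole-eye tables, and the daylight
illuminant is a 6504 K Planck curve rather than the tabulated CIE D65.
Cone-abundance ratios default to UVS:SWS:MWS:LWS = 1 : 1.92 : 2.68 : 2.7.
All of these are configuration, loadable from a directory of CSV curves
plus a YAML descriptor, because absolute JND values depend on them.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .spectral_io import (
    CANONICAL_GRID,
    GridMismatchError,
    Spectrum,
    SpectrumError,
    read_spectra,
)

__all__ = [
    "VisualSystem",
    "QuantumCatches",
    "ContrastResult",
    "JndClass",
    "quantum_catch",
    "catch_vector",
    "weber_fractions",
    "weber_from_abundances",
    "chromatic_jnd",
    "achromatic_jnd",
    "classify_jnd",
    "contrast",
    "load_viewer",
    "bluetit_d65",
]


class JndClass(str, enum.Enum):
    """Discriminability classes at the 1 and 3 JND thresholds (inclusive middle)."""

    INDISTINGUISHABLE = "indistinguishable"
    OPTIMAL_LIGHT_ONLY = "optimal_light_only"
    DISTINGUISHABLE = "distinguishable"


@dataclass
class VisualSystem:
    """A viewer: single-cone sensitivities, double cone, abundances, noise.

    Parameters
    ----------
    sensitivities
        One sensitivity :class:`Spectrum` per single-cone channel, ordered
        (e.g. UVS, SWS, MWS, LWS).
    double_cone
        Sensitivity of the double cone (luminance channel).
    abundances
        Relative abundances eta_i of the single-cone classes, > 0.
    weber_ref
        Weber fraction of the most abundant single cone, in (0, 1).
    weber_double
        Weber fraction of the double-cone (luminance) channel, in (0, 1).
    """

    sensitivities: list
    double_cone: Spectrum
    abundances: np.ndarray
    weber_ref: float = 0.05
    weber_double: float = 0.05
    name: str = ""
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sensitivities) < 2:
            raise SpectrumError("a visual system needs at least 2 single-cone channels")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.sensitivities),):
            raise SpectrumError("one abundance per single-cone channel required")
        if np.any(self.abundances <= 0):
            raise SpectrumError("abundances must be strictly positive")
        if not (0 < self.weber_ref < 1) or not (0 < self.weber_double < 1):
            raise SpectrumError("Weber fractions must lie in (0, 1)")
        grid = self.sensitivities[0].wavelengths_nm
        for s in list(self.sensitivities) + [self.double_cone]:
            if not np.array_equal(s.wavelengths_nm, grid):
                raise GridMismatchError("all sensitivity curves must share one grid")
        if not self.channel_names:
            self.channel_names = [s.label or f"cone{i}" for i, s in enumerate(self.sensitivities)]

    @property
    def n_channels(self) -> int:
        return len(self.sensitivities)

    @property
    def grid(self) -> np.ndarray:
        return self.sensitivities[0].wavelengths_nm


@dataclass
class QuantumCatches:
    """Quantum catches of one stimulus: per single cone plus the double cone."""

    single: np.ndarray
    double: float
    normalized: bool = False
    stimulus_label: str = ""
    background_label: str = ""

    def __post_init__(self) -> None:
        self.single = np.asarray(self.single, dtype=float)
        self.double = float(self.double)


@dataclass
class ContrastResult:
    """Chromatic and achromatic JND contrast for one stimulus pair."""

    delta_s: float
    delta_l: float
    class_s: JndClass
    class_l: JndClass
    stimulus_label: str = ""
    reference_label: str = ""


# ---------------------------------------------------------------------------
# quantum catches


def quantum_catch(stimulus: Spectrum, sensitivity: Spectrum, illuminant: Spectrum) -> float:
    """Trapezoidal catch integral of reflectance x sensitivity x illuminant."""
    if not (stimulus.same_grid(sensitivity) and stimulus.same_grid(illuminant)):
        raise GridMismatchError("stimulus, sensitivity and illuminant must share one grid")
    integrand = stimulus.values * sensitivity.values * illuminant.values
    q = float(np.trapezoid(integrand, stimulus.wavelengths_nm))
    if q < 0:
        raise SpectrumError("negative quantum catch: check input signs")
    return q


def catch_vector(stimulus: Spectrum, vs: VisualSystem, illuminant: Spectrum,
                 background: Spectrum | None = None) -> QuantumCatches:
    """Quantum catches of a stimulus for every channel of a viewer.

    With ``background`` given, each channel's catch is divided by the catch
    of the background in that channel (von Kries chromatic adaptation); the
    background itself then maps to all-ones.  Without a background, raw
    catches are returned.
    """
    single = np.array([quantum_catch(stimulus, s, illuminant) for s in vs.sensitivities])
    double = quantum_catch(stimulus, vs.double_cone, illuminant)
    if background is None:
        return QuantumCatches(single, double, normalized=False,
                              stimulus_label=stimulus.label)
    bg_single = np.array([quantum_catch(background, s, illuminant) for s in vs.sensitivities])
    bg_double = quantum_catch(background, vs.double_cone, illuminant)
    if np.any(bg_single == 0) or bg_double == 0:
        raise SpectrumError(
            f"degenerate adapting background {background.label!r}: zero catch in a channel"
        )
    return QuantumCatches(single / bg_single, double / bg_double, normalized=True,
                          stimulus_label=stimulus.label,
                          background_label=background.label)


# ---------------------------------------------------------------------------
# receptor noise


def weber_from_abundances(abundances, weber_ref: float = 0.05) -> np.ndarray:
    """Channel Weber fractions omega_i = omega_ref * sqrt(eta_max / eta_i).

    The most abundant channel gets exactly ``weber_ref``; sparser channels
    are noisier (omega nonincreasing in abundance).
    """
    eta = np.asarray(abundances, dtype=float)
    if np.any(eta <= 0):
        raise SpectrumError("abundances must be strictly positive")
    return weber_ref * np.sqrt(eta.max() / eta)


def weber_fractions(vs: VisualSystem) -> np.ndarray:
    """Weber fractions of a viewer's single-cone channels."""
    return weber_from_abundances(vs.abundances, vs.weber_ref)


# ---------------------------------------------------------------------------
# JND contrasts


def _signal_diffs(a, b) -> np.ndarray:
    qa = a.single if isinstance(a, QuantumCatches) else np.asarray(a, dtype=float)
    qb = b.single if isinstance(b, QuantumCatches) else np.asarray(b, dtype=float)
    if qa.shape != qb.shape:
        raise SpectrumError("catch vectors must have matching channel counts")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise SpectrumError("log receptor signals need strictly positive catches")
    return np.log(qa / qb)


def chromatic_jnd(a, b, omega) -> float:
    """Receptor-noise-limited chromatic contrast Delta S in JND.

    ``a`` and ``b`` are :class:`QuantumCatches` (or bare positive catch
    vectors) with matching channel counts; ``omega`` the per-channel Weber
    fractions.  Uses the published closed forms for 2, 3 and 4 receptor
    classes; for more channels the equivalent noise-weighted projection
    form (Mahalanobis distance of Delta f orthogonal to the achromatic
    direction) is used.
    """
    df = _signal_diffs(a, b)
    w = np.asarray(omega, dtype=float)
    if w.shape != df.shape:
        raise SpectrumError("need one Weber fraction per channel")
    if np.any(w <= 0):
        raise SpectrumError("Weber fractions must be positive")
    n = df.size
    if n == 2:
        return float(abs(df[0] - df[1]) / np.hypot(w[0], w[1]))
    if n == 3:
        num = (w[0] ** 2 * (df[1] - df[2]) ** 2
               + w[1] ** 2 * (df[0] - df[2]) ** 2
               + w[2] ** 2 * (df[0] - df[1]) ** 2)
        den = (w[0] * w[1]) ** 2 + (w[0] * w[2]) ** 2 + (w[1] * w[2]) ** 2
        return float(np.sqrt(num / den))
    if n == 4:
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        num = 0.0
        for i, j in pairs:
            k, l = (c for c in range(4) if c not in (i, j))
            num += (w[k] * w[l]) ** 2 * (df[i] - df[j]) ** 2
        den = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                for k in range(j + 1, 4):
                    den += (w[i] * w[j] * w[k]) ** 2
        return float(np.sqrt(num / den))
    # general n: project out the achromatic direction in the noise metric
    prec = 1.0 / w ** 2
    q = df @ (prec * df) - (prec @ df) ** 2 / prec.sum()
    return float(np.sqrt(max(q, 0.0)))


def achromatic_jnd(a, b, omega_double: float) -> float:
    """Luminance contrast Delta L = |ln(Q_D^a / Q_D^b)| / omega_D in JND."""
    qa = a.double if isinstance(a, QuantumCatches) else float(a)
    qb = b.double if isinstance(b, QuantumCatches) else float(b)
    if qa <= 0 or qb <= 0:
        raise SpectrumError("log receptor signals need strictly positive catches")
    if omega_double <= 0:
        raise SpectrumError("double-cone Weber fraction must be positive")
    return float(abs(np.log(qa / qb)) / omega_double)


def classify_jnd(jnd: float) -> JndClass:
    """Discriminability class of a JND value.

    Below 1: likely indistinguishable.  1 to 3 (inclusive): distinguishable
    only under optimal light.  Above 3: likely distinguishable.
    """
    if jnd < 0 or not np.isfinite(jnd):
        raise SpectrumError(f"JND must be finite and nonnegative, got {jnd}")
    if jnd < 1:
        return JndClass.INDISTINGUISHABLE
    if jnd <= 3:
        return JndClass.OPTIMAL_LIGHT_ONLY
    return JndClass.DISTINGUISHABLE


def contrast(a: QuantumCatches, b: QuantumCatches, vs: VisualSystem) -> ContrastResult:
    """Full chromatic + achromatic contrast between two catch vectors."""
    ds = chromatic_jnd(a, b, weber_fractions(vs))
    dl = achromatic_jnd(a, b, vs.weber_double)
    return ContrastResult(ds, dl, classify_jnd(ds), classify_jnd(dl),
                          stimulus_label=a.stimulus_label,
                          reference_label=b.stimulus_label)


# ---------------------------------------------------------------------------
# synthetic default viewer: pigment templates and daylight


def pigment_template(lmax: float, wavelengths=CANONICAL_GRID) -> np.ndarray:
    """Govardovskii A1 visual-pigment absorbance template (alpha + beta band).

    Normalised to peak 1 at ``lmax``.  Used to build the packaged synthetic
    sensitivity tables; it is a literature-standard template, not a measured
    blue tit curve.
    """
    w = np.asarray(wavelengths, dtype=float)
    x = lmax / w
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((w - lmb) / bb) ** 2))
    s = alpha + beta
    return s / s.max()


def _logistic_longpass(wavelengths, cut_nm: float, slope_nm: float = 8.0) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    return 1.0 / (1.0 + np.exp(-(w - cut_nm) / slope_nm))


def synthetic_daylight(wavelengths=CANONICAL_GRID, temperature_k: float = 6504.0) -> Spectrum:
    """Smooth D65-like daylight: Planck radiator at 6504 K, 100 at 560 nm.

    A synthetic stand-in for the tabulated CIE D65 spectral power
    distribution; all JND math is invariant to its overall scale.
    """
    w_m = np.asarray(wavelengths, dtype=float) * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    spd = (1.0 / w_m ** 5) / (np.expm1(h * c / (w_m * kb * temperature_k)))
    ref = np.interp(560.0, np.asarray(wavelengths, float), spd)
    return Spectrum(np.asarray(wavelengths, dtype=float), 100.0 * spd / ref,
                    label="daylight_6504K_synthetic", role="illuminant")


#: Nominal blue tit pigment peaks (nm) and oil-droplet cut-on wavelengths.
_BLUETIT_CHANNELS = {
    "UVS": (371.0, None),
    "SWS": (448.0, 410.0),
    "MWS": (503.0, 478.0),
    "LWS": (563.0, 540.0),
}
_BLUETIT_DOUBLE = (563.0, 420.0)
_BLUETIT_ABUNDANCES = (1.0, 1.92, 2.68, 2.7)


def build_bluetit_viewer(grid=CANONICAL_GRID) -> VisualSystem:
    """Synthetic blue tit viewer built from pigment templates.

    Whole-eye sensitivity of each channel is modelled as pigment template x
    ocular-media transmission (logistic cut-on near 320 nm) x oil-droplet
    long-pass filter (none for the UV cone).  Peaks, droplet cut-ons and
    abundance ratios are nominal literature values; this is a documented
    stand-in for measured sensitivity tables and is fully overridable via
    :func:`load_viewer`.
    """
    grid = np.asarray(grid, dtype=float)
    media = _logistic_longpass(grid, 322.0, 6.0)
    sens = []
    for name, (lmax, cut) in _BLUETIT_CHANNELS.items():
        s = pigment_template(lmax, grid) * media
        if cut is not None:
            s = s * _logistic_longpass(grid, cut, 10.0)
        sens.append(Spectrum(grid, s / s.max(), label=name, role="sensitivity"))
    lmax, cut = _BLUETIT_DOUBLE
    d = pigment_template(lmax, grid) * media * _logistic_longpass(grid, cut, 15.0)
    double = Spectrum(grid, d / d.max(), label="double", role="sensitivity")
    return VisualSystem(sens, double, np.array(_BLUETIT_ABUNDANCES),
                        weber_ref=0.05, weber_double=0.05,
                        name="bluetit_synthetic",
                        channel_names=list(_BLUETIT_CHANNELS))


# ---------------------------------------------------------------------------
# loading viewers from descriptor + CSV tables


def _data_dir() -> Path:
    return Path(importlib.resources.files("preyjnd") / "data")


def load_viewer(name_or_path="bluetit_d65"):
    """Load a (VisualSystem, illuminant Spectrum) pair from a descriptor.

    ``name_or_path`` is either the name of a packaged viewer (descriptor
    ``<name>.yaml`` in the package data directory) or a path to a YAML
    descriptor whose relative file references resolve against its directory.

    Descriptor keys: ``name``, ``sensitivities`` (wide CSV of sensitivity
    curves), ``channels`` (ordered single-cone column labels),
    ``double_cone`` (column label), ``abundances``, ``weber_ref``,
    ``weber_double``, ``illuminant`` (long or wide CSV with one column).
    """
    p = Path(str(name_or_path))
    if not p.suffix:
        p = _data_dir() / f"{name_or_path}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no viewer descriptor at {p}")
    with open(p) as fh:
        desc = yaml.safe_load(fh)
    base = p.parent
    curves = {s.label: s for s in read_spectra(base / desc["sensitivities"],
                                               dialect="wide_csv", role="sensitivity")}
    try:
        sens = [curves[c] for c in desc["channels"]]
        double = curves[desc["double_cone"]]
    except KeyError as e:
        raise SpectrumError(f"viewer descriptor names unknown channel {e}") from e
    vs = VisualSystem(sens, double, np.asarray(desc["abundances"], dtype=float),
                      weber_ref=float(desc.get("weber_ref", 0.05)),
                      weber_double=float(desc.get("weber_double", 0.05)),
                      name=desc.get("name", p.stem),
                      channel_names=list(desc["channels"]))
    illum = read_spectra(base / desc["illuminant"], dialect="wide_csv",
                         role="illuminant")[0]
    if not np.array_equal(illum.wavelengths_nm, vs.grid):
        raise GridMismatchError("illuminant and sensitivities must share one grid")
    return vs, illum


def bluetit_d65():
    """The packaged default viewer and daylight illuminant."""
    return load_viewer("bluetit_d65")
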