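"""Reading, validation, resampling and aggregation of reflectance spectra.

A spectrum is a wavelength-indexed curve: reflectance of an object (a
fraction in roughly [0, 1]), the relative spectral power of an illuminant,
or a photoreceptor's spectral sensitivity.  Spectrophotometer exports come
at sub-nanometre resolution (the supported instrument convention is
300-750 nm at ~0.47 nm steps, three samples per nanometre); sensitivity and
illuminant tables are published at 1 nm.  All downstream model math runs on
the canonical integer-nanometre grid 300-750 nm (451 points), so this module
provides decimation (keep the first sample in each integer-nm bin), linear
resampling, and pointwise averaging of replicate measurements.

Supported text dialects
-----------------------
long CSV
    Two columns ``wavelength_nm,value``, optional header, comma or tab.
wide CSV
    First column wavelength, each further column one spectrum, header row
    giving the labels.

Negative reflectances (instrument noise around dark measurements) are
clipped to zero with a count recorded in ``Spectrum.meta['n_clipped']``;
reflectance tables exported as percentages (maximum value > 1.5) are
auto-rescaled to fractions with a note in the metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical wavelength grid for all vision-model computation: 300-750 nm, 1 nm.
CANONICAL_GRID = np.arange(300.0, 751.0)

ROLES = ("reflectance", "illuminant", "sensitivity")
DIALECTS = ("long_csv", "wide_csv")
DECIMATIONS = ("none", "first_per_nm")

#: Reflectance maxima above this are taken to be percent exports.
_PERCENT_THRESHOLD = 1.5


class SpectrumError(ValueError):
    """Invalid spectral data (grid, values, or file contents)."""


class SpectrumParseError(SpectrumError):
    """A spectral table could not be parsed; names the offending line."""


class GridMismatchError(SpectrumError):
    """Two spectra that must share a wavelength grid do not."""


@dataclass
class Spectrum:
    """A single wavelength-indexed curve.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres, length >= 2.
    values
        Curve values, same length.  Finite; for ``role='reflectance'``
        negative values are clipped to 0 (count in ``meta['n_clipped']``).
    label
        Free-text name (e.g. ``"larva_dorsal_03"``).
    role
        One of ``reflectance``, ``illuminant``, ``sensitivity``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""
    role: str = "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise SpectrumError("wavelengths and values must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(w)):
            raise SpectrumError("non-finite wavelengths")
        if not np.all(np.diff(w) > 0):
            raise SpectrumError("wavelengths must be strictly increasing with no duplicates")
        if not np.all(np.isfinite(v)):
            raise SpectrumError(f"non-finite values in spectrum {self.label!r}")
        if self.role not in ROLES:
            raise SpectrumError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role == "reflectance":
            n_neg = int(np.sum(v < 0))
            if n_neg:
                logger.warning(
                    "clipped %d negative reflectance value(s) to 0 in %r", n_neg, self.label
                )
                v = np.clip(v, 0.0, None)
            self.meta.setdefault("n_clipped", n_neg)
        else:
            if np.any(v < 0):
                raise SpectrumError(f"{self.role} spectrum {self.label!r} has negative values")
        self.wavelengths_nm = w
        self.values = v

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def with_values(self, values: np.ndarray, **kw) -> "Spectrum":
        """Copy of this spectrum with new values (same grid)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       meta=dict(self.meta), **kw)

    def same_grid(self, other: "Spectrum") -> bool:
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one wavelength grid.

    ``group_key`` labels the replicate structure (individual, tree, paint).
    """

    spectra: list
    group_key: str = ""

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumError("SpectrumSet must be non-empty")
        ref = self.spectra[0]
        for s in self.spectra[1:]:
            if not ref.same_grid(s):
                raise GridMismatchError(
                    f"spectrum {s.label!r} does not share the grid of {ref.label!r}"
                )

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# ---------------------------------------------------------------------------
# parsing


def _read_table(path: Path) -> pd.DataFrame:
    """Read a comma- or tab-separated table; detect an optional header row.

    Returns a DataFrame of floats whose columns are named from the header
    when present, else ``col0, col1, ...``.  Raises SpectrumParseError naming
    the first non-numeric line.
    """
    raw = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                      comment="#", skip_blank_lines=True)
    raw = raw.dropna(how="all")
    first = raw.iloc[0]
    has_header = False
    try:
        first.astype(float)
    except (ValueError, TypeError):
        has_header = True
    if has_header:
        names = [str(x).strip() for x in first]
        body = raw.iloc[1:]
        line_offset = 2  # 1-based line number of the first data row
    else:
        names = [f"col{i}" for i in range(raw.shape[1])]
        body = raw
        line_offset = 1
    out = {}
    for j, name in enumerate(names):
        raw_col = body.iloc[:, j].to_numpy()
        col = np.empty(raw_col.size, dtype=float)
        for i, cell in enumerate(raw_col):
            try:
                # Python's float() is correctly rounded; pandas' fast
                # parser can lose the last ulp and break lossless roundtrips
                col[i] = float(cell)
            except (TypeError, ValueError):
                raise SpectrumParseError(
                    f"{path}: non-numeric value {cell!r} at line {i + line_offset}"
                ) from None
        out[name] = col
    return pd.DataFrame(out)


def _decimate_first_per_nm(w: np.ndarray, v: np.ndarray) -> tuple:
    """Keep the first sample encountered (ascending) in each integer-nm bin."""
    bins = np.floor(w).astype(int)
    # first occurrence of each bin in ascending wavelength order
    _, first_idx = np.unique(bins, return_index=True)
    return w[np.sort(first_idx)], v[np.sort(first_idx)]


def _clean_axis(w: np.ndarray, v: np.ndarray, label: str) -> tuple:
    """Sort by wavelength and drop exact duplicate wavelengths (keep first)."""
    order = np.argsort(w, kind="stable")
    w, v = w[order], v[order]
    keep = np.concatenate([[True], np.diff(w) > 0])
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d duplicate wavelength row(s) in %r", dropped, label)
    return w[keep], v[keep]


def _finish_spectrum(w, v, label, role, decimation, path) -> Spectrum:
    w, v = _clean_axis(np.asarray(w, float), np.asarray(v, float), label)
    if decimation == "first_per_nm":
        w, v = _decimate_first_per_nm(w, v)
    meta = {"source": str(path), "decimation": decimation}
    if role == "reflectance" and v.size and np.nanmax(v) > _PERCENT_THRESHOLD:
        logger.info("spectrum %r looks like percent reflectance; dividing by 100", label)
        v = v / 100.0
        meta["percent_rescaled"] = True
    return Spectrum(w, v, label=label, role=role, meta=meta)


def read_spectra(path, dialect: str = "long_csv", decimation: str = "none",
                 role: str = "reflectance") -> list:
    """Read one (long) or several (wide) spectra from a CSV/TSV file.

    With ``decimation='first_per_nm'`` exactly one sample per populated
    integer-nm bin is kept: the first encountered in ascending wavelength
    order (the spectrophotometer convention of using only the first of the
    three per-nanometre samples).
    """
    if dialect not in DIALECTS:
        raise SpectrumError(f"unknown dialect {dialect!r}")
    if decimation not in DECIMATIONS:
        raise SpectrumError(f"unknown decimation {decimation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise SpectrumParseError(f"{path}: need at least two columns")
    w = df.iloc[:, 0].to_numpy()
    if dialect == "long_csv":
        if df.shape[1] != 2:
            raise SpectrumParseError(
                f"{path}: long_csv expects exactly 2 columns, found {df.shape[1]}"
            )
        label = df.columns[1] if not df.columns[1].startswith("col") else path.stem
        return [_finish_spectrum(w, df.iloc[:, 1].to_numpy(), label, role, decimation, path)]
    out = []
    for name in df.columns[1:]:
        label = name if not str(name).startswith("col") else f"{path.stem}_{name}"
        out.append(_finish_spectrum(w, df[name].to_numpy(), str(label), role, decimation, path))
    return out


def read_spectrum(path, dialect: str = "long_csv", decimation: str = "none",
                  role: str = "reflectance") -> Spectrum:
    """Read a single spectrum; errors if a wide file holds more than one."""
    spectra = read_spectra(path, dialect=dialect, decimation=decimation, role=role)
    if len(spectra) != 1:
        raise SpectrumError(
            f"{path} holds {len(spectra)} spectra; use read_spectra()"
        )
    return spectra[0]


def write_spectrum(s: Spectrum, path) -> None:
    """Write a spectrum as long CSV ``wavelength_nm,<label>`` (lossless floats)."""
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, s.label or "value": s.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_spectra(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra sharing a grid as wide CSV (one column per spectrum)."""
    sset = SpectrumSet(list(spectra))
    data = {"wavelength_nm": sset.grid}
    for i, s in enumerate(sset):
        data[s.label or f"spectrum_{i}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# resampling and aggregation


def resample(s: Spectrum, grid, method: str = "linear") -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    if method != "linear":
        raise SpectrumError(f"unsupported resampling method {method!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise SpectrumError("target grid must be 1-D, strictly increasing, length >= 2")
    if grid[0] < s.wavelengths_nm[0] or grid[-1] > s.wavelengths_nm[-1]:
        raise SpectrumError(
            f"target grid [{grid[0]}, {grid[-1]}] outside source support "
            f"[{s.wavelengths_nm[0]}, {s.wavelengths_nm[-1]}]"
        )
    v = np.interp(grid, s.wavelengths_nm, s.values)
    meta = dict(s.meta)
    meta["resampled"] = True
    return Spectrum(grid, v, label=s.label, role=s.role, meta=meta)


def to_canonical(s: Spectrum, grid: np.ndarray = CANONICAL_GRID) -> Spectrum:
    """Resample onto the canonical 1-nm grid (identity if already on it)."""
    if np.array_equal(s.wavelengths_nm, grid):
        return s
    return resample(s, grid)


def mean_spectrum(sset: SpectrumSet, label: str | None = None) -> Spectrum:
    """Pointwise arithmetic mean of a set of spectra on a shared grid.

    This is the background convention for natural substrates: replicate
    needle spectra from several trees are averaged into one reference curve.
    """
    values = np.mean([s.values for s in sset], axis=0)
    if label is None:
        label = f"mean({sset.group_key or len(sset)})"
    role = sset.spectra[0].role
    return Spectrum(sset.grid.copy(), values, label=label, role=role,
                    meta={"n_averaged": len(sset)})
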