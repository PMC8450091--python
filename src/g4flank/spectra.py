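"""CD spectra, the conformation index r, and difference spectra.

The topology of an intramolecular G-quadruplex is read off its circular
dichroism spectrum through the conformation index

    r = CD265 / (|CD265| + CD290)

where CD265 and CD290 are the ellipticities at 265 and 290 nm.  r >= 0.5 marks
a predominantly parallel ensemble, 0 <= r < 0.5 hybrid, and r < 0 antiparallel.
r is a ratio, so it is invariant to positive rescaling of the spectrum and to
the units it is recorded in (mdeg or molar ellipticity).

Thermal and isothermal difference spectra (TDS/IDS) — absorbance differences
between unfolded and folded states — are formed by the same pointwise
subtraction; the pipeline decides which spectrum is the minuend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CDSpectrum",
    "ConformationResult",
    "SpectrumError",
    "read_spectrum",
    "value_at",
    "conformation_index",
    "classify_r",
    "difference_spectrum",
]

PARALLEL = "parallel"
HYBRID = "hybrid"
ANTIPARALLEL = "antiparallel"
UNDEFINED = "undefined"

#: Quality flags attached to a ConformationResult.
FLAG_SMALL_DENOM = "small-denominator"
FLAG_NEGATIVE_290 = "negative-290"
FLAG_OUT_OF_RANGE = "out-of-range-r"
FLAG_EXTRAPOLATED = "extrapolated"


class SpectrumError(ValueError):
    """Raised for unreadable spectrum files or out-of-grid queries."""


@dataclass
class CDSpectrum:
    """A spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise SpectrumError("spectrum needs at least 2 wavelength points")
        if self.values.shape != self.wavelengths.shape:
            raise SpectrumError("wavelengths and values must have the same length")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(self.wavelengths)) and np.all(np.isfinite(self.values))):
            raise SpectrumError("spectrum contains non-finite entries")

    def scaled(self, k: float) -> "CDSpectrum":
        return CDSpectrum(self.wavelengths, k * self.values, dict(self.metadata))


@dataclass(frozen=True)
class ConformationResult:
    """Conformation index r with its band readings, class label and flags."""

    r: float
    cd265: float
    cd290: float
    label: str
    flags: frozenset = frozenset()
    sample_id: str | None = None


def read_spectrum(path, metadata: dict | None = None) -> CDSpectrum:
    """Read a two-column (wavelength, signal) delimited text file.

    The delimiter is auto-detected among comma, tab and semicolon.  A single
    leading header row is tolerated; any later non-numeric or non-finite row is
    an error naming the line.  Duplicate wavelengths are averaged and the grid
    is returned sorted ascending.
    """
    path = Path(path)
    text = path.read_text()
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        for delim in (",", "\t", ";"):
            if delim in line:
                parts = [p.strip() for p in line.split(delim)]
                break
        else:
            parts = line.split()
        parts = [p for p in parts if p]
        try:
            if len(parts) < 2:
                raise ValueError
            wl, val = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not rows:  # header row
                continue
            raise SpectrumError(f"{path.name}, line {lineno}: cannot parse {raw!r}")
        if not (np.isfinite(wl) and np.isfinite(val)):
            raise SpectrumError(f"{path.name}, line {lineno}: non-finite value in {raw!r}")
        rows.append((wl, val))
    if len(rows) < 2:
        raise SpectrumError(f"{path.name}: fewer than 2 usable data points")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # average duplicate wavelengths
    uniq, inverse = np.unique(arr[:, 0], return_inverse=True)
    vals = np.bincount(inverse, weights=arr[:, 1]) / np.bincount(inverse)
    return CDSpectrum(uniq, vals, metadata or {})


def _value_at(spectrum: CDSpectrum, wavelength_nm: float, margin: float = 2.0):
    """Linear interpolation; returns (value, extrapolated?).

    Queries beyond the grid by at most ``margin`` nm return the nearest
    endpoint value with the extrapolated marker set; farther out is an error.
    """
    wl = spectrum.wavelengths
    lo, hi = wl[0], wl[-1]
    if wavelength_nm < lo - margin or wavelength_nm > hi + margin:
        raise SpectrumError(
            f"wavelength {wavelength_nm} nm outside grid [{lo}, {hi}] by more than {margin} nm"
        )
    if wavelength_nm < lo:
        return float(spectrum.values[0]), True
    if wavelength_nm > hi:
        return float(spectrum.values[-1]), True
    return float(np.interp(wavelength_nm, wl, spectrum.values)), False


def value_at(spectrum: CDSpectrum, wavelength_nm: float, margin: float = 2.0) -> float:
    """Signal at a wavelength by linear interpolation between grid neighbours."""
    return _value_at(spectrum, wavelength_nm, margin)[0]


def classify_r(r: float) -> str:
    """Topology class of an r value: thresholds are closed exactly as stated.

    parallel iff r >= 0.5; hybrid iff 0 <= r < 0.5; antiparallel iff r < 0.
    Non-finite r is undefined.
    """
    if r is None or not np.isfinite(r):
        return UNDEFINED
    if r >= 0.5:
        return PARALLEL
    if r >= 0.0:
        return HYBRID
    return ANTIPARALLEL


def conformation_index(
    spectrum: CDSpectrum,
    *,
    eps_rel: float = 1e-6,
    margin: float = 2.0,
    sample_id: str | None = None,
) -> ConformationResult:
    """Compute r = CD265/(|CD265| + CD290) and classify the topology.

    The denominator tolerance is relative to the spectrum's dynamic range
    (``eps_rel`` x max |value|), so the result is unit-independent.  A
    denominator at or below that tolerance yields an undefined label with the
    small-denominator flag.  A negative 290 nm band is computed as-is but
    flagged, as is |r| > 1 (possible only with CD290 < 0).
    """
    flags = set()
    cd265, ex265 = _value_at(spectrum, 265.0, margin)
    cd290, ex290 = _value_at(spectrum, 290.0, margin)
    if ex265 or ex290:
        flags.add(FLAG_EXTRAPOLATED)
    if cd290 < 0:
        flags.add(FLAG_NEGATIVE_290)
    denom = abs(cd265) + cd290
    eps = eps_rel * float(np.max(np.abs(spectrum.values)))
    if denom <= eps:
        flags.add(FLAG_SMALL_DENOM)
        return ConformationResult(
            r=float("nan"), cd265=cd265, cd290=cd290,
            label=UNDEFINED, flags=frozenset(flags), sample_id=sample_id,
        )
    r = cd265 / denom
    if abs(r) > 1:
        flags.add(FLAG_OUT_OF_RANGE)
    return ConformationResult(
        r=r, cd265=cd265, cd290=cd290,
        label=classify_r(r), flags=frozenset(flags), sample_id=sample_id,
    )


def difference_spectrum(
    minuend: CDSpectrum,
    subtrahend: CDSpectrum,
    normalize: bool = False,
    margin: float = 0.0,
) -> CDSpectrum:
    """Pointwise minuend − subtrahend on the overlap of the two grids.

    Both spectra are resampled (linear interpolation) onto the union of their
    grid points restricted to the overlapping wavelength range.  With
    ``normalize`` the result is scaled so max |value| = 1 — the usual
    convention for presenting TDS/IDS signatures.
    """
    lo = max(minuend.wavelengths[0], subtrahend.wavelengths[0])
    hi = min(minuend.wavelengths[-1], subtrahend.wavelengths[-1])
    if lo > hi:
        raise SpectrumError("spectra have no overlapping wavelength range")
    grid = np.union1d(minuend.wavelengths, subtrahend.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        raise SpectrumError("overlap contains fewer than 2 grid points")
    a = np.interp(grid, minuend.wavelengths, minuend.values)
    b = np.interp(grid, subtrahend.wavelengths, subtrahend.values)
    diff = a - b
    if normalize:
        peak = np.max(np.abs(diff))
        if peak > 0:
            diff = diff / peak
    meta = {"difference": True, **{k: v for k, v in minuend.metadata.items() if k != "sample_id"}}
    return CDSpectrum(grid, diff, meta)


def results_to_frame(results) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate ConformationResults (sample_id, r, cd265, cd290, label, flags)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "r": [r.r for r in results],
            "cd265": [r.cd265 for r in results],
            "cd290": [r.cd290 for r in results],
            "label": [r.label for r in results],
            "flags": [";".join(sorted(r.flags)) for r in results],
        }
    )
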