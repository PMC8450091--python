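"""UV-melting curve analysis: Tm by first-derivative extremum.

The melting temperature is taken as the temperature at which |dA/dT| of the
UV-melting curve is maximal.  The derivative is computed by central finite
differences on an optionally moving-average-smoothed curve (first derivatives
amplify noise), and the grid extremum is refined by a three-point parabolic
fit so Tm is not quantized to the temperature step.  Because the extremum of
the *absolute* derivative is used, hyper- and hypochromic transitions give the
same Tm; the monitored wavelength (conventionally 295 nm for G-quadruplexes,
hypochromic on unfolding) is metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MeltingCurve",
    "MeltingResult",
    "MeltingError",
    "read_melting_curve",
    "first_derivative",
    "compute_tm",
    "delta_tm",
]

FLAG_MULTIPLE_EXTREMA = "multiple-extrema"
FLAG_EDGE_EXTREMUM = "edge-extremum"
FLAG_LOW_AMPLITUDE = "low-amplitude"


class MeltingError(ValueError):
    """Raised for unusable melting curves or invalid smoothing parameters."""


@dataclass
class MeltingCurve:
    """Absorbance vs temperature on a strictly increasing grid (degrees C)."""

    temperatures: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.temperatures.size < 5:
            raise MeltingError("melting curve needs at least 5 points")
        if self.absorbance.shape != self.temperatures.shape:
            raise MeltingError("temperature and absorbance lengths differ")
        if not np.all(np.diff(self.temperatures) > 0):
            raise MeltingError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise MeltingError("absorbance contains non-finite values")


@dataclass(frozen=True)
class MeltingResult:
    tm: float
    derivative: np.ndarray
    direction: str  # "hyperchromic" (dA/dT > 0 at Tm) or "hypochromic"
    flags: frozenset = frozenset()
    sample_id: str | None = None


def read_melting_curve(path, metadata: dict | None = None) -> MeltingCurve:
    """Read a two-column (temperature, absorbance) delimited file."""
    from .spectra import read_spectrum

    s = read_spectrum(path, metadata)
    return MeltingCurve(s.wavelengths, s.values, s.metadata)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # odd reflection keeps the smoothed series full-length and preserves
    # linear trends at the boundaries (no flattening bias)
    if window == 1:
        return y
    half = window // 2
    padded = np.pad(y, half, mode="reflect", reflect_type="odd")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def first_derivative(curve: MeltingCurve, smooth_window: int = 5) -> np.ndarray:
    """dA/dT on the full grid: central differences, one-sided at the ends.

    ``smooth_window`` is an odd moving-average width (1 = no smoothing) and
    must be smaller than the number of points.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise MeltingError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    if smooth_window >= curve.temperatures.size:
        raise MeltingError(
            f"smooth_window {smooth_window} >= number of points {curve.temperatures.size}"
        )
    smoothed = _moving_average(curve.absorbance, smooth_window)
    return np.gradient(smoothed, curve.temperatures)


def _parabolic_refine(T: np.ndarray, absd: np.ndarray, i: int, frac: float) -> float:
    """Vertex of a parabola fit to the contiguous peak region around index i.

    The region extends while |dA/dT| stays above ``frac`` of the peak value
    (at least the three points around the grid extremum).  Fitting the whole
    peak top rather than just three points keeps the refined Tm stable when
    the derivative peak is broad and shallow relative to the noise.
    """
    lo = i
    while lo > 0 and absd[lo - 1] >= frac * absd[i]:
        lo -= 1
    hi = i
    while hi < T.size - 1 and absd[hi + 1] >= frac * absd[i]:
        hi += 1
    if hi - lo < 2:
        lo, hi = max(i - 1, 0), min(i + 1, T.size - 1)
    c2, c1, _ = np.polyfit(T[lo : hi + 1], absd[lo : hi + 1], 2)
    if c2 >= 0:  # degenerate fit: keep the grid point
        return float(T[i])
    vertex = -c1 / (2 * c2)
    if not (T[lo] <= vertex <= T[hi]):
        return float(T[i])
    return float(vertex)


def compute_tm(
    curve: MeltingCurve,
    smooth_window: int = 5,
    *,
    refine_frac: float = 0.6,
    extrema_band: float = 0.9,
    low_amp_factor: float = 2.0,
    sample_id: str | None = None,
) -> MeltingResult:
    """Tm = temperature of the global |dA/dT| extremum, parabolically refined.

    The refinement fits a parabola to the contiguous region where |dA/dT|
    stays above ``refine_frac`` of its peak (at least three points), so Tm is
    neither quantized to the grid nor thrown by point noise on a broad peak.

    Quality flags: ``multiple-extrema`` when another local maximum of |dA/dT|
    reaches ``extrema_band`` (default 90%) of the global one; ``edge-extremum``
    when the extremum sits at the first or last interior grid point;
    ``low-amplitude`` when the peak derivative does not stand out from its
    background (max |dA/dT| <= ``low_amp_factor`` x mean |dA/dT|), as for a
    featureless or purely linear curve.
    """
    d = first_derivative(curve, smooth_window)
    T = curve.temperatures
    absd = np.abs(d)
    interior = slice(1, T.size - 1)
    i = 1 + int(np.argmax(absd[interior]))

    flags = set()
    if i == 1 or i == T.size - 2:
        flags.add(FLAG_EDGE_EXTREMUM)
        tm = float(T[i])
    else:
        tm = _parabolic_refine(T, absd, i, refine_frac)

    # other strict local maxima of |dA/dT| nearly as tall as the global one
    local_max = (absd[1:-1] >= absd[:-2]) & (absd[1:-1] >= absd[2:])
    tall = np.flatnonzero(local_max & (absd[1:-1] >= extrema_band * absd[i])) + 1
    if np.any(np.abs(tall - i) > 1):
        flags.add(FLAG_MULTIPLE_EXTREMA)

    if absd[i] <= low_amp_factor * float(np.mean(absd)):
        flags.add(FLAG_LOW_AMPLITUDE)

    direction = "hyperchromic" if d[i] > 0 else "hypochromic"
    return MeltingResult(
        tm=tm, derivative=d, direction=direction,
        flags=frozenset(flags), sample_id=sample_id,
    )


def delta_tm(flanked: MeltingResult | float, bare: MeltingResult | float) -> float:
    """Tm(flanked) − Tm(bare); negative means the flanks destabilize the fold."""
    tf = flanked.tm if isinstance(flanked, MeltingResult) else float(flanked)
    tb = bare.tm if isinstance(bare, MeltingResult) else float(bare)
    return tf - tb
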