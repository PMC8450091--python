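"""Synthetic CD spectra, melting curves and whole flanking-effect experiments.

Every pipeline stage needs data with known ground truth.  This module supplies
three generators:

* **Basis spectra** — each topology (parallel, antiparallel, hybrid) is a sum
  of Gaussian bands chosen so that the conformation index of the pure basis
  lands in the correct class (a construction-time gate): the parallel basis
  has its positive band near 264 nm, the antiparallel one a positive band near
  292 nm with a negative 265 nm band, the hybrid one positive bands at both.
  Observed spectra are convex mixtures of the bases plus Gaussian noise — the
  standard linear-ensemble assumption for CD.

* **Two-state melting curves** — a van't Hoff folded fraction
  θ(T) = 1 / (1 + exp[(ΔH/R)(1/T − 1/Tm)]) (T in kelvin, ΔH < 0 for folding,
  R = 1.987e-3 kcal/(mol·K)), mixed between linear folded/unfolded baselines;
  θ(Tm) = 1/2 exactly.

* **Flanking-effect experiments** — paired bare/flanked designs whose
  topology-fraction triples are drawn around a category baseline (categories
  by shortest-loop position: 1bc, a1c, ab1, none) and, for the flanked member,
  shifted toward parallel by shift5·sat(L5) + shift3·sat(L3) with
  sat(L) = 1 − 2^−L, scaled by a per-category sensitivity.  The saturating
  form puts half of the maximal effect on the first flanking nucleotide, and
  shift5 > shift3 encodes the 5′ > 3′ asymmetry of the flanking effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import OligoDesign, shortest_loop_category
from .melting import MeltingCurve
from .spectra import CDSpectrum, conformation_index

__all__ = [
    "GaussianBand",
    "BasisModel",
    "TwoStateParams",
    "FlankingEffectModel",
    "Experiment",
    "basis_spectrum",
    "mix_spectra",
    "synth_melting",
    "synth_experiment",
    "make_pairs",
    "saturation",
    "R_GAS",
]

#: Gas constant in kcal/(mol*K).
R_GAS = 1.987e-3

TOPOLOGIES = ("parallel", "hybrid", "antiparallel")


@dataclass(frozen=True)
class GaussianBand:
    center: float  # nm
    width: float  # nm (Gaussian sigma)
    amplitude: float  # signed, arbitrary units


_DEFAULT_BANDS = {
    "parallel": (
        GaussianBand(264.0, 9.0, 1.00),
        GaussianBand(242.0, 8.0, -0.45),
    ),
    "antiparallel": (
        GaussianBand(292.0, 10.0, 0.70),
        GaussianBand(265.0, 9.0, -0.55),
        GaussianBand(245.0, 8.0, 0.35),
    ),
    "hybrid": (
        GaussianBand(290.0, 10.0, 0.65),
        GaussianBand(268.0, 9.0, 0.55),
        GaussianBand(242.0, 8.0, -0.35),
    ),
}


@dataclass(frozen=True)
class BasisModel:
    """Gaussian-band basis spectra for the three topologies.

    Construction is gated on self-consistency: the pure parallel basis must
    give r >= 0.9, the pure antiparallel basis r < 0, and the pure hybrid
    basis 0 <= r < 0.5 under the conformation index.  Band parameters carry no
    claim of spectroscopic accuracy — only the band-position logic that the
    index reads (265 vs 290 nm) matters.
    """

    bands: dict = field(default_factory=lambda: dict(_DEFAULT_BANDS))
    wl_min: float = 220.0
    wl_max: float = 320.0
    step: float = 1.0

    def __post_init__(self) -> None:
        missing = set(TOPOLOGIES) - set(self.bands)
        if missing:
            raise ValueError(f"basis model lacks topologies: {sorted(missing)}")
        if self.step <= 0 or self.wl_max <= self.wl_min:
            raise ValueError("invalid wavelength grid")
        checks = {
            "parallel": lambda r: r >= 0.9,
            "antiparallel": lambda r: r < 0,
            "hybrid": lambda r: 0 <= r < 0.5,
        }
        for topo, ok in checks.items():
            r = conformation_index(basis_spectrum(topo, self)).r
            if not ok(r):
                raise ValueError(
                    f"basis spectrum for {topo} has r = {r:.3f}, outside its class"
                )

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.wl_max - self.wl_min) / self.step)) + 1
        return self.wl_min + self.step * np.arange(n)


def basis_spectrum(topology: str, model: BasisModel | None = None) -> CDSpectrum:
    """Evaluate the Gaussian-band basis of one topology on the model grid."""
    if model is None:
        model = BasisModel()
    if topology not in model.bands:
        raise ValueError(f"unknown topology {topology!r}")
    wl = model.grid
    vals = np.zeros_like(wl)
    for band in model.bands[topology]:
        vals += band.amplitude * np.exp(-0.5 * ((wl - band.center) / band.width) ** 2)
    return CDSpectrum(wl, vals, {"topology": topology, "units": "a.u."})


def mix_spectra(
    fractions: Sequence[float],
    model: BasisModel | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> CDSpectrum:
    """Convex mixture of the (parallel, hybrid, antiparallel) bases plus noise.

    ``fractions`` must lie on the simplex to within 1e-9.  Noise is i.i.d.
    Gaussian per grid point; pass a seeded generator for reproducibility.
    """
    if model is None:
        model = BasisModel()
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,) or np.any(f < -1e-9) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions!r} are not on the simplex")
    rng = np.random.default_rng(rng)
    wl = model.grid
    vals = np.zeros_like(wl)
    for frac, topo in zip(f, TOPOLOGIES):
        if frac != 0.0:
            vals += frac * basis_spectrum(topo, model).values
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=wl.size)
    meta = {"fractions": tuple(float(x) for x in f), "units": "a.u."}
    return CDSpectrum(wl, vals, meta)


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state van't Hoff melting parameters.

    ``dH`` is the folding enthalpy in kcal/mol (negative).  Baselines are
    (intercept, slope-per-degree) pairs for the folded and unfolded states at
    the monitored wavelength; the defaults are hypochromic on unfolding, as at
    295 nm for G-quadruplexes.
    """

    tm_true: float  # degrees C
    dH: float = -40.0  # kcal/mol, folding
    baseline_folded: tuple[float, float] = (1.00, -0.0002)
    baseline_unfolded: tuple[float, float] = (0.75, 0.0001)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.dH >= 0:
            raise ValueError(f"folding enthalpy must be negative, got {self.dH}")


def folded_fraction(params: TwoStateParams, temperatures_c: np.ndarray) -> np.ndarray:
    """θ(T) for the two-state model; θ(Tm) = 1/2 exactly."""
    t_k = np.asarray(temperatures_c, dtype=float) + 273.15
    tm_k = params.tm_true + 273.15
    return 1.0 / (1.0 + np.exp((params.dH / R_GAS) * (1.0 / t_k - 1.0 / tm_k)))


def synth_melting(
    params: TwoStateParams,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    metadata: dict | None = None,
) -> MeltingCurve:
    """Simulate a UV-melting curve from two-state van't Hoff parameters."""
    if grid is None:
        grid = np.arange(20.0, 96.0, 0.5)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 5:
        raise ValueError("temperature grid needs at least 5 points")
    if not (grid[0] <= params.tm_true <= grid[-1]):
        raise ValueError(
            f"tm_true {params.tm_true} outside simulated range [{grid[0]}, {grid[-1]}]"
        )
    theta = folded_fraction(params, grid)
    bf = params.baseline_folded[0] + params.baseline_folded[1] * grid
    bu = params.baseline_unfolded[0] + params.baseline_unfolded[1] * grid
    absorbance = theta * bf + (1.0 - theta) * bu
    if params.noise_sd > 0:
        rng = np.random.default_rng(rng)
        absorbance = absorbance + rng.normal(0.0, params.noise_sd, size=grid.size)
    meta = {"wavelength_nm": 295, "tm_true": params.tm_true}
    if metadata:
        meta.update(metadata)
    return MeltingCurve(grid, absorbance, meta)


def saturation(length: int) -> float:
    """Flank-length saturation 1 − 2^−L: the first nucleotide carries half."""
    if length < 0:
        raise ValueError("flank length must be >= 0")
    return 1.0 - 2.0 ** (-length)


_K_BASELINES = {
    "1bc": (0.20, 0.45, 0.35),
    "a1c": (0.60, 0.30, 0.10),
    "ab1": (0.30, 0.50, 0.20),
    "none": (0.35, 0.40, 0.25),
}
_NA_BASELINES = {
    "1bc": (0.03, 0.25, 0.72),
    "a1c": (0.10, 0.35, 0.55),
    "ab1": (0.05, 0.30, 0.65),
    "none": (0.04, 0.28, 0.68),
}
_SENSITIVITY = {"1bc": 0.6, "a1c": 1.0, "ab1": 1.0, "none": 0.85}


@dataclass(frozen=True)
class FlankingEffectModel:
    """Ground-truth model for a synthetic flanking-effect experiment.

    ``baselines`` maps each shortest-loop category to its bare
    (parallel, hybrid, antiparallel) fraction triple; ``sensitivity`` scales
    the parallel shift per category (the 1bc category — shortest loop at the
    5′ end — responds least).  ``shift5`` must exceed ``shift3 >= 0``: the
    model encodes a stronger 5′-end effect by construction.
    """

    baselines: dict = field(default_factory=lambda: dict(_K_BASELINES))
    sensitivity: dict = field(default_factory=lambda: dict(_SENSITIVITY))
    shift5: float = 0.35
    shift3: float = 0.05
    fraction_jitter: float = 0.08
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.shift5 > self.shift3 >= 0):
            if not (self.shift5 == self.shift3 == 0):
                raise ValueError(
                    f"need shift5 > shift3 >= 0 (or both zero), got {self.shift5}, {self.shift3}"
                )
        for cat, triple in self.baselines.items():
            t = np.asarray(triple, dtype=float)
            if t.shape != (3,) or np.any(t < 0) or abs(t.sum() - 1.0) > 1e-9:
                raise ValueError(f"baseline for {cat!r} is off the simplex: {triple!r}")

    @classmethod
    def for_cation(cls, cation: str, **kw) -> "FlankingEffectModel":
        """Preset conditions: K+ (parallel/hybrid-rich) or Na+ (antiparallel-rich).

        The Na+ preset starts antiparallel-heavy and shifts harder, mirroring
        the larger topology conversions seen in sodium.
        """
        cation = cation.upper().rstrip("+")
        if cation == "K":
            return cls(**kw)
        if cation == "NA":
            kw.setdefault("shift5", 0.40)
            kw.setdefault("shift3", 0.08)
            return cls(baselines=dict(_NA_BASELINES), **kw)
        raise ValueError(f"unknown cation {cation!r}")

    def shifted(self, fractions: Sequence[float], flank5_len: int, flank3_len: int,
                category: str) -> np.ndarray:
        """Apply the parallel shift to a fraction triple, clipped to the simplex."""
        p, h, a = (float(x) for x in fractions)
        s = self.sensitivity.get(category, 1.0) * (
            self.shift5 * saturation(flank5_len) + self.shift3 * saturation(flank3_len)
        )
        p_new = min(p + s, 1.0)
        rest = h + a
        scale = (1.0 - p_new) / rest if rest > 0 else 0.0
        return np.array([p_new, h * scale, a * scale])


@dataclass
class Experiment:
    """A generated experiment: manifest, per-sample data, and the truth table."""

    manifest: pd.DataFrame
    spectra: dict
    truth: pd.DataFrame
    melting: dict = field(default_factory=dict)

    def write(self, outdir) -> Path:
        """Emit the CSV spectrum/melting files, manifest.csv and truth.csv."""
        outdir = Path(outdir)
        (outdir / "spectra").mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        for sid, spec in self.spectra.items():
            rel = f"spectra/{sid}.csv"
            pd.DataFrame(
                {"wavelength_nm": spec.wavelengths, "ellipticity": spec.values}
            ).to_csv(outdir / rel, index=False)
            manifest.loc[manifest.sample_id == sid, "spectrum_file"] = rel
        if self.melting:
            (outdir / "melting").mkdir(exist_ok=True)
            for sid, curve in self.melting.items():
                rel = f"melting/{sid}.csv"
                pd.DataFrame(
                    {"temperature_c": curve.temperatures, "absorbance": curve.absorbance}
                ).to_csv(outdir / rel, index=False)
                manifest.loc[manifest.sample_id == sid, "melting_file"] = rel
        manifest.to_csv(outdir / "manifest.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        return outdir / "manifest.csv"


def make_pairs(
    groups: Iterable, flank_scheme: str = "DT2", n_pairs: int | None = None
) -> list[tuple[OligoDesign, OligoDesign]]:
    """Enumerate (bare, flanked) design pairs from loop multisets.

    ``groups`` is an iterable of loop multisets (e.g. ``[(1,3,6), (2,4,4)]``);
    each expands to its loop permutations under both the bare (WO) scheme and
    ``flank_scheme``.  ``n_pairs`` truncates the list after enumeration.
    """
    from .design import enumerate_group

    pairs: list[tuple[OligoDesign, OligoDesign]] = []
    for ms in groups:
        bare = enumerate_group(ms, "WO")
        flanked = enumerate_group(ms, flank_scheme)
        pairs.extend(zip(bare, flanked))
    if n_pairs is not None:
        pairs = pairs[:n_pairs]
    return pairs


def _jittered_simplex(base: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    f = np.clip(base + rng.normal(0.0, jitter, size=3), 0.0, None)
    total = f.sum()
    if total <= 0:  # pathological jitter; fall back to the baseline
        return base.copy()
    return f / total


def synth_experiment(
    pairs: Sequence[tuple[OligoDesign, OligoDesign]],
    effect: FlankingEffectModel | None = None,
    *,
    basis: BasisModel | None = None,
    cation: str = "K",
    include_melting: bool = False,
    rng: np.random.Generator | int | None = None,
) -> Experiment:
    """Generate spectra (and optionally melting curves) for bare/flanked pairs.

    For each pair the bare member's topology fractions are drawn around its
    category baseline; the flanked member draws its own jitter (two separately
    prepared oligos) and then receives the parallel shift.  The truth table
    records both fraction triples and the planted Δ(parallel fraction).
    """
    if effect is None:
        effect = FlankingEffectModel()
    if basis is None:
        basis = BasisModel()
    if not pairs:
        raise ValueError("synth_experiment needs at least one (bare, flanked) pair")
    for bare, flanked in pairs:
        if bare.flank5 or bare.flank3:
            raise ValueError(f"bare member {bare.name!r} has flanks")
        if not (flanked.flank5 or flanked.flank3):
            raise ValueError(f"flanked member {flanked.name!r} has no flanks")
    rng = np.random.default_rng(effect.seed if rng is None else rng)

    man_rows, truth_rows = [], []
    spectra: dict[str, CDSpectrum] = {}
    melting: dict[str, MeltingCurve] = {}
    for idx, (bare, flanked) in enumerate(pairs):
        cat = shortest_loop_category(bare)
        base = np.asarray(effect.baselines[cat], dtype=float)
        f_bare = _jittered_simplex(base, effect.fraction_jitter, rng)
        f_flanked = effect.shifted(
            _jittered_simplex(base, effect.fraction_jitter, rng),
            len(flanked.flank5), len(flanked.flank3), cat,
        )
        pair_id = f"p{idx:03d}_{bare.name}"
        group_id = "".join(str(n) for n in sorted(bare.loops))
        tm_bare = float(rng.uniform(45.0, 65.0)) if include_melting else None
        for role, design, fracs in (
            ("bare", bare, f_bare), ("flanked", flanked, f_flanked)
        ):
            sid = f"{pair_id}_{role}"
            spectra[sid] = mix_spectra(fracs, basis, effect.noise_sd, rng)
            man_rows.append(
                {
                    "sample_id": sid,
                    "name_or_sequence": design.name,
                    "flank5": design.flank5,
                    "flank3": design.flank3,
                    "cation": cation,
                    "spectrum_file": "",
                    "melting_file": "",
                    "pair_id": pair_id,
                    "group_id": group_id,
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "pair_id": pair_id,
                    "role": role,
                    "category": cat,
                    "f_parallel": fracs[0],
                    "f_hybrid": fracs[1],
                    "f_antiparallel": fracs[2],
                }
            )
            if include_melting:
                tm = tm_bare
                if role == "flanked":  # flanks mildly destabilize, paired to the bare Tm
                    tm = max(30.0, tm_bare + float(rng.normal(-2.0, 1.5)))
                params = TwoStateParams(tm_true=tm, dH=-40.0, noise_sd=0.002)
                melting[sid] = synth_melting(params, rng=rng, metadata={"sample_id": sid})
        truth_rows[-2]["delta_parallel_true"] = np.nan
        truth_rows[-1]["delta_parallel_true"] = f_flanked[0] - f_bare[0]

    manifest = pd.DataFrame(man_rows)
    truth = pd.DataFrame(truth_rows)
    return Experiment(manifest=manifest, spectra=spectra, truth=truth, melting=melting)
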