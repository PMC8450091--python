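# Methods

## Conformation index and classification

The conformation index is computed from single-wavelength readings:
r = CD265 / (|CD265| + CD290), with CD265 and CD290 obtained by linear
interpolation between the two bracketing grid points at exactly 265 and
290 nm. No band integration or smoothing is applied — r is defined on point
ellipticities, and smoothing would silently change the statistic. Queries up
to 2 nm beyond the recorded grid return the nearest endpoint with an
`extrapolated` flag; farther out is an error.

Class boundaries are closed exactly as the statistic is defined: parallel
r ≥ 0.5, hybrid 0 ≤ r < 0.5, antiparallel r < 0. There is no hysteresis band.
Because r is a ratio, it is invariant to any positive rescaling of the
spectrum, so raw millidegrees and molar ellipticity give identical results;
the unit is only recorded as metadata.

Degenerate denominators are flagged rather than patched. The tolerance is
relative to the spectrum's dynamic range (default 10⁻⁶ × max |value|) so it
is unit-independent. |CD265| + CD290 at or below the tolerance (possible only
with a strongly negative 290 nm band) yields an undefined label with a
`small-denominator` flag; a negative CD290 is used as-is with a
`negative-290` flag, and |r| > 1 is flagged `out-of-range-r`. These flags
propagate into the output tables so a batch is auditable.

## Library design

Model sequences render as flank5 + (G-tract + T-loop)×3 + G-tract + flank3
with G-tract length 3 by default (minimum 2) and single-digit loop codes;
the model library constraint (loop lengths 1–6, total loop length 7–13) is
exposed via `enumerate_loop_multisets`. A loop-permutation group enumerates
the distinct orderings of a loop multiset (6, 3 or 1 members), in
lexicographic order. Shortest-loop categories are defined only for a unique
length-1 minimum: `1bc`, `a1c`, `ab1` by position, `none` otherwise.
Natural sequences bypass the grammar: the manifest may carry an explicit
sequence with explicit flank annotations, and pairing is always explicit via
`pair_id`, never inferred from names. The flank base defaults to thymine but
is overridable per design; a 5′-terminal phosphate is a bookkeeping flag that
does not change the rendered sequence.

## Melting analysis

Tm is the temperature of the global extremum of |dA/dT|. The derivative is a
central finite difference (one-sided at the ends) of the moving-average
smoothed absorbance; the default window is 5 points, and the padding used for
smoothing is an odd reflection so linear baselines are not distorted at the
edges. The grid extremum is refined by fitting a parabola to the contiguous
region where |dA/dT| stays within 60% of its peak (at least three points).
Fitting the whole peak top rather than three points keeps Tm stable when the
transition is broad and shallow relative to the noise; the price is a small
systematic offset (≲0.2 °C on the broadest peaks) toward the symmetric
center of a skewed peak. For shallow transitions (|ΔH| near 30 kcal/mol) a
9-point window is the recommended analysis setting and is what the recovery
analyses use.

Using |dA/dT| makes the estimate independent of transition direction
(hyper- vs hypochromic) and of affine transforms of the absorbance. Quality
flags: `multiple-extrema` when a second local maximum reaches 90% of the
global one, `edge-extremum` at the grid boundary, and `low-amplitude` when
the peak does not exceed twice the mean |dA/dT| (featureless curves). ΔTm is
Tm(flanked) − Tm(bare); negative values mean destabilization by the flanks.
No van't Hoff enthalpy or baseline fitting is attempted on measured curves.

## Flanking-effect statistics

Δr = r(flanked) − r(bare) per explicit pair; pairs with an undefined r are
excluded and counted. Group spread uses the population formula
σ = √(Σ(rᵢ−μ)²/N) — divisor N, matching the reporting convention for group
heterogeneity — while the paired t-test uses the sample standard deviation
(divisor n−1) as standard. Proportion tables report percentages to one
decimal over classified results only. The positive-Δr fraction counts
strictly positive values; zeros are non-positive.

Paired two-sided t-tests run overall, per shortest-loop category, and per
baseline topology class. A zero-variance difference vector is reported as
degenerate (p = 0 for a nonzero constant shift, p = 1 for identity) rather
than dividing by zero. Stars: *** p < 0.001, ** p < 0.01, * p < 0.05, ns
otherwise. No multiple-testing correction is applied by default (the raw
per-test p-values are the deliverable); Holm adjustment is available behind
a flag.

## Synthetic data

**Basis spectra.** Each topology is a sum of Gaussian bands on a 220–320 nm
grid (1 nm step): parallel +1.00@264/−0.45@242; antiparallel
+0.70@292/−0.55@265/+0.35@245; hybrid +0.65@290/+0.55@268/−0.35@242
(amplitude@center, widths 8–10 nm, arbitrary units). The parameters carry no
claim of spectroscopic accuracy; they are fixed defaults that satisfy a
construction-time gate — the pure parallel basis must give r ≥ 0.9, the
antiparallel basis r < 0, the hybrid basis 0 ≤ r < 0.5 — so only the
265/290 nm band logic that r reads is modeled. Observed spectra are convex
mixtures of the bases plus i.i.d. Gaussian noise per grid point (default
sd 0.02 in basis units), the standard linear-ensemble assumption for CD.
Along the parallel–antiparallel edge of the simplex, r is strictly
increasing in the parallel fraction.

**Melting curves.** Two-state van't Hoff model: folded fraction
θ(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/Tm)]) with T in kelvin,
R = 1.987×10⁻³ kcal/(mol·K), and ΔH < 0 for folding, so θ → 1 cold, θ → 0
hot, and θ(Tm) = ½ exactly. Absorbance interpolates between linear folded
and unfolded baselines (defaults 1.00 − 2×10⁻⁴·T and 0.75 + 10⁻⁴·T,
hypochromic on unfolding as at 295 nm). Note that the |dA/dT| extremum of
this model sits slightly *below* the θ = ½ temperature (≈0.35 °C at
ΔH = −40 kcal/mol, more for shallower transitions) — an intrinsic skew of
the derivative-peak definition of Tm, not an estimator artifact.

**Flanking-effect experiments.** Each bare/flanked pair belongs to a
shortest-loop category with a baseline (parallel, hybrid, antiparallel)
fraction triple; the K⁺-like preset is hybrid/parallel-leaning
(e.g. 1bc → 0.20/0.45/0.35, a1c → 0.60/0.30/0.10), the Na⁺-like preset is
antiparallel-heavy (e.g. 1bc → 0.03/0.25/0.72). Both members draw
independent jitter (sd 0.08 per component, renormalized) around the
baseline — emulating two separately prepared and measured oligos — and the
flanked member's parallel fraction is then shifted by
sens(category) × [shift5·(1−2^−L5) + shift3·(1−2^−L3)], clipped to the
simplex with the remaining mass scaled proportionally. The saturating form
puts half of the maximal effect on the first flanking nucleotide; defaults
shift5 = 0.35 > shift3 = 0.05 encode the 5′ > 3′ asymmetry, and the category
sensitivities (1bc 0.6; a1c, ab1 1.0; none 0.85) encode the weaker response
of sequences whose first loop is the shortest. All generators are
reproducible bit-for-bit given a seed.

What the generator does *not* emulate: instrument baseline drift and
wavelength-dependent noise, non-two-state (multi-transition or hysteretic)
melting, inter-quadruplex multimerization, cation-specific spectral shapes
beyond the baseline composition, and any quantitative map from true ensemble
fractions to measured ellipticities. Passing tests on synthetic data
therefore validate the pipeline's arithmetic, classification logic and
statistical machinery — not the spectroscopy of any particular sequence.

## Problem sizes and determinism

The standard analyses run at: 90 pairs for the end-to-end flanking
experiments, 100 curves for Tm-recovery (Tm ~ U(40, 70) °C,
ΔH ~ U(−60, −30) kcal/mol, noise sd 0.002, 0.5 °C grid), and 50 replicates
of 30 pairs for the zero-shift type-I control. These sizes give stable
summary statistics (positive-Δr fractions vary by a few percent across
seeds) while keeping a full run in seconds. Every random draw flows from an
explicit seed; the acceptance script derives independent sub-seeds from a
single `--seed` via a seed sequence.

## Known limitations

- r compresses the ensemble to one number; mixtures with strong hybrid
  character can sit near a class boundary, and the heat-map tables are the
  intended remedy, not a deconvolution.
- The derivative-peak Tm inherits the skew described above; comparisons of
  ΔTm between curves of similar shape are unaffected.
- The fraction-to-r map of the generator is internally consistent but not
  calibrated against measured ensembles; synthetic positive-Δr fractions
  land in the 95–99% range at the default shift, at the optimistic end of
  what mixed model/natural libraries show.
- Only single-digit loop codes parse; longer loops require explicit
  sequences through the manifest route.
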