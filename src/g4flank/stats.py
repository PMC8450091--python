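"""Flanking-effect statistics.

Given conformation-index results for paired bare/flanked oligonucleotides,
this module computes the quantities the flanking-effect analysis reports:

* Δr = r(flanked) − r(bare) per pair; positive Δr means parallelization;
* group mean and population spread σ = sqrt(Σ(x_i − μ)² / N) over a
  loop-permutation group (divisor N, not N−1, matching the reporting
  convention of the analysis);
* topology-proportion tables (percentages to one decimal);
* the fraction of pairs with strictly positive Δr;
* two-sided paired t-tests with the star convention
  *** p < 0.001, ** p < 0.01, * p < 0.05, ns otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectra import ANTIPARALLEL, HYBRID, PARALLEL, UNDEFINED, ConformationResult, classify_r

__all__ = [
    "PairComparison",
    "GroupReport",
    "TestResult",
    "Proportions",
    "pair_delta_r",
    "group_sigma",
    "group_report",
    "proportion_table",
    "positive_fraction",
    "paired_t_test",
    "significance_stars",
    "classification_matrix",
    "holm_adjust",
]


@dataclass(frozen=True)
class PairComparison:
    """A bare/flanked pair with its r values and Δr (and optionally ΔTm)."""

    pair_id: str
    condition_bare: str
    condition_flanked: str
    r_bare: float
    r_flanked: float
    delta_r: float
    label_bare: str
    label_flanked: str
    tm_bare: float | None = None
    tm_flanked: float | None = None
    delta_tm: float | None = None

    @classmethod
    def from_r(
        cls,
        pair_id: str,
        r_bare: float,
        r_flanked: float,
        condition_bare: str = "WO",
        condition_flanked: str = "W",
        **kw,
    ) -> "PairComparison":
        return cls(
            pair_id=pair_id,
            condition_bare=condition_bare,
            condition_flanked=condition_flanked,
            r_bare=r_bare,
            r_flanked=r_flanked,
            delta_r=pair_delta_r(r_flanked, r_bare),
            label_bare=classify_r(r_bare),
            label_flanked=classify_r(r_flanked),
            **kw,
        )


@dataclass(frozen=True)
class GroupReport:
    group_id: str
    values: tuple
    mean: float
    sigma: float
    n: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    name: str = "paired t-test"
    stars: str = "ns"
    degenerate: bool = False


@dataclass(frozen=True)
class Proportions:
    """Topology proportions over classified results; percentages to 1 decimal."""

    counts: dict
    n: int
    n_undefined: int = 0

    @property
    def fractions(self) -> dict:
        return {k: v / self.n for k, v in self.counts.items()}

    @property
    def percentages(self) -> dict:
        return {k: round(100.0 * v / self.n, 1) for k, v in self.counts.items()}


def pair_delta_r(r_flanked: float, r_bare: float) -> float:
    """Δr = r(flanked) − r(bare); both must be finite."""
    if not (np.isfinite(r_flanked) and np.isfinite(r_bare)):
        raise ValueError(
            f"undefined r in pair (flanked={r_flanked}, bare={r_bare}); exclude the pair"
        )
    return float(r_flanked) - float(r_bare)


def group_sigma(values) -> float:
    """Population spread sigma = sqrt(sum((x_i - mu)^2) / N), divisor N."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("group_sigma of an empty group")
    return float(np.std(arr, ddof=0))


def group_report(group_id: str, values) -> GroupReport:
    vals = tuple(float(v) for v in values)
    return GroupReport(
        group_id=group_id,
        values=vals,
        mean=float(np.mean(vals)),
        sigma=group_sigma(vals),
        n=len(vals),
    )


def proportion_table(results) -> Proportions:
    """Proportions of parallel/hybrid/antiparallel among classified results.

    Accepts ConformationResults or bare label strings.  Undefined labels are
    excluded from the denominator and counted separately.
    """
    labels = [r.label if isinstance(r, ConformationResult) else str(r) for r in results]
    if not labels:
        raise ValueError("proportion_table of an empty result list")
    n_undef = sum(1 for lab in labels if lab == UNDEFINED)
    kept = [lab for lab in labels if lab != UNDEFINED]
    if not kept:
        raise ValueError("proportion_table: every result is unclassified")
    counts = {k: kept.count(k) for k in (PARALLEL, HYBRID, ANTIPARALLEL)}
    return Proportions(counts=counts, n=len(kept), n_undefined=n_undef)


def positive_fraction(deltas) -> tuple[int, int, float]:
    """(count of Δ > 0, n, percentage to one decimal); zeros are not positive."""
    arr = np.asarray(list(deltas), dtype=float)
    if arr.size == 0:
        raise ValueError("positive_fraction of an empty list")
    pos = int(np.sum(arr > 0))
    return pos, int(arr.size), round(100.0 * pos / arr.size, 1)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_t_test(values_flanked, values_bare) -> TestResult:
    """Two-sided paired t-test of flanked vs bare values.

    t = mean(d) / (sd(d)/sqrt(n)) with sample sd (divisor n−1) and n−1 degrees
    of freedom.  A zero-variance difference vector is degenerate: p = 0 when
    the constant difference is nonzero (the shift is certain under the model),
    p = 1 when it is identically zero.
    """
    a = np.asarray(list(values_flanked), dtype=float)
    b = np.asarray(list(values_bare), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        mean = float(np.mean(d))
        p = 0.0 if mean != 0.0 else 1.0
        t = math.inf * np.sign(mean) if mean != 0.0 else 0.0
        return TestResult(
            statistic=float(t), p_value=p, n=n,
            stars=significance_stars(p), degenerate=True,
        )
    t, p = sps.ttest_rel(a, b)
    return TestResult(statistic=float(t), p_value=float(p), n=n, stars=significance_stars(float(p)))


def holm_adjust(p_values) -> list[float]:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(list(p_values), method="holm")[1])


def classification_matrix(pairs, cation: str | None = None) -> pd.DataFrame:
    """Long-format (sequence, condition, r, label) table, heat-map-ready.

    Two rows per pair (bare then flanked); the labels re-derive from r via
    classify_r so the table is self-consistent.
    """
    rows = []
    for p in pairs:
        rows.append(
            {"sequence": p.pair_id, "condition": p.condition_bare,
             "r": p.r_bare, "label": classify_r(p.r_bare)}
        )
        rows.append(
            {"sequence": p.pair_id, "condition": p.condition_flanked,
             "r": p.r_flanked, "label": classify_r(p.r_flanked)}
        )
    df = pd.DataFrame(rows, columns=["sequence", "condition", "r", "label"])
    if cation is not None:
        df["cation"] = cation
    return df
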