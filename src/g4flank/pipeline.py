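"""Manifest-driven orchestration: classify, melt, and run the flanking stats.

A run starts from a manifest CSV with the columns

    sample_id, name_or_sequence, flank5, flank3, cation,
    spectrum_file, melting_file, pair_id, group_id

where file paths are relative to the manifest's directory.  Rows sharing a
``pair_id`` form a bare/flanked pair: the bare member is the row without
flanks.  Pairing is always explicit via ``pair_id`` — never inferred from
name similarity — so natural (non-model) sequences are first-class.

Processing is forgiving per row: unreadable files are logged and skipped so a
batch does not die on one bad spectrum; callers receive the failures next to
the results and the CLI maps them to exit status 2 (partial success).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import melting as melt_mod
from . import spectra as spec_mod
from . import stats as stats_mod
from .design import parse_name, shortest_loop_category

__all__ = [
    "RunConfig",
    "MANIFEST_COLUMNS",
    "read_manifest",
    "run_classify",
    "run_melt",
    "run_stats",
]

MANIFEST_COLUMNS = [
    "sample_id",
    "name_or_sequence",
    "flank5",
    "flank3",
    "cation",
    "spectrum_file",
    "melting_file",
    "pair_id",
    "group_id",
]


@dataclass
class RunConfig:
    """Knobs for a pipeline run; every CLI flag maps onto one field."""

    manifest: Path
    outdir: Path
    cation: str | None = None  # filter; None = all rows
    smooth_window: int = 5  # moving-average width for dA/dT
    margin: float = 2.0  # nm of tolerated extrapolation at 265/290
    eps_rel: float = 1e-6  # relative denominator tolerance for r
    seed: int = 0
    holm: bool = False  # Holm-adjust the paired-test p-values
    normalize_diff: bool = False

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.outdir = Path(self.outdir)
        if self.margin <= 0 or self.eps_rel <= 0:
            raise ValueError("tolerances must be positive")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    if df.empty:
        raise ValueError(f"manifest {path} has no rows")
    if df.sample_id.duplicated().any():
        dupes = df.sample_id[df.sample_id.duplicated()].tolist()
        raise ValueError(f"duplicate sample_id(s) in manifest: {dupes}")
    return df


def _filter_cation(df: pd.DataFrame, cation: str | None) -> pd.DataFrame:
    if cation is None:
        return df
    return df[df.cation.str.upper().str.rstrip("+") == cation.upper().rstrip("+")]


def run_classify(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Conformation-index table for every manifest row with a spectrum file.

    Returns (results, failures); failures carry sample_id and the reason.
    Writes ``conformation.csv`` into the output directory.
    """
    df = _filter_cation(read_manifest(config.manifest), config.cation)
    base = config.manifest.parent
    results, failures = [], []
    for row in df.itertuples():
        if not row.spectrum_file:
            continue
        try:
            spectrum = spec_mod.read_spectrum(base / row.spectrum_file)
            res = spec_mod.conformation_index(
                spectrum,
                eps_rel=config.eps_rel,
                margin=config.margin,
                sample_id=row.sample_id,
            )
            results.append(res)
        except (OSError, ValueError) as exc:
            failures.append({"sample_id": row.sample_id, "reason": str(exc)})
    table = spec_mod.results_to_frame(results)
    config.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(config.outdir / "conformation.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(config.outdir / "classify_failures.csv", index=False)
    return table, failures


def run_melt(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Tm table for every manifest row with a melting file (``melting.csv``)."""
    df = _filter_cation(read_manifest(config.manifest), config.cation)
    base = config.manifest.parent
    rows, failures = [], []
    for row in df.itertuples():
        if not row.melting_file:
            continue
        try:
            curve = melt_mod.read_melting_curve(base / row.melting_file)
            res = melt_mod.compute_tm(
                curve, config.smooth_window, sample_id=row.sample_id
            )
            rows.append(
                {
                    "sample_id": row.sample_id,
                    "tm": res.tm,
                    "direction": res.direction,
                    "flags": ";".join(sorted(res.flags)),
                }
            )
        except (OSError, ValueError) as exc:
            failures.append({"sample_id": row.sample_id, "reason": str(exc)})
    table = pd.DataFrame(rows, columns=["sample_id", "tm", "direction", "flags"])
    config.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(config.outdir / "melting.csv", index=False)
    if failures:
        pd.DataFrame(failures).to_csv(config.outdir / "melt_failures.csv", index=False)
    return table, failures


def _condition_of(row) -> str:
    if not row.flank5 and not row.flank3:
        return "WO"
    if row.flank5 and row.flank3:
        return f"DT{len(row.flank5)}"
    if row.flank5:
        return f"5'T{len(row.flank5)}"
    return f"3'T{len(row.flank3)}"


def _category_of(name: str) -> str:
    try:
        return shortest_loop_category(parse_name(name))
    except ValueError:
        return "none"


def build_pairs(
    manifest: pd.DataFrame,
    conformation: pd.DataFrame,
    melting: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Join manifest pairs with their r (and Tm) values.

    A usable pair has exactly one unflanked and one flanked member, both with
    a finite r.  Everything else is excluded with a reason.
    """
    r_by_id = dict(zip(conformation.sample_id, conformation.r))
    label_by_id = dict(zip(conformation.sample_id, conformation.label))
    tm_by_id = (
        dict(zip(melting.sample_id, melting.tm)) if melting is not None else {}
    )
    rows, excluded = [], []
    for pair_id, members in manifest[manifest.pair_id != ""].groupby("pair_id"):
        bare = members[(members.flank5 == "") & (members.flank3 == "")]
        flanked = members[(members.flank5 != "") | (members.flank3 != "")]
        if len(bare) != 1 or len(flanked) != 1:
            excluded.append(
                {"pair_id": pair_id,
                 "reason": f"{len(bare)} bare / {len(flanked)} flanked members"}
            )
            continue
        b, f = bare.iloc[0], flanked.iloc[0]
        r_b, r_f = r_by_id.get(b.sample_id), r_by_id.get(f.sample_id)
        if r_b is None or r_f is None or not (np.isfinite(r_b) and np.isfinite(r_f)):
            excluded.append({"pair_id": pair_id, "reason": "missing or undefined r"})
            continue
        tm_b, tm_f = tm_by_id.get(b.sample_id), tm_by_id.get(f.sample_id)
        rows.append(
            {
                "pair_id": pair_id,
                "group_id": b.group_id,
                "cation": b.cation,
                "category": _category_of(b.name_or_sequence),
                "condition_bare": "WO",
                "condition_flanked": _condition_of(f),
                "r_bare": r_b,
                "r_flanked": r_f,
                "delta_r": stats_mod.pair_delta_r(r_f, r_b),
                "label_bare": label_by_id[b.sample_id],
                "label_flanked": label_by_id[f.sample_id],
                "tm_bare": tm_b,
                "tm_flanked": tm_f,
                "delta_tm": (
                    melt_mod.delta_tm(tm_f, tm_b)
                    if tm_b is not None and tm_f is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows), excluded


def _test_to_dict(t: stats_mod.TestResult) -> dict:
    return {
        "statistic": t.statistic,
        "p_value": t.p_value,
        "n": t.n,
        "stars": t.stars,
        "degenerate": t.degenerate,
    }


def run_stats(
    config: RunConfig,
    conformation: pd.DataFrame | None = None,
    melting: pd.DataFrame | None = None,
) -> dict:
    """The full flanking-effect report from classification (and Tm) tables.

    Writes pairs.csv, groups.csv, proportions.csv, tests.csv and summary.json
    into the output directory and returns the summary dict.
    """
    manifest = _filter_cation(read_manifest(config.manifest), config.cation)
    if conformation is None:
        conformation, _ = run_classify(config)
    if melting is None:
        melt_path = config.outdir / "melting.csv"
        melting = pd.read_csv(melt_path) if melt_path.exists() else None

    pairs, excluded = build_pairs(manifest, conformation, melting)
    config.outdir.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(config.outdir / "pairs.csv", index=False)
    if pairs.empty:
        raise ValueError("no usable bare/flanked pairs in the manifest")

    # per-group spread of r, bare vs flanked
    group_rows = []
    for (gid, cation), sub in pairs.groupby(["group_id", "cation"]):
        for role, col in (("WO", "r_bare"), ("W", "r_flanked")):
            rep = stats_mod.group_report(gid, sub[col])
            group_rows.append(
                {"group_id": gid, "cation": cation, "condition": role,
                 "n": rep.n, "mean_r": rep.mean, "sigma_r": rep.sigma}
            )
    groups = pd.DataFrame(group_rows)
    groups.to_csv(config.outdir / "groups.csv", index=False)

    prop_rows = []
    for role, col in (("WO", "label_bare"), ("W", "label_flanked")):
        prop = stats_mod.proportion_table(list(pairs[col]))
        prop_rows.append({"condition": role, "n": prop.n, **prop.percentages})
    proportions = pd.DataFrame(prop_rows)
    proportions.to_csv(config.outdir / "proportions.csv", index=False)

    n_pos, n_all, pct = stats_mod.positive_fraction(pairs.delta_r)

    tests: dict[str, stats_mod.TestResult] = {}
    tests["all"] = stats_mod.paired_t_test(pairs.r_flanked, pairs.r_bare)
    for cat, sub in pairs.groupby("category"):
        if len(sub) >= 2:
            tests[f"category:{cat}"] = stats_mod.paired_t_test(sub.r_flanked, sub.r_bare)
    for topo, sub in pairs.groupby("label_bare"):
        if len(sub) >= 2:
            tests[f"baseline:{topo}"] = stats_mod.paired_t_test(sub.r_flanked, sub.r_bare)
    if config.holm:
        adj = stats_mod.holm_adjust([t.p_value for t in tests.values()])
        tests = {
            k: dataclasses.replace(
                t, p_value=p, stars=stats_mod.significance_stars(p)
            )
            for (k, t), p in zip(tests.items(), adj)
        }
    tests_df = pd.DataFrame(
        [{"test": k, **_test_to_dict(t)} for k, t in tests.items()]
    )
    tests_df.to_csv(config.outdir / "tests.csv", index=False)

    summary = {
        "n_pairs": int(n_all),
        "n_excluded_pairs": len(excluded),
        "positive_delta_r": {"count": n_pos, "n": n_all, "percent": pct},
        "mean_delta_r": float(pairs.delta_r.mean()),
        "proportions": {
            row["condition"]: {
                k: row[k] for k in ("parallel", "hybrid", "antiparallel")
            }
            for row in prop_rows
        },
        "per_category": {
            cat: {
                "n": int(len(sub)),
                "mean_delta_r": float(sub.delta_r.mean()),
            }
            for cat, sub in pairs.groupby("category")
        },
        "tests": {k: _test_to_dict(t) for k, t in tests.items()},
        "holm_adjusted": bool(config.holm),
        "seed": config.seed,
    }
    if pairs.delta_tm.notna().any():
        dt = pairs.delta_tm.dropna()
        summary["delta_tm"] = {
            "n": int(dt.size),
            "mean": float(dt.mean()),
            "n_below_4C": int((dt.abs() < 4.0).sum()),
        }
    with open(config.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
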