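"""Orchestration of the two study workflows and their tabular outputs.

``run_size_stability`` takes calibrated measurement tables grouped by
composition and condition (t0 / overnight), fits the lognormal size law per
group, tests all composition pairs within each timepoint and each t0-vs-
overnight pair on the log scale, and assembles the stability table
(medians, counts, total-surface ratios).

``run_deformability`` takes ellipse-fit tables per composition and field
level, computes the per-vesicle surface-area deformation sigma, fits the
lognormal sigma law per group, tests composition pairs per field level, and
reports the minimum detectable median-sigma ratio at the configured power.

Both return plain DataFrames (written as CSVs by ``write_*_outputs``) plus a
run log capturing every choice that affects the numbers: inputs, calibration,
dropped-row counts, alphas, test variant, seed.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import distfit, stats
from .geometry import prolate_surface, rest_radius, sigma as sigma_of, ProlateSpheroid, sphere_surface
from .io_measurements import MeasurementTable, read_imagej_csv

__all__ = [
    "RunConfig",
    "SizeStabilityResult",
    "DeformabilityResult",
    "run_size_stability",
    "run_deformability",
    "load_config",
    "read_config_tables",
    "write_size_stability_outputs",
    "write_deformability_outputs",
]

logger = logging.getLogger("guvmorph")


@dataclass(frozen=True)
class RunConfig:
    """File map and analysis knobs for one pipeline run (YAML-loadable)."""

    inputs: tuple[dict, ...]  # each: path, calibration, composition, condition
    alpha: float = stats.DEFAULT_ALPHA
    power_alpha: float = 0.05
    power: float = 0.80
    t_variant: str = "pooled"
    output_dir: str = "guvmorph_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power_alpha < 1.0):
            raise ValueError("alphas must lie in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    inputs = tuple(raw.pop("inputs", ()))
    return RunConfig(inputs=inputs, **raw)


def read_config_tables(config: RunConfig) -> list[MeasurementTable]:
    """Read every input file of the config with its own calibration and tags."""
    tables = []
    for item in config.inputs:
        tables.append(
            read_imagej_csv(
                item["path"],
                calibration=float(item["calibration"]),
                composition=str(item["composition"]),
                condition=str(item["condition"]),
            )
        )
    return tables


def _group_tables(
    tables: Sequence[MeasurementTable],
) -> dict[tuple[str, str], MeasurementTable]:
    """Merge tables sharing (composition, condition) into one per group."""
    grouped: dict[tuple[str, str], list[MeasurementTable]] = {}
    for t in tables:
        grouped.setdefault((t.composition, t.condition), []).append(t)
    out = {}
    for key, parts in grouped.items():
        if len(parts) == 1:
            out[key] = parts[0]
        else:
            data = pd.concat([p.data for p in parts], ignore_index=True)
            out[key] = MeasurementTable(data=data, composition=key[0], condition=key[1])
    return out


# --- size / stability workflow ---------------------------------------------


@dataclass
class SizeStabilityResult:
    summaries: pd.DataFrame
    pairwise_tests: pd.DataFrame
    stability_tests: pd.DataFrame
    stability_table: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def _summary_row(comp: str, cond: str, s: distfit.SampleSummary) -> dict:
    return {
        "composition": comp,
        "condition": cond,
        "n": s.count,
        "mu": s.fit.mu,
        "s": s.fit.s,
        "median_um": s.median,
        "mode_um": s.mode,
        "p05_um": s.p05,
        "p95_um": s.p95,
        "total_surface_um2": s.total_surface,
    }


def _test_row(res: stats.LogTestResult, condition: str) -> dict:
    return {
        "condition": condition,
        "group1": res.groups[0],
        "group2": res.groups[1],
        "n1": res.n[0],
        "n2": res.n[1],
        "test": res.test,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "alpha": res.alpha,
        "significant": res.significant,
        "degenerate": res.degenerate,
    }


def run_size_stability(
    tables: Sequence[MeasurementTable],
    alpha: float = stats.DEFAULT_ALPHA,
    t_variant: str = "pooled",
) -> SizeStabilityResult:
    """Full size-distribution and temporal-stability analysis.

    Groups with fewer than 2 vesicles are excluded from fitting and testing
    with a logged warning rather than a crash.
    """
    grouped = _group_tables(tables)
    excluded = [key for key, t in grouped.items() if len(t) < 2]
    for key in excluded:
        logger.warning("group %s has n < 2; excluded from analysis", key)
    grouped = {k: v for k, v in grouped.items() if k not in excluded}

    diameters = {key: t.diameters for key, t in grouped.items()}
    summaries = {
        key: distfit.summarize(distfit.fit_lognormal(d), d)
        for key, d in diameters.items()
    }
    summary_df = pd.DataFrame(
        [_summary_row(c, k, s) for (c, k), s in sorted(summaries.items())]
    )

    # pairwise composition tests within each condition
    pair_rows = []
    conditions = sorted({cond for _, cond in grouped})
    for cond in conditions:
        comps = sorted(c for c, k in grouped if k == cond)
        for c1, c2 in itertools.combinations(comps, 2):
            res = stats.log_t_test(
                diameters[(c1, cond)],
                diameters[(c2, cond)],
                variant=t_variant,
                alpha=alpha,
                groups=(c1, c2),
            )
            pair_rows.append(_test_row(res, cond))
    pairwise_df = pd.DataFrame(pair_rows)

    # t0 vs overnight per composition, plus the stability table
    stab_rows, table_rows = [], []
    for comp in sorted({c for c, _ in grouped}):
        if (comp, "t0") not in grouped or (comp, "overnight") not in grouped:
            continue
        res = stats.log_t_test(
            diameters[(comp, "t0")],
            diameters[(comp, "overnight")],
            variant=t_variant,
            alpha=alpha,
            groups=(f"{comp}@t0", f"{comp}@overnight"),
        )
        stab_rows.append(_test_row(res, f"{comp}: t0 vs overnight"))
        s_t0, s_on = summaries[(comp, "t0")], summaries[(comp, "overnight")]
        table_rows.append(
            {
                "composition": comp,
                "median_t0_um": s_t0.median,
                "median_overnight_um": s_on.median,
                "count_t0": s_t0.count,
                "count_overnight": s_on.count,
                "surface_ratio_pct": distfit.surface_ratio(s_on, s_t0),
            }
        )

    run_log = {
        "workflow": "size-stability",
        "groups": {f"{c}|{k}": len(t) for (c, k), t in grouped.items()},
        "excluded_groups": [f"{c}|{k}" for c, k in excluded],
        "alpha": alpha,
        "t_variant": t_variant,
    }
    return SizeStabilityResult(
        summaries=summary_df,
        pairwise_tests=pairwise_df,
        stability_tests=pd.DataFrame(stab_rows),
        stability_table=pd.DataFrame(table_rows),
        run_log=run_log,
    )


# --- deformability workflow -------------------------------------------------


@dataclass
class DeformabilityResult:
    records: pd.DataFrame
    summaries: pd.DataFrame
    tests: pd.DataFrame
    mdr: pd.DataFrame
    run_log: dict = field(default_factory=dict)


def deformation_records(table: MeasurementTable) -> tuple[pd.DataFrame, int]:
    """Per-vesicle deformation geometry from one ellipse-fit table.

    Rows with missing or non-positive axes are dropped; returns the records
    and the number of dropped rows.
    """
    df = table.data
    maj = df["major_um"].to_numpy(dtype=float)
    mino = df["minor_um"].to_numpy(dtype=float)
    ok = np.isfinite(maj) & np.isfinite(mino) & (maj > 0) & (mino > 0)
    dropped = int((~ok).sum())
    rows = []
    for pid, M, m in zip(df["particle_id"].to_numpy()[ok], maj[ok], mino[ok]):
        a, b = (M / 2.0, m / 2.0) if M >= m else (m / 2.0, M / 2.0)
        sph = ProlateSpheroid(a, b)
        rest = rest_radius(sph)
        rows.append(
            {
                "particle_id": pid,
                "composition": table.composition,
                "field_level": table.condition,
                "a_um": a,
                "b_um": b,
                "r0_um": rest.r0,
                "s_sphere_um2": sphere_surface(rest),
                "s_prolate_um2": prolate_surface(sph),
                "sigma": sigma_of(sph),
            }
        )
    return pd.DataFrame(rows), dropped


def run_deformability(
    tables: Sequence[MeasurementTable],
    alpha: float = stats.DEFAULT_ALPHA,
    power_alpha: float = 0.05,
    power: float = 0.80,
    t_variant: str = "pooled",
) -> DeformabilityResult:
    """Full deformability analysis across compositions and field levels."""
    grouped = _group_tables(tables)
    record_frames, dropped_counts = [], {}
    for key, t in sorted(grouped.items()):
        recs, dropped = deformation_records(t)
        dropped_counts[f"{key[0]}|{key[1]}"] = dropped
        record_frames.append(recs)
    record_cols = [
        "particle_id", "composition", "field_level", "a_um", "b_um",
        "r0_um", "s_sphere_um2", "s_prolate_um2", "sigma",
    ]
    record_frames = [f for f in record_frames if not f.empty]
    records = (
        pd.concat(record_frames, ignore_index=True)
        if record_frames
        else pd.DataFrame(columns=record_cols)
    )

    sigma_by_group: dict[tuple[str, str], np.ndarray] = {}
    summary_rows = []
    for (comp, level), sub in records.groupby(["composition", "field_level"]):
        sig = sub["sigma"].to_numpy(dtype=float)
        sigma_by_group[(comp, level)] = sig
        if len(sig) >= 2 and np.all(sig > 0):
            fit = distfit.fit_lognormal(sig)
            s = distfit.summarize(fit, sig)
            summary_rows.append(
                {
                    "composition": comp,
                    "field_level": level,
                    "n": s.count,
                    "mu": fit.mu,
                    "s": fit.s,
                    "median_sigma": s.median,
                    "mode_sigma": s.mode,
                    "p05_sigma": s.p05,
                    "p95_sigma": s.p95,
                    "max_sigma": float(sig.max()),
                }
            )
        else:
            summary_rows.append(
                {
                    "composition": comp,
                    "field_level": level,
                    "n": len(sig),
                    "mu": np.nan,
                    "s": np.nan,
                    "median_sigma": float(np.median(sig)) if len(sig) else np.nan,
                    "mode_sigma": np.nan,
                    "p05_sigma": np.nan,
                    "p95_sigma": np.nan,
                    "max_sigma": float(sig.max()) if len(sig) else np.nan,
                }
            )

    # composition pairs per field level: t-test, F-test and MDR at target power
    test_rows, mdr_rows = [], []
    levels = sorted({lvl for _, lvl in sigma_by_group})
    for level in levels:
        comps = sorted(c for c, lvl in sigma_by_group if lvl == level)
        for c1, c2 in itertools.combinations(comps, 2):
            s1, s2 = sigma_by_group[(c1, level)], sigma_by_group[(c2, level)]
            if len(s1) < 2 or len(s2) < 2:
                continue
            if np.all(s1 > 0) and np.all(s2 > 0):
                t_res = stats.log_t_test(
                    s1, s2, variant=t_variant, alpha=alpha, groups=(c1, c2)
                )
                f_res = stats.log_f_test(s1, s2, alpha=alpha, groups=(c1, c2))
                test_rows.append(_test_row(t_res, level))
                test_rows.append(_test_row(f_res, level))
                s_pooled = stats.pooled_log_sd(s1, s2)
                mdr = stats.minimum_detectable_ratio(
                    stats.PowerSpec(
                        n1=len(s1), n2=len(s2), s_log=s_pooled,
                        alpha=power_alpha, power=power,
                    )
                )
                mdr_rows.append(
                    {
                        "field_level": level,
                        "group1": c1,
                        "group2": c2,
                        "n1": len(s1),
                        "n2": len(s2),
                        "pooled_s_log": s_pooled,
                        "alpha": power_alpha,
                        "power": power,
                        "minimum_detectable_ratio": mdr,
                    }
                )
            else:
                # undeformed (sigma = 0) groups: the log-scale test is undefined
                test_rows.append(
                    {
                        "condition": level,
                        "group1": c1,
                        "group2": c2,
                        "n1": len(s1),
                        "n2": len(s2),
                        "test": f"t-{t_variant}",
                        "statistic": np.nan,
                        "df": np.nan,
                        "p_value": np.nan,
                        "alpha": alpha,
                        "significant": False,
                        "degenerate": True,
                    }
                )

    run_log = {
        "workflow": "deformability",
        "groups": {f"{c}|{k}": len(t) for (c, k), t in grouped.items()},
        "dropped_rows": dropped_counts,
        "alpha": alpha,
        "power_alpha": power_alpha,
        "power": power,
        "t_variant": t_variant,
    }
    return DeformabilityResult(
        records=records,
        summaries=pd.DataFrame(summary_rows),
        tests=pd.DataFrame(test_rows),
        mdr=pd.DataFrame(mdr_rows),
        run_log=run_log,
    )


# --- output writers ---------------------------------------------------------


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _write_log(log: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_size_stability_outputs(result: SizeStabilityResult, outdir: str | Path) -> None:
    """Write summaries, pairwise tests, stability tests/table and the run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write(result.summaries, out / "size_summaries.csv")
    _write(result.pairwise_tests, out / "size_pairwise_tests.csv")
    _write(result.stability_tests, out / "stability_tests.csv")
    _write(result.stability_table, out / "stability_table.csv")
    _write_log(result.run_log, out / "run_log.json")


def write_deformability_outputs(result: DeformabilityResult, outdir: str | Path) -> None:
    """Write per-vesicle records, sigma summaries, tests, MDR and the run log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write(result.records, out / "deformation_records.csv")
    _write(result.summaries, out / "deformation_summaries.csv")
    _write(result.tests, out / "deformation_tests.csv")
    _write(result.mdr, out / "deformation_mdr.csv")
    _write_log(result.run_log, out / "run_log.json")
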