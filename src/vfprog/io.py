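"""File schemas, validation and pipeline orchestration.

The exchange format is a long CSV: one row per (subject, eye, visit, test
type) carrying reliability indices, the 52 sensitivities ``s01..s52`` in
grid-index order, and the machine global indices.  Dates are integer days
from the cohort baseline.  ``run_pipeline`` ties the stages together:
baseline screen -> event detection under both criteria -> agreement ->
survival -> mixed-model trends -> optional power simulation, writing one
results directory with all tables and a run log.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementTable, cohen_kappa, mcnemar_exact
from .deviations import NormativeModel, VFSeries, VFTest, synthetic_normative_model
from .events import (DefectCriterion, LESS_CONSERVATIVE, MORE_CONSERVATIVE,
                     baseline_is_normal, detect_event, event_summary)
from .grid import build_grid
from .survival import breslow_test, cox_robust, km_estimate
from .synth import CohortTables, DAYS_PER_YEAR, SyntheticCohortConfig, simulate_cohort
from .trend import fit_lmm, prepare_long_indices, slope_in_db

__all__ = ["SENS_COLUMNS", "LONG_COLUMNS", "read_cohort", "series_from_long",
           "run_pipeline"]

SENS_COLUMNS = [f"s{i + 1:02d}" for i in range(52)]
LONG_COLUMNS = ["subject_id", "eye_id", "eye_side", "test_type",
                "visit_date_days", "fl", "fp", "fn", *SENS_COLUMNS,
                "md_db", "psd_db"]

PAIRING_WINDOW_DAYS = 30
MIN_VISIT_SEPARATION_DAYS = int(3 * 365.25 / 12)


class SchemaError(ValueError):
    """Raised with an itemized list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def read_cohort(path_or_df) -> tuple[pd.DataFrame, dict]:
    """Load and validate a long VF table.

    Returns the table sorted by eye, test type and date, plus a report
    dict: SAP/FDT visits without a partner of the other type within the
    30-day pairing window, and consecutive same-eye visits closer than 3
    months.
    """
    df = (pd.read_csv(path_or_df) if not isinstance(path_or_df, pd.DataFrame)
          else path_or_df.copy())
    errors: list[str] = []
    if df.empty:
        raise SchemaError(["empty cohort table"])
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        errors.append(f"missing columns: {missing}")
    else:
        if df[SENS_COLUMNS].isna().any().any():
            errors.append("missing sensitivity values")
        key = ["subject_id", "eye_id", "visit_date_days", "test_type"]
        if df.duplicated(key).any():
            errors.append("duplicate (subject, eye, visit, test_type) keys")
        bad_tt = set(df["test_type"]) - {"SAP", "FDT"}
        if bad_tt:
            errors.append(f"unknown test types: {sorted(bad_tt)}")
    if errors:
        raise SchemaError(errors)
    df = df.sort_values(["eye_id", "test_type", "visit_date_days"],
                        kind="mergesort").reset_index(drop=True)
    unpaired: list[tuple] = []
    close_visits: list[tuple] = []
    for eye, g in df.groupby("eye_id"):
        days = {tt: g.loc[g.test_type == tt, "visit_date_days"].to_numpy()
                for tt in ("SAP", "FDT")}
        for tt, other in (("SAP", "FDT"), ("FDT", "SAP")):
            for d in days.get(tt, ()):
                if len(days[other]) == 0 or np.min(np.abs(days[other] - d)) > PAIRING_WINDOW_DAYS:
                    unpaired.append((eye, tt, int(d)))
        for tt in ("SAP", "FDT"):
            gaps = np.diff(np.sort(days[tt]))
            for gap in gaps[gaps < MIN_VISIT_SEPARATION_DAYS]:
                close_visits.append((eye, tt, int(gap)))
    report = {"n_rows": len(df), "n_eyes": df["eye_id"].nunique(),
              "unpaired": unpaired, "close_visits": close_visits}
    return df, report


def series_from_long(df: pd.DataFrame, norm: NormativeModel) -> dict[tuple[str, str], VFSeries]:
    """Build derived VFSeries keyed by (eye_id, test_type)."""
    out: dict[tuple[str, str], VFSeries] = {}
    for (eye, tt), g in df.groupby(["eye_id", "test_type"]):
        tests = [
            VFTest(
                subject_id=r.subject_id,
                eye_id=eye,
                eye_side=r.eye_side,
                day=int(r.visit_date_days),
                test_type=tt,
                sens=np.array([getattr(r, c) for c in SENS_COLUMNS], float),
                fl=float(r.fl), fp=float(r.fp), fn=float(r.fn),
            ).derive(norm)
            for r in g.itertuples()
        ]
        out[(eye, tt)] = VFSeries(
            subject_id=tests[0].subject_id, eye_id=eye,
            eye_side=tests[0].eye_side, test_type=tt, tests=tests,
        )
    return out


def _screen_eyes(series: dict, norm: NormativeModel, grids: dict) -> tuple[list[str], list[str]]:
    """Eyes whose first two reliable tests of BOTH types are jointly normal."""
    eyes = sorted({eye for eye, _ in series})
    passed, excluded = [], []
    for eye in eyes:
        ok = True
        for tt in ("SAP", "FDT"):
            s = series.get((eye, tt))
            rel = s.reliable_tests() if s else []
            if len(rel) < 2:
                ok = False
                break
            grid = grids[s.eye_side]
            if not baseline_is_normal((rel[0], rel[1]), norm, grid):
                ok = False
                break
        (passed if ok else excluded).append(eye)
    return passed, excluded


def _trend_table(df: pd.DataFrame) -> pd.DataFrame:
    """S2-like long index table from the exam table (time from each eye's
    own baseline, in years)."""
    base = df.groupby("eye_id")["visit_date_days"].transform("min")
    out = df[["subject_id", "eye_id", "test_type", "md_db", "psd_db"]].copy()
    out["time_years"] = (df["visit_date_days"] - base) / DAYS_PER_YEAR
    return out


def run_pipeline(
    out_dir,
    cohort: CohortTables | None = None,
    vf_path=None,
    baseline_path=None,
    config: SyntheticCohortConfig | None = None,
    norm: NormativeModel | None = None,
    criteria: tuple[DefectCriterion, ...] = (LESS_CONSERVATIVE, MORE_CONSERVATIVE),
    survival_criterion: str = "less_conservative",
    run_power: bool = False,
    power_config=None,
) -> dict:
    """Execute the full analysis sequence and write a results bundle.

    Inputs come from an in-memory :class:`CohortTables`, from CSV paths,
    or (default) from simulation under ``config``.  Writes events,
    agreement, survival and trend tables plus ``summary.json`` and a run
    log to ``out_dir`` and returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    norm = norm or synthetic_normative_model()
    if cohort is None:
        if vf_path is not None:
            vf, report = read_cohort(vf_path)
            baseline = pd.read_csv(baseline_path) if baseline_path else None
            cfg_echo = {"input": str(vf_path)}
        else:
            config = config or SyntheticCohortConfig()
            cohort = simulate_cohort(config, norm=norm)
    if cohort is not None:
        vf, report = read_cohort(cohort.vf_long)
        baseline = cohort.baseline
        cfg_echo = cohort.config
        cohort.vf_long.to_csv(out / "vf_long.csv", index=False)
        baseline.to_csv(out / "baseline_covariates.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)

    grids = {"OD": build_grid("OD"), "OS": build_grid("OS")}
    series = series_from_long(vf, norm)
    passed, excluded = _screen_eyes(series, norm, grids)

    summary: dict = {
        "package_version": __version__,
        "n_eyes_input": vf["eye_id"].nunique(),
        "n_eyes_screened_in": len(passed),
        "n_eyes_screened_out": len(excluded),
        "validation": {k: len(v) if isinstance(v, list) else v
                       for k, v in report.items()},
        "criteria": {},
    }

    events_rows = []
    outcomes_by_crit: dict[str, list] = {}
    for crit in criteria:
        outcomes = []
        for eye in passed:
            for tt in ("SAP", "FDT"):
                s = series[(eye, tt)]
                o = detect_event(s, grids[s.eye_side], crit)
                outcomes.append(o)
                events_rows.append(
                    {
                        "eye_id": o.eye_id,
                        "subject_id": o.subject_id,
                        "test_type": tt,
                        "detected": int(o.detected),
                        "time_days": o.time,
                        "criterion_id": crit.name or f"size{crit.min_cluster_size}",
                    }
                )
        outcomes_by_crit[crit.name] = outcomes
        summ = event_summary(outcomes)
        if "table" in summ:
            tbl = AgreementTable(**{f"n_{k}": v for k, v in summ["table"].items()})
            kr = cohen_kappa(tbl)
            summ["kappa"] = {"kappa": round(kr.kappa, 2),
                             "ci": [round(kr.ci_low, 2), round(kr.ci_high, 2)],
                             "interpretation": kr.interpretation}
            summ["mcnemar_p"] = round(mcnemar_exact(tbl), 4)
        summary["criteria"][crit.name] = summ
    events_df = pd.DataFrame(events_rows)
    events_df.to_csv(out / "events.csv", index=False)

    # survival stage on the chosen criterion
    ev = events_df[events_df.criterion_id == survival_criterion].rename(
        columns={"time_days": "time", "detected": "status"})
    ev = ev[ev.time > 0]
    surv: dict = {}
    if ev.status.sum() > 0:
        for tt in ("SAP", "FDT"):
            km = km_estimate(ev[ev.test_type == tt])
            km.to_csv(out / f"km_{tt.lower()}.csv", index=False)
        try:
            surv["breslow"] = breslow_test(ev)
        except ValueError as exc:
            surv["breslow"] = {"error": str(exc)}
        if baseline is not None:
            for tt in ("SAP", "FDT"):
                merged = ev[ev.test_type == tt].merge(
                    baseline, on=["eye_id", "subject_id"], how="inner")
                if merged.status.sum() >= 5:
                    fit = cox_robust(merged)
                    fit.summary.to_csv(out / f"cox_{tt.lower()}.csv")
                    surv[f"cox_{tt}"] = {
                        c: {"hazard_ratio": round(r.hazard_ratio, 3),
                            "p_value": round(r.p_value, 4)}
                        for c, r in fit.summary.iterrows()
                    }
    summary["survival"] = surv

    # trend stage
    trend_tbl = prepare_long_indices(_trend_table(vf))
    trend_tbl.to_csv(out / "long_indices.csv", index=False)
    summary["trend"] = {}
    for resp in ("MD", "PSD"):
        fit = fit_lmm(trend_tbl, response=resp)
        fit.fixed_effects.to_csv(out / f"lmm_{resp.lower()}.csv")
        summary["trend"][resp] = {
            "fixed_effects": {
                k: round(float(v), 5)
                for k, v in fit.fixed_effects["estimate"].items()
            },
            "slope_db_per_year": {
                tt: round(slope_in_db(fit, tt), 3) for tt in ("SAP", "FDT")
            },
            "interaction_p": round(fit.wald_p("time_fdt_interaction"), 4),
        }

    if run_power:
        from .power import PowerSimConfig, run_power_sim
        pr = run_power_sim(power_config or PowerSimConfig())
        summary["power"] = {"power": pr.power, "mc_se": pr.mc_se,
                            "n_converged": pr.n_converged}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"vfprog {__version__} python {platform.python_version()}\n")
        fh.write(f"config: {json.dumps(cfg_echo, default=str)}\n")
        fh.write(f"eyes screened in/out: {len(passed)}/{len(excluded)}\n")
    return summary
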