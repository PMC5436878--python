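"""Synthetic longitudinal SAP/FDT cohort generator.

Stands in for a glaucoma-suspect cohort followed with paired perimetry:
155 subjects contributing ~221 eyes, 5-13 visits per eye (median 6) about
11 months apart, all eyes normal at baseline, and a minority developing a
localized defect that grows as a connected region within one hemifield
and deepens linearly.  Measurement noise follows the instruments'
signatures: SAP noise grows with the depth of true loss and rounds to
1 dB steps; FDT noise is constant and the result snaps to the 15 discrete
FDT levels.  Two eyes of a subject share a progression-propensity term,
inducing the within-subject correlation that motivates the cluster-robust
sandwich and the nested mixed model downstream.

Everything is driven by one :class:`SyntheticCohortConfig` and a seed;
the same seed reproduces the cohort exactly.  Separate helpers generate
baseline-covariate survival tables and long global-index tables directly
from the downstream models (proportional hazards, hierarchical linear
mixed model) for parameter-recovery testing at chosen effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .deviations import NormativeModel, VFTest, synthetic_normative_model
from .events import baseline_is_normal
from .grid import Grid24_2, build_grid
from .scales import log10_to_db, quantize_fdt

__all__ = [
    "SyntheticCohortConfig",
    "CohortTables",
    "simulate_cohort",
    "inject_defect",
    "apply_measurement_model",
    "simulate_survival_table",
    "simulate_long_index_table",
]

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25


@dataclass
class SyntheticCohortConfig:
    """All distributions, effect sizes and noise parameters of the cohort."""

    n_subjects: int = 155
    two_eye_prob: float = 66 / 155          # gives E[eyes] = 221
    gon_fraction: float = 100 / 221         # vs ocular hypertension
    # visit schedule: count = 5 + Poisson(lam) truncated at 13 gives the
    # reported median of 6 within the 5..13 range
    visit_count_min: int = 5
    visit_count_max: int = 13
    visit_count_lam: float = 1.7
    visit_interval_mean_months: float = 11.0
    visit_interval_sd_months: float = 2.8
    visit_interval_min_months: float = 3.0
    fdt_day_offset_sd: float = 5.0          # days between paired SAP and FDT
    # progression model
    progression_fraction: float = 0.12
    age_progression_log_or: float = 0.08    # per year of age, on the logit
    subject_propensity_sd: float = 1.0      # shared two-eye frailty (logit)
    defect_initial_size: int = 3
    defect_growth_per_visit: float = 0.75   # expected locations per visit
    defect_max_size: int = 10
    defect_deepening_db: float = 2.0        # SAP dB per visit per location
    defect_max_depth_db: float = 22.0
    #: FDT dB of true loss per SAP dB; equal loss in log10 contrast units
    #: already maps to 2 FDT dB per SAP dB (1 log10 unit = 10 SAP dB =
    #: 20 FDT dB), and the factor multiplies that 2:1 relation
    fdt_defect_gain: float = 1.0
    md_drift_db_per_year: float = -0.05     # diffuse SAP-dB drift
    # measurement model
    sap_noise_sd0: float = 1.7
    sap_noise_slope: float = 0.15           # extra SD per dB of true loss
    fdt_noise_sd: float = 2.8
    unreliable_rate: float = 0.03
    sap_floor_db: float = 0.0
    sap_ceil_db: float = 40.0
    # baseline covariates
    age_mean: float = 57.2
    age_sd: float = 8.9
    rim_area_mean: float = 1.35             # mm^2
    rim_area_sd: float = 0.30
    rnfl_mean_um: float = 230.0
    rnfl_sd_um: float = 55.0
    cdr_mean: float = 0.35
    cdr_sd: float = 0.12
    seed: int = 12345
    max_baseline_resample: int = 100

    def __post_init__(self) -> None:
        for name in ("two_eye_prob", "gon_fraction", "progression_fraction",
                     "unreliable_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("sap_noise_sd0", "sap_noise_slope", "fdt_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.visit_count_min < 3 and self.progression_fraction > 0:
            raise ValueError("progressing eyes need at least 3 visits")


@dataclass(eq=False)
class CohortTables:
    """Generator output: pipeline inputs plus ground truth."""

    vf_long: pd.DataFrame     # long per-exam table (cli_io schema)
    baseline: pd.DataFrame    # covariate table (S1-like schema)
    truth: pd.DataFrame       # per-eye ground truth for recovery testing
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _visit_days(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(min(cfg.visit_count_min + rng.poisson(cfg.visit_count_lam),
                cfg.visit_count_max))
    intervals = rng.normal(cfg.visit_interval_mean_months,
                           cfg.visit_interval_sd_months, size=n - 1)
    intervals = np.maximum(intervals, cfg.visit_interval_min_months)
    return np.concatenate([[0.0], np.cumsum(intervals)]) * DAYS_PER_MONTH


def inject_defect(
    rng: np.random.Generator,
    grid: Grid24_2,
    n_visits: int,
    onset_visit: int,
    initial_size: int = 3,
    growth_per_visit: float = 0.75,
    max_size: int = 10,
    deepening_db: float = 1.8,
    max_depth_db: float = 22.0,
) -> tuple[np.ndarray, tuple[int, ...], str]:
    """Grow a connected, hemifield-contained defect.

    Returns a ``(n_visits, 52)`` array of true sensitivity depressions
    (<= 0, SAP dB), the ordered tuple of involved locations, and the
    hemifield.  The region starts at a random seed location, expands along
    grid adjacency at ``growth_per_visit`` expected locations per visit up
    to ``max_size``, never crosses the horizontal midline, and each
    location deepens linearly from the visit it joins the region.
    """
    if not 0 <= onset_visit < n_visits:
        raise ValueError("onset_visit must fall within the follow-up")
    hemifield = "superior" if rng.random() < 0.5 else "inferior"
    hemi_idx = np.flatnonzero(grid.hemifield_mask(hemifield))
    seed_loc = int(rng.choice(hemi_idx))
    adj = grid.hemifield_adjacency()
    # randomized breadth-first growth order within the hemifield
    order = [seed_loc]
    frontier = set()
    while len(order) < max_size:
        frontier = {
            int(j) for i in order for j in np.flatnonzero(adj[i])
        } - set(order)
        if not frontier:
            break
        weights = np.array([adj[sorted(order), j].sum() for j in sorted(frontier)], float)
        probs = weights / weights.sum()
        order.append(int(rng.choice(sorted(frontier), p=probs)))
    depth = np.zeros((n_visits, 52))
    for k, loc in enumerate(order):
        if k < initial_size:
            joins = onset_visit
        else:
            if growth_per_visit <= 0:
                break
            joins = onset_visit + math.ceil((k - initial_size + 1) / growth_per_visit)
        if joins >= n_visits:
            continue
        for v in range(joins, n_visits):
            depth[v, loc] = -min(deepening_db * (v - joins + 1), max_depth_db)
    return depth, tuple(order), hemifield


def apply_measurement_model(
    true_sens: np.ndarray,
    test_type: str,
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
    true_depth: np.ndarray | None = None,
) -> np.ndarray:
    """Observe true sensitivities through the instrument's noise model.

    SAP: heteroscedastic Gaussian noise (SD grows with true loss depth),
    rounded to 1 dB and clamped to the instrument range.  FDT:
    homoscedastic Gaussian noise, snapped to the 15 discrete FDT levels.
    """
    true_sens = np.asarray(true_sens, dtype=float)
    if test_type == "SAP":
        depth = np.zeros_like(true_sens) if true_depth is None else np.maximum(-true_depth, 0.0)
        sd = cfg.sap_noise_sd0 + cfg.sap_noise_slope * depth
        raw = true_sens + rng.normal(0.0, 1.0, true_sens.shape) * sd
        return np.clip(np.rint(raw), cfg.sap_floor_db, cfg.sap_ceil_db)
    if test_type == "FDT":
        raw = true_sens + rng.normal(0.0, cfg.fdt_noise_sd, true_sens.shape)
        return quantize_fdt(raw)
    raise ValueError(f"unknown test_type {test_type!r}")


def _reliability(rng: np.random.Generator, unreliable_rate: float) -> tuple[float, float, float]:
    fl, fp, fn = rng.uniform(0.0, 0.25, size=3).round(2)
    if rng.random() < unreliable_rate:
        which = rng.integers(0, 3)
        vals = [fl, fp, fn]
        vals[which] = round(rng.uniform(0.34, 0.6), 2)
        fl, fp, fn = vals
    return float(fl), float(fp), float(fn)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _make_eye(
    cfg: SyntheticCohortConfig,
    rng: np.random.Generator,
    subject_id: str,
    eye_id: str,
    eye_side: str,
    progresses: bool,
    grids: dict[str, Grid24_2],
    norm: NormativeModel,
) -> tuple[list[dict], dict]:
    days = _visit_days(cfg, rng)
    n_visits = len(days)
    grid = grids[eye_side]
    sap_entry = norm.entry("SAP")
    fdt_entry = norm.entry("FDT")
    true_mean = {"SAP": sap_entry.true_mean_db, "FDT": fdt_entry.true_mean_db}

    years = days / DAYS_PER_YEAR
    drift = cfg.md_drift_db_per_year * years  # diffuse SAP-dB component
    defect = np.zeros((n_visits, 52))
    onset_visit = -1
    locations: tuple[int, ...] = ()
    hemifield = ""
    if progresses:
        onset_visit = int(rng.integers(2, n_visits))
        defect, locations, hemifield = inject_defect(
            rng, grid, n_visits, onset_visit,
            initial_size=cfg.defect_initial_size,
            growth_per_visit=cfg.defect_growth_per_visit,
            max_size=cfg.defect_max_size,
            deepening_db=cfg.defect_deepening_db,
            max_depth_db=cfg.defect_max_depth_db,
        )
    # true deviations per instrument scale: an equal loss in log10 units is
    # twice as many FDT dB as SAP dB
    true_dev = {"SAP": drift[:, None] + defect,
                "FDT": (drift[:, None] + defect) * 2.0 * cfg.fdt_defect_gain}

    # "true onset": first visit with >= 3 locations truly beyond the SAP
    # TD 5% cutoff (well defined regardless of measurement noise)
    true_onset_visit = -1
    for v in range(n_visits):
        if (true_dev["SAP"][v] <= sap_entry.td_cuts[0]).sum() >= 3:
            true_onset_visit = v
            break

    rows: list[dict] = []
    for v in range(n_visits):
        for tt in ("SAP", "FDT"):
            for attempt in range(cfg.max_baseline_resample + 1):
                sens = apply_measurement_model(
                    true_mean[tt] + true_dev[tt][v], tt, cfg, rng,
                    true_depth=true_dev[tt][v],
                )
                # first two visits must be reliable and individually clean
                # enough that the eye can pass the two-test baseline screen
                if v < 2:
                    fl, fp, fn = _reliability(rng, 0.0)
                    probe = VFTest(subject_id, eye_id, eye_side, 0, tt,
                                   sens, fl, fp, fn).derive(norm)
                    pair = (probe, probe)
                    if baseline_is_normal(pair, norm, grid):
                        break
                else:
                    fl, fp, fn = _reliability(rng, cfg.unreliable_rate)
                    break
            day = days[v]
            if tt == "FDT":
                day = max(0.0, day + rng.normal(0.0, cfg.fdt_day_offset_sd))
            test = VFTest(subject_id, eye_id, eye_side, int(round(day)), tt,
                          sens, fl, fp, fn).derive(norm)
            row = {
                "subject_id": subject_id,
                "eye_id": eye_id,
                "eye_side": eye_side,
                "test_type": tt,
                "visit_date_days": int(round(day)),
                "fl": fl,
                "fp": fp,
                "fn": fn,
            }
            row.update({f"s{i + 1:02d}": float(sens[i]) for i in range(52)})
            row["md_db"] = round(test.md, 2)
            row["psd_db"] = round(test.psd, 2)
            rows.append(row)
    truth = {
        "subject_id": subject_id,
        "eye_id": eye_id,
        "eye_side": eye_side,
        "progresses": progresses,
        "onset_visit": onset_visit,
        "true_onset_visit": true_onset_visit,
        "true_onset_day": (int(round(days[true_onset_visit]))
                           if true_onset_visit >= 0 else -1),
        "n_visits": n_visits,
        "last_day": int(round(days[-1])),
        "hemifield": hemifield,
        "defect_locations": ";".join(map(str, locations)),
    }
    return rows, truth


def simulate_cohort(cfg: SyntheticCohortConfig | None = None,
                    norm: NormativeModel | None = None) -> CohortTables:
    """Generate a full synthetic cohort.

    Returns the long per-exam table (cli_io schema), the baseline
    covariate table and a ground-truth table.  Byte-identical for a given
    config; all randomness flows from ``cfg.seed``.
    """
    cfg = cfg or SyntheticCohortConfig()
    rng = np.random.default_rng(cfg.seed)
    norm = norm or synthetic_normative_model()
    grids = {"OD": build_grid("OD"), "OS": build_grid("OS")}

    base_logit = math.log(cfg.progression_fraction / (1 - cfg.progression_fraction)) \
        if 0 < cfg.progression_fraction < 1 else -math.inf

    # fixed number of two-eye subjects, so the default scale lands exactly
    # on round(155 * 66/155) = 66 bilateral subjects -> 221 eyes
    n_two = int(round(cfg.two_eye_prob * cfg.n_subjects))
    two_eye_subjects = set(rng.choice(cfg.n_subjects, size=n_two,
                                      replace=False))
    vf_rows: list[dict] = []
    truth_rows: list[dict] = []
    cov_rows: list[dict] = []
    for s in range(cfg.n_subjects):
        subject_id = f"S{s + 1:04d}"
        age = float(rng.normal(cfg.age_mean, cfg.age_sd))
        frailty = float(rng.normal(0.0, cfg.subject_propensity_sd))
        n_eyes = 2 if s in two_eye_subjects else 1
        sides = ["OD", "OS"] if n_eyes == 2 else [rng.choice(["OD", "OS"])]
        for side in sides:
            eye_id = f"{subject_id}-{side}"
            gon = rng.random() < cfg.gon_fraction
            if cfg.progression_fraction <= 0:
                progresses = False
            elif cfg.progression_fraction >= 1:
                progresses = True
            else:
                logit = (base_logit + frailty
                         + cfg.age_progression_log_or * (age - cfg.age_mean))
                progresses = rng.random() < 1.0 / (1.0 + math.exp(-logit))
            rows, truth = _make_eye(cfg, rng, subject_id, eye_id, side,
                                    progresses, grids, norm)
            vf_rows.extend(rows)
            truth_rows.append(truth)
            cov_rows.append(
                {
                    "subject_id": subject_id,
                    "eye_id": eye_id,
                    "age": round(age, 1),
                    "rim_area": round(float(rng.normal(
                        cfg.rim_area_mean - (0.15 if gon else 0.0),
                        cfg.rim_area_sd)), 3),
                    "rnfl": round(float(rng.normal(
                        cfg.rnfl_mean_um - (20.0 if gon else 0.0),
                        cfg.rnfl_sd_um)), 1),
                    "cdr": round(float(np.clip(rng.normal(
                        cfg.cdr_mean + (0.12 if gon else 0.0),
                        cfg.cdr_sd), 0.02, 0.95)), 3),
                    "diagnosis": "GON" if gon else "OHT",
                }
            )
    return CohortTables(
        vf_long=pd.DataFrame(vf_rows),
        baseline=pd.DataFrame(cov_rows),
        truth=pd.DataFrame(truth_rows),
        config=asdict(cfg),
    )


# ---------------------------------------------------------------------------
# model-direct tables for parameter-recovery checks
# ---------------------------------------------------------------------------

def simulate_survival_table(
    n_subjects: int = 600,
    two_eye_prob: float = 66 / 155,
    age_log_hr: float = math.log(1.13),
    baseline_hazard_per_year: float = 0.06,
    frailty_sd: float = 0.25,
    followup_years: tuple[float, float] = (3.0, 8.0),
    age_mean: float = 57.2,
    age_sd: float = 8.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table drawn directly from a proportional-hazards model.

    Exponential event times with hazard
    ``h0 * exp(age_log_hr * (age - age_mean) + frailty)``, a shared
    log-normal frailty per subject (its two eyes), and uniform
    administrative censoring.  Includes null covariates (rim area, RNFL,
    cup-disc ratio) independent of outcome, on their natural scales.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject_id = f"P{s + 1:05d}"
        age = float(rng.normal(age_mean, age_sd))
        z = float(rng.normal(0.0, frailty_sd))
        n_eyes = 2 if rng.random() < two_eye_prob else 1
        for e in range(n_eyes):
            rate = baseline_hazard_per_year * math.exp(
                age_log_hr * (age - age_mean) + z)
            t_event = rng.exponential(1.0 / rate)
            t_cens = rng.uniform(*followup_years)
            t = min(t_event, t_cens)
            rows.append(
                {
                    "subject_id": subject_id,
                    "eye_id": f"{subject_id}-{e}",
                    "time": t * DAYS_PER_YEAR,
                    "status": int(t_event <= t_cens),
                    "age": age,
                    "rim_area": float(rng.normal(1.35, 0.30)),
                    "rnfl": float(rng.normal(230.0, 55.0)),
                    "cdr": float(np.clip(rng.normal(0.35, 0.12), 0.02, 0.95)),
                }
            )
    return pd.DataFrame(rows)


#: Fixed effects mimicking the magnitudes of the trend analysis defaults
#: (log10 units; reference type SAP).
TREND_FIXED_DEFAULTS = {
    "MD": {"intercept": -0.021, "fdt_offset": -0.017,
           "time_slope": -0.002, "time_fdt_interaction": 0.001},
    "PSD": {"intercept": 0.154, "fdt_offset": -0.015,
            "time_slope": 0.005, "time_fdt_interaction": -0.001},
}

TREND_VARIANCE_DEFAULTS = {
    "subject_intercept_var": 1.0e-3,
    "subject_slope_var": 2.5e-5,
    "subject_int_slope_cov": -5.0e-6,
    "eye_intercept_var": 4.0e-4,
    "residual_var": 9.0e-4,
}


def simulate_long_index_table(
    n_subjects: int = 155,
    two_eye_prob: float = 66 / 155,
    visit_years: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
    response: str = "PSD",
    fixed: dict | None = None,
    variance: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long global-index table drawn directly from the hierarchical LMM.

    Both test types share each eye's random effects (paired testing of the
    same eye); columns follow the S2-like schema (subject_id, eye_id,
    test_type, time_years, md_db, psd_db) with the *other* index filled
    from its own defaults without random effects, so the frame round-trips
    through :func:`vfprog.trend.prepare_long_indices`.
    """
    response = response.upper()
    fx = dict(TREND_FIXED_DEFAULTS[response], **(fixed or {}))
    vc = dict(TREND_VARIANCE_DEFAULTS, **(variance or {}))
    rng = np.random.default_rng(seed)
    cov = np.array([
        [vc["subject_intercept_var"], vc["subject_int_slope_cov"]],
        [vc["subject_int_slope_cov"], vc["subject_slope_var"]],
    ])
    other = "MD" if response == "PSD" else "PSD"
    rows = []
    t = np.asarray(visit_years, float)
    for s in range(n_subjects):
        subject_id = f"L{s + 1:05d}"
        u = rng.multivariate_normal(np.zeros(2), cov)
        n_eyes = 2 if rng.random() < two_eye_prob else 1
        for e in range(n_eyes):
            v = rng.normal(0.0, math.sqrt(vc["eye_intercept_var"]))
            for tt in ("SAP", "FDT"):
                is_fdt = float(tt == "FDT")
                mu = (fx["intercept"] + fx["fdt_offset"] * is_fdt
                      + u[0] + v
                      + (fx["time_slope"]
                         + fx["time_fdt_interaction"] * is_fdt + u[1]) * t)
                y = mu + rng.normal(0.0, math.sqrt(vc["residual_var"]),
                                    size=len(t))
                y_other = (TREND_FIXED_DEFAULTS[other]["intercept"]
                           + TREND_FIXED_DEFAULTS[other]["time_slope"] * t)
                for k in range(len(t)):
                    rec = {
                        "subject_id": subject_id,
                        "eye_id": f"{subject_id}-{e}",
                        "test_type": tt,
                        "time_years": float(t[k]),
                    }
                    rec[f"{response.lower()}_db"] = float(log10_to_db(y[k], tt))
                    rec[f"{other.lower()}_db"] = float(log10_to_db(y_other[k], tt))
                    rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["subject_id", "eye_id", "test_type", "time_years",
               "md_db", "psd_db"]]
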