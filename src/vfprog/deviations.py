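"""Per-location deviation maps, probability levels, global indices and a
glaucoma-hemifield-test surrogate.

A perimetric exam arrives as 52 raw sensitivities (dB).  Against a
normative model this module derives

* **total deviation** (TD): sensitivity minus the normative mean,
* **pattern deviation** (PD): TD minus the general-height estimate (the
  7th-best TD value, i.e. the 85th percentile), which removes diffuse
  loss and isolates localized defects,
* **probability levels**: each PD value quantized to the standard plot
  levels P < 5%, 2%, 1%, 0.5% ("or worse" reading: a value exactly at a
  cutoff receives that level),
* **global indices** MD (mean of TD) and PSD (standard deviation of TD),
* a **GHT surrogate**: mirrored superior/inferior zone scores in the
  style of the Asman-Heijl glaucoma hemifield test.

The instruments' proprietary normative databases are not available, so
:func:`synthetic_normative_model` builds a fully synthetic one: smooth
eccentricity-dependent mean sensitivities with Gaussian test-retest noise,
with all probability cutpoints, the PSD 95th percentile and the GHT zone
thresholds calibrated by Monte Carlo on simulated healthy fields.  User
tables in the same schema are accepted via :meth:`NormativeModel.from_frame`.
The GHT here is an explicitly simplified surrogate of the proprietary
algorithm: same architecture (five mirrored zone pairs, probability-rank
scores, normative percentile limits), not the same zones or limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid24_2, build_grid
from .scales import quantize_fdt

__all__ = [
    "P_LEVELS",
    "P_NONE",
    "NormativeEntry",
    "NormativeModel",
    "VFTest",
    "VFSeries",
    "total_deviation",
    "pattern_deviation",
    "probability_levels",
    "global_indices",
    "ght_surrogate",
    "ght_zones",
    "synthetic_normative_model",
]

#: plot probability levels, least to most extreme
P_LEVELS: tuple[float, ...] = (0.05, 0.02, 0.01, 0.005)
#: sentinel level for "not significant"
P_NONE: float = 1.0

#: GHT-style score contributed by one location at each probability level
GHT_SCORE = {P_NONE: 0, 0.05: 1, 0.02: 2, 0.01: 5, 0.005: 10}

RELIABILITY_CUTOFF = 0.33  # max fixation-loss / false-pos / false-neg rate


# ---------------------------------------------------------------------------
# normative model
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class NormativeEntry:
    """Normative quantities for one test type.

    ``td_cuts`` / ``pd_cuts`` are (4, 52) arrays of deviation cutoffs for
    the levels in :data:`P_LEVELS`; a deviation at or below a cutoff is at
    that level or worse.  ``psd_cut95`` is the healthy 95th percentile of
    PSD ("PSD at P < 5%" means PSD above it).
    """

    test_type: str
    mean_db: np.ndarray
    sd_db: np.ndarray
    td_cuts: np.ndarray
    pd_cuts: np.ndarray
    psd_cut95: float
    ght_diff_borderline: np.ndarray = field(default=None)
    ght_diff_onl: np.ndarray = field(default=None)
    ght_zone_high: np.ndarray = field(default=None)
    #: underlying noise-free healthy sensitivity (set by the synthetic
    #: builder; used by the cohort generator as the true surface)
    true_mean_db: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        for cuts in (self.td_cuts, self.pd_cuts):
            if cuts.shape != (len(P_LEVELS), 52):
                raise ValueError("cutpoint arrays must have shape (4, 52)")
            # cut(0.5%) <= cut(1%) <= cut(2%) <= cut(5%) on the deviation scale
            if not np.all(np.diff(cuts, axis=0) <= 1e-12):
                raise ValueError("probability cutpoints must be monotone")


@dataclass(eq=False)
class NormativeModel:
    """Per-location normative data for both test types on a reference grid."""

    entries: dict[str, NormativeEntry]

    def entry(self, test_type: str) -> NormativeEntry:
        try:
            return self.entries[test_type]
        except KeyError:
            raise KeyError(
                f"normative model has no entry for test type {test_type!r}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tt, e in self.entries.items():
            for i in range(52):
                rows.append(
                    {
                        "test_type": tt,
                        "index": i,
                        "mean_db": e.mean_db[i],
                        "sd_db": e.sd_db[i],
                        "cut5": e.pd_cuts[0, i],
                        "cut2": e.pd_cuts[1, i],
                        "cut1": e.pd_cuts[2, i],
                        "cut05": e.pd_cuts[3, i],
                        "td_cut5": e.td_cuts[0, i],
                        "td_cut2": e.td_cuts[1, i],
                        "td_cut1": e.td_cuts[2, i],
                        "td_cut05": e.td_cuts[3, i],
                        "psd_cut95": e.psd_cut95,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormativeModel":
        entries = {}
        for tt, g in df.groupby("test_type"):
            g = g.sort_values("index")
            if len(g) != 52:
                raise ValueError(f"normative table for {tt} must cover 52 locations")
            pd_cuts = g[["cut5", "cut2", "cut1", "cut05"]].to_numpy().T
            td_cols = ["td_cut5", "td_cut2", "td_cut1", "td_cut05"]
            td_cuts = g[td_cols].to_numpy().T if set(td_cols) <= set(g) else pd_cuts.copy()
            entries[tt] = NormativeEntry(
                test_type=tt,
                mean_db=g["mean_db"].to_numpy(float),
                sd_db=g["sd_db"].to_numpy(float),
                td_cuts=td_cuts,
                pd_cuts=pd_cuts,
                psd_cut95=float(g["psd_cut95"].iloc[0]) if "psd_cut95" in g else np.inf,
            )
        return cls(entries=entries)


# ---------------------------------------------------------------------------
# single-exam container
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class VFTest:
    """One perimetric exam with derived maps."""

    subject_id: str
    eye_id: str
    eye_side: str
    day: int  # days from cohort baseline
    test_type: str
    sens: np.ndarray  # (52,) dB
    fl: float  # fixation losses
    fp: float  # false positives
    fn: float  # false negatives
    td: np.ndarray | None = None
    pd_map: np.ndarray | None = None
    levels: np.ndarray | None = None
    md: float | None = None
    psd: float | None = None

    @property
    def reliable(self) -> bool:
        return max(self.fl, self.fp, self.fn) <= RELIABILITY_CUTOFF

    def derive(self, norm: NormativeModel) -> "VFTest":
        """Fill TD/PD maps, probability levels, MD and PSD in place."""
        entry = norm.entry(self.test_type)
        self.td = total_deviation(self.sens, entry)
        self.pd_map = pattern_deviation(self.td)
        self.levels = probability_levels(self.pd_map, entry)
        self.md, self.psd = global_indices(self.td)
        return self


@dataclass(eq=False)
class VFSeries:
    """One eye's longitudinal exam sequence for one test type."""

    subject_id: str
    eye_id: str
    eye_side: str
    test_type: str
    tests: list[VFTest]

    def __post_init__(self) -> None:
        self.tests = sorted(self.tests, key=lambda t: t.day)

    def reliable_tests(self) -> list[VFTest]:
        return [t for t in self.tests if t.reliable]


# ---------------------------------------------------------------------------
# map operations
# ---------------------------------------------------------------------------

def total_deviation(sens: np.ndarray, entry: NormativeEntry) -> np.ndarray:
    """TD[i] = sensitivity[i] - normative mean[i] (dB)."""
    sens = np.asarray(sens, dtype=float)
    if sens.shape != (52,):
        raise ValueError("expected 52 sensitivities")
    return sens - entry.mean_db


def general_height(td: np.ndarray, rank: int = 7) -> float:
    """General-height estimate: the ``rank``-th best TD value (default 7th,
    the 85th percentile of 52)."""
    return float(np.sort(np.asarray(td, dtype=float))[-rank])


def pattern_deviation(td: np.ndarray, rank: int = 7) -> np.ndarray:
    """PD = TD minus the general height; invariant to uniform shifts."""
    td = np.asarray(td, dtype=float)
    return td - general_height(td, rank=rank)


def probability_levels(pd_map: np.ndarray, entry: NormativeEntry,
                       cuts: np.ndarray | None = None) -> np.ndarray:
    """Quantize PD values to plot probability levels.

    Returns a (52,) float array with values in {1.0, 0.05, 0.02, 0.01,
    0.005}; 1.0 means not significant.  A deviation exactly at a cutoff is
    assigned that level (inclusive "or worse" reading), and deeper
    deviations never receive a less extreme level.
    """
    pd_map = np.asarray(pd_map, dtype=float)
    cuts = entry.pd_cuts if cuts is None else cuts
    out = np.full(52, P_NONE)
    for k, p in enumerate(P_LEVELS):  # least to most extreme
        out[pd_map <= cuts[k]] = p
    return out


def total_deviation_levels(td: np.ndarray, entry: NormativeEntry) -> np.ndarray:
    return probability_levels(td, entry, cuts=entry.td_cuts)


def global_indices(td: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """Unweighted MD (mean of TD) and PSD (SD of TD about MD).

    The instruments' indices weight locations by normative variance with
    proprietary weights; the unweighted moments used here are the standard
    approximation.  ``ddof=1`` gives the sample-SD convention.
    """
    td = np.asarray(td, dtype=float)
    return float(td.mean()), float(td.std(ddof=ddof))


# ---------------------------------------------------------------------------
# GHT surrogate
# ---------------------------------------------------------------------------

def ght_zones() -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Five mirrored (superior, inferior) zone index pairs.

    Zones are index sets on the reference (OD) grid; because OS grids are
    built index-mirrored, the same index sets apply to either eye.
    Partition of the 26 superior locations (nasal-positive x):
    paracentral (y=3, |x|<=9), temporal (x<=-15), nasal (x>=15),
    inner arcuate (y=9, |x|<=9), outer arcuate (y=15, |x|<=9 and y=21).
    """
    ref = build_grid("OD")
    by_xy = {(p.x, p.y): p.index for p in ref.locations}
    preds = [
        lambda x, y: y == 3 and abs(x) <= 9,
        lambda x, y: x <= -15,
        lambda x, y: x >= 15,
        lambda x, y: y == 9 and abs(x) <= 9,
        lambda x, y: (y == 15 and abs(x) <= 9) or y == 21,
    ]
    zones = []
    for pred in preds:
        sup = tuple(i for (x, y), i in sorted(by_xy.items()) if y > 0 and pred(x, y))
        inf = tuple(by_xy[(ref.locations[i].x, -ref.locations[i].y)] for i in sup)
        zones.append((sup, inf))
    return zones


def ght_zone_scores(levels: np.ndarray,
                    zones: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(superior, inferior) probability-rank score per zone pair."""
    if zones is None:
        zones = ght_zones()
    levels = np.asarray(levels)
    sup = np.array([sum(GHT_SCORE[levels[i]] for i in s) for s, _ in zones], float)
    inf = np.array([sum(GHT_SCORE[levels[i]] for i in s) for _, s in zones], float)
    return sup, inf


def ght_surrogate(levels: np.ndarray, entry: NormativeEntry) -> str:
    """Classify a field as ``"within normal limits"``, ``"borderline"`` or
    ``"outside normal limits"`` from mirrored zone scores.

    Outside normal limits when any zone pair's score difference exceeds its
    calibrated 99.5th healthy percentile, or both members of a pair exceed
    the individual-zone limit; borderline when a difference exceeds the
    97th percentile only.
    """
    sup, inf = ght_zone_scores(levels)
    diff = np.abs(sup - inf)
    d_onl = entry.ght_diff_onl
    d_bord = entry.ght_diff_borderline
    high = entry.ght_zone_high
    if d_onl is None or d_bord is None or high is None:
        raise ValueError("normative entry lacks GHT thresholds")
    if np.any(diff > d_onl) or np.any((sup > high) & (inf > high)):
        return "outside normal limits"
    if np.any(diff > d_bord):
        return "borderline"
    return "within normal limits"


# ---------------------------------------------------------------------------
# synthetic normative model
# ---------------------------------------------------------------------------

def _healthy_mean_db(grid: Grid24_2, center_db: float, ecc_slope: float) -> np.ndarray:
    xy = grid.coords()
    ecc = np.hypot(xy[:, 0], xy[:, 1])
    return center_db - ecc_slope * ecc


def _observe_healthy(rng: np.random.Generator, test_type: str, true_mean: np.ndarray,
                     sd: np.ndarray, n: int, discretize: bool) -> np.ndarray:
    raw = true_mean + rng.normal(0.0, 1.0, size=(n, 52)) * sd
    if not discretize:
        return raw
    if test_type == "FDT":
        return quantize_fdt(raw)
    return np.clip(np.rint(raw), 0.0, 40.0)


def synthetic_normative_model(
    n_sim: int = 8000,
    seed: int = 20_2,
    sap_center_db: float = 33.0,
    sap_ecc_slope: float = 0.25,
    sap_sd_db: float = 1.7,
    fdt_center_db: float = 30.0,
    fdt_ecc_slope: float = 0.15,
    fdt_sd_db: float = 2.8,
    discretize: bool = True,
) -> NormativeModel:
    """Build a synthetic normative model calibrated by Monte Carlo.

    Healthy fields are simulated (eccentricity-dependent mean, Gaussian
    test-retest noise, instrument discretization unless ``discretize`` is
    False), and every normative quantity is taken from the simulated
    healthy distribution: per-location means, TD and PD probability
    cutpoints as empirical quantiles, the PSD 95th percentile, and the GHT
    zone-score thresholds.  Deterministic for given arguments.
    """
    grid = build_grid("OD")
    rng = np.random.default_rng(seed)
    zones = ght_zones()
    entries: dict[str, NormativeEntry] = {}
    params = {
        "SAP": (sap_center_db, sap_ecc_slope, sap_sd_db),
        "FDT": (fdt_center_db, fdt_ecc_slope, fdt_sd_db),
    }
    for tt, (center, slope, sd) in params.items():
        true_mean = _healthy_mean_db(grid, center, slope)
        sd_arr = np.full(52, sd)
        obs = _observe_healthy(rng, tt, true_mean, sd_arr, n_sim, discretize)
        mean_db = obs.mean(axis=0)
        td = obs - mean_db
        g = np.sort(td, axis=1)[:, -7]  # general height per simulated field
        pd_map = td - g[:, None]
        q = np.asarray(P_LEVELS)
        td_cuts = np.quantile(td, q[:, None], axis=0).reshape(4, 52)
        pd_cuts = np.quantile(pd_map, q[:, None], axis=0).reshape(4, 52)
        # enforce exact monotonicity against quantile-interpolation ties
        td_cuts = np.minimum.accumulate(td_cuts, axis=0)
        pd_cuts = np.minimum.accumulate(pd_cuts, axis=0)
        psd = td.std(axis=1, ddof=1)
        entry = NormativeEntry(
            test_type=tt,
            mean_db=mean_db,
            sd_db=td.std(axis=0, ddof=1),
            td_cuts=td_cuts,
            pd_cuts=pd_cuts,
            psd_cut95=float(np.quantile(psd, 0.95)),
            true_mean_db=true_mean,
        )
        # GHT calibration on the same healthy simulations
        lv = np.empty((n_sim, 52))
        for j in range(n_sim):
            lv[j] = probability_levels(pd_map[j], entry)
        diffs = np.empty((n_sim, len(zones)))
        scores = np.empty((n_sim, len(zones), 2))
        for j in range(n_sim):
            s, i = ght_zone_scores(lv[j], zones)
            diffs[j] = np.abs(s - i)
            scores[j, :, 0], scores[j, :, 1] = s, i
        entry.ght_diff_borderline = np.quantile(diffs, 0.97, axis=0)
        entry.ght_diff_onl = np.quantile(diffs, 0.995, axis=0)
        entry.ght_zone_high = np.quantile(scores.reshape(n_sim, -1).max(axis=1),
                                          0.995) * np.ones(len(zones))
        entries[tt] = entry
    return NormativeModel(entries=entries)
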