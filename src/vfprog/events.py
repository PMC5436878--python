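"""Cluster-based event criteria for the onset of glaucomatous VF defects.

An eye develops a visual-field defect when a qualifying cluster — at least
``min_cluster_size`` adjacent locations in the same hemifield on the
pattern-deviation plot, all at P < 5% or worse with at least one at
P < 1% or worse — appears on a test and is confirmed on two additional
consecutive reliable tests (three consecutive qualifying tests in total).
Two conservatism levels are used: cluster size >= 3 ("less conservative")
and >= 4 ("more conservative").  Eyes that never meet the criterion are
censored at their last reliable follow-up.

Baseline eligibility screening uses a related but distinct rule: an eye is
abnormal at baseline if, on two consecutive baseline tests of the same
type, it shows a GHT-surrogate result outside normal limits, a PSD above
the healthy 95th percentile, or a qualifying cluster of three *non-edge*
locations.  The edge exclusion applies only to the baseline screen, not to
the follow-up event criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .deviations import NormativeModel, VFSeries, VFTest, ght_surrogate
from .grid import Grid24_2, edge_locations

__all__ = [
    "DefectCriterion",
    "LESS_CONSERVATIVE",
    "MORE_CONSERVATIVE",
    "EventOutcome",
    "find_qualifying_clusters",
    "detect_event",
    "baseline_is_normal",
    "event_summary",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class DefectCriterion:
    """Parameters of the cluster event criterion."""

    min_cluster_size: int = 3
    p_all: float = 0.05  # every cluster member at this level or worse
    p_one: float = 0.01  # at least one member at this level or worse
    n_confirmations: int = 2  # additional consecutive qualifying tests
    same_locations_required: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.min_cluster_size < 3:
            raise ValueError("min_cluster_size must be >= 3")
        if self.n_confirmations < 1:
            raise ValueError("n_confirmations must be >= 1")
        if self.p_one > self.p_all:
            raise ValueError("p_one must be at least as extreme as p_all")


LESS_CONSERVATIVE = DefectCriterion(min_cluster_size=3, name="less_conservative")
MORE_CONSERVATIVE = DefectCriterion(min_cluster_size=4, name="more_conservative")


@dataclass(eq=False)
class EventOutcome:
    """Detection-or-censoring record for one eye and test type."""

    eye_id: str
    subject_id: str
    test_type: str
    detected: bool
    event_time: float | None = None   # days; date of the final confirming test
    censor_time: float | None = None  # days; last reliable follow-up
    qualifying_visits: tuple[int, ...] = ()       # indices in the reliable sequence
    qualifying_clusters: tuple[frozenset, ...] = ()
    too_few_tests: bool = False

    def __post_init__(self) -> None:
        if (self.event_time is None) == (self.censor_time is None):
            raise ValueError("exactly one of event_time / censor_time must be set")

    @property
    def time(self) -> float:
        return self.event_time if self.detected else self.censor_time


def find_qualifying_clusters(
    levels: np.ndarray,
    grid: Grid24_2,
    criterion: DefectCriterion,
    allowed: frozenset[int] | None = None,
) -> set[frozenset[int]]:
    """All maximal qualifying clusters on one probability-level map.

    A cluster is a maximal connected component — under the grid adjacency
    restricted to a single hemifield — of locations at ``p_all`` or worse,
    of size >= ``min_cluster_size``, containing at least one location at
    ``p_one`` or worse.  ``allowed`` optionally restricts the candidate
    locations (used by the baseline screen's non-edge rule).
    """
    levels = np.asarray(levels, dtype=float)
    abnormal = set(np.flatnonzero(levels <= criterion.p_all))
    if allowed is not None:
        abnormal &= set(allowed)
    if not abnormal:
        return set()
    adj = grid.hemifield_adjacency()
    g = nx.Graph()
    g.add_nodes_from(abnormal)
    nodes = sorted(abnormal)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if adj[a, b]:
                g.add_edge(a, b)
    out = set()
    for comp in nx.connected_components(g):
        if len(comp) >= criterion.min_cluster_size and any(
            levels[i] <= criterion.p_one for i in comp
        ):
            out.add(frozenset(int(i) for i in comp))
    return out


def _run_qualifies(clusters_per_test: list[set[frozenset[int]]],
                   criterion: DefectCriterion) -> bool:
    """Whether a window of consecutive tests satisfies the confirmation rule."""
    if any(not c for c in clusters_per_test):
        return False
    if not criterion.same_locations_required:
        return True
    shared = None
    for clusters in clusters_per_test:
        union = frozenset().union(*clusters)
        shared = union if shared is None else shared & union
    return len(shared) >= criterion.min_cluster_size


def detect_event(series: VFSeries, grid: Grid24_2,
                 criterion: DefectCriterion) -> EventOutcome:
    """Scan an eye's reliable-test sequence for a confirmed defect.

    The earliest run of ``1 + n_confirmations`` consecutive reliable tests
    each holding a qualifying cluster triggers detection; the event time is
    the date of the final (confirming) test of the run.  Otherwise the eye
    is censored at its last reliable test.  Tests must carry derived
    probability levels.
    """
    tests = series.reliable_tests()
    need = 1 + criterion.n_confirmations
    base = dict(eye_id=series.eye_id, subject_id=series.subject_id,
                test_type=series.test_type)
    if len(tests) < need:
        last = tests[-1].day if tests else 0.0
        return EventOutcome(detected=False, censor_time=float(last),
                            too_few_tests=True, **base)
    clusters = [
        find_qualifying_clusters(t.levels, grid, criterion) for t in tests
    ]
    for start in range(len(tests) - need + 1):
        window = clusters[start:start + need]
        if _run_qualifies(window, criterion):
            visits = tuple(range(start, start + need))
            return EventOutcome(
                detected=True,
                event_time=float(tests[start + need - 1].day),
                qualifying_visits=visits,
                qualifying_clusters=tuple(
                    frozenset().union(*w) for w in window
                ),
                **base,
            )
    return EventOutcome(detected=False, censor_time=float(tests[-1].day), **base)


def baseline_is_normal(test_pair: tuple[VFTest, VFTest], norm: NormativeModel,
                       grid: Grid24_2) -> bool:
    """Baseline eligibility: True when the eye does NOT show confirmed
    abnormality of its type on both baseline tests.

    Abnormality on a single test = GHT surrogate outside normal limits, or
    PSD above the healthy 95th percentile, or a qualifying cluster of
    three non-edge locations (P < 5% all, P < 1% one).  Only abnormality
    present on *both* tests disqualifies the eye.
    """
    a, b = test_pair
    if a.eye_id != b.eye_id or a.test_type != b.test_type:
        raise ValueError("baseline pair must share eye and test type")
    entry = norm.entry(a.test_type)
    non_edge = frozenset(range(grid.n)) - edge_locations(grid)
    crit = DefectCriterion(min_cluster_size=3)
    for t in (a, b):
        if t.levels is None or t.psd is None:
            raise ValueError("baseline tests must carry derived maps")
        abnormal = (
            ght_surrogate(t.levels, entry) == "outside normal limits"
            or t.psd > entry.psd_cut95
            or bool(find_qualifying_clusters(t.levels, grid, crit,
                                             allowed=non_edge))
        )
        if not abnormal:
            return True
    return False


def event_summary(outcomes: list[EventOutcome]) -> dict:
    """Counts, percentages, 2x2 agreement table and lead times.

    Expects one outcome per eye per test type (SAP and FDT).  Lead time is
    SAP event time minus FDT event time in months (positive = FDT earlier),
    for eyes detected by both.
    """
    df = pd.DataFrame(
        {
            "eye_id": [o.eye_id for o in outcomes],
            "test_type": [o.test_type for o in outcomes],
            "detected": [o.detected for o in outcomes],
            "time": [o.time for o in outcomes],
        }
    )
    wide = df.pivot(index="eye_id", columns="test_type",
                    values=["detected", "time"])
    n = len(wide)
    det = {tt: wide[("detected", tt)].eq(True)
           for tt in ("SAP", "FDT") if ("detected", tt) in wide}
    counts = {tt: int(det[tt].sum()) for tt in det}
    pct = {tt: round(100.0 * counts[tt] / n, 1) if n else 0.0 for tt in det}
    result = {"n_eyes": n, "events": counts, "percent": pct}
    if set(det) == {"SAP", "FDT"}:
        both = det["SAP"] & det["FDT"]
        result["table"] = {
            "both": int(both.sum()),
            "sap_only": int((det["SAP"] & ~det["FDT"]).sum()),
            "fdt_only": int((det["FDT"] & ~det["SAP"]).sum()),
            "neither": int((~det["SAP"] & ~det["FDT"]).sum()),
        }
        lead = (
            wide.loc[both, ("time", "SAP")] - wide.loc[both, ("time", "FDT")]
        ) / DAYS_PER_MONTH
        result["lead_time_months"] = {
            str(k): float(v) for k, v in lead.items()
        }
    return result
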