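import numpy as np
import pytest

from vfprog.deviations import P_NONE, VFTest
from vfprog.events import (LESS_CONSERVATIVE, MORE_CONSERVATIVE,
                           DefectCriterion, baseline_is_normal, detect_event,
                           event_summary, find_qualifying_clusters)
from vfprog.grid import edge_locations
from conftest import levels_from, series_from_levels, xy_index


# ---------------------------------------------------------------------------
# independent oracle: union-find components over abnormal locations
# ---------------------------------------------------------------------------

def oracle_clusters(levels, grid, criterion, allowed=None):
    levels = np.asarray(levels)
    nodes = [i for i in range(52) if levels[i] <= criterion.p_all
             and (allowed is None or i in allowed)]
    parent = {i: i for i in nodes}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in nodes:
        for b in nodes:
            if a < b and grid.adjacency[a, b] \
                    and grid.locations[a].hemifield == grid.locations[b].hemifield:
                parent[find(a)] = find(b)
    comps = {}
    for i in nodes:
        comps.setdefault(find(i), set()).add(i)
    return {
        frozenset(c) for c in comps.values()
        if len(c) >= criterion.min_cluster_size
        and any(levels[i] <= criterion.p_one for i in c)
    }


class TestFindQualifyingClusters:
    def test_all_normal_gives_empty_set(self, grid_od):
        assert find_qualifying_clusters(np.full(52, P_NONE), grid_od,
                                        LESS_CONSERVATIVE) == set()

    def test_three_collinear_neighbours(self, grid_od):
        lv = levels_from({(3, 3): 0.05, (9, 3): 0.05, (15, 3): 0.01},
                         grid=grid_od)
        c3 = find_qualifying_clusters(lv, grid_od, LESS_CONSERVATIVE)
        assert len(c3) == 1 and len(next(iter(c3))) == 3
        assert find_qualifying_clusters(lv, grid_od, MORE_CONSERVATIVE) == set()

    def test_cluster_needs_one_deep_location(self, grid_od):
        lv = levels_from({(3, 3): 0.05, (9, 3): 0.05, (15, 3): 0.02},
                         grid=grid_od)
        assert find_qualifying_clusters(lv, grid_od, LESS_CONSERVATIVE) == set()

    def test_midline_straddle_never_qualifies(self, grid_od):
        lv = levels_from({(3, 3): 0.005, (9, 3): 0.005,
                          (3, -3): 0.005, (9, -3): 0.005}, grid=grid_od)
        assert find_qualifying_clusters(lv, grid_od, LESS_CONSERVATIVE) == set()
        assert find_qualifying_clusters(lv, grid_od, MORE_CONSERVATIVE) == set()

    @pytest.mark.parametrize("criterion", [LESS_CONSERVATIVE, MORE_CONSERVATIVE])
    def test_matches_union_find_oracle_on_random_maps(self, grid_od, criterion):
        rng = np.random.default_rng(4242)
        choices = np.array([P_NONE, 0.05, 0.02, 0.01, 0.005])
        for _ in range(1000):
            lv = rng.choice(choices, size=52,
                            p=[0.75, 0.10, 0.06, 0.05, 0.04])
            assert find_qualifying_clusters(lv, grid_od, criterion) == \
                oracle_clusters(lv, grid_od, criterion)


def _qualifying_map(grid, hemi="sup"):
    pts = {(3, 3): 0.05, (9, 3): 0.05, (15, 3): 0.005} if hemi == "sup" \
        else {(3, -3): 0.05, (9, -3): 0.05, (15, -3): 0.005}
    return levels_from(pts, grid=grid)


class TestDetectEvent:
    def test_event_dated_at_final_confirming_test(self, grid_od):
        q = _qualifying_map(grid_od)
        clean = np.full(52, P_NONE)
        series = series_from_levels([clean, clean, clean, q, q, q])
        out = detect_event(series, grid_od, LESS_CONSERVATIVE)
        assert out.detected
        assert out.event_time == series.tests[5].day
        assert out.qualifying_visits == (3, 4, 5)

    def test_nonconsecutive_qualification_is_censored(self, grid_od):
        q = _qualifying_map(grid_od)
        clean = np.full(52, P_NONE)
        series = series_from_levels([clean, clean, clean, q, clean, q])
        out = detect_event(series, grid_od, LESS_CONSERVATIVE)
        assert not out.detected
        assert out.censor_time == series.tests[-1].day

    def test_earliest_run_wins(self, grid_od):
        q = _qualifying_map(grid_od)
        series = series_from_levels([q] * 6)
        out = detect_event(series, grid_od, LESS_CONSERVATIVE)
        assert out.detected and out.event_time == series.tests[2].day

    def test_too_few_reliable_tests_censors_with_flag(self, grid_od):
        q = _qualifying_map(grid_od)
        series = series_from_levels([q, q], reliable=[True, True])
        out = detect_event(series, grid_od, LESS_CONSERVATIVE)
        assert not out.detected and out.too_few_tests

    def test_unreliable_tests_do_not_break_a_run(self, grid_od):
        q = _qualifying_map(grid_od)
        clean = np.full(52, P_NONE)
        # the unreliable clean exam between qualifying exams is excluded,
        # so the reliable sequence q,q,q remains consecutive
        series = series_from_levels(
            [clean, q, clean, q, q],
            reliable=[True, True, False, True, True],
        )
        out = detect_event(series, grid_od, LESS_CONSERVATIVE)
        assert out.detected and out.event_time == series.tests[4].day

    def test_same_location_mode_requires_overlap(self, grid_od):
        sup = _qualifying_map(grid_od, "sup")
        inf = _qualifying_map(grid_od, "inf")
        strict = DefectCriterion(min_cluster_size=3,
                                 same_locations_required=True)
        wander = series_from_levels([sup, inf, sup])
        assert detect_event(wander, grid_od, LESS_CONSERVATIVE).detected
        assert not detect_event(wander, grid_od, strict).detected
        stable = series_from_levels([sup, sup, sup])
        assert detect_event(stable, grid_od, strict).detected

    def test_truncation_after_detection_is_harmless(self, grid_od):
        q = _qualifying_map(grid_od)
        clean = np.full(52, P_NONE)
        full = series_from_levels([q, q, q, clean, clean])
        cut = series_from_levels([q, q, q])
        a = detect_event(full, grid_od, LESS_CONSERVATIVE)
        b = detect_event(cut, grid_od, LESS_CONSERVATIVE)
        assert a.detected and b.detected and a.event_time == b.event_time


def test_criterion_monotonicity_on_synthetic_cohort(small_cohort, norm):
    """Every size-4 detection is a size-3 detection with no later onset."""
    from vfprog.grid import build_grid
    from vfprog.io import series_from_long
    grids = {"OD": build_grid("OD"), "OS": build_grid("OS")}
    series = series_from_long(small_cohort.vf_long, norm)
    n4 = 0
    for s in series.values():
        g = grids[s.eye_side]
        o3 = detect_event(s, g, LESS_CONSERVATIVE)
        o4 = detect_event(s, g, MORE_CONSERVATIVE)
        if o4.detected:
            n4 += 1
            assert o3.detected and o3.event_time <= o4.event_time
    assert n4 >= 1  # the cohort must exercise the comparison


class TestBaselineScreen:
    def _clean_test(self, norm, tt="SAP"):
        entry = norm.entry(tt)
        return VFTest("s", "e", "OD", 0, tt, entry.mean_db.copy(),
                      0.0, 0.0, 0.0).derive(norm)

    def _defect_test(self, norm, grid, pts, depth=-12.0, tt="SAP"):
        entry = norm.entry(tt)
        idx = xy_index(grid)
        sens = entry.mean_db.copy()
        for p in pts:
            sens[idx[p]] += depth
        return VFTest("s", "e", "OD", 0, tt, sens, 0.0, 0.0, 0.0).derive(norm)

    def test_two_normal_tests_pass(self, norm, grid_od):
        a, b = self._clean_test(norm), self._clean_test(norm)
        assert baseline_is_normal((a, b), norm, grid_od)

    def test_unconfirmed_abnormality_passes(self, norm, grid_od):
        bad = self._defect_test(norm, grid_od, [(3, 3), (9, 3), (15, 3)])
        ok = self._clean_test(norm)
        assert baseline_is_normal((bad, ok), norm, grid_od)

    def test_confirmed_cluster_fails(self, norm, grid_od):
        pts = [(3, 3), (9, 3), (15, 3)]
        a = self._defect_test(norm, grid_od, pts)
        b = self._defect_test(norm, grid_od, pts)
        assert not baseline_is_normal((a, b), norm, grid_od)

    def test_edge_members_do_not_count_toward_baseline_cluster(self, norm,
                                                               grid_od):
        # a 3-cluster with one member on the nasal edge: only 2 non-edge
        # members, so the baseline cluster rule is not met; PSD/GHT may
        # still flag such a deep defect, so keep it shallow and diffuse-free
        idx = xy_index(grid_od)
        edges = edge_locations(grid_od)
        assert idx[(27, 3)] in edges
        pts = [(27, 3), (21, 3), (15, 3)]
        a = self._defect_test(norm, grid_od, pts, depth=-7.0)
        b = self._defect_test(norm, grid_od, pts, depth=-7.0)
        crit = DefectCriterion(min_cluster_size=3)
        non_edge = frozenset(range(52)) - edges
        assert find_qualifying_clusters(a.levels, grid_od, crit,
                                        allowed=non_edge) == set()

    def test_mismatched_pair_rejected(self, norm, grid_od):
        a = self._clean_test(norm, "SAP")
        b = self._clean_test(norm, "FDT")
        with pytest.raises(ValueError):
            baseline_is_normal((a, b), norm, grid_od)


class TestEventSummary:
    def _outcome(self, eye, tt, detected, time):
        from vfprog.events import EventOutcome
        return EventOutcome(
            eye_id=eye, subject_id=eye.split("-")[0], test_type=tt,
            detected=detected,
            event_time=time if detected else None,
            censor_time=None if detected else time,
        )

    def test_percentages_and_table(self):
        outcomes = []
        for i in range(221):
            eye = f"s{i:03d}-OD"
            sap = i < 11
            fdt = i < 8 or (11 <= i < 24)  # 8 both, 3 SAP-only, 13 FDT-only
            outcomes.append(self._outcome(eye, "SAP", sap, 1000.0))
            outcomes.append(self._outcome(eye, "FDT", fdt, 900.0))
        s = event_summary(outcomes)
        assert s["events"] == {"SAP": 11, "FDT": 21}
        assert s["percent"]["FDT"] == 9.5 and s["percent"]["SAP"] == 5.0
        assert s["table"] == {"both": 8, "sap_only": 3, "fdt_only": 13,
                              "neither": 197}

    def test_lead_time_sign_positive_when_fdt_earlier(self):
        outcomes = [
            self._outcome("e1-OD", "SAP", True, 1000.0),
            self._outcome("e1-OD", "FDT", True, 700.0),
        ]
        s = event_summary(outcomes)
        assert s["lead_time_months"]["e1-OD"] == pytest.approx(
            300.0 / (365.25 / 12))

    def test_no_events(self):
        outcomes = [self._outcome("e1-OD", tt, False, 500.0)
                    for tt in ("SAP", "FDT")]
        s = event_summary(outcomes)
        assert s["events"] == {"SAP": 0, "FDT": 0}
        assert s["lead_time_months"] == {}
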