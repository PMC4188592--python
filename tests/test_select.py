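import numpy as np
import pytest
from shapely.geometry import Point, box

from vmekde import (
    Extent,
    KDEConfig,
    SelectionCriteria,
    ThresholdCurve,
    ThresholdStep,
    analyze_records,
    build_curve,
    find_candidates,
    flag_isolated_polygons,
    kde,
    select_threshold,
    summarize_enclosure,
)

from conftest import records_frame


def curve_from_ratios(ratios, base_area=100.0, n_new=10):
    """Synthetic curve whose successive area ratios are exactly `ratios`."""
    steps = [ThresholdStep(float(len(ratios) + 1), [], base_area,
                           n_points_enclosed=5, n_new_points=5,
                           n_new_points_in_new_areas=5)]
    area = base_area
    enclosed = 5
    for i, r in enumerate(ratios):
        area *= r
        enclosed += n_new
        steps.append(ThresholdStep(
            float(len(ratios) - i), [], area,
            n_points_enclosed=enclosed, n_new_points=n_new,
            n_new_points_in_new_areas=n_new // 2,
        ))
    return ThresholdCurve(steps)


class TestFindCandidates:
    def test_single_jump_after_plateau(self):
        curve = curve_from_ratios([1.02, 1.05, 1.58, 1.10])
        cands = find_candidates(curve)
        assert len(cands) == 1
        # thresholds run 5,4,3,2,1: the 1.58 pair is (3, 2), upper 3
        assert cands[0].upper_level == 3.0
        assert cands[0].area_ratio == pytest.approx(1.58)

    def test_gradual_curve_has_no_candidates(self):
        curve = curve_from_ratios([1.15] * 5)
        assert find_candidates(curve) == []

    def test_jump_breaking_the_plateau_is_itself_a_candidate(self):
        curve = curve_from_ratios([1.03, 1.25, 1.02])
        cands = find_candidates(curve)
        assert [c.area_ratio for c in cands] == [pytest.approx(1.25)]

    def test_needs_three_steps(self):
        with pytest.raises(ValueError):
            find_candidates(ThresholdCurve(curve_from_ratios([1.5]).steps[:2]))

    def test_ordered_by_ratio_descending(self):
        curve = curve_from_ratios([1.02, 1.3, 1.7, 1.4])
        cands = find_candidates(curve)
        assert [round(c.area_ratio, 2) for c in cands] == [1.7, 1.4, 1.3]


class TestSelectThreshold:
    def test_unique_qualifying_jump_selects_its_upper_level(self):
        curve = curve_from_ratios([1.02, 1.05, 1.58, 1.10])
        res = select_threshold(curve, records_frame([], [], []))
        assert res.selected_threshold == 3.0
        assert "selected" in res.narrative

    def test_gradual_increase_is_flagged_not_selected(self):
        curve = curve_from_ratios([1.15] * 5)
        res = select_threshold(curve, records_frame([], [], []))
        assert res.selected_threshold is None
        assert res.curve_flags == {"gradual-increase"}

    def test_flat_curve_reports_no_large_jump(self):
        curve = curve_from_ratios([1.01, 1.02, 1.01])
        res = select_threshold(curve, records_frame([], [], []))
        assert res.selected_threshold is None
        assert res.curve_flags == {"no-large-jump"}

    def test_impossible_jump_min_selects_nothing(self):
        curve = curve_from_ratios([1.02, 1.05, 1.58, 1.10])
        res = select_threshold(curve, records_frame([], [], []),
                               SelectionCriteria(jump_min=1e9))
        assert res.selected_threshold is None

    def test_permissive_jump_min_selects_first_post_plateau_step(self):
        curve = curve_from_ratios([1.02, 1.3, 1.5])
        res = select_threshold(curve, records_frame([], [], []),
                               SelectionCriteria(jump_min=1.01))
        # first step out of the establishment plateau wins, not the 1.5 one
        assert res.selected_threshold == 3.0

    def test_single_datum_jump_is_vetoed(self):
        curve = curve_from_ratios([1.02, 1.6], n_new=1)
        res = select_threshold(curve, records_frame([], [], []))
        assert res.selected_threshold is None
        assert "single-point-jump" in res.rejection_flags[0]

    def test_veto_passes_nomination_to_next_jump(self):
        # a one-datum jump precedes a well-supported one: the supported
        # jump's upper level is selected even though its ratio is smaller
        steps = [
            ThresholdStep(5.0, [], 100.0, 5, 5, 5),
            ThresholdStep(4.0, [], 103.0, 5, 0, 0),
            ThresholdStep(3.0, [], 170.0, 6, 1, 1),    # x1.65, single datum
            ThresholdStep(2.0, [], 175.0, 6, 0, 0),
            ThresholdStep(1.0, [], 240.0, 16, 10, 6),  # x1.37, supported
        ]
        res = select_threshold(ThresholdCurve(steps), records_frame([], [], []))
        assert res.selected_threshold == 2.0
        assert "single-point-jump" in res.rejection_flags[0]


class TestRejectionOnRealSurfaces:
    def test_corridor_merge_without_interior_points_is_flagged(self):
        # two kernels 1.2 h apart merge through an empty corridor; the merge
        # step's growth is all bridge, and the bridge holds no new points
        ext = Extent(0, 0, 1000, 1000)
        h = 100.0
        df = records_frame([400.0, 520.0], [500.0, 500.0], [1.0, 1.0])
        surf = kde(df, KDEConfig(h, 2.0, ext))
        saddle = 2 * (1 - 0.6**2) ** 2
        levels = [0.95, 0.9, 0.86, saddle * 1.01, saddle * 0.93]
        curve = build_curve(surf, df, levels)
        res = select_threshold(
            curve, df,
            SelectionCriteria(jump_min=1.1, min_new_points=1, plateau_tol=0.02),
            surf,
        )
        merged = [i for i, c in enumerate(res.candidate_jumps)
                  if c.n_merge_events]
        assert merged and any(
            "merge-without-support" in res.rejection_flags[i] for i in merged
        )

    def test_selection_invariant_to_levels_above_surface_maximum(self,
                                                                 demo_scene):
        res1 = analyze_records(demo_scene.records)
        vmax = res1.surface.values.max()
        extended = [vmax * 4, vmax * 2] + list(res1.levels)
        res2 = analyze_records(demo_scene.records, levels=extended)
        assert (res2.selection.selected_threshold
                == res1.selection.selected_threshold)


class TestSummarizeEnclosure:
    def test_polygons_covering_everything_enclose_all_biomass(self):
        df = records_frame([1, 2, 8], [1, 7, 2], [1.0, 2.0, 3.0])
        bf, af = summarize_enclosure(None, [box(0, 0, 10, 10)], df)
        assert bf == 1.0
        assert af > 1.0  # polygon larger than the points' convex hull

    def test_empty_polygon_set(self):
        df = records_frame([1, 2, 3], [1, 2, 3], [1.0, 2.0, 3.0])
        assert summarize_enclosure(None, [], df) == (0.0, 0.0)

    def test_zero_total_biomass_is_an_error(self):
        df = records_frame([1, 2], [1, 2], [0.0, 0.0])
        with pytest.raises(ValueError):
            summarize_enclosure(None, [box(0, 0, 1, 1)], df)

    def test_explicit_mask_overrides_convex_hull(self):
        df = records_frame([1, 2, 3], [1, 2, 3], [1.0, 2.0, 3.0])
        _, af = summarize_enclosure(None, [box(0, 0, 5, 5)], df,
                                    sampled_area_mask=box(0, 0, 10, 10))
        assert af == pytest.approx(25 / 100)

    def test_concentrated_scene_fractions(self, demo_scene, demo_analysis):
        # most biomass sits in the aggregations, which occupy a small share
        # of the surveyed window
        sel = demo_analysis.selection.selected_threshold
        step = next(s for s in demo_analysis.curve.steps if s.threshold == sel)
        pos = demo_scene.records[demo_scene.records["biomass"] > 0]
        bf, af = summarize_enclosure(demo_analysis.surface, step.polygons,
                                     pos, demo_scene.records)
        assert bf > 0.9
        assert af < 0.35


class TestIsolatedPolygons:
    def test_single_record_polygons_are_flagged(self):
        df = records_frame([1, 5, 5.5], [1, 5, 5.5], [1.0, 1.0, 1.0])
        polys = [box(0, 0, 2, 2), box(4, 4, 6, 6), box(8, 8, 9, 9)]
        assert flag_isolated_polygons(polys, df) == [True, False, False]
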