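import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vmekde import (
    SceneSpec,
    generate_scene,
    harmonize_surveys,
    ks_two_sample,
    make_multisurvey,
    threshold_ladder,
)

from conftest import records_frame


def brute_force_ks(a, b):
    """sup |ECDF_a - ECDF_b| evaluated at every sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    best = 0.0
    for t in np.concatenate([a, b]):
        d = abs(np.mean(a <= t) - np.mean(b <= t))
        best = max(best, d)
    return best


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0 and p == 1

    def test_interleaved_samples_match_hand_derived_statistic(self):
        # ECDFs of (1,2,3) vs (1.5,2.5,3.5) never differ by more than 1/3
        d, _ = ks_two_sample([1, 2, 3], [1.5, 2.5, 3.5])
        assert d == pytest.approx(1 / 3)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 20), st.integers(1, 20))
    def test_matches_ecdf_brute_force(self, seed, na, nb):
        rng = np.random.default_rng(seed)
        a, b = rng.lognormal(0, 1, na), rng.lognormal(0, 1, nb)
        d, _ = ks_two_sample(a, b)
        assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_common_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1.2, 25)
        d0, _ = ks_two_sample(a, b)
        for f in (np.exp, lambda v: v**3, lambda v: 2 * v + 7):
            d1, _ = ks_two_sample(f(a), f(b))
            assert d1 == pytest.approx(d0, abs=1e-12)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        reps, rej = 400, 0
        for _ in range(reps):
            a, b = rng.lognormal(0, 1, 60), rng.lognormal(0, 1, 60)
            rej += ks_two_sample(a, b)[1] < 0.05
        # binomial 99% band around 0.05 at 400 reps
        assert 0.02 <= rej / reps <= 0.085


class TestThresholdLadder:
    def test_restriction_below_both_minima_leaves_d_unchanged(self):
        rng = np.random.default_rng(3)
        a, b = 1 + rng.lognormal(0, 1, 40), 1 + rng.lognormal(0.5, 1, 40)
        rungs = [0.0, 0.2, 0.9]  # all below min(a), min(b)
        ladder = threshold_ladder(a, b, rungs)
        ds = {c.ks_stat for c in ladder}
        assert len(ds) == 1

    def test_rungs_must_strictly_increase(self):
        with pytest.raises(ValueError):
            threshold_ladder([1, 2], [1, 2], [0.5, 0.5])

    def test_insufficient_n_rung_flagged_not_tested(self):
        a = np.linspace(1, 10, 50)
        b = np.linspace(0.1, 0.9, 50)  # all below the top rung
        ladder = threshold_ladder(a, b, [0.0, 1.0], min_n=5)
        top = ladder[-1]
        assert not top.usable and np.isnan(top.ks_stat)
        assert "insufficient n" in top.note

    def test_ascending_order_of_results(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(0, 1, 60), rng.lognormal(0, 1, 60)
        ladder = threshold_ladder(a, b, [0.0, 0.5, 1.0])
        assert [c.weight_threshold for c in ladder] == [0.0, 0.5, 1.0]


def deterministic_lognormal(n, mu=0.0, sigma=1.0):
    """Equally spaced quantiles of a lognormal: a noise-free sample."""
    q = (np.arange(n) + 0.5) / n
    return stats.lognorm.ppf(q, sigma, scale=np.exp(mu))


class TestHarmonizeSurveys:
    def test_contamination_below_cutoff_recovers_cutoff_rung(self):
        # gear B catches below 1 kg halved: distributions differ only
        # below 1 kg, so the ladder should settle exactly on the 1 kg rung
        base = deterministic_lognormal(400)
        contaminated = np.where(base < 1.0, base * 0.5, base)
        df_a = records_frame(np.arange(400), np.arange(400), base,
                             gear="Campelen")
        df_b = records_frame(np.arange(400), np.arange(400), contaminated,
                             gear="Lofoten")
        df = pd.concat([df_a, df_b], ignore_index=True)
        res = harmonize_surveys(df, thresholds=(0.1, 0.25, 0.5, 1.0, 2.0),
                                reference_gear="Campelen")
        assert res.combinable_threshold == 1.0
        assert res.gear_threshold == 1.0

    def test_single_survey_group_is_trivial(self):
        df = records_frame([0, 1, 2], [0, 1, 2], [1, 2, 3])
        res = harmonize_surveys(df, thresholds=(0.0, 1.0))
        assert res.combinable_threshold == 0.0
        assert "no harmonization needed" in res.decision_note

    def test_identical_gears_combine_at_lowest_rung(self):
        base = deterministic_lognormal(500)
        df_a = records_frame(np.arange(500), np.arange(500), base,
                             gear="Campelen")
        df_b = records_frame(np.arange(500), np.arange(500), base,
                             gear="Lofoten")
        df = pd.concat([df_a, df_b], ignore_index=True)
        res = harmonize_surveys(df, thresholds=(0.05, 0.2, 1.0),
                                reference_gear="Campelen")
        assert res.combinable_threshold == 0.05

    def test_duration_then_gear_uses_max_of_both(self):
        # durations differ below 0.5 kg within the reference gear; gears
        # differ below 1 kg: combinable must be the larger of the two
        base = deterministic_lognormal(400)
        d15 = np.where(base < 0.5, base * 0.5, base)
        gearb = np.where(base < 1.0, base * 0.5, base)
        frames = [
            records_frame(np.arange(400), np.arange(400), d15,
                          gear="Campelen", duration=15.0),
            records_frame(np.arange(400), np.arange(400), base,
                          gear="Campelen", duration=30.0),
            records_frame(np.arange(400), np.arange(400), gearb,
                          gear="Lofoten", duration=30.0),
        ]
        df = pd.concat(frames, ignore_index=True)
        res = harmonize_surveys(df, thresholds=(0.1, 0.25, 0.5, 1.0, 2.0),
                                reference_gear="Campelen")
        assert res.duration_threshold == 0.5
        assert res.gear_threshold == 1.0
        assert res.combinable_threshold == 1.0

    def test_heavy_data_reduction_recommends_split_models(self):
        # pooling only possible above a rung that keeps <10% of the records
        base = deterministic_lognormal(300, mu=-1.2, sigma=0.6)
        gearb = np.where(base < 1.0, base * 0.3, base)
        df_a = records_frame(np.arange(300), np.arange(300), base,
                             gear="Campelen")
        df_b = records_frame(np.arange(300), np.arange(300), gearb,
                             gear="Lofoten")
        df = pd.concat([df_a, df_b], ignore_index=True)
        res = harmonize_surveys(df, thresholds=(0.05, 0.2, 1.0),
                                reference_gear="Campelen")
        assert res.combinable_threshold == 1.0
        assert "per-region" in res.decision_note

    def test_pervasive_gear_effect_yields_no_threshold(self):
        scene = generate_scene(SceneSpec(seed=5))
        df = make_multisurvey(scene, {"Campelen": 1.0, "Lofoten": 0.5},
                              cutoff=1e9)
        res = harmonize_surveys(df, thresholds=(0.05, 0.2, 1.0),
                                reference_gear="Campelen")
        assert res.combinable_threshold is None
        assert "not combinable" in res.decision_note
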