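"""Clinical rubrics, GCS composition, normalization and group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mscpotency import (SubScores, compare_groups, global_clinical_score,
                        humanization_filter, normalize_gcs, score_behavior,
                        score_cohort, score_grid, score_strength, score_weight,
                        weight_loss_pct)
from mscpotency.clinical import score_record
from mscpotency.simulate import simulate_cohort


class TestRubrics:
    def test_weight_loss_pct_arithmetic(self):
        assert weight_loss_pct(18, 20) == pytest.approx(10.0)
        assert weight_loss_pct(20, 20) == 0.0
        assert weight_loss_pct(22, 20) == pytest.approx(-10.0)
        with pytest.raises(ValueError):
            weight_loss_pct(18, 0)

    @pytest.mark.parametrize("loss,expected", [
        (-2.0, 0), (0.0, 0), (4.99, 0), (5.0, 1), (9.99, 1), (10.0, 2),
        (12.0, 2), (14.99, 2), (15.0, 3), (40.0, 3)])
    def test_weight_score_bins(self, loss, expected):
        assert score_weight(loss) == expected

    def test_weight_score_death_overrides(self):
        assert score_weight(0.0, dead=True) == 3

    @pytest.mark.parametrize("loss,expected", [
        (-3.0, 0), (0.0, 0), (5.0, 1), (9.99, 1), (10.0, 2), (19.99, 2),
        (20.0, 3), (25.0, 3), (29.99, 3), (30.0, 4), (80.0, 4)])
    def test_strength_score_bins(self, loss, expected):
        assert score_strength(loss) == expected

    def test_strength_score_death_overrides(self):
        assert score_strength(-5.0, dead=True) == 4

    @pytest.mark.parametrize("tr,expected", [
        (60.0, 0), (59.0, 1), (45.0, 1), (44.0, 2), (40.0, 2), (30.0, 2),
        (29.9, 3), (0.0, 3)])
    def test_grid_score_bins(self, tr, expected):
        assert score_grid(tr) == expected

    def test_grid_score_death_and_range(self):
        assert score_grid(60.0, dead=True) == 3
        with pytest.raises(ValueError):
            score_grid(61.0)
        with pytest.raises(ValueError):
            score_grid(-1.0)

    def test_behavior_grade_2_5_rejected(self):
        with pytest.raises(ValueError):
            score_behavior(2.5)
        assert score_behavior(1.5) == 1.5
        assert score_behavior(0.0, dead=True) == 3.0

    @given(st.floats(min_value=-10, max_value=60, allow_nan=False),
           st.floats(min_value=0, max_value=30, allow_nan=False))
    def test_subscores_monotone_in_severity(self, loss, delta):
        assert score_weight(loss + delta) >= score_weight(loss)
        assert score_strength(loss + delta) >= score_strength(loss)
        tr = float(np.clip(loss, 0, 60))
        tr_worse = float(np.clip(loss - delta, 0, 60))
        assert score_grid(tr_worse) >= score_grid(tr)


class TestGlobalScore:
    @pytest.mark.parametrize("sub,expected", [
        (SubScores(2, 3, 2, 1.0), 6.5),
        (SubScores(0, 0, 0, 0.0), 0.0),
        (SubScores(3, 4, 3, 3.0), 10.0)])
    def test_formula(self, sub, expected):
        assert global_clinical_score(sub) == expected

    def test_dead_animal_scores_exactly_ten(self):
        assert global_clinical_score(score_record(0, 0, 60, 0, dead=True)) == 10.0

    @given(st.integers(0, 3), st.integers(0, 4), st.integers(0, 3),
           st.sampled_from([0.0, 0.5, 1.0, 1.5, 2.0, 3.0]))
    def test_bounds_and_monotonicity(self, w, s, g, b):
        gcs = global_clinical_score(SubScores(w, s, g, b))
        assert 0 <= gcs <= 10
        if w < 3:
            worse = global_clinical_score(SubScores(w + 1, s, g, b))
            assert worse >= gcs


class TestNormalize:
    @staticmethod
    def scores(gcs_by_week):
        return pd.DataFrame([{"animal": "m1", "arm": "placebo", "week": w,
                              "gcs": v} for w, v in gcs_by_week.items()])

    def test_ratio_and_difference(self):
        frame = self.scores({2: 3.0, 4: 6.0})
        ratio = normalize_gcs(frame, mode="ratio")
        assert ratio.loc[ratio.week == 4, "normalized_gcs"].item() == 2.0
        assert ratio.loc[ratio.week == 2, "normalized_gcs"].item() == 1.0
        diff = normalize_gcs(frame, mode="difference")
        assert diff.loc[diff.week == 4, "normalized_gcs"].item() == 3.0
        assert diff.loc[diff.week == 2, "normalized_gcs"].item() == 0.0

    def test_missing_baseline_names_animal(self):
        frame = self.scores({3: 3.0})
        with pytest.raises(ValueError, match="m1"):
            normalize_gcs(frame, baseline_week=2)

    def test_zero_baseline_suggests_difference_mode(self):
        frame = self.scores({2: 0.0, 4: 2.0})
        with pytest.raises(ValueError, match="difference"):
            normalize_gcs(frame, mode="ratio")

    def test_ratio_round_trip_recovers_gcs(self):
        rng = np.random.default_rng(8)
        rows = [{"animal": f"m{i}", "arm": "cMSC", "week": w,
                 "gcs": float(rng.integers(1, 11))}
                for i in range(5) for w in range(2, 7)]
        frame = pd.DataFrame(rows)
        norm = normalize_gcs(frame, baseline_week=2, mode="ratio")
        base = frame[frame.week == 2].set_index("animal")["gcs"]
        recovered = norm["normalized_gcs"] * norm["animal"].map(base)
        assert np.allclose(recovered, frame["gcs"], atol=1e-12)


class TestHumanizationFilter:
    def test_one_subthreshold_placebo_gives_n_8(self):
        cohort, truth = simulate_cohort(n_per_arm=9,
                                        planted_failures={"placebo": 1},
                                        seed=42)
        retained, excluded = humanization_filter(cohort, threshold=0.4)
        sizes = retained.groupby("arm")["animal"].nunique()
        assert sizes["placebo"] == 8
        assert sizes["rMSC"] == 9 and sizes["cMSC"] == 9
        assert list(excluded["animal"]) == truth.humanization_failures

    def test_no_exclusions_when_all_humanized(self):
        cohort, _ = simulate_cohort(n_per_arm=4, seed=0)
        retained, excluded = humanization_filter(cohort)
        assert excluded.empty
        assert retained["animal"].nunique() == 12

    def test_matches_brute_force_scan(self):
        cohort, _ = simulate_cohort(n_per_arm=6, humanization_fail_rate=0.3,
                                    seed=9)
        _, excluded = humanization_filter(cohort)
        last = cohort.sort_values("week").groupby("animal")["cd45_pct"].last()
        brute = sorted(last.index[last < 0.4])
        assert sorted(excluded["animal"]) == brute


class TestCompareGroups:
    @staticmethod
    def normalized_from(cohort):
        scores = score_cohort(cohort)
        return normalize_gcs(scores, baseline_week=2, mode="ratio")

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(7)
        rows = []
        values = rng.uniform(1, 3, size=(6, 3))
        for arm in ("placebo", "cMSC"):
            for i in range(6):
                for j, week in enumerate((3, 4, 5)):
                    rows.append({"animal": f"{arm}{i}", "arm": arm,
                                 "week": week,
                                 "normalized_gcs": values[i, j]})
        comparison = compare_groups(pd.DataFrame(rows))
        assert (comparison.pairwise["p_adj"] > 0.9).all()

    def test_single_group_rejected(self):
        frame = pd.DataFrame({"animal": ["a", "b"], "arm": ["placebo"] * 2,
                              "week": [3, 3], "normalized_gcs": [1.0, 2.0]})
        with pytest.raises(ValueError):
            compare_groups(frame)

    def test_halved_severity_detected_in_majority_of_replicates(self):
        wins = 0
        for seed in range(5):
            cohort, _ = simulate_cohort(n_per_arm=9, seed=300 + seed)
            comparison = compare_groups(self.normalized_from(cohort),
                                        excluded_weeks=(3,))
            pw = comparison.pairwise
            hit = pw[(pw.week.isin([4, 5, 6]))
                     & (pw.group1.isin(["cMSC", "placebo"]))
                     & (pw.group2.isin(["cMSC", "placebo"]))]
            if (hit["p_adj"] < 0.05).any():
                wins += 1
        assert wins >= 4

    def test_permuting_arms_destroys_significance(self):
        cohort, _ = simulate_cohort(n_per_arm=9, seed=77)
        normalized = self.normalized_from(cohort)
        rng = np.random.default_rng(0)
        animals = normalized["animal"].unique()
        arm_of = normalized.drop_duplicates("animal").set_index("animal")["arm"]
        n_sig = 0
        n_perm = 10
        for _ in range(n_perm):
            permuted = pd.Series(rng.permutation(arm_of.to_numpy()),
                                 index=animals)
            shuffled = normalized.copy()
            shuffled["arm"] = shuffled["animal"].map(permuted)
            pw = compare_groups(shuffled, excluded_weeks=(3,)).pairwise
            hit = pw[(pw.week == 5) & (pw.group1.isin(["cMSC", "placebo"]))
                     & (pw.group2.isin(["cMSC", "placebo"]))]
            if (hit["p_adj"] < 0.05).any():
                n_sig += 1
        assert n_sig <= 3  # ~nominal rate, not systematic significance

    def test_excluded_weeks_dropped_from_summary(self):
        cohort, _ = simulate_cohort(n_per_arm=4, seed=1)
        comparison = compare_groups(self.normalized_from(cohort),
                                    excluded_weeks=(3, 7))
        assert 3 not in set(comparison.summary["week"])


class TestEffectRecovery:
    def test_planted_multiplier_recovered_within_ten_percent(self):
        cohort, truth = simulate_cohort(n_per_arm=50, seed=11)
        scores = score_cohort(cohort)
        norm = normalize_gcs(scores, baseline_week=2, mode="ratio")
        post = norm[norm.week > 2]
        means = post.groupby("arm")["normalized_gcs"].mean()
        ratio = means["cMSC"] / means["placebo"]
        planted = truth.effect_multiplier["cMSC"]
        assert abs(ratio - planted) / planted < 0.10

    def test_dead_animals_carry_maximal_score_forward(self):
        cohort, truth = simulate_cohort(n_per_arm=9, death_hazard=0.4,
                                        seed=13)
        assert truth.deaths  # hazard high enough to plant deaths
        scores = score_cohort(cohort, death_mode="carry_forward")
        dead_rows = scores[scores.dead]
        assert (dead_rows["gcs"] == 10.0).all()
        dropped = score_cohort(cohort, death_mode="drop_after_death")
        assert len(dropped) < len(scores)
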