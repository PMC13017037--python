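"""Trait-index formulas, criterion detection, and table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitnet.cohort import CohortConfig, generate_cohort
from traitnet.scoring import (
    TRAITS,
    basal_per_gram,
    build_trait_table,
    chance_level,
    days_to_criterion,
    lateralization_indices,
    percent_change,
    phase_index,
    zone_percentage,
)


class TestFormulas:
    @pytest.mark.parametrize(
        "value, baseline, expected",
        [(5.5, 5.0, 10.0), (300, 150, 100.0), (7.3, 7.3, 0.0), (4.5, 5.0, -10.0)],
    )
    def test_percent_change(self, value, baseline, expected):
        assert percent_change(value, baseline) == pytest.approx(expected)

    def test_percent_change_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            percent_change(1.0, 0.0)

    @pytest.mark.parametrize(
        "time_in, denom, expected",
        [(1200, 1800, 66.666667), (0, 1800, 0.0), (1800, 1800, 100.0)],
    )
    def test_zone_percentage(self, time_in, denom, expected):
        assert zone_percentage(time_in, denom) == pytest.approx(expected)

    def test_sociability_excludes_center_time(self):
        # near=300 s, center=600 s of an 1800 s trial -> 300/1200 = 25%
        assert zone_percentage(300, 1800 - 600) == pytest.approx(25.0)

    def test_zone_percentage_zero_denominator_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(zone_percentage(0, 0))

    @pytest.mark.parametrize(
        "cw, ccw, rel, ab",
        [(300, 100, 50.0, 50.0), (250, 250, 0.0, 0.0), (0, 400, -100.0, 100.0)],
    )
    def test_lateralization_indices(self, cw, ccw, rel, ab):
        assert lateralization_indices(cw, ccw) == pytest.approx((rel, ab))

    def test_lateralization_zero_times_is_missing(self):
        with pytest.warns(UserWarning):
            rel, ab = lateralization_indices(0, 0)
        assert np.isnan(rel) and np.isnan(ab)

    @given(cw=st.floats(0, 1800), ccw=st.floats(0, 1800))
    @settings(deadline=None, max_examples=100)
    def test_lateralization_bounds_and_identity(self, cw, ccw):
        if cw + ccw == 0:
            return
        rel, ab = lateralization_indices(cw, ccw)
        assert -100 <= rel <= 100
        assert ab == abs(rel)

    @pytest.mark.parametrize(
        "bpm, weight, expected", [(172, 2.0, 86.0), (0, 1.5, 0.0), (160, 1.6, 100.0)]
    )
    def test_basal_per_gram(self, bpm, weight, expected):
        assert basal_per_gram(bpm, weight) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "after, before, expected", [(8, 4, -1.0), (5, 5, 0.0), (2, 4, 0.5)]
    )
    def test_phase_index(self, after, before, expected):
        assert phase_index(after, before) == pytest.approx(expected)

    def test_phase_index_rejects_zero_baseline(self):
        with pytest.raises(ValueError):
            phase_index(3, 0)


class TestCriterion:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([3, 4, 5, 6], 4),          # windows 7, 9, 11 -> day 4
            ([6, 4], 2),                # fastest possible learner
            ([5, 4, 5, 4, 5], None),    # all windows <= 9
            ([5, 5], 2),                # boundary: exactly 10 of 12
            ([], None),
            ([6], None),                # one day can never satisfy a 2-day rule
        ],
    )
    def test_days_to_criterion(self, counts, expected):
        assert days_to_criterion(counts) == expected

    def test_rejects_out_of_range_counts(self):
        with pytest.raises(ValueError):
            days_to_criterion([3, 7])

    @given(
        counts=st.lists(st.integers(0, 6), min_size=2, max_size=12),
        extra=st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    @settings(deadline=None, max_examples=200)
    def test_invariant_to_days_after_criterion(self, counts, extra):
        d = days_to_criterion(counts)
        if d is not None:
            assert days_to_criterion(counts[:d] + extra) == d

    def test_overlapping_windows_beat_disjoint_blocks(self):
        # days 2+3 reach 10 but the aligned blocks (1,2) and (3,4) never do
        assert days_to_criterion([2, 5, 5, 2]) == 3


class TestChanceLevel:
    def test_open_field_band_rounds_to_40(self):
        assert round(chance_level("open_field", 40, 4.5)) == 40
        assert chance_level("open_field", 40, 4.5) == pytest.approx(39.9375)

    @pytest.mark.parametrize("band, expected", [(0, 0.0), (20, 100.0)])
    def test_band_boundaries(self, band, expected):
        assert chance_level("open_field", 40, band) == pytest.approx(expected)

    def test_half_split_apparatuses(self):
        assert chance_level("scototaxis") == 50.0
        assert chance_level("sociability") == 50.0

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            chance_level("open_field", 40, 25)


class TestBuildTraitTable:
    def test_behavior_scores_average_the_two_trials(self, cohort24):
        table = build_trait_table(cohort24)
        of = cohort24.open_field
        s = of.subject.iloc[0]
        per_trial = [
            zone_percentage(r.time_outer_s, r.time_total_s)
            for r in of[of.subject == s].sort_values("trial").itertuples()
        ]
        assert table.at[s, "thigmotaxis"] == pytest.approx(np.mean(per_trial))

    def test_missing_phase_propagates_only_to_dependent_cells(self):
        cohort = generate_cohort(CohortConfig(seed=2, missing_rate=0.0))
        s = cohort.subjects[0]
        cohort.maze = cohort.maze[
            ~((cohort.maze.subject == s) & (cohort.maze.phase == "memory"))
        ]
        table = build_trait_table(cohort)
        assert np.isnan(table.at[s, "memory"])
        assert table.loc[s].drop("memory").notna().all()

    def test_first_trial_control_matches_trial_one_exactly(self, cohort24):
        table = build_trait_table(cohort24, lateralization_trials="first")
        lat = cohort24.lateralization
        row = lat[(lat.test == "motor") & (lat.trial == 1)].iloc[0]
        rel, ab = lateralization_indices(row.time_cw_s, row.time_ccw_s)
        assert table.at[row.subject, "motor_lat_rel"] == pytest.approx(rel)
        assert table.at[row.subject, "motor_lat_abs"] == pytest.approx(ab)

    def test_raw_control_variables(self, cohort24):
        table = build_trait_table(cohort24, stress="raw", flexibility="raw_days")
        vent = cohort24.ventilation.set_index(["subject", "condition"])
        s = cohort24.subjects[0]
        assert table.at[s, "stress_metabolism"] == pytest.approx(
            float(vent.loc[(s, "stress"), "bpm"])
        )
        # raw flexibility column holds reversal days-to-criterion (integers)
        vals = table["flexibility"].dropna()
        assert (vals == vals.round()).all() and (vals >= 2).all()

    def test_table_invariants(self, trait_table24):
        t = trait_table24
        assert list(t.columns) == TRAITS
        for col in ("thigmotaxis", "scototaxis", "sociability"):
            assert t[col].dropna().between(0, 100).all()
        for col in ("motor_lat_rel", "visual_lat_rel"):
            assert t[col].dropna().between(-100, 100).all()
        for col in ("motor_lat_abs", "visual_lat_abs"):
            assert t[col].dropna().between(0, 100).all()
        assert (t["spatial_learning"].dropna() >= 2).all()

    def test_subject_order_independence(self, cohort24):
        table = build_trait_table(cohort24)
        shuffled = cohort24.copy()
        shuffled.subjects = list(reversed(cohort24.subjects))
        table2 = build_trait_table(shuffled)
        pd.testing.assert_frame_equal(table.sort_index(), table2.sort_index())

    def test_duplicate_subject_ids_rejected(self, cohort24):
        bad = cohort24.copy()
        bad.subjects = list(cohort24.subjects)
        bad.subjects[1] = bad.subjects[0]
        with pytest.raises(ValueError, match="duplicate"):
            build_trait_table(bad)
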