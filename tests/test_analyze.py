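"""Heatmap aggregation, localization scoring and the summary statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortexcam import analyze as an
from cortexcam import synthdata as sd


class TestAggregate:
    def test_identical_heatmaps_mean(self):
        h = np.random.default_rng(0).standard_normal((3, 4, 4))
        h[:] = h[0]
        agg = an.aggregate_heatmaps(h, [1, 1, 1], [1, 1, 1], "patient", "correct")
        assert agg.n_samples == 3
        assert np.allclose(agg.values, h[0])

    def test_opposite_heatmaps_cancel(self):
        h0 = np.random.default_rng(1).standard_normal((4, 4))
        agg = an.aggregate_heatmaps(
            np.stack([h0, -h0]), [1, 1], [1, 1], "patient", "correct"
        )
        assert np.abs(agg.values).max() < 1e-12

    def test_cells_match_hand_computed_means(self):
        """6 hand-made heatmaps across a mixed correctness/group fixture."""
        maps = np.arange(6, dtype=float).reshape(6, 1, 1)
        labels = [1, 1, 1, 0, 0, 0]
        preds = [1, 0, 1, 0, 0, 1]
        cells = {
            ("patient", "correct"): (0 + 2) / 2,
            ("patient", "incorrect"): 1.0,
            ("control", "correct"): (3 + 4) / 2,
            ("control", "incorrect"): 5.0,
            ("all", "correct"): (0 + 2 + 3 + 4) / 4,
        }
        total = 0
        for (grp, corr), want in cells.items():
            agg = an.aggregate_heatmaps(maps, preds, labels, grp, corr)
            assert agg.values[0, 0] == pytest.approx(want)
            if grp != "all":
                total += agg.n_samples
        assert total == 6

    def test_empty_cell_is_missing(self):
        maps = np.ones((2, 2, 2))
        agg = an.aggregate_heatmaps(maps, [1, 1], [1, 1], "patient", "incorrect")
        assert agg.values is None and agg.n_samples == 0

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            an.aggregate_heatmaps(np.ones((2, 2, 2)), [1], [1, 0])


class TestRoiTimeCourse:
    def _agg(self, values):
        return an.AggregateHeatmap(values, 1, "lrp", "patient", "correct")

    def test_peak_at_hot_bin(self):
        h = np.zeros((4, 4, 16))
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = True
        h[1, 1, 6] = 3.0  # 300-350 ms bin
        tc = an.roi_time_course(self._agg(h), mask)
        assert tc.peak_window_ms == (300.0, 350.0)

    def test_uniform_ties_to_earliest(self):
        h = np.ones((4, 4, 16))
        mask = np.ones((4, 4), bool)
        tc = an.roi_time_course(self._agg(h), mask)
        assert tc.peak_window_ms == (0.0, 50.0)

    def test_magnitude_is_default(self):
        h = np.zeros((2, 2, 16))
        mask = np.ones((2, 2), bool)
        h[..., 3] = -5.0
        h[..., 9] = 2.0
        assert an.roi_time_course(self._agg(h), mask).peak_window_ms == (150.0, 200.0)
        signed = an.roi_time_course(self._agg(h), mask, magnitude=False)
        assert signed.peak_window_ms == (450.0, 500.0)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            an.roi_time_course(self._agg(np.ones((2, 2, 16))), np.zeros((2, 2), bool))


class TestLocalizationScore:
    def _agg(self, values):
        return an.AggregateHeatmap(values, 1, "ggcam", "patient", "correct")

    def test_heatmap_equals_mask_scores_one(self):
        mask = np.zeros((6, 6, 4), bool)
        mask[2:4, 2:4, 1] = True
        assert an.localization_score(self._agg(mask.astype(float)), mask) == 1.0

    def test_independent_noise_is_chance(self):
        rng = np.random.default_rng(7)
        mask = np.zeros((10, 10, 8), bool)
        mask[3:6, 3:6, 2] = True
        aucs = [
            an.localization_score(self._agg(rng.standard_normal(mask.shape)), mask)
            for _ in range(30)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_monotone_in_snr(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((10, 10, 8), bool)
        mask[3:6, 3:6, 2] = True
        noise = rng.standard_normal(mask.shape)
        aucs = [
            an.localization_score(self._agg(s * mask + noise), mask)
            for s in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b >= a for a, b in zip(aucs, aucs[1:]))
        assert aucs[-1] > 0.9

    def test_degenerate_mask_errors(self):
        with pytest.raises(ValueError):
            an.localization_score(self._agg(np.ones((2, 2))), np.ones((2, 2), bool))


class TestSummaryStats:
    """The group statistics recompute the printed clinical-table values."""

    @pytest.mark.parametrize(
        "ctl,pat,expected",
        [
            ((66.00, 6.37), (65.96, 5.94), -0.01),   # age
            ((4.94, 3.36), (47.53, 19.46), 3.05),    # RBD questionnaire
            ((5.88, 4.40), (13.02, 7.76), 1.13),     # autonomic scale
            ((3.39, 1.55), (6.92, 4.31), 1.09),      # sleep quality
            ((4.2, 2.74), (5.27, 3.32), 0.35),       # daytime sleepiness
            ((27.45, 1.49), (25.57, 3.04), -0.78),   # MoCA total
            ((28.88, 1.29), (27.27, 2.14), -0.91),   # MMSE
        ],
    )
    def test_cohen_d_reproduces_printed_values(self, ctl, pat, expected):
        # agreement at the tables' printed precision; the summaries are
        # themselves rounded, so allow one unit in the second decimal
        d = an.cohen_d(ctl[0], ctl[1], 49, pat[0], pat[1], 49)
        assert d == pytest.approx(expected, abs=0.01)

    def test_cohen_d_identical_groups_zero(self):
        assert an.cohen_d(5.0, 2.0, 10, 5.0, 2.0, 10) == 0.0

    def test_cohen_d_zero_sd_missing(self):
        assert np.isnan(an.cohen_d(1.0, 0.0, 5, 2.0, 0.0, 5))

    def test_t_test_age_row(self):
        t, p = an.independent_t_test(66.00, 6.37, 49, 65.96, 5.94, 49)
        assert p == pytest.approx(0.974, abs=0.002)

    def test_t_test_equal_means(self):
        t, p = an.independent_t_test(3.0, 1.0, 10, 3.0, 1.0, 10)
        assert t == 0.0 and p == 1.0

    def test_t_test_degenerate_equal(self):
        assert an.independent_t_test(2.0, 0.0, 5, 2.0, 0.0, 5) == (0.0, 1.0)

    def test_fisher_exact_vs_enumeration(self):
        """Two-sided p by exhaustive hypergeometric enumeration with fixed
        margins; the sex table prints 0.529."""
        table = np.array([[33, 16], [29, 20]])
        p = an.fisher_exact(table)

        n1, n2 = table[0].sum(), table[1].sum()
        c1 = table[:, 0].sum()
        obs = stats.hypergeom.pmf(table[0, 0], n1 + n2, n1, c1)
        total = 0.0
        for a in range(max(0, c1 - n2), min(n1, c1) + 1):
            pa = stats.hypergeom.pmf(a, n1 + n2, n1, c1)
            if pa <= obs * (1 + 1e-12):
                total += pa
        assert p == pytest.approx(total, abs=1e-12)
        assert p == pytest.approx(0.529, abs=1e-3)

    def test_pearson_directions(self):
        x = np.arange(10.0)
        rho, p = an.pearson_one_tailed(x, x, "positive")
        assert rho == pytest.approx(1.0) and p < 1e-12
        rho, p = an.pearson_one_tailed(x, -x, "positive")
        assert rho == pytest.approx(-1.0) and p > 0.999

    def test_pearson_rho26_significant_at_98(self):
        """A construction with sample rho = 0.26 at n = 98 is one-tailed
        significant below 0.01, cross-checked against the t-distribution."""
        rng = np.random.default_rng(0)
        n = 98
        x = rng.standard_normal(n)
        xc = x - x.mean()
        xc /= np.linalg.norm(xc)
        e = rng.standard_normal(n)
        e -= e.mean()
        e -= (e @ xc) * xc  # orthogonalize against x
        e /= np.linalg.norm(e)
        target = 0.26
        y = target * xc + np.sqrt(1 - target**2) * e
        rho, p = an.pearson_one_tailed(x, y, "positive")
        assert rho == pytest.approx(target, abs=1e-9)
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        assert p == pytest.approx(stats.t.sf(t, n - 2), rel=1e-9)
        assert p < 0.01

    def test_matches_reference_library_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.standard_normal(12) * rng.uniform(0.5, 2)
            b = rng.standard_normal(15) + rng.uniform(-1, 1)
            t_ref = stats.ttest_ind(a, b)
            t, p = an.independent_t_test(
                a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
            )
            assert t == pytest.approx(t_ref.statistic, rel=1e-9)
            assert p == pytest.approx(t_ref.pvalue, rel=1e-9)
            x, y = rng.standard_normal((2, 20))
            rho, p1 = an.pearson_one_tailed(x, y, "positive")
            ref = stats.pearsonr(x, y, alternative="greater")
            assert rho == pytest.approx(ref.statistic, rel=1e-12)
            assert p1 == pytest.approx(ref.pvalue, rel=1e-9)


class TestRoiMeanCurrentDensity:
    def _sets(self, small_surface, values):
        out = []
        for i, v in enumerate(values):
            data = np.full((2, small_surface.n_vertices, 800), v, dtype=np.float32)
            out.append(
                sd.SourceTrialSet(
                    data=data, t_start_ms=-1200.0, t_end_ms=800.0, fs_hz=400.0,
                    subject_id=f"s{i}", group="control" if i % 2 == 0 else "patient",
                )
            )
        return out

    def test_constant_sources(self, small_surface):
        sets = self._sets(small_surface, [1.5, -2.0])
        df = an.roi_mean_current_density(sets, small_surface, 0, (300, 350))
        assert df.roi_mean.tolist() == pytest.approx([1.5, -2.0])

    def test_unknown_region(self, small_surface):
        sets = self._sets(small_surface, [1.0])
        with pytest.raises(ValueError):
            an.roi_mean_current_density(sets, small_surface, 99, (300, 350))

    def test_patients_attenuated(self, small_surface, small_effect, tiny_cohort):
        table, sets = tiny_cohort
        df = an.roi_mean_current_density(
            sets, small_surface, small_effect.roi_region_id, small_effect.window_ms
        )
        g = df.merge(table[["subject_id", "group"]], on="subject_id", suffixes=("", "_t"))
        assert (
            g[g.group == "patient"].roi_mean.mean()
            < g[g.group == "control"].roi_mean.mean()
        )

    def test_correlation_recovery_with_scores(self, small_surface, small_effect, tiny_cohort):
        table, sets = tiny_cohort
        scored = sd.simulate_clinical_scores(table, 0.9, "mmse_like", seed=5)
        df = an.roi_mean_current_density(
            sets, small_surface, small_effect.roi_region_id, small_effect.window_ms
        )
        merged = df.merge(scored, on="subject_id")
        rho, _ = an.pearson_one_tailed(merged.roi_mean, merged.mmse_like, "positive")
        assert rho > 0.5  # strong target at small n


def test_group_stats_table_layout():
    df = pd.DataFrame(
        {
            "group": ["control"] * 5 + ["patient"] * 5,
            "v": [1, 2, 3, 2, 1, 4, 5, 6, 5, 4],
        }
    )
    out = an.group_stats_table(df, ["v"])
    row = out.iloc[0]
    assert row.variable == "v"
    assert row.patient_mean > row.control_mean
    assert row.p_value < 0.01
    assert row.cohen_d > 0
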