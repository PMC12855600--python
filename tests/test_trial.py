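"""EQ-5D mapping, QALY areas, missingness accounting, panel regressions."""

import numpy as np
import pandas as pd
import pytest

from ahusce.simulate import GeneratorConfig, generate_trial_panel
from ahusce.trial import (
    SCHEDULED_MONTHS,
    TrialPanel,
    auc_qalys,
    fit_panel_model,
    map_eq5d,
    missingness_report,
    synthetic_crosswalk,
)


@pytest.fixture(scope="module")
def crosswalk():
    return synthetic_crosswalk()


class TestCrosswalkMapping:
    def test_full_health_maps_to_one(self, crosswalk):
        assert map_eq5d((1, 1, 1, 1, 1), crosswalk) == pytest.approx(1.0)

    def test_missing_dimension_propagates(self, crosswalk):
        assert np.isnan(map_eq5d((1, 1, np.nan, 1, 1), crosswalk))

    def test_tabulated_profile_lookup(self, crosswalk):
        expected = float(
            crosswalk.set_index("profile").loc["22222", "utility"]
        )
        assert map_eq5d((2, 2, 2, 2, 2), crosswalk) == expected

    def test_crosswalk_monotone_in_every_dimension(self, crosswalk):
        cw = crosswalk.set_index("profile")["utility"]
        base = list("22222")
        for d in range(5):
            worse = base.copy()
            worse[d] = "4"
            assert cw["".join(worse)] < cw["".join(base)]

    def test_covers_all_profiles(self, crosswalk):
        assert len(crosswalk) == 5**5
        assert crosswalk["utility"].min() == pytest.approx(-0.2)


class TestAUC:
    def test_constant_utility_two_years(self):
        months = np.array(SCHEDULED_MONTHS)
        assert auc_qalys(np.ones(len(months)), months) == pytest.approx(2.0)

    def test_two_point_trapezoid(self):
        assert auc_qalys([0.8, 0.6], [0, 24]) == pytest.approx(1.4)

    def test_all_missing_is_incomplete(self):
        assert np.isnan(auc_qalys([np.nan] * 8, SCHEDULED_MONTHS))

    def test_missing_baseline_is_incomplete(self):
        assert np.isnan(auc_qalys([np.nan, 0.9, 0.8], [0, 12, 24]))

    def test_interior_gap_uses_available_visits(self):
        # trapezoid over observed visits only: (0,1.0) -> (24,0.5)
        assert auc_qalys([1.0, np.nan, 0.5], [0, 12, 24]) == pytest.approx(1.5)


class TestMissingness:
    def _panel(self, rows):
        base_cols = {f"eq5d_{i}": 1 for i in range(1, 6)}
        df = pd.DataFrame([
            {"patient_id": pid, "arm": arm, "age": 40, "male": 1, "month": m,
             **base_cols, "utility": u, "monthly_cost": c, "relapse": 0}
            for pid, arm, m, u, c in rows
        ])
        return TrialPanel(df)

    def test_fully_complete_panel(self):
        rows = [("A", "withdrawal", m, 0.9, 100.0) for m in SCHEDULED_MONTHS]
        rows += [("B", "comparison", m, 0.9, 100.0) for m in SCHEDULED_MONTHS]
        rep = missingness_report(self._panel(rows)).set_index(["instrument", "arm"])
        assert (rep["prop_any_missing"] == 0.0).all()

    def test_single_missing_visit_flags_patient(self):
        rows = [("A", "withdrawal", m, (np.nan if m == 3 else 0.9), 100.0)
                for m in SCHEDULED_MONTHS]
        rep = missingness_report(self._panel(rows)).set_index(["instrument", "arm"])
        assert rep.loc[("eq5d", "withdrawal"), "prop_any_missing"] == 1.0
        assert rep.loc[("cost", "withdrawal"), "prop_any_missing"] == 0.0

    def test_generator_calibration_at_scale(self):
        """MCAR rates hit the published any-missing proportions."""
        cfg = GeneratorConfig(seed=5, n_withdrawal=600, n_comparison=600, n_outliers=0)
        rep = missingness_report(generate_trial_panel(cfg)).set_index(["instrument", "arm"])
        for (inst, arm), target in (
            (("eq5d", "withdrawal"), 0.61),
            (("eq5d", "comparison"), 0.91),
            (("cost", "withdrawal"), 0.57),
            (("cost", "comparison"), 0.91),
        ):
            se = np.sqrt(target * (1 - target) / 600)
            assert rep.loc[(inst, arm), "prop_any_missing"] == pytest.approx(
                target, abs=3.5 * se
            ), (inst, arm)


class TestPanelModel:
    def test_zero_noise_zero_effects_gives_zero_coefficients(self):
        cfg = GeneratorConfig(
            seed=2, n_withdrawal=40, n_comparison=40, n_outliers=0,
            utility_residual_sd=1e-8, utility_intercept_sd=1e-8,
            utility_baseline_sd=0.03, utility_baseline_mean=0.6,
            utility_month_slope=0.0, utility_age_effect=0.0,
            utility_male_effect=0.0, utility_withdrawal_effect=0.0,
            utility_relapse_effect=0.0, utility_const=0.0,
            utility_baseline_slope=1.0,
            p_any_missing_eq5d=(0.0, 0.0), p_any_missing_cost=(0.0, 0.0),
        )
        res = fit_panel_model(generate_trial_panel(cfg), "utility")
        for name in ("month", "age", "male", "withdrawal", "relapse", "const"):
            assert res.coef(name) == pytest.approx(0.0, abs=1e-6), name
        assert res.coef("baseline") == pytest.approx(1.0, abs=1e-6)

    def test_recovers_published_utility_effects_at_n500(self):
        """Generating truths (the published withdrawal and relapse effects)
        fall inside their 95% CIs at 500 patients."""
        cfg = GeneratorConfig(
            seed=18, n_withdrawal=300, n_comparison=200, n_outliers=0,
            utility_baseline_mean=0.70,  # away from the EQ-5D ceiling
            p_any_missing_eq5d=(0.3, 0.3), p_any_missing_cost=(0.3, 0.3),
        )
        res = fit_panel_model(generate_trial_panel(cfg), "utility")
        for name, truth in (
            ("withdrawal", cfg.utility_withdrawal_effect),
            ("relapse", cfg.utility_relapse_effect),
            ("month", cfg.utility_month_slope),
        ):
            lo, hi = res.ci(name)
            assert lo <= truth <= hi, (name, truth, lo, hi)

    def test_recovers_published_cost_slopes_at_n500(self):
        cfg = GeneratorConfig(
            seed=23, n_withdrawal=300, n_comparison=200, n_outliers=0,
            p_any_missing_eq5d=(0.3, 0.3), p_any_missing_cost=(0.3, 0.3),
        )
        res = fit_panel_model(generate_trial_panel(cfg), "monthly_cost")
        for name, truth in (
            ("baseline", cfg.cost_baseline_slope),
            ("withdrawal", cfg.cost_withdrawal_effect),
            ("relapse", cfg.cost_relapse_effect),
        ):
            lo, hi = res.ci(name)
            assert lo <= truth <= hi, (name, truth, lo, hi)

    def test_ci_coverage_over_replicates(self):
        """Per-coefficient 95% CI coverage >= 90% over 50 seeded replicates
        (utility model, ceiling-free regime)."""
        names = ("month", "age", "male", "baseline", "withdrawal", "relapse", "const")
        hits = {k: 0 for k in names}
        reps = 50
        for r in range(reps):
            cfg = GeneratorConfig(
                seed=1000 + r, n_withdrawal=120, n_comparison=80, n_outliers=0,
                utility_baseline_mean=0.70,
                p_any_missing_eq5d=(0.3, 0.3), p_any_missing_cost=(0.3, 0.3),
            )
            res = fit_panel_model(generate_trial_panel(cfg), "utility")
            truth = dict(
                month=cfg.utility_month_slope, age=cfg.utility_age_effect,
                male=cfg.utility_male_effect, baseline=cfg.utility_baseline_slope,
                withdrawal=cfg.utility_withdrawal_effect,
                relapse=cfg.utility_relapse_effect, const=cfg.utility_const,
            )
            for k in names:
                lo, hi = res.ci(k)
                hits[k] += lo <= truth[k] <= hi
        for k in names:
            assert hits[k] / reps >= 0.90, (k, hits[k] / reps)

    def test_singular_design_names_columns(self):
        cfg = GeneratorConfig(seed=3, n_withdrawal=20, n_comparison=10, n_outliers=0,
                              p_any_missing_eq5d=(0.0, 0.0), p_any_missing_cost=(0.0, 0.0))
        panel = generate_trial_panel(cfg)
        df = panel.data.copy()
        df["age"] = 50.0  # no variation
        df["male"] = 1
        with pytest.raises(ValueError, match="singular"):
            fit_panel_model(TrialPanel(df), "utility")

    def test_outlier_exclusion_changes_summaries(self):
        cfg = GeneratorConfig(seed=9)
        panel = generate_trial_panel(cfg)
        outlier_id = f"W{cfg.n_withdrawal:02d}"
        kept = panel.exclude_patients([outlier_id])
        assert kept.data["patient_id"].nunique() == panel.data["patient_id"].nunique() - 1
        mean_with = panel.data["monthly_cost"].mean()
        mean_without = kept.data["monthly_cost"].mean()
        assert mean_without < mean_with
        with pytest.raises(ValueError, match="unknown"):
            panel.exclude_patients(["nope"])


def test_panel_round_trip(tmp_path):
    cfg = GeneratorConfig(seed=4)
    panel = generate_trial_panel(cfg)
    path = tmp_path / "panel.csv"
    panel.to_csv(path)
    again = TrialPanel.from_csv(path)
    pd.testing.assert_frame_equal(
        panel.data.reset_index(drop=True), again.data, check_dtype=False
    )
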