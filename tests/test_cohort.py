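"""Synthetic cohort generation: calibration, determinism, invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binom

from laceroc.cohort import (
    CohortConfig,
    CohortConfigError,
    CalibrationError,
    ComponentParams,
    DEFAULT_RATES,
    calibrate_intercept,
    calibrate_intercepts,
    generate_cohort,
    read_cohort_csv,
    simulate_frame,
    write_cohort_csv,
)
from laceroc.pipeline import score_table
from laceroc.roc import roc_curve


def zero_rates():
    return {k: (0.0,) * 5 for k in DEFAULT_RATES}


class TestConfigValidation:
    def test_defaults_are_valid_and_sized_like_the_reference_cohort(self):
        config = CohortConfig()
        assert sum(config.n_per_band) == 32270

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_per_band": (0, 1, 1, 1, 1)}, "n_per_band"),
            ({"discrimination_slope": -0.1}, "discrimination_slope"),
            (
                {"band_outcome_rates": {**DEFAULT_RATES, "death_6mo": (0.5, 1.2, 0.1, 0.1, 0.1)}},
                "band_outcome_rates",
            ),
            (
                # 30-day mortality cannot exceed 6-month mortality
                {"band_outcome_rates": {**DEFAULT_RATES, "death_30d": (0.9,) * 5}},
                "death_30d",
            ),
        ],
    )
    def test_invalid_configs_name_the_offending_field(self, kwargs, field):
        with pytest.raises(CohortConfigError, match=field):
            CohortConfig(**kwargs)

    def test_component_params_validation(self):
        with pytest.raises(CohortConfigError, match="p_emergent"):
            ComponentParams(p_emergent=1.5)
        with pytest.raises(CohortConfigError, match="charlson_probs"):
            ComponentParams(charlson_probs=(1.0,) * 11)


class TestCalibration:
    def test_zero_slope_closed_form(self):
        for rate in (0.005, 0.05, 0.5, 0.9):
            assert calibrate_intercept(rate, 0.0, [3, 7, 9]) == pytest.approx(logit(rate))

    def test_mean_probability_hits_target_vs_grid_oracle(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 20, 500)
        slope, target = 0.5, 0.05
        c = calibrate_intercept(target, slope, scores)
        centered = slope * (scores - scores.mean())
        assert expit(c + centered).mean() == pytest.approx(target, abs=1e-6)
        # coarse grid search oracle agrees with the root-finder
        grid = np.linspace(-20, 5, 200_001)
        means = expit(grid[:, None] + centered[None, :]).mean(axis=1)
        c_grid = grid[np.argmin(np.abs(means - target))]
        assert c == pytest.approx(c_grid, abs=1e-3)

    def test_intercept_monotone_in_target_rate(self):
        scores = [2, 5, 9, 14]
        lo = calibrate_intercept(0.05, 0.3, scores)
        hi = calibrate_intercept(0.10, 0.3, scores)
        assert hi > lo

    @pytest.mark.parametrize("rate", [0.0, 1.0])
    def test_degenerate_rates_signal_no_finite_intercept(self, rate):
        with pytest.raises(CalibrationError):
            calibrate_intercept(rate, 0.5, [1, 2, 3])

    def test_per_band_api_handles_degenerate_bands(self):
        config = CohortConfig(
            band_outcome_rates={
                **DEFAULT_RATES,
                "death_6mo": (0.0, 0.02, 0.048, 0.077, 0.156),
                "death_30d": (0.0, 0.007, 0.018, 0.029, 0.060),
            }
        )
        samples = [np.arange(20)] * 5
        intercepts = calibrate_intercepts(config, samples, outcome="death_6mo")
        assert intercepts[0] is None
        assert all(i is not None for i in intercepts[1:])
        assert list(intercepts[1:]) == sorted(intercepts[1:])  # rates increase with age


class TestGeneration:
    def test_band_counts_and_total_match_config(self):
        df = simulate_frame(CohortConfig(seed=3))
        assert len(df) == 32270
        edges = [18, 50, 60, 70, 80, np.inf]
        counts = pd.cut(df.age_years, edges, right=False).value_counts(sort=False)
        assert counts.tolist() == [8403, 4304, 4739, 6068, 8756]

    def test_reproducible_and_seed_sensitive(self, tmp_path):
        config = CohortConfig(n_per_band=(200,) * 5, seed=42)
        a = simulate_frame(config)
        b = simulate_frame(config)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_frame(CohortConfig(n_per_band=(200,) * 5, seed=43))
        assert not a.equals(c)
        # byte-identical CSV round trip
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort_csv(a, p1)
        write_cohort_csv(b, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_rate_zero_slope_generates_no_deaths(self):
        config = CohortConfig(
            n_per_band=(500,) * 5, band_outcome_rates=zero_rates(),
            discrimination_slope=0.0, seed=1,
        )
        df = simulate_frame(config)
        assert not df.died_within_6mo.any()
        assert not df.died_within_30d.any()

    def test_thirty_day_deaths_subset_of_six_month_deaths(self):
        df = simulate_frame(CohortConfig(n_per_band=(2000,) * 5, seed=9))
        assert not (df.died_within_30d & ~df.died_within_6mo).any()

    def test_ages_respect_band_intervals_and_107_cap(self):
        df = simulate_frame(CohortConfig(n_per_band=(500,) * 5, seed=4))
        assert df.age_years.min() >= 18
        assert df.age_years.max() <= 107

    def test_marginal_rate_within_99pct_binomial_interval_at_slope_zero(self):
        n = 50_000
        rate = 0.156
        config = CohortConfig(
            n_per_band=(1, 1, 1, 1, n),
            band_outcome_rates={**zero_rates(), "death_6mo": (0.0, 0.0, 0.0, 0.0, rate)},
            discrimination_slope=0.0,
            seed=11,
        )
        df = simulate_frame(config)
        deaths = int(df.died_within_6mo.sum())
        lo, hi = binom.interval(0.99, n, rate)
        assert lo <= deaths <= hi

    def test_frequent_readmission_rate_calibrated_through_poisson_counts(self):
        n = 50_000
        config = CohortConfig(
            n_per_band=(1, 1, 1, 1, n),
            band_outcome_rates={**zero_rates(), "frequent_readmit": (0, 0, 0, 0, 0.067)},
            discrimination_slope=0.0,
            seed=12,
        )
        df = simulate_frame(config)
        frequent = int((df.readmissions_28d >= 2).sum())
        lo, hi = binom.interval(0.99, n, 0.067)
        assert lo <= frequent <= hi

    def test_auc_nondecreasing_in_discrimination_slope(self):
        """Mean AUC over three seeds at 20,000 episodes per run: monotone in
        the slope grid, and within 0.01 of chance when the slope is zero
        (averaging keeps the chance check well inside its sampling noise)."""
        mean_aucs = []
        for slope in (0.0, 0.2, 0.5, 1.0):
            aucs = []
            for seed in (0, 1, 2):
                config = CohortConfig(
                    n_per_band=(1, 1, 1, 1, 20_000),
                    discrimination_slope=slope,
                    seed=seed,
                )
                df = simulate_frame(config)
                aucs.append(
                    roc_curve(df.lace_total.to_numpy(), df.died_within_6mo.to_numpy()).auc
                )
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs == sorted(mean_aucs)
        assert abs(mean_aucs[0] - 0.5) <= 0.01

    def test_generate_cohort_returns_validated_records(self):
        records = generate_cohort(CohortConfig(n_per_band=(50,) * 5, seed=2))
        assert len(records) == 250
        assert all(r.died_within_6mo or not r.died_within_30d for r in records)
        assert len({r.episode_id for r in records}) == 250

    def test_emitted_icd10_codes_reproduce_drawn_charlson_index(self):
        df = simulate_frame(CohortConfig(n_per_band=(300,) * 5, seed=5))
        rescored = score_table(df.drop(columns=["charlson_index", "lace_total"]))
        np.testing.assert_array_equal(
            rescored.charlson_index.to_numpy(), df.charlson_index.to_numpy()
        )
        np.testing.assert_array_equal(
            rescored.lace_total.to_numpy(), df.lace_total.to_numpy()
        )


class TestCsvRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        df = simulate_frame(CohortConfig(n_per_band=(100,) * 5, seed=6))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(df, path)
        back = read_cohort_csv(path)
        assert len(back) == len(df)
        np.testing.assert_array_equal(
            back.died_within_6mo.to_numpy(), df.died_within_6mo.to_numpy()
        )

    def test_validator_reports_line_numbers(self, tmp_path):
        df = simulate_frame(CohortConfig(n_per_band=(5,) * 5, seed=7))
        df.loc[3, "age_years"] = 12  # under-age on data line 4
        path = tmp_path / "bad.csv"
        write_cohort_csv(df, path)
        with pytest.raises(ValueError, match="line 4"):
            read_cohort_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        pd.DataFrame({"episode_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing required columns"):
            read_cohort_csv(path)
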