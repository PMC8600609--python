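import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valvect import UNDEFINED_RATIO, StatsError, icc_agreement, spearman
from valvect import phantom as ph
from valvect.stats import velocity_regression

from .oracles import icc21, spearman_rho


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).rho == pytest.approx(-1.0)

    def test_tied_values_match_rank_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        assert spearman(x, y).rho == pytest.approx(spearman_rho(x, y), abs=1e-12)

    def test_sentinel_ranks_above_all_finite(self):
        ratios = [0.4, 1.2, UNDEFINED_RATIO, 0.9]
        velocity = [4.1, 3.0, 2.6, 3.4]
        with_sentinel = spearman(ratios, velocity).rho
        with_large = spearman([0.4, 1.2, 99.0, 0.9], velocity).rho
        assert with_sentinel == pytest.approx(with_large)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y).rho
        assert spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)


class TestICC:
    def test_identical_raters_give_unity(self):
        table = np.tile(np.arange(10.0)[:, None], (1, 3))
        res = icc_agreement(table)
        assert res.icc == pytest.approx(1.0)
        assert res.model.startswith("two-way random")

    def test_independent_raters_near_zero(self, rng):
        table = rng.normal(size=(200, 2))
        res = icc_agreement(table)
        assert abs(res.icc) < 0.15
        assert res.ci_low <= res.icc <= res.ci_high

    def test_hand_anova_table(self):
        # classic 6-subject, 2-rater agreement example, evaluated by the
        # explicit ANOVA oracle
        table = np.array(
            [[9.0, 2.0], [6.0, 1.0], [8.0, 4.0], [7.0, 1.0], [10.0, 5.0], [6.0, 2.0]]
        )
        res = icc_agreement(table)
        assert res.icc == pytest.approx(icc21(table), abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        table = rng.normal(10.0, 2.0, size=(20, 3)) + rng.normal(
            0.0, 1.5, size=(20, 1)
        )
        res = icc_agreement(table)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 3),
                "rater": np.tile(np.arange(3), 20),
                "score": table.ravel(),
            }
        )
        pg = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = pg.loc["ICC(A,1)"]  # two-way random, absolute agreement, single
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)

    def test_classic_judges_example(self):
        # 6 targets rated by 4 judges; the textbook ICC(2,1) is 0.29 with a
        # 95% CI of about (0.019, 0.761)
        table = np.array(
            [
                [9, 2, 5, 8],
                [6, 1, 3, 2],
                [8, 4, 6, 8],
                [7, 1, 2, 6],
                [10, 5, 6, 9],
                [6, 2, 4, 7],
            ],
            dtype=float,
        )
        res = icc_agreement(table)
        assert res.icc == pytest.approx(0.28976, abs=1e-5)
        assert res.ci_low == pytest.approx(0.019, abs=3e-3)
        assert res.ci_high == pytest.approx(0.761, abs=2e-3)

    def test_missing_cells_rejected(self):
        table = np.ones((6, 2))
        table[0, 0] = np.nan
        with pytest.raises(StatsError, match="missing"):
            icc_agreement(table)

    def test_too_small_tables_rejected(self):
        with pytest.raises(StatsError):
            icc_agreement(np.ones((3, 2)))


class TestVelocityRegression:
    def test_noiseless_model_has_unit_r2(self, rng):
        n = 60
        age = rng.uniform(55, 85, n)
        female = rng.random(n) < 0.4
        score = rng.uniform(40, 400, n)
        velocity = 0.5 + 0.01 * age + 0.3 * female + 0.4 * np.log2(score) \
            + 0.1 * female * np.log2(score)
        df = pd.DataFrame(
            {
                "age": age,
                "sex": np.where(female, "F", "M"),
                "score": score,
                "peak_velocity_ms": velocity,
            }
        )
        res = velocity_regression(df, "score")
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients["log2_score"] == pytest.approx(0.4, abs=1e-9)
        assert res.coefficients["female_x_log2_score"] == pytest.approx(0.1, abs=1e-9)

    def test_non_positive_scores_reported(self):
        df = pd.DataFrame(
            {
                "age": np.full(20, 70.0),
                "sex": ["M"] * 20,
                "score": np.r_[np.full(19, 50.0), 0.0],
                "peak_velocity_ms": np.full(20, 3.0),
            }
        )
        with pytest.raises(StatsError, match="19"):
            velocity_regression(df, "score")

    def test_interaction_type_i_error_calibrated(self):
        hits = 0
        reps = 400
        for seed in range(reps):
            df = ph.cohort_frame(
                ph.simulate_cohort(
                    164,
                    seed=seed,
                    velocity_model="log2",
                    female_fraction=0.5,
                    sex_calcific_logit_shift=0.0,
                    sex_burden_log_shift=0.0,
                )
            )
            res = velocity_regression(df, "true_fibrocalcific_volume")
            hits += res.p_values["female_x_log2_score"] < 0.05
        assert 0.02 <= hits / reps <= 0.09

    def test_interaction_power_at_cohort_size(self):
        hits = 0
        reps = 200
        for seed in range(reps):
            df = ph.cohort_frame(
                ph.simulate_cohort(
                    164,
                    seed=seed,
                    velocity_model="log2",
                    sex_velocity_interaction=0.2,
                    female_fraction=0.5,
                    sex_calcific_logit_shift=0.0,
                    sex_burden_log_shift=0.0,
                )
            )
            res = velocity_regression(df, "true_fibrocalcific_volume")
            hits += res.p_values["female_x_log2_score"] < 0.05
        assert hits / reps > 0.80
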