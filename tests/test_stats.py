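"""Stay tables, Spearman/signed-rank machinery, lap-wise tests, LMMs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import statsmodels.api as sm

from twostep.stats import (
    fit_lmm,
    lapwise_rank_sum,
    spearman_by_session,
    spec_transition,
    spec_vte1_full,
    spec_vte_correlation,
    stay_probability_table,
    wilcoxon_signed_rank_exact,
)
from twostep.synth import CohortConfig, PRESETS, gen_cohort, gen_lmm_dataset

from tests._oracles import brute_force_signed_rank_p


def _laps_frame(choices1, transitions=None, delays=None, session="s1", rat=1):
    n = len(choices1)
    return pd.DataFrame(
        {
            "rat_id": rat,
            "session_id": session,
            "lap": np.arange(1, n + 1),
            "choice1": choices1,
            "transition": transitions or ["common"] * n,
            "delay_s": delays if delays is not None else np.linspace(2, 28, n),
        }
    )


class TestStayProbability:
    def test_constant_policy_stays_everywhere(self):
        df = _laps_frame(["A"] * 40)
        tbl = stay_probability_table(df)
        measured = tbl.dropna(subset=["stay_fraction"])
        assert (measured["stay_fraction"] == 1.0).all()

    def test_each_eligible_lap_lands_in_exactly_one_cell(self):
        rng = np.random.default_rng(0)
        df = _laps_frame(
            list(rng.choice(["A", "B"], 60)),
            list(rng.choice(["common", "rare"], 60)),
            rng.uniform(1, 30, 60),
        )
        tbl = stay_probability_table(df)
        assert tbl["n"].sum() == 59  # all laps but the session's first

    def test_empty_bins_are_missing_not_zero(self):
        df = _laps_frame(["A", "B", "A", "B"], delays=[2.0, 2.5, 2.2, 2.8])
        tbl = stay_probability_table(df)
        high_bins = tbl[tbl["delay_bin"].apply(lambda b: b.left >= 5)]
        assert high_bins["stay_fraction"].isna().all()


class TestSpearmanBySession:
    def _frame(self, x, y, n_sessions=6, n=30):
        rows = []
        for s in range(n_sessions):
            rows.append(
                pd.DataFrame(
                    {"rat_id": 1, "session_id": f"s{s}", "x": x(s, n), "y": y(s, n)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_perfect_correlation(self, rng):
        df = self._frame(
            lambda s, n: rng.normal(size=n), lambda s, n: np.arange(n), n_sessions=6
        )
        df["y"] = df.groupby("session_id")["x"].transform(lambda v: v * 2 + 1)
        res = spearman_by_session(df, "x", "y")
        assert (res.rho == 1.0).all()
        # minimum attainable two-sided p for 6 all-positive values
        assert res.p_group == pytest.approx(2 / 2**6)

    def test_monotone_transform_invariance(self, rng):
        df = self._frame(lambda s, n: rng.normal(size=n), lambda s, n: rng.normal(size=n))
        a = spearman_by_session(df, "x", "y")
        df["x"] = np.exp(df["x"])  # strictly increasing transform
        b = spearman_by_session(df, "x", "y")
        assert np.allclose(a.rho.to_numpy(), b.rho.to_numpy())

    def test_constant_sessions_dropped(self, rng):
        df = self._frame(lambda s, n: rng.normal(size=n), lambda s, n: rng.normal(size=n))
        df.loc[df["session_id"] == "s0", "x"] = 1.0
        res = spearman_by_session(df, "x", "y")
        assert res.n_dropped == 1 and len(res.rho) == 5


class TestWilcoxonExact:
    def test_seven_same_sign_prints_0156(self):
        assert wilcoxon_signed_rank_exact(np.ones(7)) == pytest.approx(2 / 2**7)
        assert round(wilcoxon_signed_rank_exact([3, 1, 4, 1, 5, 9, 2.6]), 6) == 0.015625

    def test_five_same_sign(self):
        assert wilcoxon_signed_rank_exact([1, 2, 3, 4, 5]) == pytest.approx(2 / 2**5)

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(0.3, 1.0, 11)
        assert wilcoxon_signed_rank_exact(d) == wilcoxon_signed_rank_exact(-d)

    def test_matches_brute_force_enumeration(self, rng):
        for n in range(4, 13):
            d = np.round(rng.normal(0.2, 1.0, n), 3)
            d = d[d != 0]
            assert wilcoxon_signed_rank_exact(d) == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12
            )

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.floats(-10, 10).map(lambda x: round(x, 2)).filter(lambda x: x != 0.0),
            min_size=3,
            max_size=10,
        )
    )
    def test_enumeration_property(self, diffs):
        d = np.asarray(diffs)
        assert wilcoxon_signed_rank_exact(d) == pytest.approx(
            brute_force_signed_rank_p(d), abs=1e-12
        )

    def test_handles_tied_magnitudes(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, 3.0])
        p = wilcoxon_signed_rank_exact(d)
        assert p == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_large_n_close_to_scipy_approximation(self, rng):
        d = rng.normal(0.25, 1.0, 60)
        ours = wilcoxon_signed_rank_exact(d)
        ref = sps.wilcoxon(d, correction=True, mode="approx").pvalue
        assert ours == pytest.approx(ref, rel=0.02)

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_exact([0.0, 0.0])


class TestLapwiseRankSum:
    def _frame(self, shift_laps=(), shift=0.0, n_sessions=80, n_laps=70, seed=1):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_sessions):
            vals = rng.normal(0.0, 1.0, n_laps)
            for lap in shift_laps:
                vals[lap - 1] += shift
            rows.append(
                pd.DataFrame(
                    {"rat_id": 1, "session_id": f"s{s}", "lap": np.arange(1, n_laps + 1), "v": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_null_data_yields_no_flags(self):
        out = lapwise_rank_sum(self._frame(), "v")
        assert not out["significant"].any()

    def test_shifted_early_laps_are_flagged(self):
        out = lapwise_rank_sum(self._frame(shift_laps=range(1, 11), shift=1.0), "v")
        flagged = set(out.loc[out["significant"], "lap"])
        assert set(range(1, 11)) <= flagged
        assert not (flagged - set(range(1, 11)))

    def test_bonferroni_never_flags_above_corrected_threshold(self):
        out = lapwise_rank_sum(self._frame(seed=7), "v", alpha=0.05)
        m = len(out)
        assert ((out["p_raw"] >= 0.05 / m) == ~out["significant"]).all()


class TestFitLmm:
    def test_zero_variance_components_match_ols(self, rng):
        # residuals centered within every session leave no between-group
        # variance, so the ML variance components sit on the zero boundary
        # and the GLS fixed effects collapse to OLS
        cfg = CohortConfig(n_rats=3, sessions_per_rat=3, laps_per_session=30)
        spec = spec_transition("y")
        df, _ = gen_lmm_dataset(
            spec,
            {"Intercept": 4.0, "rare": 0.3, "rare_prev": -0.2},
            {"sigma_r": 0.0, "sigma_s": 0.0, "sigma_eps": 0.0},
            cfg,
            seed=5,
        )
        eps = rng.normal(0.0, 0.5, len(df))
        eps -= pd.Series(eps).groupby(df["session_id"].to_numpy()).transform("mean").to_numpy()
        df["y"] = df["y"] + eps
        fit = fit_lmm(spec, df)
        X = sm.add_constant(df[["rare", "rare_prev"]].to_numpy())
        ols = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert fit.boundary  # variance components on the zero boundary
        assert fit.fixed["estimate"].to_numpy() == pytest.approx(ols, abs=1e-6)

    def test_null_effect_ci_covers_zero(self):
        cfg = CohortConfig(n_rats=4, sessions_per_rat=4, laps_per_session=40)
        spec = spec_vte_correlation()
        hits = 0
        for rep in range(8):
            df, _ = gen_lmm_dataset(
                spec, {"zlogidphi1": 0.0},
                {"sigma_r": 0.2, "sigma_s": 0.3, "sigma_eps": 1.0}, cfg, seed=50 + rep,
            )
            fit = fit_lmm(spec, df)
            row = fit.fixed.loc["zlogidphi1"]
            hits += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert hits >= 7  # ~95% nominal coverage

    def test_zscored_inputs_center_the_intercept(self):
        cfg = CohortConfig(n_rats=3, sessions_per_rat=4, laps_per_session=40)
        spec = spec_vte_correlation()
        df, _ = gen_lmm_dataset(
            spec, {"zlogidphi1": 0.1}, {"sigma_r": 0.0, "sigma_s": 0.0, "sigma_eps": 1.0},
            cfg, seed=9,
        )
        # route through the pooled z-scoring path used for raw measurements
        df = df.rename(columns={"zlogidphi1": "logidphi_cp1", "zlogidphi2": "logidphi_cp2"})
        fit = fit_lmm(spec, df)
        assert abs(fit.fixed.loc["Intercept", "estimate"]) < 0.05
        assert abs(fit.fixed.loc["Intercept", "tstat"]) < 2.0

    def test_full_interaction_spec_has_eight_fixed_terms(self):
        cfg = CohortConfig(n_rats=3, sessions_per_rat=8, laps_per_session=60)
        spec = spec_vte1_full()
        df, _ = gen_lmm_dataset(
            spec,
            {"Intercept": 4.3, "repeat": -0.46, "delay_prev": 0.006},
            {"sigma_r": 0.1, "sigma_s": 0.2, "sigma_eps": 0.9},
            cfg,
            seed=3,
        )
        fit = fit_lmm(spec, df)
        assert len(fit.fixed) == 8
        assert fit.fixed.loc["repeat", "p"] < 0.05
        assert fit.fixed.loc["repeat", "ci_low"] < -0.46 < fit.fixed.loc["repeat", "ci_high"]
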