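"""MLE fitting, BIC comparison, recovery, and predictive checks."""

import math

import numpy as np
import pandas as pd
import pytest

import prosocial_effort as pe


def ttest_rel_oracle(a, b):
    """Independent paired-t implementation: direct closed form on differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
    return t, n - 1


class TestBic:
    @pytest.mark.parametrize(
        "lnl,p,n,expected",
        [
            (-80.0, 2, 150, 2 * math.log(150) + 160.0),
            (0.0, 0, 10, 0.0),
        ],
    )
    def test_closed_form(self, lnl, p, n, expected):
        assert pe.bic(lnl, p, n) == pytest.approx(expected, abs=1e-10)

    def test_parameter_penalty_gap(self):
        lnl = -100.0
        assert pe.bic(lnl, 4, 225) - pe.bic(lnl, 2, 225) == pytest.approx(2 * math.log(225))

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            pe.bic(-1.0, 2, 0)


class TestFitMle:
    def test_recovers_k_ordering(self, study1):
        """Simulated k_self < k_charity is recovered in the majority of refits."""
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))
        wins = 0
        n_reps = 15
        for rep in range(n_reps):
            sim = pe.SimParams(
                k={"self": 0.8, "charity": 1.2}, beta={"self": 5.0, "charity": 5.0}
            )
            trials = pe.simulate_participant(study1, sim, participant_id="p0", seed=100 + rep)
            fit = pe.fit_mle(trials, spec, n_starts=6, seed=rep)
            wins += fit.params.k["self"] < fit.params.k["charity"]
        assert wins > n_reps / 2

    def test_no_discounting_signal_pushes_k_to_floor(self, study1):
        """All-effortful choices with rewards above baseline leave k at ~0."""
        spec = pe.spec_from_name("linear_kShared_betaShared", ("self", "charity"))
        trials = pe.build_design(study1, seed=0)
        trials["participant_id"] = "p0"
        trials["choice"] = 1
        fit = pe.fit_mle(trials, spec, n_starts=8, seed=2)
        assert fit.params.k["self"] < 0.05

    def test_multistart_agrees_with_single_start_on_easy_instance(self, study1):
        sim = pe.SimParams(k={"self": 1.0, "charity": 1.0}, beta={"self": 6.0, "charity": 6.0})
        trials = pe.simulate_participant(study1, sim, participant_id="p0", seed=9)
        spec = pe.spec_from_name("linear_kShared_betaShared", ("self", "charity"))
        f1 = pe.fit_mle(trials, spec, n_starts=1, seed=0)
        f20 = pe.fit_mle(trials, spec, n_starts=20, seed=0)
        assert -f1.log_likelihood == pytest.approx(-f20.log_likelihood, abs=1e-4)

    def test_bic_identity_and_determinism(self, small_cohort):
        trials, _ = small_cohort
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))
        sub = trials[trials["participant_id"] == "p000"]
        a = pe.fit_mle(sub, spec, n_starts=5, seed=3)
        b = pe.fit_mle(sub, spec, n_starts=5, seed=3)
        assert a.log_likelihood == b.log_likelihood
        assert a.bic == pytest.approx(
            spec.n_params * math.log(a.n_trials) - 2 * a.log_likelihood, abs=1e-12
        )

    def test_fitted_nll_beats_generating_params(self, small_cohort):
        trials, params = small_cohort
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))
        for (pid, sub), sim in zip(sorted(trials.groupby("participant_id")), params):
            fit = pe.fit_mle(sub, spec, n_starts=5, seed=1)
            gen = pe.ParamVector(k=dict(sim.k), beta=dict(sim.beta))
            nll_gen = pe.negative_log_likelihood(gen, spec, sub)
            assert -fit.log_likelihood <= nll_gen + 1e-6

    def test_missing_target_rejected(self, small_cohort):
        trials, _ = small_cohort
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "stranger"))
        with pytest.raises(ValueError):
            pe.fit_mle(trials[trials["participant_id"] == "p000"], spec)


class TestCompareModels:
    def fit_grid(self, trials, specs, n_starts=4, seed=0):
        return pe.fit_cohort(trials, specs, n_starts=n_starts, seed=seed)

    def test_shared_generator_favors_shared_spec(self, study1):
        """Identical k and beta across targets: parsimony favors shared params."""
        def sampler(rng):
            k = float(rng.uniform(0.9, 1.2))
            b = float(rng.uniform(4, 8))
            return pe.SimParams(
                k={"self": k, "charity": k}, beta={"self": b, "charity": b}
            )

        trials, _ = pe.simulate_cohort(study1, sampler, n_participants=5, seed=21)
        specs = [
            pe.spec_from_name("linear_kShared_betaShared", ("self", "charity")),
            pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity")),
        ]
        comp = pe.compare_models(self.fit_grid(trials, specs))
        assert comp.best_summed == "linear_kShared_betaShared"

    def test_per_target_generator_favors_per_target_spec(self, study1):
        def sampler(rng):
            return pe.SimParams(
                k={"self": float(rng.uniform(0.7, 0.9)), "charity": float(rng.uniform(1.1, 1.3))},
                beta={"self": float(rng.uniform(5, 9)), "charity": float(rng.uniform(3, 6))},
            )

        trials, _ = pe.simulate_cohort(study1, sampler, n_participants=5, seed=22)
        specs = [
            pe.spec_from_name("linear_kShared_betaShared", ("self", "charity")),
            pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity")),
        ]
        comp = pe.compare_models(self.fit_grid(trials, specs))
        assert comp.best_summed == "linear_kTarget_betaTarget"

    def test_deterministic_and_aggregates(self, small_cohort):
        trials, _ = small_cohort
        specs = [
            pe.spec_from_name("linear_kShared_betaShared", ("self", "charity")),
            pe.spec_from_name("parabolic_kShared_betaShared", ("self", "charity")),
        ]
        fits = self.fit_grid(trials, specs)
        c1 = pe.compare_models(fits)
        c2 = pe.compare_models(fits)
        pd.testing.assert_frame_equal(c1.table, c2.table)
        # summed = mean * n_participants
        row = c1.table.iloc[0]
        assert row["summed_bic"] == pytest.approx(row["mean_bic"] * 6)
        assert c1.table["n_wins"].sum() == 6

    def test_incomplete_grid_rejected(self, small_cohort):
        trials, _ = small_cohort
        specs = [
            pe.spec_from_name("linear_kShared_betaShared", ("self", "charity")),
            pe.spec_from_name("linear_kTarget_betaShared", ("self", "charity")),
        ]
        fits = self.fit_grid(trials[trials["participant_id"].isin(["p000", "p001"])], specs)
        with pytest.raises(ValueError):
            pe.compare_models(fits[:-1])  # one participant lacks one model


class TestPredictiveCheck:
    def test_matches_correlation_oracle(self, handcrafted_trials):
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))
        params = pe.ParamVector(
            k={"self": 0.6, "charity": 1.0}, beta={"self": 3.0, "charity": 2.0}
        )
        fit = pe.FitResult(
            participant_id="p0", spec=spec, params=params, log_likelihood=-1.0,
            n_trials=4, n_starts=1, converged=True, best_start=0,
        )
        check = pe.predictive_check(fit, handcrafted_trials)
        # independent oracle: plain Pearson formula over the 4 trials
        p = []
        for _, row in handcrafted_trials.iterrows():
            sv = row["reward"] * (1 - params.k[row["target"]] * row["effort_rank"] / 5)
            p.append(1.0 / (1.0 + math.exp(-params.beta[row["target"]] * (sv - 1.0))))
        p = np.array(p)
        c = handcrafted_trials["choice"].to_numpy(float)
        r_oracle = ((p - p.mean()) * (c - c.mean())).sum() / (
            math.sqrt(((p - p.mean()) ** 2).sum()) * math.sqrt(((c - c.mean()) ** 2).sum())
        )
        assert not check.undefined
        assert check.r == pytest.approx(r_oracle, abs=1e-10)

    def test_flat_probabilities_flagged(self, handcrafted_trials):
        spec = pe.spec_from_name("linear_kShared_betaShared", ("self", "charity"))
        params = pe.ParamVector(
            k={"self": 0.5, "charity": 0.5}, beta={"self": 0.0, "charity": 0.0}
        )
        fit = pe.FitResult(
            participant_id="p0", spec=spec, params=params, log_likelihood=-1.0,
            n_trials=4, n_starts=1, converged=True, best_start=0,
        )
        check = pe.predictive_check(fit, handcrafted_trials)
        assert check.undefined and math.isnan(check.r)


class TestRecoveryAndContrasts:
    def test_recovery_report_shapes_and_zero_noise_ordering(self):
        spec = pe.spec_from_name("linear_kTarget_betaTarget", ("self", "charity"))

        def sampler(rng):
            return pe.ParamVector(
                k={"self": float(rng.uniform(0.7, 0.9)), "charity": float(rng.uniform(1.1, 1.3))},
                beta={"self": 25.0, "charity": 25.0},  # near-deterministic choices
            )

        rep = pe.parameter_recovery(spec, sampler, n_participants=4, seed=3, n_starts=4)
        assert list(rep.true.columns) == list(spec.param_names)
        assert rep.true.shape == rep.recovered.shape == (4, 4)
        assert (rep.nll_at_fit <= rep.nll_at_true + 1e-6).all()
        # near-deterministic generation: recovered k ordering matches truth
        assert (rep.recovered["k_self"] < rep.recovered["k_charity"]).all()
        summary = rep.summary().set_index("parameter")
        assert set(summary.index) == set(spec.param_names)
        # k varies across participants so its recovery r is defined; the
        # generating beta is constant, so its r is undefined (NaN)
        assert summary.loc[["k_self", "k_charity"], "r"].between(-1, 1).all()
        assert summary.loc[["beta_self", "beta_charity"], "r"].isna().all()

    def test_khat_rises_as_effortful_rate_falls(self, study1):
        """Lower simulated effortful rates (larger true k) give larger k-hat."""
        spec = pe.spec_from_name("linear_kShared_betaShared", ("self", "charity"))
        khats = []
        for k_true in (0.8, 1.0, 1.2):
            sim = pe.SimParams(
                k={"self": k_true, "charity": k_true}, beta={"self": 6.0, "charity": 6.0}
            )
            trials = pe.simulate_participant(study1, sim, participant_id="p0", seed=17)
            fit = pe.fit_mle(trials, spec, n_starts=5, seed=0)
            khats.append(fit.params.k["self"])
        assert khats[0] < khats[1] < khats[2]

    def test_paired_contrast_matches_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.3, size=12)
        b = a + rng.normal(0.2, 0.2, size=12)
        res = pe.paired_parameter_contrast(a, b)
        t_oracle, df_oracle = ttest_rel_oracle(a, b)
        assert res.t == pytest.approx(t_oracle, abs=1e-8)
        assert res.df == df_oracle
        r_oracle = math.copysign(
            math.sqrt(t_oracle**2 / (t_oracle**2 + df_oracle)), t_oracle
        )
        assert res.r == pytest.approx(r_oracle, abs=1e-10)
        with pytest.raises(ValueError):
            pe.paired_parameter_contrast(a, b[:-1])
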