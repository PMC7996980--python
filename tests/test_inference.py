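import numpy as np
import pytest
from scipy import stats

from exminmod.inference import (
    FAST_N_BURN,
    FAST_N_ITER,
    GlucoseLikelihood,
    PosteriorChains,
    PriorSpec,
    SubjectDataset,
    adaptive_metropolis,
    filter_sessions,
    free_parameters,
    log_likelihood,
    sample_posterior,
    summarize,
)
from exminmod.model_core import ModelParameters
from exminmod.simulate import simulate
from exminmod.synthetic_cohort import (
    build_schedule,
    default_exercise_trace,
    default_insulin_profile,
    generate_dataset,
)


def _noiseless_dataset(params, schedule=None):
    return generate_dataset(params, schedule=schedule, noise_cv=0.0, seed=0, subject_id="exact")


class TestLogLikelihood:
    def test_zero_residuals_leave_only_normalisation(self, ref_params):
        ds = _noiseless_dataset(ref_params)
        like = GlucoseLikelihood(ds, variant=6)
        ghat = like.predict(ref_params)
        sigma = 0.02 * ghat
        expected = -np.sum(np.log(sigma * np.sqrt(2 * np.pi)))
        assert like(ref_params) == pytest.approx(expected, rel=1e-6)

    def test_single_observation_normal_density(self):
        # y = Ghat = 5 mmol/L, sigma = 0.1: LL = -log(0.1*sqrt(2*pi))
        assert -np.log(0.1 * np.sqrt(2 * np.pi)) == pytest.approx(1.3836, abs=2e-4)

    def test_matches_scipy_normal_density(self, ref_params, study_dataset):
        like = GlucoseLikelihood(study_dataset, variant=6)
        ghat = like.predict(ref_params)
        oracle = stats.norm.logpdf(study_dataset.glucose, ghat, 0.02 * ghat).sum()
        assert like(ref_params) == pytest.approx(oracle, rel=1e-10)

    def test_fast_predictor_matches_adaptive_solver(
        self, ref_params, study_dataset, insulin_profile, session_60min
    ):
        like = GlucoseLikelihood(study_dataset, variant=6)
        ghat = like.predict(ref_params)
        traj = simulate(
            ref_params, insulin_profile, session_60min, t_grid=study_dataset.times
        )
        assert np.max(np.abs(ghat - traj.G) / traj.G) < 1e-6

    @pytest.mark.parametrize("variant", [1, 2, 3, 4, 5])
    def test_fast_predictor_matches_solver_all_variants(
        self, ref_params, study_dataset, insulin_profile, session_60min, variant
    ):
        p = ref_params.with_variant(variant)
        ghat = GlucoseLikelihood(study_dataset, variant=variant).predict(p)
        traj = simulate(p, insulin_profile, session_60min, t_grid=study_dataset.times)
        assert np.max(np.abs(ghat - traj.G) / traj.G) < 1e-6


class TestSampler:
    def test_same_seed_identical_chains(self, study_dataset):
        a = sample_posterior(study_dataset, 6, seed=5, n_iter=600, n_burn=400)
        b = sample_posterior(study_dataset, 6, seed=5, n_iter=600, n_burn=400)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])
        np.testing.assert_array_equal(a.deviance, b.deviance)

    def test_deviance_replays_exactly(self, study_dataset):
        chains = sample_posterior(study_dataset, 6, seed=9, n_iter=800, n_burn=600)
        like = GlucoseLikelihood(study_dataset, 6)
        for i in (0, 50, 199):
            replay = -2.0 * like(chains.parameters_at(i))
            assert replay == pytest.approx(chains.deviance[i], rel=1e-12)

    def test_constant_likelihood_recovers_prior(self):
        # with a flat likelihood the marginal chains must reproduce the prior
        prior = PriorSpec()
        names = free_parameters(6)
        mu, sd = prior.mu_z(names), prior.sd_z(names)

        def log_post(z):
            return prior.log_prior_z(names, z), 0.0

        samples, _, _ = adaptive_metropolis(
            log_post, mu.copy(), n_iter=60_000, n_burn=10_000, seed=123
        )
        thinned = samples[::2]  # ~25k draws
        for j, name in enumerate(names):
            d, _ = stats.kstest(thinned[:, j], "norm", args=(mu[j], sd[j]))
            assert d < 0.05, f"KS distance {d:.3f} for {name}"

    def test_conjugate_normal_mean_posterior(self):
        # toy: y_i ~ N(theta, sigma2), theta ~ N(m0, tau2); closed-form posterior
        rng = np.random.default_rng(7)
        sigma, tau, m0, theta_true, n = 1.0, 2.0, 0.0, 1.5, 20
        y = rng.normal(theta_true, sigma, n)
        post_var = 1.0 / (n / sigma**2 + 1.0 / tau**2)
        post_mean = post_var * (y.sum() / sigma**2 + m0 / tau**2)

        def log_post(z):
            ll = float(stats.norm.logpdf(y, z[0], sigma).sum())
            lp = float(stats.norm.logpdf(z[0], m0, tau))
            return ll + lp, ll

        samples, _, acc = adaptive_metropolis(
            log_post, np.array([0.0]), n_iter=30_000, n_burn=10_000, seed=17
        )
        mc_se = np.sqrt(post_var / 200)  # generous effective-sample allowance
        assert samples.mean() == pytest.approx(post_mean, abs=5 * mc_se)
        assert samples.std() == pytest.approx(np.sqrt(post_var), rel=0.1)
        assert 0.1 < acc < 0.6

    def test_variant_parameter_sets(self):
        assert free_parameters(2) == ("Gp0", "p1", "p2", "p3", "e1")
        assert free_parameters(6) == ("Gp0", "p1", "p2", "p3", "e1", "e2")

    def test_denser_schedule_shrinks_exercise_gain_posteriors(self, ref_params):
        sparse = build_schedule()
        dense = np.unique(
            np.concatenate([np.arange(930.0, 1081.0, 7.5), np.arange(1082.5, 1141.0, 2.5),
                            np.arange(1143.75, 1171.0, 3.75)])
        )
        session = default_exercise_trace()
        profile = default_insulin_profile(ref_params.Insb, session)
        kw = dict(insulin_profile=profile, session=session, seed=21)
        ds_sparse = generate_dataset(ref_params, schedule=sparse, **kw)
        ds_dense = generate_dataset(ref_params, schedule=dense, **kw)
        mcmc = dict(seed=3, n_iter=40_000, n_burn=20_000)
        ch_sparse = sample_posterior(ds_sparse, 6, **mcmc)
        ch_dense = sample_posterior(ds_dense, 6, **mcmc)
        s_sparse, s_dense = summarize(ch_sparse), summarize(ch_dense)
        assert s_dense.stats.loc["e1", "sd"] < s_sparse.stats.loc["e1", "sd"]
        assert s_dense.stats.loc["e2", "sd"] < s_sparse.stats.loc["e2", "sd"]


class TestSummaries:
    def _chains(self, values):
        arr = np.asarray(values, dtype=float)
        return PosteriorChains(
            params={"p1": arr},
            deviance=np.zeros(arr.size),
            accept_rate=0.3,
            seed=0,
            n_iter=arr.size,
            n_burn=0,
            variant=6,
            insb=10.0,
        )

    def test_constant_chain(self):
        s = summarize(self._chains([2.5] * 10))
        assert s.median("p1") == 2.5
        assert s.iqr("p1") == (2.5, 2.5)
        assert s.cv("p1") == 0.0

    def test_order_statistic_median(self):
        s = summarize(self._chains(np.arange(1, 102)))
        assert s.median("p1") == 51

    def test_lognormal_cv_closed_form(self):
        rng = np.random.default_rng(0)
        draws = np.exp(rng.normal(0.0, 0.25, 200_000))
        s = summarize(self._chains(draws))
        assert s.cv("p1") == pytest.approx(np.sqrt(np.exp(0.0625) - 1.0), rel=0.02)


class TestSessionFiltering:
    def _dataset(self, glucose, symptoms, session=None):
        n = len(glucose)
        times = 930.0 + 30.0 * np.arange(n)
        if session is None:
            session = default_exercise_trace(t_start=times[-1] + 10, duration=30)
        return SubjectDataset(
            subject_id="F",
            times=times,
            glucose=np.asarray(glucose, float),
            insulin=np.full(n, 10.0),
            vo2=np.full(n, 3.5),
            session=session,
            symptoms=np.asarray(symptoms, bool) if symptoms is not None else None,
        )

    def test_symptomatic_below_3_3_excluded(self):
        ds = self._dataset([5.0, 3.2, 6.0], [False, True, False])
        assert filter_sessions([ds]) == []

    def test_below_3_0_excluded_regardless(self):
        ds = self._dataset([5.0, 2.9, 6.0], [False, False, False])
        assert filter_sessions([ds]) == []

    def test_mild_low_without_symptoms_retained(self):
        ds = self._dataset([5.0, 3.4, 6.0], [False, False, False])
        assert filter_sessions([ds]) == [ds]

    def test_asymptomatic_low_above_3_0_retained(self):
        ds = self._dataset([5.0, 3.1, 6.0], [False, False, False])
        assert filter_sessions([ds]) == [ds]

    def test_missing_symptom_flags_warns_and_keeps(self, caplog):
        ds = self._dataset([5.0, 3.2, 6.0], None)
        with caplog.at_level("WARNING", logger="exminmod"):
            kept = filter_sessions([ds])
        assert kept == [ds]
        assert any("symptom" in rec.message for rec in caplog.records)

    def test_post_exercise_hypo_does_not_exclude(self):
        session = default_exercise_trace(t_start=960.0, duration=30.0)
        ds = self._dataset([5.0, 5.5, 4.8, 2.5], [False] * 4, session=session)
        # last sample (t=1020) is after the session end (990+recovery scope)
        assert filter_sessions([ds]) == [ds]
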