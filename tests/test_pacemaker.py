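import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from methyltraj import (InputError, MethylationDataset, epm_cross_validate,
                        epm_fit, epm_predict, epm_site_update, epm_state_update)


def _dataset(betas, ages):
    betas = np.asarray(betas, dtype=float)
    return MethylationDataset(
        betas=betas,
        sample_ids=[f"s{i}" for i in range(betas.shape[1])],
        ages=np.asarray(ages, dtype=float),
        probe_ids=[f"cg{i}" for i in range(betas.shape[0])],
        probe_types=np.array(["I"] * betas.shape[0], dtype=object),
    )


class TestSiteUpdate:
    def test_exact_linear_site(self):
        s = np.linspace(0, 50, 12)
        betas = (0.1 + 0.002 * s).reshape(1, -1)
        m0, r = epm_site_update(betas, s)
        assert m0[0] == pytest.approx(0.1, abs=1e-12)
        assert r[0] == pytest.approx(0.002, abs=1e-12)

    def test_constant_site(self):
        s = np.linspace(0, 50, 10)
        m0, r = epm_site_update(np.full((1, 10), 0.37), s)
        assert r[0] == pytest.approx(0.0, abs=1e-15)
        assert m0[0] == pytest.approx(0.37)

    def test_matches_grid_search_oracle(self, rng):
        # two-stage grid refinement of the squared error surface
        s = rng.uniform(0, 40, 20)
        betas = (0.3 + 0.004 * s + rng.normal(0, 0.02, 20)).reshape(1, -1)
        m0, r = epm_site_update(betas, s)

        def rss(m, rr):
            return ((betas[0] - m - rr * s) ** 2).sum()

        best = (np.inf, None, None)
        m_grid = np.linspace(0.0, 0.6, 121)
        r_grid = np.linspace(-0.01, 0.01, 121)
        for _ in range(4):
            for m in m_grid:
                for rr in r_grid:
                    v = rss(m, rr)
                    if v < best[0]:
                        best = (v, m, rr)
            m_grid = np.linspace(best[1] - (m_grid[1] - m_grid[0]) * 2,
                                 best[1] + (m_grid[1] - m_grid[0]) * 2, 41)
            r_grid = np.linspace(best[2] - (r_grid[1] - r_grid[0]) * 2,
                                 best[2] + (r_grid[1] - r_grid[0]) * 2, 41)
        assert m0[0] == pytest.approx(best[1], abs=1e-4)
        assert r[0] == pytest.approx(best[2], abs=1e-4)

    def test_zero_variance_states_rejected(self):
        with pytest.raises(InputError):
            epm_site_update(np.ones((2, 4)), np.full(4, 3.0))


class TestStateUpdate:
    def test_single_site_inverts_the_line(self):
        s_true = 12.5
        m = np.array([[0.2 + 0.01 * s_true]])
        s = epm_state_update(m, np.array([0.2]), np.array([0.01]))
        assert s[0] == pytest.approx(s_true, abs=1e-10)

    def test_opposite_rates_agree_with_single_site(self):
        s_true = 8.0
        m = np.array([[0.2 + 0.01 * s_true], [0.9 - 0.01 * s_true]])
        both = epm_state_update(m, np.array([0.2, 0.9]), np.array([0.01, -0.01]))
        one = epm_state_update(m[:1], np.array([0.2]), np.array([0.01]))
        assert both[0] == pytest.approx(one[0], abs=1e-10)

    def test_matches_scalar_minimization_oracle(self, rng):
        m0 = rng.uniform(0.2, 0.8, 50)
        r = rng.uniform(-0.01, 0.01, 50)
        column = (m0 + r * 20.0 + rng.normal(0, 0.02, 50)).reshape(-1, 1)
        s = epm_state_update(column, m0, r)[0]
        res = minimize_scalar(lambda v: ((column[:, 0] - m0 - r * v) ** 2).sum(),
                              bounds=(-100, 200), method="bounded",
                              options={"xatol": 1e-10})
        assert s == pytest.approx(res.x, abs=1e-6)

    def test_all_zero_rates_rejected(self):
        with pytest.raises(InputError):
            epm_state_update(np.ones((2, 3)), np.ones(2), np.zeros(2))


class TestFit:
    def test_fixed_point_on_noiseless_data(self, clean_cohort):
        train = clean_cohort["train"]
        truth = clean_cohort["truth"].states_for(train)
        model = epm_fit(train, initial_states=truth)
        assert model.rss_history[1] <= 1e-16 * train.betas.size + 1e-12

    def test_rss_history_non_increasing(self, small_cohort):
        model = epm_fit(small_cohort["train"])
        assert (np.diff(model.rss_history) <= 1e-9).all()

    def test_recovers_generating_states(self, small_cohort):
        train = small_cohort["train"]
        model = epm_fit(train)
        truth = small_cohort["truth"].states_for(train)
        assert np.corrcoef(model.states, truth)[0, 1] >= 0.95

    def test_affine_scale_pinned_by_age_initialization(self):
        # latent trend chosen nearly linear with unit slope over the age range,
        # so the generating states live on the age scale that the
        # initialization pins
        from methyltraj import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_samples=150, n_sites=200, noise_sd=0.0,
                               latent_form_params=(1000 / 3, 0.001, 1.0, 0.002),
                               site_rate_range=(0.002, 0.008), seed=17)
        train, _, _, truth = simulate_cohort(cfg)
        model = epm_fit(train)
        slope = np.polyfit(truth.states_for(train), model.states, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_constant_initial_states_rejected(self):
        ds = _dataset(np.random.default_rng(0).uniform(0.2, 0.8, (5, 6)),
                      np.full(6, 10.0))
        with pytest.raises(InputError):
            epm_fit(ds)


class TestPredict:
    def test_training_samples_reproduce_fitted_states(self, small_cohort):
        train = small_cohort["train"]
        model = epm_fit(train)
        np.testing.assert_allclose(epm_predict(model, train), model.states,
                                   atol=1e-10)

    def test_duplicated_sample_equal_predictions(self, small_cohort):
        train = small_cohort["train"]
        model = epm_fit(train)
        dup = train.select_samples([3, 3])
        pred = epm_predict(model, dup)
        assert pred[0] == pred[1]

    def test_noiseless_held_out_sample_recovered_exactly(self, rng):
        m0 = rng.uniform(0.2, 0.7, 40)
        r = rng.uniform(0.002, 0.01, 40)
        s_train = np.linspace(0, 20, 30)
        train = _dataset(m0[:, None] + np.outer(r, s_train), s_train)
        model = epm_fit(train)
        s_new = 13.7
        held = _dataset((m0 + r * s_new).reshape(-1, 1), [s_new])
        # map the generating state through the model's affine frame
        a, b = np.polyfit(s_train, model.states, 1)
        assert epm_predict(model, held)[0] == pytest.approx(a * s_new + b, abs=1e-8)

    def test_missing_sites_rejected(self, small_cohort):
        train = small_cohort["train"]
        model = epm_fit(train)
        with pytest.raises(InputError):
            epm_predict(model, train.select_probes(train.probe_ids[:-2]))


class TestCrossValidate:
    def test_leave_one_out_covers_every_sample(self, rng):
        betas = rng.uniform(0.2, 0.8, (20, 12))
        ages = np.linspace(0, 80, 12)
        betas[0] = 0.2 + 0.005 * ages
        ds = _dataset(betas, ages)
        states = epm_cross_validate(ds, n_folds=12, seed=0)
        assert states.shape == (12,) and np.isfinite(states).all()

    def test_fold_assignment_deterministic(self, small_cohort):
        a = epm_cross_validate(small_cohort["train"], n_folds=5, seed=3)
        b = epm_cross_validate(small_cohort["train"], n_folds=5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_out_of_fold_states_track_truth(self, small_cohort):
        train = small_cohort["train"]
        states = epm_cross_validate(train, n_folds=5, seed=0)
        truth = small_cohort["truth"].states_for(train)
        assert np.corrcoef(states, truth)[0, 1] >= 0.95

    def test_too_many_folds_rejected(self, rng):
        ds = _dataset(rng.uniform(0.2, 0.8, (5, 4)), [1, 2, 3, 4])
        with pytest.raises(InputError):
            epm_cross_validate(ds, n_folds=5)


class TestNoiseRobustness:
    def test_doubling_noise_keeps_strong_rate_signs(self):
        from methyltraj import SimulationConfig, simulate_cohort
        base = dict(n_samples=150, n_sites=200, seed=21)
        signs = {}
        for noise in (0.02, 0.04):
            cfg = SimulationConfig(noise_sd=noise, **base)
            train, _, _, truth = simulate_cohort(cfg)
            model = epm_fit(train)
            # rate-estimation standard error from the residuals
            resid = train.betas - (model.intercepts[:, None]
                                   + np.outer(model.rates, model.states))
            sc = model.states - model.states.mean()
            se = np.sqrt((resid ** 2).sum(1) / (len(sc) - 2) / (sc @ sc))
            strong = np.abs(truth.site_rates) > 3 * se
            signs[noise] = np.sign(model.rates[strong & (truth.site_rates != 0)])
        n = min(len(signs[0.02]), len(signs[0.04]))
        assert (signs[0.02][:n] == signs[0.04][:n]).all()
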