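"""ML logistic fitting: oracles, consistency, invariances, bootstrap SEs."""

import numpy as np
import pytest
import statsmodels.api as sm

from texcue.errors import NonIdentifiableError
from texcue.psychofit import (
    LogisticPsychometric,
    bootstrap_se,
    fit_ml,
    fit_with_se,
    logistic,
)
from texcue.synthetic_observer import ObserverModel, PsychometricDataset, simulate_session

#: lighter optimiser settings for Monte-Carlo loops (same optimum, fewer starts)
FAST = dict(grid_alpha=21, grid_beta=13, n_starts=1)


def make_dataset(k_counts, x=None, n=20, **labels):
    k_counts = np.asarray(k_counts)
    if x is None:
        x = np.linspace(-0.5, 0.5, len(k_counts))
    return PsychometricDataset(
        x_levels=x,
        n_per_level=np.full(len(k_counts), n),
        k_chose_nontexture=k_counts,
        **labels,
    )


class TestLogisticFunction:
    def test_half_at_alpha(self):
        assert logistic(0.3, alpha=0.3, beta=7.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert logistic(1e3, 0.0, 5.0) == pytest.approx(1.0)
        assert logistic(-1e3, 0.0, 5.0) == pytest.approx(0.0)

    def test_three_quarters_identity(self):
        alpha, beta = -0.2, 9.0
        assert logistic(alpha + np.log(3) / beta, alpha, beta) == pytest.approx(0.75)

    def test_strictly_increasing(self):
        x = np.linspace(-2, 2, 101)
        assert np.all(np.diff(logistic(x, 0.1, 4.0)) > 0)


def grid_search_oracle(ds, alpha_range=(-1.2, 1.2), n_alpha=4801, n_beta=400):
    """Dense brute-force likelihood grid, independent of the fitting path."""
    alphas = np.linspace(*alpha_range, n_alpha)
    betas = np.geomspace(0.5, 200, n_beta)
    x, k, n = ds.x_levels, ds.k_chose_nontexture, ds.n_per_level
    best = (np.inf, None, None)
    for chunk in np.array_split(betas, 20):
        z = chunk[None, :, None] * (x[None, None, :] - alphas[:, None, None])
        nll = np.sum(
            k * np.logaddexp(0, -z) + (n - k) * np.logaddexp(0, z), axis=-1
        )
        ia, ib = np.unravel_index(np.argmin(nll), nll.shape)
        if nll[ia, ib] < best[0]:
            best = (nll[ia, ib], alphas[ia], chunk[ib])
    return best


class TestMaximumLikelihoodFit:
    def test_symmetric_data_pse_at_centre(self):
        """Counts mirror-symmetric about a level pin the PSE to that level."""
        k = np.array([1, 3, 6, 10, 14, 17, 19])
        ds = make_dataset(k, x=np.linspace(-0.3, 0.3, 7))
        fit = fit_ml(ds)
        assert fit.converged
        assert fit.alpha == pytest.approx(0.0, abs=1e-6)

    def test_consistency_at_large_n(self, default_ladder):
        """ML recovers (alpha=0, beta=8) from 10^4 trials per level."""
        model = ObserverModel(0.0, 0.0, 8.0, 8.0)
        ds = simulate_session(model, "Separate", default_ladder, 10_000, seed=11)
        fit = fit_ml(ds)
        assert fit.alpha == pytest.approx(0.0, abs=0.01)
        assert fit.beta == pytest.approx(8.0, rel=0.05)

    def test_matches_brute_force_grid_oracle(self, default_ladder):
        """The optimiser lands on the dense-grid likelihood maximum."""
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 20:
            model = ObserverModel(
                rng.uniform(-0.25, 0.25), 0.0, rng.uniform(4, 18), 8.0
            )
            ds = simulate_session(
                model, "Separate", default_ladder, 20,
                seed=rng.integers(2**31),
            )
            try:
                fit = fit_ml(ds)
            except NonIdentifiableError:
                continue
            if not fit.converged:
                continue
            nll_g, alpha_g, beta_g = grid_search_oracle(ds)
            assert abs(fit.alpha - alpha_g) < 1e-3
            assert fit.neg_log_likelihood <= nll_g + 1e-9
            checked += 1

    def test_matches_binomial_glm(self, default_ladder):
        """Independent route: statsmodels binomial GLM finds the same optimum."""
        model = ObserverModel(-0.08, 0.0, 9.0, 9.0)
        for seed in (1, 2, 3):
            ds = simulate_session(model, "Separate", default_ladder, 40, seed=seed)
            fit = fit_ml(ds)
            endog = np.column_stack(
                [ds.k_chose_nontexture, ds.n_per_level - ds.k_chose_nontexture]
            )
            res = sm.GLM(
                endog, sm.add_constant(ds.x_levels), family=sm.families.Binomial()
            ).fit()
            b0, b1 = res.params
            assert fit.beta == pytest.approx(b1, rel=1e-4)
            assert fit.alpha == pytest.approx(-b0 / b1, abs=1e-5)

    def test_translation_equivariance(self, default_ladder):
        ds = make_dataset([0, 2, 5, 9, 13, 17, 19, 20], x=default_ladder.log_ratios)
        f0 = fit_ml(ds)
        c = 0.37
        shifted = PsychometricDataset(
            x_levels=ds.x_levels + c,
            n_per_level=ds.n_per_level,
            k_chose_nontexture=ds.k_chose_nontexture,
        )
        f1 = fit_ml(shifted)
        # internal centring makes the shift exact up to optimiser tolerance
        assert f1.alpha - f0.alpha == pytest.approx(c, abs=1e-7)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-6)

    def test_invariant_to_level_reordering(self, default_ladder):
        ds = make_dataset([1, 2, 6, 8, 12, 16, 19, 19], x=default_ladder.log_ratios)
        perm = np.array([3, 0, 7, 5, 1, 6, 2, 4])
        shuffled = PsychometricDataset(
            x_levels=ds.x_levels[perm],
            n_per_level=ds.n_per_level[perm],
            k_chose_nontexture=ds.k_chose_nontexture[perm],
        )
        f0, f1 = fit_ml(ds), fit_ml(shuffled)
        assert f1.alpha == pytest.approx(f0.alpha, abs=1e-9)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-9)

    @pytest.mark.parametrize(
        "k_counts",
        [np.zeros(8, int), np.full(8, 20), np.full(8, 10)],
        ids=["all-zero", "all-ceiling", "constant-proportion"],
    )
    def test_non_identifiable_signals(self, k_counts):
        with pytest.raises(NonIdentifiableError):
            fit_ml(make_dataset(k_counts))

    def test_too_few_levels(self):
        with pytest.raises(NonIdentifiableError):
            fit_ml(make_dataset([3, 17], x=np.array([0.0, 0.0])))

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = LogisticPsychometric(grid_alpha=31)
        assert clone(est).get_params()["grid_alpha"] == 31
        est.set_params(n_starts=2)
        x = np.linspace(-0.5, 0.5, 8)
        y = np.array([0.05, 0.1, 0.3, 0.45, 0.6, 0.8, 0.9, 0.95])
        est.fit(x.reshape(-1, 1), y, sample_weight=np.full(8, 20))
        p = est.predict([est.alpha_])
        assert p[0] == pytest.approx(0.5)


class TestBootstrap:
    def _dataset(self, default_ladder, n=20, seed=31):
        model = ObserverModel(-0.05, 0.0, 10.0, 10.0)
        return simulate_session(model, "Separate", default_ladder, n, seed=seed)

    def test_same_seed_identical_ses(self, default_ladder):
        ds = self._dataset(default_ladder)
        fit = fit_ml(ds)
        se1 = bootstrap_se(ds, fit, n_boot=150, seed=5)
        se2 = bootstrap_se(ds, fit, n_boot=150, seed=5)
        assert se1 == se2

    def test_se_shrinks_with_trials(self, default_ladder):
        """se_alpha decreases monotonically over n in {20, 200, 2000}."""
        ses = []
        for n in (20, 200, 2000):
            ds = self._dataset(default_ladder, n=n, seed=8)
            fit = fit_ml(ds, **FAST)
            se_a, _ = bootstrap_se(ds, fit, n_boot=150, seed=9)
            ses.append(se_a)
        assert ses[0] > ses[1] > ses[2]

    def test_matches_monte_carlo_sampling_sd(self, default_ladder):
        """Parametric-bootstrap SE tracks the true sampling SD of alpha-hat.

        The oracle is the SD of ML estimates over 500 fresh datasets drawn
        at the same truth; the bootstrap runs on an idealised dataset whose
        counts sit exactly at the expected proportions.
        """
        alpha, beta, n = -0.05, 10.0, 20
        x = default_ladder.log_ratios
        model = ObserverModel(alpha, alpha, beta, beta)

        est = LogisticPsychometric(**FAST)
        alphas = []
        for seed in range(500):
            ds = simulate_session(model, "Separate", default_ladder, n, seed=seed)
            try:
                est.fit(ds.x_levels, ds.proportions, ds.n_per_level)
            except NonIdentifiableError:
                continue
            if est.converged_:
                alphas.append(est.alpha_)
        mc_sd = np.std(alphas, ddof=1)

        ideal = PsychometricDataset(
            x_levels=x,
            n_per_level=np.full(8, n),
            k_chose_nontexture=np.round(n * logistic(x, alpha, beta)).astype(int),
        )
        fit = fit_ml(ideal, **FAST)
        se_a, _ = bootstrap_se(ideal, fit, n_boot=400, seed=10)
        assert se_a == pytest.approx(mc_sd, rel=0.15)

    def test_fit_with_se_populates_record(self, default_ladder):
        ds = self._dataset(default_ladder)
        fit = fit_with_se(ds, n_boot=120, seed=3, **FAST)
        assert fit.se_alpha > 0 and fit.se_beta > 0
        assert fit.n_boot == 120

    def test_n_boot_floor(self, default_ladder):
        ds = self._dataset(default_ladder)
        fit = fit_ml(ds)
        with pytest.raises(ValueError):
            bootstrap_se(ds, fit, n_boot=50)


class TestRecoveryProperties:
    def test_parameter_recovery_within_bootstrap_error(self, default_ladder):
        """Across 200 study-scale sessions, |alpha error| ~ bootstrap SE.

        Median absolute PSE error stays under 1.5x the median bootstrap SE,
        and the fitted likelihood beats the generating parameters' likelihood
        in at least 95% of sessions (ML optimality).
        """
        alpha, beta = -0.1, 10.0
        model = ObserverModel(alpha, alpha, beta, beta)
        est = LogisticPsychometric(**FAST)
        errors, ses, ml_wins, total = [], [], 0, 0
        for seed in range(200):
            ds = simulate_session(model, "Separate", default_ladder, 20, seed=seed)
            try:
                est.fit(ds.x_levels, ds.proportions, ds.n_per_level)
            except NonIdentifiableError:
                continue
            if not est.converged_:
                continue
            total += 1
            errors.append(abs(est.alpha_ - alpha))
            x, k, n = ds.x_levels, ds.k_chose_nontexture, ds.n_per_level
            z = beta * (x - alpha)
            nll_truth = np.sum(
                k * np.logaddexp(0, -z) + (n - k) * np.logaddexp(0, z)
            )
            if est.nll_ <= nll_truth + 1e-9:
                ml_wins += 1
            if seed < 60:  # bootstrap SEs on a representative subset
                se_a, _, _ = est.parametric_bootstrap(
                    ds.x_levels, ds.n_per_level, n_boot=100, random_state=seed
                )
                ses.append(se_a)
        assert np.median(errors) < 1.5 * np.median(ses)
        assert ml_wins / total >= 0.95
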