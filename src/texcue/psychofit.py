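"""Maximum-likelihood logistic psychometric fitting with bootstrap SEs.

The psychometric function is the two-parameter logistic

    p(x) = 1 / (1 + exp(-beta * (x - alpha)))

on the abscissa ``x = log10(non-texture contrast / texture contrast)``.
``alpha`` is the point of subjective equality (PSE): the log contrast ratio
at which the two cues are chosen equally often.  ``beta`` is the slope per
log10 unit.  Guess and lapse rates are fixed at zero.

Fitting maximises the binomial log-likelihood

    sum_i [ k_i log p(x_i) + (n_i - k_i) log(1 - p(x_i)) ]

by a multi-start Nelder-Mead search seeded from a coarse (alpha, log beta)
grid — the small 8-point datasets of this design can have flat or multimodal
likelihoods, so a gradient-free multi-start is preferred over a single
Newton path.  Standard errors come from a parametric bootstrap: resample
``k* ~ Binomial(n, p_hat)`` at each level, refit, and take the SD of the
refitted parameters.

The estimator follows the scikit-learn protocol (``fit(X, y,
sample_weight)`` with proportions in ``y`` and trial counts in
``sample_weight``) so it composes with sklearn tooling; :func:`fit_ml` and
:func:`bootstrap_se` wrap it for :class:`PsychometricDataset` inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

from .errors import NonIdentifiableError
from .synthetic_observer import PsychometricDataset

__all__ = [
    "LogisticFit",
    "LogisticPsychometric",
    "UnstableFitWarning",
    "bootstrap_se",
    "fit_ml",
    "fit_with_se",
    "logistic",
]


class UnstableFitWarning(UserWarning):
    """More than 20% of bootstrap refits were non-identifiable."""


def logistic(x, alpha: float, beta: float):
    """Two-parameter logistic: 0.5 at ``x = alpha``, slope ``beta``."""
    x = np.asarray(x, dtype=float)
    out = expit(beta * (x - alpha))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LogisticFit:
    """A fitted psychometric function with optional bootstrap SEs."""

    alpha: float
    beta: float
    neg_log_likelihood: float
    converged: bool
    se_alpha: float = float("nan")
    se_beta: float = float("nan")
    n_boot: int = 0
    unstable: bool = False
    message: str = ""

    def predict(self, x):
        return logistic(x, self.alpha, self.beta)


def _nll(alpha: float, log_beta: float, x, k, n) -> float:
    """Binomial negative log-likelihood; stable at saturated probabilities."""
    z = np.exp(log_beta) * (x - alpha)
    # -log p = softplus(-z), -log(1-p) = softplus(z)
    return float(np.sum(k * np.logaddexp(0.0, -z) + (n - k) * np.logaddexp(0.0, z)))


def _nll_grid(alphas, log_betas, x, k, n) -> np.ndarray:
    """Vectorised NLL over an (alpha, log beta) grid; shape (na, nb)."""
    z = np.exp(log_betas)[None, :, None] * (
        x[None, None, :] - alphas[:, None, None]
    )
    return np.sum(
        k * np.logaddexp(0.0, -z) + (n - k) * np.logaddexp(0.0, z), axis=-1
    )


class LogisticPsychometric(BaseEstimator):
    """Maximum-likelihood two-parameter logistic psychometric estimator.

    Parameters
    ----------
    grid_alpha, grid_beta : int
        Resolution of the coarse start grid over alpha (spanning the data
        range extended by one full range either side) and log beta.
    beta_range : (float, float)
        Slope bracket, per abscissa unit, for the start grid.  Fits may leave
        the bracket; beta above ``max_beta`` marks the fit non-converged
        (effectively a step function: no finite ML slope).
    n_starts : int
        Number of best grid points used to start Nelder-Mead.
    tol : float
        Objective-function tolerance of each Nelder-Mead polish.
    max_beta : float
        Identifiability ceiling on the fitted slope.

    Attributes
    ----------
    alpha_, beta_ : float
        ML estimates (PSE and slope).
    nll_ : float
        Negative log-likelihood at the optimum.
    converged_ : bool
        False if no Nelder-Mead start converged or the slope hit ``max_beta``.
    """

    def __init__(
        self,
        grid_alpha: int = 41,
        grid_beta: int = 25,
        beta_range: tuple[float, float] = (0.25, 400.0),
        n_starts: int = 3,
        tol: float = 1e-8,
        max_beta: float = 1e4,
    ):
        self.grid_alpha = grid_alpha
        self.grid_beta = grid_beta
        self.beta_range = beta_range
        self.n_starts = n_starts
        self.tol = tol
        self.max_beta = max_beta

    # -- validation ---------------------------------------------------------

    def _validate(self, X, y, sample_weight):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if sample_weight is None:
            n = np.ones_like(x)
        else:
            n = np.asarray(sample_weight, dtype=float).reshape(-1)
        if not (len(x) == len(y) == len(n)):
            raise ValueError("X, y and sample_weight must have equal length")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(n <= 0):
            raise ValueError("inputs must be finite with positive trial counts")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("y must be response proportions in [0, 1]")
        if len(np.unique(x)) < 2:
            raise NonIdentifiableError("need >= 2 distinct x levels to fit")
        k = y * n
        if np.all(k == 0):
            raise NonIdentifiableError(
                "all responses 0: no finite ML slope exists"
            )
        if np.all(k == n):
            raise NonIdentifiableError(
                "all responses at ceiling: no finite ML slope exists"
            )
        if np.allclose(y, y[0]):
            raise NonIdentifiableError(
                "constant response proportions: slope is not identifiable"
            )
        order = np.argsort(x, kind="stable")  # reorder-invariance by construction
        return x[order], k[order], n[order]

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        """Fit by ML.

        Parameters
        ----------
        X : array-like, shape (n_levels,) or (n_levels, 1)
            Abscissa values (log10 contrast ratios).
        y : array-like
            Proportion of "non-texture more salient" responses per level.
        sample_weight : array-like, optional
            Trials per level (defaults to 1 per level).
        """
        x, k, n = self._validate(X, y, sample_weight)
        x_mean = float(np.mean(x))  # centring makes shift equivariance exact
        xc = x - x_mean
        span = max(float(np.ptp(xc)), 1e-6)

        alphas = np.linspace(xc.min() - span, xc.max() + span, self.grid_alpha)
        log_betas = np.log(
            np.geomspace(self.beta_range[0], self.beta_range[1], self.grid_beta)
        )
        grid = _nll_grid(alphas, log_betas, xc, k, n)
        flat_order = np.argsort(grid, axis=None, kind="stable")

        best = None
        any_converged = False
        for pos in flat_order[: self.n_starts]:
            ia, ib = np.unravel_index(pos, grid.shape)
            res = minimize(
                lambda p: _nll(p[0], p[1], xc, k, n),
                x0=np.array([alphas[ia], log_betas[ib]]),
                method="Nelder-Mead",
                options={
                    "fatol": self.tol,
                    "xatol": 1e-9,
                    "maxiter": 600,
                    "maxfev": 1200,
                },
            )
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res

        alpha_hat = float(best.x[0]) + x_mean
        beta_hat = float(np.exp(best.x[1]))
        converged = any_converged and beta_hat <= self.max_beta
        message = "" if converged else (
            f"slope {beta_hat:.3g} exceeds identifiability ceiling"
            if beta_hat > self.max_beta
            else str(best.message)
        )

        self.alpha_ = alpha_hat
        self.beta_ = beta_hat
        self.nll_ = float(best.fun)
        self.converged_ = converged
        self.message_ = message
        self.n_levels_ = len(x)
        self.x_mean_ = x_mean
        return self

    def predict(self, X):
        """Predicted probability of a non-texture response at each X."""
        if not hasattr(self, "alpha_"):
            raise AttributeError("estimator is not fitted")
        return logistic(np.asarray(X, dtype=float).reshape(-1), self.alpha_, self.beta_)

    # -- uncertainty --------------------------------------------------------

    def parametric_bootstrap(
        self,
        X,
        sample_weight,
        n_boot: int = 400,
        random_state: int | np.random.SeedSequence | None = 0,
    ) -> tuple[float, float, int]:
        """Bootstrap SEs of (alpha, beta) by binomial resampling from the fit.

        Returns ``(se_alpha, se_beta, n_failed)`` where ``n_failed`` counts
        non-identifiable or non-converged refits (excluded from the SDs).
        Deterministic given ``random_state``.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100 for stable SEs")
        if not hasattr(self, "alpha_"):
            raise AttributeError("fit before bootstrapping")
        x = np.asarray(X, dtype=float).reshape(-1)
        n = np.asarray(sample_weight, dtype=float).reshape(-1)
        p_hat = logistic(x, self.alpha_, self.beta_)
        rng = np.random.default_rng(random_state)
        refit = LogisticPsychometric(**self.get_params())

        alphas, betas, n_failed = [], [], 0
        for _ in range(n_boot):
            k_star = rng.binomial(n.astype(int), p_hat)
            try:
                refit.fit(x, k_star / n, sample_weight=n)
            except NonIdentifiableError:
                n_failed += 1
                continue
            if not refit.converged_:
                n_failed += 1
                continue
            alphas.append(refit.alpha_)
            betas.append(refit.beta_)
        if len(alphas) < 2:
            raise NonIdentifiableError(
                "bootstrap produced fewer than 2 identifiable refits"
            )
        return (
            float(np.std(alphas, ddof=1)),
            float(np.std(betas, ddof=1)),
            n_failed,
        )


# ---------------------------------------------------------------------------
# Dataset-level wrappers


def fit_ml(data: PsychometricDataset, **estimator_params) -> LogisticFit:
    """ML logistic fit of one session's counts."""
    est = LogisticPsychometric(**estimator_params)
    est.fit(
        data.x_levels,
        data.proportions,
        sample_weight=data.n_per_level,
    )
    if not est.converged_:
        warnings.warn(
            f"psychometric fit did not converge: {est.message_}",
            UnstableFitWarning,
            stacklevel=2,
        )
    return LogisticFit(
        alpha=est.alpha_,
        beta=est.beta_,
        neg_log_likelihood=est.nll_,
        converged=est.converged_,
        message=est.message_,
    )


def bootstrap_se(
    data: PsychometricDataset,
    fit: LogisticFit,
    n_boot: int = 400,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap SEs for a fitted session; see the estimator."""
    est = LogisticPsychometric()
    est.alpha_, est.beta_ = fit.alpha, fit.beta
    se_a, se_b, n_failed = est.parametric_bootstrap(
        data.x_levels, data.n_per_level, n_boot=n_boot, random_state=seed
    )
    if n_failed > 0.2 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits were non-identifiable; "
            "standard errors may be unreliable",
            UnstableFitWarning,
            stacklevel=2,
        )
    return se_a, se_b


def fit_with_se(
    data: PsychometricDataset,
    n_boot: int = 400,
    seed: int | np.random.SeedSequence | None = 0,
    **estimator_params,
) -> LogisticFit:
    """Convenience: ML fit plus bootstrap SEs in one LogisticFit record."""
    fit = fit_ml(data, **estimator_params)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UnstableFitWarning)
        se_a, se_b = bootstrap_se(data, fit, n_boot=n_boot, seed=seed)
        unstable = any(
            issubclass(w.category, UnstableFitWarning) for w in caught
        )
    return replace(
        fit, se_alpha=se_a, se_beta=se_b, n_boot=n_boot, unstable=unstable
    )
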