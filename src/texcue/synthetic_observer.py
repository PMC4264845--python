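"""Synthetic forced-choice data under the logistic decision model.

A session presents 8 log-spaced contrast-ratio levels, 20 trials each (160
trials).  At abscissa ``x = log10(non-texture contrast / texture contrast)``
the probability of judging the non-texture cue more salient is the logistic
``1 / (1 + exp(-beta (x - alpha)))``; responses are binomial draws from it.
A cohort pairs a Separate and a Combined session per observer, with the
observer's true PSE shift (Combined minus Separate alpha) drawn from a
normal distribution — the minimal generative assumption consistent with
reporting only a mean and SD of observed shifts.

One master seed spawns independent substreams per observer and session, so a
cohort is bit-reproducible while sessions stay statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stimulus import ContrastLadder

__all__ = [
    "ObserverModel",
    "PsychometricDataset",
    "simulate_cohort",
    "simulate_session",
]

COMPARISONS = ("Dark", "Red", "Violet")
CONDITIONS = ("Separate", "Combined")


@dataclass(frozen=True)
class ObserverModel:
    """True logistic parameters of one observer in both conditions.

    ``alpha`` is the PSE in log10 contrast-ratio units; ``beta`` the slope
    per log10 unit.  Negative alphas mean more texture contrast is required
    at the PSE; a positive shift means less texture contrast is needed in
    the Combined condition.
    """

    alpha_separate: float
    alpha_combined: float
    beta_separate: float
    beta_combined: float

    def __post_init__(self):
        if not (self.beta_separate > 0 and self.beta_combined > 0):
            raise ValueError("logistic slopes must be > 0")
        if not math.isfinite(self.alpha_combined - self.alpha_separate):
            raise ValueError("true shift must be finite")

    @property
    def true_shift(self) -> float:
        return self.alpha_combined - self.alpha_separate

    def params(self, condition: str) -> tuple[float, float]:
        if condition == "Separate":
            return self.alpha_separate, self.beta_separate
        if condition == "Combined":
            return self.alpha_combined, self.beta_combined
        raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class PsychometricDataset:
    """Per-level response counts for one observer x comparison x condition.

    ``x_levels`` are log10 contrast ratios; ``k_chose_nontexture`` counts the
    trials (out of ``n_per_level``) on which the non-texture cue was judged
    more salient.
    """

    x_levels: np.ndarray
    n_per_level: np.ndarray
    k_chose_nontexture: np.ndarray
    observer: str = "synthetic"
    comparison: str = "Dark"
    condition: str = "Separate"

    def __post_init__(self):
        x = np.asarray(self.x_levels, dtype=float)
        n = np.asarray(self.n_per_level, dtype=int)
        k = np.asarray(self.k_chose_nontexture, dtype=int)
        if not (x.shape == n.shape == k.shape) or x.ndim != 1:
            raise ValueError("x, n and k must be 1-d arrays of equal length")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("counts must satisfy 0 <= k <= n at every level")
        object.__setattr__(self, "x_levels", x)
        object.__setattr__(self, "n_per_level", n)
        object.__setattr__(self, "k_chose_nontexture", k)

    @property
    def n_trials(self) -> int:
        return int(self.n_per_level.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.k_chose_nontexture / self.n_per_level


def _logistic(x: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # local copy to keep this module import-light; psychofit owns the public one
    z = beta * (np.asarray(x, dtype=float) - alpha)
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def simulate_session(
    model: ObserverModel,
    condition: str,
    ladder: ContrastLadder,
    n_per_level: int = 20,
    seed: int | np.random.SeedSequence = 0,
    observer: str = "synthetic",
    comparison: str = "Dark",
) -> PsychometricDataset:
    """Simulate one session's counts: k ~ Binomial(n, logistic(x; a, b))."""
    if n_per_level < 1:
        raise ValueError("n_per_level must be >= 1")
    alpha, beta = model.params(condition)
    x = ladder.log_ratios
    p = _logistic(x, alpha, beta)
    rng = np.random.default_rng(seed)
    k = rng.binomial(n_per_level, p)
    return PsychometricDataset(
        x_levels=x,
        n_per_level=np.full(len(x), n_per_level, dtype=int),
        k_chose_nontexture=k,
        observer=observer,
        comparison=comparison,
        condition=condition,
    )


def simulate_cohort(
    n_observers: int,
    mean_shift: float,
    sd_shift: float,
    base_alpha: float,
    betas: tuple[float, float],
    ladder: ContrastLadder,
    seed: int | np.random.SeedSequence = 0,
    n_per_level: int = 20,
    comparison: str = "Dark",
    return_models: bool = False,
) -> list[tuple[PsychometricDataset, PsychometricDataset]]:
    """Simulate a cohort: (Separate, Combined) dataset pair per observer.

    Per-observer true shifts are drawn from Normal(mean_shift, sd_shift);
    every observer shares ``base_alpha`` in the Separate condition and the
    condition-specific slopes ``betas = (beta_separate, beta_combined)``.
    The master seed spawns one substream per observer session, so the whole
    design is reproducible from the seed alone.  With ``return_models=True``
    each tuple also carries the generating :class:`ObserverModel` (useful for
    recovery studies).
    """
    if n_observers < 2:
        raise ValueError("a cohort needs at least 2 observers")
    if sd_shift < 0:
        raise ValueError("sd_shift must be >= 0")
    beta_sep, beta_comb = betas
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    shift_stream, *session_streams = root.spawn(1 + 2 * n_observers)
    shifts = np.random.default_rng(shift_stream).normal(
        mean_shift, sd_shift, size=n_observers
    )

    cohort = []
    for i in range(n_observers):
        model = ObserverModel(
            alpha_separate=base_alpha,
            alpha_combined=base_alpha + shifts[i],
            beta_separate=beta_sep,
            beta_combined=beta_comb,
        )
        name = f"S{i + 1}"
        sep = simulate_session(
            model, "Separate", ladder, n_per_level,
            seed=session_streams[2 * i], observer=name, comparison=comparison,
        )
        comb = simulate_session(
            model, "Combined", ladder, n_per_level,
            seed=session_streams[2 * i + 1], observer=name, comparison=comparison,
        )
        cohort.append((sep, comb, model) if return_models else (sep, comb))
    return cohort
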