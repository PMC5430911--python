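"""Memory-decay Bayesian observer: trial-by-trial intention priors.

The observer tracks, for each intention i, an exponentially lag-weighted
event count

    w_i(t) = sum_{p=1..t-1} alpha^(-p) * 1[event at lag p == i]

(p = 1 is the most recent past event) and converts it to a probability with
one pseudo-count of Laplace smoothing per intention:

    prob(e_t = i) = (w_i + s) / sum_j (w_j + s)

alpha = 1 is the ideal observer (lossless counting: Laplace-smoothed
relative frequency); alpha > 1 discounts older events, modelling limited
memory.  Before any event is seen the prior is flat.  In the social task the
relevant statistic is conditional on the first actor's move (cooperate after
cooperation vs. after defection), so counts are kept separately per context
and each trial reads the trace of its own context.

The decay parameter is estimated by scanning a grid of alpha values; at each
value the prior trace feeds the standardized logistic choice model
(:func:`intentprior.behavior.fit_choice_model`) and alpha is chosen to
minimize the sum of squared residuals between the observed correct responses
and the fitted response probabilities, refined by golden-section search
around the best grid point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .behavior import BehavioralFit, fit_choice_model

__all__ = [
    "ObserverConfig",
    "PriorTrace",
    "ObserverFit",
    "prior_trace",
    "fit_alpha",
    "default_alpha_grid",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Decay and smoothing parameters of the observer.

    ``alpha`` may be a scalar (shared decay, the default behaviour) or a
    per-intention sequence.  ``smoothing`` is the pseudo-count added to each
    intention's weighted count.
    """

    alpha: float | Sequence[float] = 1.0
    n_intentions: int = 2
    smoothing: float = 1.0

    def __post_init__(self) -> None:
        alphas = self.alpha_vector
        if np.any(alphas < 1.0):
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")
        if self.smoothing <= 0:
            raise ValueError(f"smoothing must be > 0, got {self.smoothing}")
        if self.n_intentions < 2:
            raise ValueError("need at least 2 intentions")

    @property
    def alpha_vector(self) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if a.size == 1:
            a = np.full(self.n_intentions, float(a[0]))
        if a.size != self.n_intentions:
            raise ValueError(
                f"alpha vector length {a.size} != n_intentions {self.n_intentions}"
            )
        return a


@dataclass(frozen=True)
class PriorTrace:
    """Per-trial prior probabilities, evaluated before each trial's event.

    ``probs[t, i]`` is the observer's probability that trial t enacts
    intention ``labels[i]``, computed from trials 1..t-1 only; row 0 is the
    flat prior.  Rows sum to one.
    """

    labels: tuple[str, ...]
    probs: np.ndarray
    contexts: Optional[tuple] = None

    def prob_of(self, events: Sequence[str]) -> np.ndarray:
        """Probability assigned to the intention actually enacted per trial."""
        idx = {lab: k for k, lab in enumerate(self.labels)}
        cols = np.array([idx[e] for e in events])
        return self.probs[np.arange(len(events)), cols]


def _resolve_labels(
    events: Sequence[str], labels: Optional[Sequence[str]]
) -> tuple[str, ...]:
    if labels is None:
        labels = tuple(sorted(set(events)))
    labels = tuple(labels)
    unknown = set(events) - set(labels)
    if unknown:
        raise ValueError(f"unknown intention label(s): {sorted(unknown)}")
    return labels


def prior_trace(
    events: Sequence[str],
    config: ObserverConfig = ObserverConfig(),
    labels: Optional[Sequence[str]] = None,
    contexts: Optional[Sequence] = None,
) -> PriorTrace:
    """Run the observer over an event sequence.

    ``contexts``, when given (social task), keys a separate weighted-count
    history per context value; trial t's row uses the history of trial t's
    own context.  The update is incremental: after each event every existing
    weight decays by one lag (division by alpha) and the new event enters at
    lag 1 with weight 1/alpha.
    """
    labels = _resolve_labels(events, labels)
    k = len(labels)
    cfg = ObserverConfig(
        alpha=config.alpha, n_intentions=k, smoothing=config.smoothing
    )
    alphas = cfg.alpha_vector
    idx = {lab: j for j, lab in enumerate(labels)}
    s = cfg.smoothing

    n = len(events)
    probs = np.empty((n, k))
    if contexts is None:
        ctx_seq = [None] * n
    else:
        if len(contexts) != n:
            raise ValueError("contexts must align with events")
        ctx_seq = list(contexts)
    weights: dict = {}
    for t, (e, c) in enumerate(zip(events, ctx_seq)):
        w = weights.setdefault(c, np.zeros(k))
        probs[t] = (w + s) / np.sum(w + s)
        j = idx[e]
        w /= alphas
        w[j] += 1.0 / alphas[j]
    return PriorTrace(labels=labels, probs=probs, contexts=tuple(ctx_seq))


def default_alpha_grid(stop: float = 3.0, step: float = 0.05) -> np.ndarray:
    """Default search grid for the decay parameter: [1, stop] in ``step``s."""
    return np.round(np.arange(1.0, stop + step / 2, step), 10)


@dataclass(frozen=True)
class ObserverFit:
    """Result of the joint alpha / choice-model fit."""

    alpha_hat: float
    objective_curve: np.ndarray  # SSE per grid point
    grid: np.ndarray
    betas: BehavioralFit
    separation: bool


def _sse_at_alpha(
    alpha: float,
    events: Sequence[str],
    evidence: np.ndarray,
    correct: np.ndarray,
    labels: tuple[str, ...],
    contexts,
    smoothing: float,
) -> tuple[float, BehavioralFit]:
    trace = prior_trace(
        events,
        ObserverConfig(alpha=alpha, n_intentions=len(labels), smoothing=smoothing),
        labels=labels,
        contexts=contexts,
    )
    prior = trace.prob_of(events)
    fit = fit_choice_model(prior, evidence, correct)
    sse = float(np.sum((correct - fit.fitted_probs) ** 2))
    return sse, fit


def fit_alpha(
    events: Sequence[str],
    evidence: Sequence[float],
    correct: Sequence[int],
    grid: Optional[Sequence[float]] = None,
    labels: Optional[Sequence[str]] = None,
    contexts: Optional[Sequence] = None,
    smoothing: float = 1.0,
    refine_tol: float = 1e-3,
) -> ObserverFit:
    """Estimate the memory-decay parameter by least squares on responses.

    For each candidate alpha the observer trace is recomputed, the
    standardized logistic choice model refitted, and the candidate scored by
    the Brier-type sum of squared residuals between correct responses and
    fitted probabilities.  Ties break toward smaller alpha; a golden-section
    refinement (tolerance ``refine_tol``) runs between the grid neighbours
    of the best grid point.
    """
    if grid is None:
        grid = default_alpha_grid()
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    if np.any(grid < 1.0):
        raise ValueError("alpha grid values must be >= 1")
    grid = np.sort(grid)
    evidence = np.asarray(evidence, dtype=float)
    correct = np.asarray(correct, dtype=float)
    if not (len(events) == len(evidence) == len(correct)):
        raise ValueError("events, evidence and correct must have equal length")
    labels = _resolve_labels(events, labels)

    curve = np.empty(grid.size)
    fits: list[BehavioralFit] = []
    for i, a in enumerate(grid):
        curve[i], fit = _sse_at_alpha(
            a, events, evidence, correct, labels, contexts, smoothing
        )
        fits.append(fit)
    best = int(np.argmin(curve))  # argmin returns the first (smallest alpha) tie

    alpha_hat = float(grid[best])
    best_fit = fits[best]
    best_sse = curve[best]
    if grid.size > 1:
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, grid.size - 1)]
        if hi - lo > refine_tol:
            invphi = (np.sqrt(5.0) - 1.0) / 2.0
            a, b = float(lo), float(hi)
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fc, fit_c = _sse_at_alpha(c, events, evidence, correct, labels, contexts, smoothing)
            fd, fit_d = _sse_at_alpha(d, events, evidence, correct, labels, contexts, smoothing)
            while b - a > refine_tol:
                if fc <= fd:
                    b, d, fd = d, c, fc
                    c = b - invphi * (b - a)
                    fc, fit_c = _sse_at_alpha(
                        c, events, evidence, correct, labels, contexts, smoothing
                    )
                else:
                    a, c, fc = c, d, fd
                    d = a + invphi * (b - a)
                    fd, fit_d = _sse_at_alpha(
                        d, events, evidence, correct, labels, contexts, smoothing
                    )
            for cand, f_cand, fit_cand in [(c, fc, fit_c), (d, fd, fit_d)]:
                if f_cand < best_sse or (f_cand == best_sse and cand < alpha_hat):
                    alpha_hat, best_sse, best_fit = float(cand), f_cand, fit_cand

    return ObserverFit(
        alpha_hat=alpha_hat,
        objective_curve=curve,
        grid=grid,
        betas=best_fit,
        separation=best_fit.separation,
    )
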