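"""AUC-induced minimax loss for imbalanced binary classification.

The squared pairwise AUC surrogate ``mean over (positive, negative) pairs of
(1 - (f+ - f-))**2`` is expensive to optimize directly (it couples every pair
of samples).  The stochastic saddle-point reformulation replaces it with a
per-sample objective over the model scores ``f`` and three auxiliary scalars:
``mu1`` and ``mu2`` (class-conditional score centers, minimized) and ``theta``
(an ascent variable, maximized):

    L = mean_i [ (1-p) * (f_i - mu1)^2 * 1[b_i = 1]
               + p * (f_i - mu2)^2 * 1[b_i = 0]
               - p * (1-p) * theta^2
               + 2 * (1 + theta) * (p * f_i * 1[b_i = 0]
                                    - (1-p) * f_i * 1[b_i = 1]) ]

where ``p`` is the positive-class proportion.  At the inner optimum
(``mu1* = m1``, ``mu2* = m0``, ``theta* = m0 - m1`` with ``m1``/``m0`` the
class-conditional score means) the objective equals

    p * (1 - p) * (pairwise_surrogate - 1)

with class-conditional variances taken in the population (1/n) convention —
the saddle identity that serves as this module's correctness contract.
Because every term touches one sample at a time, the loss is minibatch
friendly and its class-proportion weighting makes it robust to imbalance.

A weighted cross-entropy baseline is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoredBatch",
    "MinimaxState",
    "minimax_objective",
    "minimax_gradients",
    "closed_form_inner",
    "brute_force_inner",
    "pairwise_surrogate",
    "weighted_cross_entropy",
    "weighted_cross_entropy_gradient",
]

_EPS = 1e-7  # probability clamp for cross-entropy


@dataclass
class ScoredBatch:
    """Real-valued model scores paired with binary labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        self.labels = np.asarray(self.labels).ravel()
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same length")
        if self.scores.size < 1:
            raise ValueError("batch must contain at least one sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        self.labels = self.labels.astype(np.int64)

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean())


@dataclass
class MinimaxState:
    """Auxiliary scalars of the saddle objective for one scoring head.

    ``p`` is the positive-class proportion, fixed per training fold.
    """

    mu1: float = 0.0
    mu2: float = 0.0
    theta: float = 0.0
    p: float = 0.5

    def __post_init__(self):
        for name in ("mu1", "mu2", "theta", "p"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def minimax_objective(batch: ScoredBatch, state: MinimaxState) -> float:
    """Empirical saddle objective for a scored batch at a given state."""
    f, b = batch.scores, batch.labels
    p, mu1, mu2, theta = state.p, state.mu1, state.mu2, state.theta
    pos = b == 1
    neg = ~pos
    terms = np.zeros_like(f)
    terms[pos] = (1.0 - p) * (f[pos] - mu1) ** 2
    terms[neg] = p * (f[neg] - mu2) ** 2
    lin = np.where(neg, p * f, -(1.0 - p) * f)
    terms += 2.0 * (1.0 + theta) * lin
    terms -= p * (1.0 - p) * theta**2
    return float(terms.mean())


def minimax_gradients(batch: ScoredBatch, state: MinimaxState
                      ) -> tuple[np.ndarray, float, float, float]:
    """Analytic gradients of :func:`minimax_objective`.

    Returns ``(d/dscores, d/dmu1, d/dmu2, d/dtheta)``.  ``theta`` is an
    ascent variable; callers performing gradient ascent on it should flip the
    sign of its gradient before a descent update.
    """
    f, b = batch.scores, batch.labels
    p, mu1, mu2, theta = state.p, state.mu1, state.mu2, state.theta
    n = f.size
    pos = b == 1
    neg = ~pos
    df = np.empty_like(f)
    df[pos] = 2.0 * (1.0 - p) * (f[pos] - mu1) - 2.0 * (1.0 + theta) * (1.0 - p)
    df[neg] = 2.0 * p * (f[neg] - mu2) + 2.0 * (1.0 + theta) * p
    df /= n
    dmu1 = float(-2.0 * (1.0 - p) * (f[pos] - mu1).sum() / n)
    dmu2 = float(-2.0 * p * (f[neg] - mu2).sum() / n)
    dtheta = float(-2.0 * p * (1.0 - p) * theta
                   + 2.0 * (p * f[neg].sum() - (1.0 - p) * f[pos].sum()) / n)
    return df, dmu1, dmu2, dtheta


def closed_form_inner(batch: ScoredBatch, p: float | None = None) -> MinimaxState:
    """Exact inner optimum of the saddle objective for fixed scores.

    Minimizes over ``(mu1, mu2)`` and maximizes over ``theta``:
    ``mu1* = m1`` (mean positive score), ``mu2* = m0`` (mean negative score),
    and ``theta* = m0 - m1`` when ``p`` equals the batch positive fraction
    (the general stationary value for other ``p`` is used otherwise).
    """
    b = batch.labels
    n1, n0 = int(b.sum()), int((1 - b).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("inner optimum undefined: batch must contain both classes")
    if p is None:
        p = batch.positive_fraction
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    f = batch.scores
    m1 = float(f[b == 1].mean())
    m0 = float(f[b == 0].mean())
    n = f.size
    theta = (p * (n0 / n) * m0 - (1.0 - p) * (n1 / n) * m1) / (p * (1.0 - p))
    return MinimaxState(mu1=m1, mu2=m0, theta=float(theta), p=float(p))


def brute_force_inner(batch: ScoredBatch, p: float | None = None,
                      lo: float = -2.0, hi: float = 2.0, step: float = 1e-3
                      ) -> MinimaxState:
    """Brute-force grid optimum of the inner problem — a verification oracle.

    The objective is separable in ``(mu1, mu2, theta)``: each scalar appears
    in a disjoint group of terms, so the joint grid optimum over the cube is
    found exactly by a 1-D grid scan per coordinate.  ``mu1``/``mu2`` minimize
    their quadratic groups, ``theta`` maximizes its group.
    """
    b = batch.labels
    if b.min() == b.max():
        raise ValueError("inner optimum undefined: batch must contain both classes")
    if p is None:
        p = batch.positive_fraction
    f = batch.scores
    n = f.size
    grid = np.arange(lo, hi + step / 2, step)
    pos, neg = f[b == 1], f[b == 0]
    # terms containing mu1: (1-p) * sum (f_pos - mu1)^2 / n  -> minimize
    obj1 = (1.0 - p) * ((pos[None, :] - grid[:, None]) ** 2).sum(axis=1) / n
    mu1 = grid[int(np.argmin(obj1))]
    obj2 = p * ((neg[None, :] - grid[:, None]) ** 2).sum(axis=1) / n
    mu2 = grid[int(np.argmin(obj2))]
    # terms containing theta: -p(1-p) theta^2 + 2 theta (p*sum f_neg - (1-p)*sum f_pos)/n
    lin = (p * neg.sum() - (1.0 - p) * pos.sum()) / n
    obj3 = -p * (1.0 - p) * grid**2 + 2.0 * grid * lin
    theta = grid[int(np.argmax(obj3))]
    return MinimaxState(mu1=float(mu1), mu2=float(mu2), theta=float(theta), p=float(p))


def pairwise_surrogate(batch: ScoredBatch) -> float:
    """Mean squared pairwise AUC surrogate ``(1 - (f+ - f-))**2``."""
    b = batch.labels
    pos = batch.scores[b == 1]
    neg = batch.scores[b == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("pairwise surrogate undefined: batch must contain both classes")
    margins = 1.0 - (pos[:, None] - neg[None, :])
    return float((margins**2).mean())


def weighted_cross_entropy(batch: ScoredBatch,
                           class_weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Class-weighted binary cross-entropy over scores in (0, 1).

    ``class_weights = (w0, w1)`` weight negative and positive samples; the
    mean is taken over the batch (denominator ``n``, not the weight sum).
    Scores at exactly 0 or 1 are clamped to ``1e-7`` from the boundary.
    """
    f = np.clip(batch.scores, _EPS, 1.0 - _EPS)
    b = batch.labels
    w = np.where(b == 1, class_weights[1], class_weights[0])
    ce = -(b * np.log(f) + (1 - b) * np.log1p(-f))
    return float((w * ce).mean())


def weighted_cross_entropy_gradient(batch: ScoredBatch,
                                    class_weights: tuple[float, float] = (1.0, 1.0)
                                    ) -> np.ndarray:
    """Gradient of :func:`weighted_cross_entropy` with respect to the scores."""
    f = np.clip(batch.scores, _EPS, 1.0 - _EPS)
    b = batch.labels
    w = np.where(b == 1, class_weights[1], class_weights[0])
    grad = w * (-b / f + (1 - b) / (1.0 - f)) / f.size
    # clamped scores sit on a flat section of the loss
    grad[(batch.scores <= _EPS) | (batch.scores >= 1.0 - _EPS)] = 0.0
    return grad
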