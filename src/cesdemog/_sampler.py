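"""Low-level MCMC building blocks shared by the model fitters.

Random-walk Metropolis steps with per-block adaptive scales (adapted during
warmup only, frozen afterwards so the retained chain is a valid fixed-kernel
Markov chain), and a univariate stepping-out slice sampler for the
variance-scale parameters.
"""

from __future__ import annotations

from collections.abc import Callable

import numpy as np


class AdaptiveScale:
    """Per-component log proposal scales with Robbins-Monro adaptation."""

    def __init__(self, shape=(), init: float = -1.0, target: float = 0.44):
        self.log_scale = np.full(shape, float(init))
        self.target = target

    @property
    def scale(self) -> np.ndarray:
        return np.exp(self.log_scale)

    def update(self, accepted, iteration: int) -> None:
        rate = min(0.25, 3.0 / np.sqrt(iteration + 1.0))
        ls = self.log_scale + rate * (np.asarray(accepted, dtype=float) - self.target)
        self.log_scale = np.clip(ls, -12.0, 6.0)


def metropolis_accept(rng: np.random.Generator, log_ratio: np.ndarray) -> np.ndarray:
    """Vectorized accept/reject; NaN log-ratios are rejected."""
    log_ratio = np.asarray(log_ratio, dtype=float)
    u = rng.random(log_ratio.shape) if log_ratio.shape else rng.random()
    with np.errstate(invalid="ignore"):
        acc = np.log(u) < log_ratio
    return acc & ~np.isnan(log_ratio)


def slice_sample(
    logf: Callable[[float], float],
    x0: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One update of a univariate slice sampler with stepping-out."""
    y = logf(x0) - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    steps = max_steps
    while steps > 0 and logf(left) > y:
        left -= w
        steps -= 1
    steps = max_steps
    while steps > 0 and logf(right) > y:
        right += w
        steps -= 1
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0
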