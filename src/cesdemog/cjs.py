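"""Cormack-Jolly-Seber likelihood kernels.

The CJS model conditions on each individual's first capture and models
subsequent encounters through per-interval apparent survival ``phi`` and a
recapture probability ``p``.  Two equivalent forms are provided: an exact
per-history probability (marginalizing over the latent death time, exposed so
independent oracles can check it) and the m-array multinomial form used by the
samplers, which aggregates all histories of a site into released/recaptured
counts.
"""

from __future__ import annotations

import numpy as np

from .ces_io import CaptureHistoryMatrix

_TINY = 1e-300


def _check_probs(phi: np.ndarray, p: float | np.ndarray) -> None:
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(phi <= 0) or np.any(phi > 1):
        raise ValueError("phi must lie in (0, 1]")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")


def cjs_history_probability(
    history, first_idx: int | None = None, phi=None, p: float = None
) -> float:
    """Exact probability of a capture history after its first capture.

    ``history`` is a 0/1 sequence over T occasions; ``phi`` gives the T-1
    per-interval survival probabilities (a scalar is broadcast) and ``p`` the
    per-occasion recapture probability.  The probability marginalizes over the
    unobserved death time: the segment up to the last capture is a product of
    survival and detection/non-detection terms, and the tail is the standard
    chi recursion (probability of never being seen again).
    """
    h = np.asarray(history, dtype=int)
    T = h.size
    if first_idx is None:
        first_idx = int(h.argmax())
    if h[first_idx] != 1:
        raise ValueError("history must have a 1 at first_idx")
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (max(T - 1, 0),)).copy()
    _check_probs(phi if phi.size else np.array([1.0]), p)

    last = int(np.flatnonzero(h).max())
    logprob = 0.0
    for t in range(first_idx, last):
        logprob += np.log(phi[t])
        logprob += np.log(p) if h[t + 1] == 1 else np.log1p(-p)
    # chi: probability of never being recaptured after occasion `last`
    chi = 1.0
    for t in range(T - 2, last - 1, -1):
        chi = (1.0 - phi[t]) + phi[t] * (1.0 - p) * chi
    return float(np.exp(logprob) * chi)


def build_m_array(chm: CaptureHistoryMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a history matrix into m-array counts.

    Returns ``(m, never)`` where ``m[i, j]`` counts individuals released at
    occasion ``i`` (0-based, i < T-1) next recaptured at occasion ``j`` and
    ``never[i]`` those released at ``i`` and never seen again.  Every capture
    is a release (no losses on capture).
    """
    H = chm.histories
    T = chm.n_years
    m = np.zeros((max(T - 1, 0), T), dtype=np.int64)
    never = np.zeros(max(T - 1, 0), dtype=np.int64)
    for row in H:
        caps = np.flatnonzero(row)
        for a, b in zip(caps[:-1], caps[1:]):
            m[a, b] += 1
        last = caps[-1]
        if last < T - 1:
            never[last] += 1
    return m, never


def marray_loglik(
    m_arrays: np.ndarray, never: np.ndarray, phi: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Per-site m-array log-likelihoods, vectorized over sites.

    Parameters
    ----------
    m_arrays : (K, T-1, T) int array of recapture counts
    never : (K, T-1) int array of never-seen-again counts
    phi : (K, T-1) per-site, per-interval survival probabilities
    p : (K,) per-site recapture probabilities

    Returns the length-K vector of multinomial log-likelihoods (up to the
    combinatorial constant, which is parameter-free).
    """
    phi = np.asarray(phi, dtype=float)
    p = np.asarray(p, dtype=float)
    K, Tm1 = phi.shape
    T = Tm1 + 1
    # cumulative log-survival: cc[k, t] = sum_{u < t} log phi[k, u]
    cc = np.concatenate([np.zeros((K, 1)), np.cumsum(np.log(phi), axis=1)], axis=1)
    i_idx = np.arange(Tm1)[:, None]   # release occasion
    j_idx = np.arange(T)[None, :]     # recapture occasion
    valid = j_idx > i_idx             # (T-1, T)
    # log nu[k, i, j] = (cc[k, j] - cc[k, i]) + log p + (j-i-1) log(1-p)
    surv = cc[:, None, :] - cc[:, :Tm1, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log1mp = np.log1p(-p)
        gaps = (j_idx - i_idx - 1)[None, :, :]
        lognu = surv + np.log(p)[:, None, None] + np.where(
            gaps > 0, gaps * np.where(np.isfinite(log1mp), log1mp, -np.inf)[:, None, None], 0.0
        )
    lognu = np.where(valid[None, :, :], lognu, -np.inf)
    nu = np.where(valid[None, :, :], np.exp(lognu), 0.0)
    chi = np.clip(1.0 - nu.sum(axis=2), 0.0, 1.0)  # (K, T-1)

    ll = np.where(m_arrays > 0, m_arrays * np.where(np.isfinite(lognu), lognu, 0.0), 0.0).sum(
        axis=(1, 2)
    )
    # -inf where a positive count lands on a zero-probability cell
    impossible = ((m_arrays > 0) & ~np.isfinite(lognu)).any(axis=(1, 2))
    ll_chi = np.where(never > 0, never * np.log(np.maximum(chi, _TINY)), 0.0).sum(axis=1)
    out = ll + ll_chi
    out[impossible] = -np.inf
    return out


def histories_loglik(chm: CaptureHistoryMatrix, phi, p: float) -> float:
    """Sum of log history probabilities (slow reference form)."""
    total = 0.0
    for row, f in zip(chm.histories, chm.first_idx):
        total += np.log(cjs_history_probability(row, int(f), phi=phi, p=p))
    return float(total)
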