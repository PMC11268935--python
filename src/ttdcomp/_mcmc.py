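"""Adaptive random-walk Metropolis sampler.

All model parameters are mapped to an unconstrained space by the callers
(logit for probabilities, log for positive scales), so a Gaussian random-walk
proposal is appropriate.  During warmup the proposal covariance is re-estimated
from the chain history (Haario-style) and the global step size is tuned toward
a target acceptance rate; after warmup the proposal is frozen so the kept
draws are a valid Markov chain.  Chains are fully independent given the seed,
which is what split-R-hat diagnostics assume.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["run_chains"]

_TARGET_ACCEPT = 0.30
_COV_JITTER = 1e-8


def _run_single_chain(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    iterations: int,
    warmup: int,
    rng: np.random.Generator,
    target_accept: float,
) -> tuple[np.ndarray, float]:
    dim = x0.size
    x = np.array(x0, dtype=float)
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior density")

    chol = np.eye(dim) * (0.1 / np.sqrt(dim))
    log_scale = 0.0
    history = np.empty((warmup, dim))
    kept = np.empty((iterations - warmup, dim))
    # refresh the proposal covariance a few times during warmup, always from
    # the most recent half of the accumulated history
    refresh_at = {int(warmup * f) for f in (0.25, 0.5, 0.75)} if warmup >= 40 else set()
    n_accept_kept = 0

    for i in range(iterations):
        step = np.exp(log_scale) * (chol @ rng.standard_normal(dim))
        prop = x + step
        lp_prop = float(log_post(prop))
        log_ratio = lp_prop - lp
        accept_prob = 1.0 if log_ratio >= 0 else float(np.exp(log_ratio))
        if not np.isfinite(lp_prop):
            accept_prob = 0.0
        if rng.random() < accept_prob:
            x, lp = prop, lp_prop
            if i >= warmup:
                n_accept_kept += 1
        if i < warmup:
            history[i] = x
            log_scale += (accept_prob - target_accept) / (1.0 + i) ** 0.6
            if i in refresh_at:
                seg = history[i // 2 : i + 1]
                cov = np.atleast_2d(np.cov(seg.T))
                cov[np.diag_indices(dim)] += _COV_JITTER
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass  # keep the previous proposal shape
        else:
            kept[i - warmup] = x

    acc_rate = n_accept_kept / max(iterations - warmup, 1)
    return kept, acc_rate


def run_chains(
    log_post: Callable[[np.ndarray], float],
    x0s: np.ndarray,
    iterations: int,
    warmup: int,
    seed: int | np.random.SeedSequence,
    target_accept: float = _TARGET_ACCEPT,
) -> tuple[np.ndarray, np.ndarray]:
    """Run independent chains; return (draws, acceptance_rates).

    Parameters
    ----------
    log_post
        Log posterior density on the unconstrained space (may return -inf).
    x0s
        Initial points, one row per chain, shape (n_chains, dim).
    iterations, warmup
        Total iterations per chain and how many of them to discard/adapt on.
    seed
        Integer or SeedSequence; each chain gets an independent child stream.

    Returns
    -------
    draws : ndarray, shape (n_chains, iterations - warmup, dim)
    acceptance_rates : ndarray, shape (n_chains,)
    """
    x0s = np.atleast_2d(np.asarray(x0s, dtype=float))
    n_chains = x0s.shape[0]
    if n_chains < 1:
        raise ValueError("need at least one chain")
    if not 0 <= warmup < iterations:
        raise ValueError("require 0 <= warmup < iterations")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(int(seed))
    )
    draws = np.empty((n_chains, iterations - warmup, x0s.shape[1]))
    acc = np.empty(n_chains)
    for c, child in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(child)
        draws[c], acc[c] = _run_single_chain(
            log_post, x0s[c], iterations, warmup, rng, target_accept
        )
    return draws, acc
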