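"""Seeded random-walk Metropolis samplers with split-R-hat diagnostics.

Both model fits in this package have low-dimensional or per-report
factorizable posteriors, so plain adaptive random-walk Metropolis mixes
well: a joint sampler for small parameter blocks and an elementwise
sampler for vectors of conditionally independent latents.  Step sizes are
adapted only during warmup (Robbins-Monro on the log step), so the kept
draws form a valid Markov chain.  Everything is driven by an explicit
integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "rw_metropolis",
    "elementwise_rw_metropolis",
    "split_rhat",
    "ess_mean",
]

_ADAPT_KAPPA = 0.75  # Robbins-Monro decay exponent


def rw_metropolis(
    logpost,
    x0: np.ndarray,
    *,
    n_chains: int = 3,
    n_iter: int = 4000,
    seed: int = 0,
    target_accept: float = 0.30,
    init_step: float = 0.2,
) -> np.ndarray:
    """Adaptive random-walk Metropolis over a small parameter vector.

    Parameters
    ----------
    logpost
        Vectorized log posterior density mapping an array of shape
        ``(n_chains, dim)`` to ``(n_chains,)``.  May return ``-inf``
        outside the support.
    x0
        Initial point, shape ``(dim,)`` or ``(n_chains, dim)``.  When a
        single point is given, chains are jittered around it.

    Returns
    -------
    ndarray of shape ``(n_chains, n_kept, dim)`` where ``n_kept`` is
    ``n_iter - n_iter // 2`` (the first half is warmup and discarded).
    """
    rng = np.random.default_rng(seed)
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    dim = x0.shape[-1]
    if x0.shape[0] == 1:
        x = np.repeat(x0, n_chains, axis=0) + 0.1 * rng.standard_normal((n_chains, dim))
    else:
        x = x0.copy()
    lp = np.asarray(logpost(x), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log posterior not finite at the initial point")

    warmup = n_iter // 2
    kept = np.empty((n_chains, n_iter - warmup, dim))
    log_step = np.full(n_chains, np.log(init_step))
    scale = np.ones((n_chains, dim))
    hist = []  # warmup history for per-dimension scaling

    for i in range(n_iter):
        step = np.exp(log_step)[:, None]
        prop = x + step * scale * rng.standard_normal((n_chains, dim))
        lp_prop = np.asarray(logpost(prop), dtype=float)
        accept_p = np.exp(np.minimum(0.0, lp_prop - lp))
        acc = rng.random(n_chains) < accept_p
        x[acc] = prop[acc]
        lp[acc] = lp_prop[acc]
        if i < warmup:
            gamma = (i + 1) ** -_ADAPT_KAPPA
            log_step += gamma * (accept_p - target_accept)
            hist.append(x.copy())
            # refresh the per-dimension proposal scale twice during warmup
            if i in (warmup // 2, (3 * warmup) // 4):
                sd = np.std(np.asarray(hist), axis=0)
                scale = np.maximum(sd, 1e-3)
                hist.clear()
        else:
            kept[:, i - warmup] = x
    return kept


def elementwise_rw_metropolis(
    logpost_el,
    x0: np.ndarray,
    *,
    n_chains: int = 3,
    n_iter: int = 4000,
    seed: int = 0,
    target_accept: float = 0.44,
    init_step: float | np.ndarray = 0.3,
) -> np.ndarray:
    """Random-walk Metropolis for conditionally independent scalar latents.

    ``logpost_el`` maps ``(n_chains, n)`` to ``(n_chains, n)`` where entry
    ``[c, j]`` is the log density of latent ``j`` (the joint factorizes, so
    per-latent accept/reject is exact).  Step sizes adapt per latent.

    Returns draws of shape ``(n_chains, n_kept, n)``.
    """
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, dtype=float)
    n = x0.shape[-1]
    if x0.ndim == 1:
        x = np.tile(x0, (n_chains, 1)) + 0.1 * rng.standard_normal((n_chains, n))
    else:
        x = x0.copy()
    lp = np.asarray(logpost_el(x), dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log posterior not finite at the initial point")

    warmup = n_iter // 2
    kept = np.empty((n_chains, n_iter - warmup, n))
    log_step = np.broadcast_to(np.log(init_step), (n_chains, n)).copy()

    for i in range(n_iter):
        prop = x + np.exp(log_step) * rng.standard_normal((n_chains, n))
        lp_prop = np.asarray(logpost_el(prop), dtype=float)
        accept_p = np.exp(np.minimum(0.0, lp_prop - lp))
        acc = rng.random((n_chains, n)) < accept_p
        x = np.where(acc, prop, x)
        lp = np.where(acc, lp_prop, lp)
        if i < warmup:
            log_step += (i + 1) ** -_ADAPT_KAPPA * (accept_p - target_accept)
        else:
            kept[:, i - warmup] = x
    return kept


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R-hat convergence diagnostic.

    ``draws`` has shape ``(n_chains, n_draws, ...)``; each chain is split
    in half, doubling the chain count, and the classic Gelman-Rubin
    potential scale reduction factor is computed per trailing index.
    """
    draws = np.asarray(draws, dtype=float)
    c, d = draws.shape[:2]
    half = d // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    m, nd = split.shape[:2]
    mean_c = split.mean(axis=1)
    var_c = split.var(axis=1, ddof=1)
    w = var_c.mean(axis=0)
    b = nd * mean_c.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (nd - 1) / nd * w + b / nd
        rhat = np.sqrt(var_hat / w)
    # a chain stuck at a constant has w == 0; treat as converged if B is 0 too
    return np.where(w > 0, rhat, np.where(b > 0, np.inf, 1.0))


def ess_mean(draws: np.ndarray) -> np.ndarray:
    """Effective sample size for the posterior mean, via ArviZ.

    ``draws``: ``(n_chains, n_draws)`` or ``(n_chains, n_draws, n)``.
    """
    import arviz as az

    arr = np.asarray(draws, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if arr.ndim == 2:
            return np.asarray(az.ess(arr, method="mean"))
        ds = az.convert_to_dataset(arr)
        return np.asarray(az.ess(ds, method="mean")["x"])
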