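"""MCMC convergence diagnostics: split Gelman-Rubin R-hat and effective
sample size, vectorized over an arbitrary trailing parameter shape."""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "ess"]


def _split(chains: np.ndarray) -> np.ndarray:
    c, t = chains.shape[:2]
    half = t // 2
    return np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)


def gelman_rubin(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat of Gelman & Rubin for ``chains`` of shape
    (n_chains, n_iter, ...); returns an array of the trailing shape.

    Each chain is split in half so within-chain nonstationarity also inflates
    the statistic. Parameters with zero total variance (constants) get 1.0.
    """
    chains = np.asarray(chains)
    if chains.ndim < 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    sp = _split(chains)
    m, n = sp.shape[:2]
    if n < 2:
        raise ValueError("chains too short to split")
    means = sp.mean(axis=1, dtype=float)
    variances = sp.var(axis=1, ddof=1, dtype=float)
    w = variances.mean(axis=0)
    b_over_n = means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    # the estimator can dip below 1 by sampling noise; report the
    # conventional floor so "1.0" always reads "no evidence of non-convergence"
    return np.where(w > 0, np.maximum(rhat, 1.0), 1.0)


def _ess_block(flat: np.ndarray) -> np.ndarray:
    """ESS for split chains ``flat`` of shape (m, n, p)."""
    m, n, p = flat.shape
    centered = flat - flat.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n

    chain_var = acov[:, 0] * n / max(n - 1.0, 1.0)
    w = chain_var.mean(axis=0)
    mean_acov = acov.mean(axis=0)  # (n, p)
    b_over_n = flat.mean(axis=1).var(axis=0, ddof=1) if m > 1 else np.zeros(p)
    var_hat = (n - 1) / n * w + b_over_n

    safe = var_hat > 0
    vh = np.where(safe, var_hat, 1.0)
    rho = 1.0 - (w[None, :] - mean_acov) / vh[None, :]
    rho[0] = 1.0
    npairs = n // 2
    pairs = rho[0 : 2 * npairs : 2] + rho[1 : 2 * npairs : 2]  # (npairs, p)
    # Geyer: truncate at the first negative pair sum, enforce monotone decrease
    neg = pairs < 0
    first_neg = np.where(neg.any(axis=0), neg.argmax(axis=0), npairs)
    mono = np.minimum.accumulate(pairs, axis=0)
    mask = np.arange(npairs)[:, None] < first_neg[None, :]
    tau = 2.0 * (mono * mask).sum(axis=0) - 1.0
    tau = np.maximum(tau, 1e-12)
    out = m * n / tau
    return np.where(safe, np.minimum(out, m * n * 10.0), m * n)


def ess(chains: np.ndarray, block: int = 128) -> np.ndarray:
    """Effective sample size from chain autocorrelations.

    Uses FFT autocovariances averaged across split chains and Geyer's initial
    positive-pair truncation with a monotone-decrease correction. Shape
    semantics as in :func:`gelman_rubin`; single chains are allowed.
    Parameters are processed in blocks of ``block`` to bound FFT memory.
    """
    chains = np.asarray(chains)
    if chains.ndim < 2:
        raise ValueError("chains must be (n_chains, n_iter, ...)")
    sp = _split(chains) if chains.shape[1] >= 4 else chains
    m, n = sp.shape[:2]
    flat = sp.reshape(m, n, -1)
    p = flat.shape[2]
    out = np.empty(p)
    for start in range(0, p, block):
        stop = min(start + block, p)
        out[start:stop] = _ess_block(np.ascontiguousarray(flat[:, :, start:stop], dtype=float))
    return out.reshape(sp.shape[2:])
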