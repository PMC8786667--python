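"""Convergence diagnostics for multi-chain MCMC output."""

from __future__ import annotations

import numpy as np
import pandas as pd


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor (PSRF) for one parameter.

    Parameters
    ----------
    chains : (n_chains, n_iter) array
        Post-burn-in draws, equal length per chain.

    Returns
    -------
    float
        sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
        variance and B the between-chain variance of chain means.
        Constant chains (zero variance everywhere) return 1.0 by
        convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need >= 2 iterations per chain")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def gelman_rubin_all(draws: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """PSRF for every parameter in a (n_chains, n_iter, n_params) array."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    vals = [gelman_rubin(draws[:, :, j]) for j in range(draws.shape[2])]
    idx = names if names is not None else list(range(draws.shape[2]))
    return pd.Series(vals, index=idx, name="psrf")
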