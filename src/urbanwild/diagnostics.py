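"""Posterior-predictive checks and convergence diagnostics.

Model adequacy follows the squared-Pearson-residual discrepancy: the
statistic T is computed per posterior draw on the observed data and on data
simulated from that draw, and the Bayesian p-value p_B = Pr(T_sim > T_obs)
summarizes the comparison.  Fit is deemed adequate when 0.1 < p_B < 0.9.
Convergence is checked with the split-chain potential scale reduction
factor (R-hat), gated at 1.1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

ADEQUACY_WINDOW = (0.1, 0.9)
RHAT_GATE = 1.1


@dataclass
class PPCResult:
    """Posterior-predictive check output.

    ``p_b`` is the fraction of draws whose simulated-data statistic exceeds
    the observed-data statistic; ``adequate`` iff 0.1 < p_b < 0.9.
    """

    T_obs: np.ndarray
    T_sim: np.ndarray
    p_b: float
    adequate: bool


def pearson_T_counts(counts: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Sum of squared Pearson residuals for Poisson counts, per draw.

    T = sum_sites (y - mu)^2 / mu, using the Poisson variance = mean.
    ``mu`` has shape (n_draws, n_sites); a zero fitted mean with a positive
    count yields an infinite contribution and is flagged.
    """
    counts = np.asarray(counts, dtype=float)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    if np.any((mu == 0) & (counts[None, :] > 0)):
        logger.warning("zero fitted mean with positive count: infinite Pearson contribution")
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (counts[None, :] - mu) ** 2 / mu
        resid = np.where((mu == 0) & (counts[None, :] == 0), 0.0, resid)
    return resid.sum(axis=1)


def pearson_T_occupancy(
    Y: np.ndarray,
    effort: np.ndarray,
    mu: np.ndarray,
    tol: float = 1e-12,
) -> np.ndarray:
    """Sum of squared Pearson residuals for Bernoulli detection histories.

    ``mu`` is the per-draw probability of a detection in each site-occasion
    cell — either the marginal psi*p or the latent-conditional z*p,
    whichever conditioning the caller adopts — with shape
    (n_draws, n_sites, n_occasions).  Cells with degenerate variance
    (mu of exactly 0 or 1) are skipped with a log entry.

    T = sum over surveyed cells of (y - mu)^2 / (mu (1 - mu)).
    """
    Y = np.asarray(Y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mask = np.asarray(effort, dtype=bool)[None, :, :] & (mu > tol) & (mu < 1 - tol)
    n_skipped = int((~mask & np.asarray(effort, bool)[None, :, :]).sum())
    if n_skipped:
        logger.info("skipped %d degenerate Bernoulli cells (mu in {0,1})", n_skipped)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (Y[None, :, :] - mu) ** 2 / (mu * (1 - mu))
    return np.where(mask, resid, 0.0).sum(axis=(1, 2))


def bayes_p(T_obs: np.ndarray, T_sim: np.ndarray) -> PPCResult:
    """Bayesian p-value p_B = Pr(T_sim > T_obs) over matched draws."""
    T_obs = np.asarray(T_obs, dtype=float)
    T_sim = np.asarray(T_sim, dtype=float)
    if T_obs.shape != T_sim.shape:
        raise ValueError("T_obs and T_sim must have equal draw counts")
    if T_obs.size < 100:
        warnings.warn(f"only {T_obs.size} draws: p_B resolution is coarse", stacklevel=2)
    p = float(np.mean(T_sim > T_obs))
    lo, hi = ADEQUACY_WINDOW
    return PPCResult(T_obs=T_obs, T_sim=T_sim, p_b=p, adequate=bool(lo < p < hi))


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Each chain is split in half; R-hat is sqrt(((n-1)/n W + B/n) / W) over
    the split chains, the standard Gelman-Rubin construction.  Requires at
    least two chains of equal length.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    m, n = chains.shape
    if m < 2:
        raise ValueError("R-hat requires at least two chains")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    n = half
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))
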