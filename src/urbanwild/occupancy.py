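"""Multispecies occupancy model with multivariate-Bernoulli latent states.

The latent presence/absence vector of S species at a site is one draw from
a multivariate Bernoulli: one probability per joint state (for two species
the familiar psi11, psi10, psi01, psi00 cells).  Cells are built from
log-linear natural parameters — per-species first-order terms f_s on
logit-linear covariate scales and pairwise second-order terms f_st — via a
softmax over the 2^S states, which guarantees the cells are a probability
vector and reduces exactly to independent single-species occupancy when all
f_st = 0.  Conditional on presence, daily detection/non-detection is
Bernoulli with a species-specific, covariate-dependent detection
probability p; an optional site-level normal random intercept on the
detection logit (used for coyote in the motivating analysis) is
marginalized by Gauss-Hermite quadrature.

Posterior sampling uses an affine-invariant ensemble sampler (emcee); each
requested chain is an independently seeded ensemble, and convergence is
gated on split-chain R-hat <= 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import halfnorm, logistic

from .data import DetectionHistory
from .diagnostics import rhat

__all__ = [
    "OccupancyModelSpec",
    "PosteriorDraws",
    "joint_state_probs",
    "natural_to_cell",
    "site_likelihood",
    "build_design",
    "fit_mcmc",
    "marginal_occupancy",
    "significance_report",
]

DEFAULT_PRIOR_SCALE = np.sqrt(10.0)   # weakly-informative logistic prior
RESTRICTIVE_PRIOR_SCALE = 1.0         # logistic(0, 1) shrinkage prior
CORRELATION_THRESHOLD = 0.60


def _states(S: int) -> np.ndarray:
    """All 2^S presence/absence vectors, ordered with all-present first.

    For S = 2 the order is (1,1), (1,0), (0,1), (0,0) — the psi11, psi10,
    psi01, psi00 convention.
    """
    grid = np.indices((2,) * S).reshape(S, -1).T
    return 1 - grid


def joint_state_probs(f1: np.ndarray, f12: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cell probabilities of the multivariate Bernoulli from natural parameters.

    Parameters
    ----------
    f1
        First-order natural parameters, shape (n_sites, S).
    f12
        Symmetric pairwise second-order parameters, shape (S, S)
        (diagonal ignored).

    Returns
    -------
    probs : (n_sites, 2^S) probabilities summing to 1 per site
    states : (2^S, S) presence indicator per state
    """
    f1 = np.atleast_2d(np.asarray(f1, dtype=float))
    S = f1.shape[1]
    states = _states(S)
    energy = f1 @ states.T  # (N, 2^S)
    if S > 1:
        F = np.asarray(f12, dtype=float).copy()
        np.fill_diagonal(F, 0.0)
        # 0.5 z'Fz with zero diagonal counts each unordered pair once
        energy = energy + 0.5 * np.einsum("ms,st,mt->m", states, F, states)
    log_probs = energy - logsumexp(energy, axis=1, keepdims=True)
    return np.exp(log_probs), states


def natural_to_cell(f1, f2, f12) -> np.ndarray:
    """Two-species cells (psi11, psi10, psi01, psi00) from natural parameters.

    Softmax over the four joint states with energies
    {f1 + f2 + f12, f1, f2, 0}; computed on the log scale so large inputs
    never overflow.  Accepts scalars or per-site arrays.
    """
    f1, f2, f12 = np.broadcast_arrays(
        np.asarray(f1, float), np.asarray(f2, float), np.asarray(f12, float)
    )
    F = np.zeros((2, 2))
    out = np.empty(f1.shape + (4,))
    it = np.nditer(f1, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        F[0, 1] = F[1, 0] = f12[idx]
        probs, _ = joint_state_probs(np.array([[f1[idx], f2[idx]]]), F)
        out[idx] = probs[0]
    return out


def site_likelihood(
    y: np.ndarray,
    cell_probs: np.ndarray,
    p: np.ndarray,
    effort: np.ndarray | None = None,
) -> float:
    """Marginal likelihood of one site's detection histories.

    Sums over the 2^S joint latent states: each state contributes its cell
    probability times, per species, the Bernoulli likelihood of the history
    given presence, or an indicator that the history is all-zero given
    absence.

    Parameters
    ----------
    y
        Detection histories, shape (S, K) in {0, 1}.
    cell_probs
        Joint state probabilities, length 2^S, ordered as :func:`_states`.
    p
        Detection probabilities: shape (S,) for occasion-constant or (S, K)
        per occasion; all entries in (0, 1).
    effort
        Optional (K,) or (S, K) mask of surveyed occasions (default all).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    S, K = y.shape
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = np.repeat(p[:, None], K, axis=1)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("detection probabilities must lie strictly in (0, 1)")
    eff = np.ones((S, K)) if effort is None else np.broadcast_to(np.asarray(effort, float), (S, K))
    states = _states(S)
    cell_probs = np.asarray(cell_probs, dtype=float)
    if cell_probs.shape != (2**S,):
        raise ValueError(f"expected {2**S} cell probabilities, got shape {cell_probs.shape}")

    log_present = np.sum(eff * (y * np.log(p) + (1 - y) * np.log1p(-p)), axis=1)  # (S,)
    all_zero = np.all(y * eff == 0, axis=1)
    log_absent = np.where(all_zero, 0.0, -np.inf)

    with np.errstate(divide="ignore"):
        state_loglik = states @ log_present + (1 - states) @ np.where(
            np.isneginf(log_absent), -1e300, log_absent
        )
        state_loglik[np.any((1 - states) * np.isneginf(log_absent)[None, :], axis=1)] = -np.inf
        total = logsumexp(state_loglik, b=cell_probs)
    return float(np.exp(total))


@dataclass
class PosteriorDraws:
    """MCMC output: named coefficient draws per chain plus diagnostics."""

    names: list[str]
    chains: np.ndarray  # (n_chains, n_draws, n_params)

    def __post_init__(self) -> None:
        self.chains = np.asarray(self.chains, dtype=float)
        if self.chains.ndim != 3 or self.chains.shape[2] != len(self.names):
            raise ValueError("chains must have shape (n_chains, n_draws, n_params)")
        if not np.all(np.isfinite(self.chains)):
            raise ValueError("non-finite posterior draws")

    @property
    def draws(self) -> np.ndarray:
        """All chains pooled, shape (n_chains * n_draws, n_params)."""
        return self.chains.reshape(-1, self.chains.shape[2])

    def param(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def rhat(self) -> pd.Series:
        vals = [rhat(self.chains[:, :, j]) for j in range(len(self.names))]
        return pd.Series(vals, index=self.names, name="rhat")

    def to_frame(self) -> pd.DataFrame:
        """Tidy draws table (chain, draw, parameter columns)."""
        C, n, P = self.chains.shape
        df = pd.DataFrame(self.draws, columns=self.names)
        df.insert(0, "draw", np.tile(np.arange(n), C))
        df.insert(0, "chain", np.repeat(np.arange(C), n))
        return df


@dataclass
class OccupancyModelSpec:
    """Configuration for a multispecies occupancy fit.

    Occupancy and detection covariates are named columns of the site table;
    both design matrices get an intercept and are mean-centered.  Columns
    caught by the pairwise-correlation rule (|r| > 0.60) receive the
    restrictive logistic(0, 1) prior; all others the weak default.
    Pairwise interaction terms are fixed at 0 (species independence) unless
    ``estimate_interactions`` is set, in which case one f12 scalar per
    species pair is sampled.
    """

    species: list[str]
    occ_covariates: list[str] = field(default_factory=list)
    det_covariates: list[str] = field(default_factory=list)
    estimate_interactions: bool = False
    random_effect_species: list[str] = field(default_factory=list)
    prior_scale: float = DEFAULT_PRIOR_SCALE
    restrictive_scale: float = RESTRICTIVE_PRIOR_SCALE
    correlation_threshold: float = CORRELATION_THRESHOLD
    gh_nodes: int = 20

    def n_params(self) -> int:
        S = len(self.species)
        n = S * (1 + len(self.occ_covariates)) + S * (1 + len(self.det_covariates))
        if self.estimate_interactions:
            n += S * (S - 1) // 2
        n += len(self.random_effect_species)
        return n


def build_design(
    sites: pd.DataFrame,
    covariates: list[str],
    correlation_threshold: float = CORRELATION_THRESHOLD,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Intercept + mean-centered covariate design matrix with prior flags.

    Returns (X, column names, restrictive mask).  The restrictive mask marks
    covariate columns involved in any pairwise Pearson correlation above the
    threshold; duplicated columns raise (unidentifiable design).
    """
    cols = [np.ones(len(sites))]
    for name in covariates:
        x = sites[name].to_numpy(dtype=float)
        cols.append(x - x.mean())
    X = np.column_stack(cols)
    names = ["intercept"] + list(covariates)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design is rank-deficient; check covariates {covariates}")
    assert np.all(np.abs(X[:, 1:].mean(axis=0)) < 1e-10) if len(covariates) else True
    restrictive = np.zeros(X.shape[1], dtype=bool)
    if len(covariates) >= 2:
        corr = np.corrcoef(X[:, 1:].T)
        flagged = np.any(np.abs(corr - np.eye(len(covariates))) > correlation_threshold, axis=1)
        restrictive[1:] = flagged
    return X, names, restrictive


class _OccupancyPosterior:
    """Log-posterior of the MVB occupancy model on sufficient statistics.

    Detection probability is occasion-constant per site, so each site and
    species contributes (detections d, effort nights k); the likelihood is
    a logsumexp over joint states of log cell probability plus per-species
    detection terms, with an optional Gauss-Hermite marginalized random
    detection intercept.
    """

    def __init__(self, spec: OccupancyModelSpec, history: DetectionHistory, sites: pd.DataFrame):
        order = [history.species.index(sp) for sp in spec.species]
        self.spec = spec
        self.d = history.Y[order].sum(axis=2).astype(float)          # (S, N)
        self.k = history.effort.sum(axis=1).astype(float)            # (N,)
        self.X_occ, self.occ_names, occ_restr = build_design(
            sites, spec.occ_covariates, spec.correlation_threshold
        )
        self.X_det, self.det_names, det_restr = build_design(
            sites, spec.det_covariates, spec.correlation_threshold
        )
        self.S, self.N = self.d.shape
        self.states = _states(self.S)
        self.n_occ, self.n_det = self.X_occ.shape[1], self.X_det.shape[1]
        self.pair_index = [
            (i, j) for i in range(self.S) for j in range(i + 1, self.S)
        ] if spec.estimate_interactions else []
        self.re_index = [spec.species.index(sp) for sp in spec.random_effect_species]
        nodes, weights = np.polynomial.hermite.hermgauss(spec.gh_nodes)
        self.gh_nodes_std = nodes * np.sqrt(2.0)
        self.gh_logw = np.log(weights / np.sqrt(np.pi))

        self.names: list[str] = []
        scales = []
        for sp in spec.species:
            self.names += [f"occ[{sp}]:{c}" for c in self.occ_names]
            scales += list(np.where(occ_restr, spec.restrictive_scale, spec.prior_scale))
        for sp in spec.species:
            self.names += [f"det[{sp}]:{c}" for c in self.det_names]
            scales += list(np.where(det_restr, spec.restrictive_scale, spec.prior_scale))
        for i, j in self.pair_index:
            self.names.append(f"f12[{spec.species[i]},{spec.species[j]}]")
            scales.append(spec.prior_scale)
        for sp in spec.random_effect_species:
            self.names.append(f"log_sd_det[{sp}]")
            scales.append(np.nan)  # half-normal prior handled separately
        self.prior_scales = np.asarray(scales)
        self.ndim = len(self.names)

    def unpack(self, theta: np.ndarray):
        S, no, nd = self.S, self.n_occ, self.n_det
        B = theta[: S * no].reshape(S, no)
        A = theta[S * no : S * (no + nd)].reshape(S, nd)
        pos = S * (no + nd)
        f12 = np.zeros((S, S))
        for (i, j) in self.pair_index:
            f12[i, j] = f12[j, i] = theta[pos]
            pos += 1
        log_sds = theta[pos:]
        return B, A, f12, log_sds

    def log_prob(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        B, A, f12, log_sds = self.unpack(theta)
        if np.any(np.abs(log_sds) > 10):
            return -np.inf

        n_fixed = self.ndim - len(log_sds)
        lp = float(np.sum(logistic.logpdf(theta[:n_fixed], scale=self.prior_scales[:n_fixed])))
        for ls in log_sds:
            lp += halfnorm.logpdf(np.exp(ls), scale=1.0) + ls  # Jacobian of log transform

        f1 = self.X_occ @ B.T                                  # (N, S)
        log_cell = f1 @ self.states.T
        if self.S > 1:
            log_cell = log_cell + 0.5 * np.einsum("ms,st,mt->m", self.states, f12, self.states)
        log_cell = log_cell - logsumexp(log_cell, axis=1, keepdims=True)   # (N, 2^S)

        eta = self.X_det @ A.T                                 # (N, S)
        logp = -np.logaddexp(0.0, -eta)
        log1mp = -np.logaddexp(0.0, eta)
        log_present = self.d.T * logp + (self.k[:, None] - self.d.T) * log1mp  # (N, S)
        for s, ls in zip(self.re_index, log_sds):
            sd = np.exp(ls)
            eta_u = eta[:, s, None] + sd * self.gh_nodes_std[None, :]          # (N, Q)
            lp_u = -np.logaddexp(0.0, -eta_u)
            l1p_u = -np.logaddexp(0.0, eta_u)
            contrib = self.d.T[:, s, None] * lp_u + (self.k[:, None] - self.d.T[:, s, None]) * l1p_u
            log_present[:, s] = logsumexp(contrib + self.gh_logw[None, :], axis=1)

        with np.errstate(divide="ignore"):
            log_absent = np.where(self.d.T == 0, 0.0, -np.inf)                 # (N, S)
        state_ll = log_cell + log_present @ self.states.T
        absent_bad = (self.d.T > 0) @ (1 - self.states).T > 0                  # (N, 2^S)
        state_ll = np.where(absent_bad, -np.inf, state_ll)
        ll = float(np.sum(logsumexp(state_ll, axis=1)))
        out = lp + ll
        if np.isnan(out):
            raise FloatingPointError(
                f"NaN posterior density at parameters {dict(zip(self.names, theta))}"
            )
        return out


def _run_ensembles(
    log_prob, ndim: int, names: list[str], chains: int, warmup: int, iters: int,
    seed: int, nwalkers: int | None = None, init_scale: float = 0.1,
    thin_to: int = 1000, init_center: np.ndarray | None = None,
) -> PosteriorDraws:
    """Run independently seeded emcee ensembles and pool each into a chain."""
    import emcee

    nwalkers = nwalkers or max(2 * ndim + 2, 12)
    center = np.zeros(ndim) if init_center is None else np.asarray(init_center, float)
    all_chains = []
    for c in range(chains):
        rng = np.random.default_rng((seed + 1000003 * c) % 2**31)
        p0 = center[None, :] + init_scale * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState((seed + 1000003 * c) % 2**31).get_state()
        state = sampler.run_mcmc(p0, warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, iters, progress=False)
        flat = sampler.get_chain(flat=True)
        if not np.all(np.isfinite(sampler.get_log_prob(flat=True))):
            bad = names[int(np.argmax(~np.isfinite(flat).all(axis=0)))]
            raise RuntimeError(f"sampler diverged; non-finite density near parameter {bad!r}")
        step = max(len(flat) // thin_to, 1)
        all_chains.append(flat[::step][:thin_to])
    n = min(len(ch) for ch in all_chains)
    return PosteriorDraws(names=list(names), chains=np.stack([ch[:n] for ch in all_chains]))


def fit_mcmc(
    spec: OccupancyModelSpec,
    history: DetectionHistory,
    sites: pd.DataFrame,
    chains: int = 2,
    warmup: int = 400,
    iters: int = 400,
    seed: int = 0,
    nwalkers: int | None = None,
) -> PosteriorDraws:
    """Sample the occupancy posterior.

    Two independently seeded ensembles by default; attach
    ``PosteriorDraws.rhat()`` to check the R-hat <= 1.1 convergence gate.
    """
    post = _OccupancyPosterior(spec, history, sites)
    return _run_ensembles(post.log_prob, post.ndim, post.names, chains, warmup, iters, seed, nwalkers)


def _psi_draws(
    spec: OccupancyModelSpec, draws: PosteriorDraws, post: _OccupancyPosterior, X: np.ndarray
) -> np.ndarray:
    """Marginal occupancy per draw/site/species, shape (n_draws, N, S)."""
    theta = draws.draws
    n_draws = theta.shape[0]
    out = np.empty((n_draws, X.shape[0], post.S))
    for t in range(n_draws):
        B, _, f12, _ = post.unpack(theta[t])
        probs, states = joint_state_probs(X @ B.T, f12)
        for s in range(post.S):
            out[t, :, s] = probs[:, states[:, s] == 1].sum(axis=1)
    return out


def marginal_occupancy(
    spec: OccupancyModelSpec,
    draws: PosteriorDraws,
    history: DetectionHistory,
    sites: pd.DataFrame,
    strata: list[str] = ("development_level", "plot_type"),
) -> pd.DataFrame:
    """Posterior marginal occupancy by stratum.

    For every sampled stratum (unsampled combinations are absent from the
    output, never extrapolated) the per-draw occupancy is averaged over the
    stratum's sites; returns mean and central 95% credible bounds per
    species.  For interacting pairs the marginal is the sum of all joint
    states in which the species is present (psi11 + psi10 for species 1).
    """
    post = _OccupancyPosterior(spec, history, sites)
    psi = _psi_draws(spec, draws, post, post.X_occ)  # (n_draws, N, S)
    strata = list(strata)
    rows = []
    for key, grp in sites.groupby(strata, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        idx = grp.index.to_numpy()
        stratum_draws = psi[:, idx, :].mean(axis=1)  # (n_draws, S)
        for s, sp in enumerate(spec.species):
            lo, hi = np.percentile(stratum_draws[:, s], [2.5, 97.5])
            rows.append(
                dict(zip(strata, key))
                | {
                    "species": sp,
                    "psi_mean": float(stratum_draws[:, s].mean()),
                    "psi_lo": float(lo),
                    "psi_hi": float(hi),
                }
            )
    return pd.DataFrame(rows)


def significance_report(draws: PosteriorDraws, rhat_gate: float = 1.1) -> pd.DataFrame:
    """Coefficient table with central 95% credible intervals.

    A predictor is significant when its interval excludes zero; parameters
    failing the R-hat convergence gate are flagged and never reported
    significant.
    """
    theta = draws.draws
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    rh = draws.rhat().to_numpy()
    converged = rh <= rhat_gate
    return pd.DataFrame(
        {
            "parameter": draws.names,
            "mean": theta.mean(axis=0),
            "cri_lo": lo,
            "cri_hi": hi,
            "rhat": rh,
            "converged": converged,
            "significant": converged & ((lo > 0) | (hi < 0)),
        }
    )
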