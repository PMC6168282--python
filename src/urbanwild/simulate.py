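"""Synthetic camera-trap surveys with known ground truth.

The generator produces exactly the statistical structure the downstream
models assume: sites stratified into five development levels and four plot
types (yards unavailable in the urban and wild strata), species-specific
occupancy and detection probabilities on logit-linear covariate scales,
latent presence drawn from a multivariate-Bernoulli joint state (log-linear
natural parameters; zero interaction reproduces independence), daily
Bernoulli detection histories over ~21-day deployments, and Poisson photo
streams whose burst structure round-trips exactly through the 60-s sequence
collapsing rule.

Every draw flows from a single seed; a fixed seed gives byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DEVELOPMENT_LEVELS, PLOT_TYPES, DetectionHistory
from .occupancy import joint_state_probs

#: housing-density sampling ranges per development level (houses/km^2)
DENSITY_RANGES = {
    "urban": (1000.5, 4000.0),
    "suburban": (147.048, 1000.0),
    "exurban": (12.64, 147.047),
    "rural": (0.51, 12.63),
    "wild": (0.0, 0.49),
}

#: plot types available within each development level (no residential yards
#: in the urban or wild strata)
PLOT_AVAILABILITY = {
    "urban": ["large_forest", "small_forest", "open"],
    "suburban": PLOT_TYPES,
    "exurban": PLOT_TYPES,
    "rural": PLOT_TYPES,
    "wild": ["large_forest", "small_forest", "open"],
}

#: continuous covariates drawn as standard normals
CONTINUOUS_COVARIATES = [
    "core_forest_5km",
    "forest_100m",
    "deer_rate",
    "rodent_rate",
    "detection_distance",
    "temperature",
    "ndvi",
]
INDICATOR_COVARIATES = {"hunting": 0.4, "camera_reconyx": 0.5}


@dataclass
class SpeciesParams:
    """Logit-linear coefficients for one species.

    ``occ_coefs`` / ``det_coefs`` map covariate names to slopes;
    intercepts are on the logit scale.  ``event_rate`` is the expected
    number of independent detection events per camera-night for the photo
    stream generator.  ``detection_random_sd`` adds a site-level normal
    intercept to the detection logit (the structure the coyote random
    effect models).
    """

    name: str
    occ_intercept: float = 0.0
    occ_coefs: dict[str, float] = field(default_factory=dict)
    det_intercept: float = -1.0
    det_coefs: dict[str, float] = field(default_factory=dict)
    event_rate: float = 0.1
    detection_random_sd: float = 0.0


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic survey.

    ``n_sites_per_cell`` gives the number of camera sites in each available
    (development level x plot type) cell; 21-day deployments mirror the
    three-week protocol of the field design.  ``interactions`` holds
    pairwise log-linear natural parameters f12 by species-name pair; all
    absent pairs are 0 (independence).  ``correlated_pair`` optionally makes
    two continuous covariates correlated at ``rho`` to exercise the
    restrictive-prior rule downstream.
    """

    species: list[SpeciesParams]
    n_sites_per_cell: int = 8
    n_days: int = 21
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    correlated_pair: tuple[str, str, float] | None = None
    photos_per_event_mean: float = 4.0
    max_intra_burst_gap: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites_per_cell < 1 or self.n_days < 1:
            raise ValueError("empty stratum plan: n_sites_per_cell and n_days must be >= 1")
        if not self.species:
            raise ValueError("at least one species required")
        if not (0 < self.photos_per_event_mean) or not (1 <= self.max_intra_burst_gap < 60):
            raise ValueError("burst parameters out of range")


def simulate_sites(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a stratified site table.

    Housing densities fall inside each level's bin; plot types follow
    stratum availability; continuous covariates are standard normals and
    indicators Bernoulli.  Covariates are *not* mean-centered here — that is
    a modelling step.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    k = 0
    for level in DEVELOPMENT_LEVELS:
        lo, hi = DENSITY_RANGES[level]
        for plot in PLOT_AVAILABILITY[level]:
            for _ in range(config.n_sites_per_cell):
                density = rng.uniform(lo, hi)
                start = pd.Timestamp("2014-01-01") + pd.Timedelta(days=int(rng.integers(0, 365)))
                rows.append(
                    {
                        "site_id": f"site{k:04d}",
                        "city": "DC" if rng.random() < 0.5 else "Raleigh",
                        "housing_density": density,
                        "development_level": level,
                        "plot_type": plot,
                        "deploy_start": start,
                        "deploy_end": start + pd.Timedelta(days=config.n_days - 1),
                    }
                )
                k += 1
    sites = pd.DataFrame(rows)
    n = len(sites)
    X = rng.standard_normal((n, len(CONTINUOUS_COVARIATES)))
    cov = pd.DataFrame(X, columns=CONTINUOUS_COVARIATES)
    if config.correlated_pair is not None:
        a, b, rho = config.correlated_pair
        cov[b] = rho * cov[a] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    for name, p in INDICATOR_COVARIATES.items():
        cov[name] = (rng.random(n) < p).astype(int)
    cov["yard"] = (sites["plot_type"] == "yard").astype(int)
    cov["year"] = rng.integers(2012, 2017, n)
    return pd.concat([sites, cov], axis=1)


def _linear(intercept: float, coefs: dict[str, float], sites: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(sites), float(intercept))
    for name, beta in coefs.items():
        eta = eta + beta * sites[name].to_numpy(dtype=float)
    return eta


def simulate_occupancy_survey(
    config: ScenarioConfig,
    sites: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DetectionHistory, dict]:
    """Forward-simulate the multispecies occupancy model.

    Latent presence Z is drawn per site from the joint state distribution
    implied by the log-linear natural parameters (independent Bernoullis
    when all pairwise interactions are zero); daily detections are
    Bernoulli(p_i) where z = 1 and structurally zero where z = 0.

    Returns the detection history and a ground-truth dict with keys
    ``Z`` (species x site), ``psi_marginal``, ``p`` and ``state_probs``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if sites is None:
        sites = simulate_sites(config, rng)
    S, N, D = len(config.species), len(sites), config.n_days
    names = [sp.name for sp in config.species]

    f1 = np.stack([_linear(sp.occ_intercept, sp.occ_coefs, sites) for sp in config.species])
    f12 = np.zeros((S, S))
    for (a, b), v in config.interactions.items():
        i, j = names.index(a), names.index(b)
        f12[i, j] = f12[j, i] = v
    probs, states = joint_state_probs(f1.T, f12)  # (N, 2^S), (2^S, S)

    cum = np.cumsum(probs, axis=1)
    u = rng.random(N)
    state_idx = (u[:, None] > cum).sum(axis=1)
    Z = states[state_idx].T.astype(np.uint8)  # (S, N)

    p = np.stack(
        [1 / (1 + np.exp(-_linear(sp.det_intercept, sp.det_coefs, sites))) for sp in config.species]
    )
    for s, sp in enumerate(config.species):
        if sp.detection_random_sd > 0:
            u_site = rng.normal(0, sp.detection_random_sd, N)
            p[s] = 1 / (1 + np.exp(-(np.log(p[s] / (1 - p[s])) + u_site)))

    effort = np.ones((N, D), dtype=bool)
    Y = (rng.random((S, N, D)) < (Z[:, :, None] * p[:, :, None])).astype(np.uint8)
    Y &= effort[None, :, :]
    history = DetectionHistory(species=names, sites=sites["site_id"].tolist(), Y=Y, effort=effort)
    truth = {
        "Z": Z,
        "psi_marginal": np.stack([probs[:, states[:, s] == 1].sum(axis=1) for s in range(S)]),
        "p": p,
        "state_probs": probs,
        "states": states,
    }
    return history, truth


def simulate_count_survey(
    config: ScenarioConfig,
    sites: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a timestamped photo stream from Poisson detection events.

    Events per site and species are Poisson(event_rate x nights).  Each
    event expands into a photo burst with intra-burst gaps strictly under
    60 s and inter-event gaps strictly over 60 s, so the sequence-collapsing
    rule recovers the event count exactly.

    Returns (photo records, latent event counts per site x species).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if sites is None:
        sites = simulate_sites(config, rng)
    nights = config.n_days
    horizon = nights * 86400
    rows, truth_rows = [], []
    for site in sites.itertuples(index=False):
        t0 = site.deploy_start
        for sp in config.species:
            if sp.event_rate < 0:
                raise ValueError("event intensities must be >= 0")
            n_events = int(rng.poisson(sp.event_rate * nights))
            placed = 0
            if n_events > 0:
                starts = np.sort(rng.uniform(0, horizon, n_events))
                t_min = 0.0
                for s in starts:
                    s = max(s, t_min)
                    n_photos = 1 + int(rng.poisson(config.photos_per_event_mean - 1))
                    gaps = rng.integers(1, config.max_intra_burst_gap + 1, max(n_photos - 1, 0))
                    times = s + np.concatenate([[0.0], np.cumsum(gaps)])
                    if times[-1] >= horizon:
                        break  # deployment full; truth reflects placed events only
                    group = 1 + int(rng.poisson(0.3))
                    counts = np.minimum(1 + rng.integers(0, group, n_photos), group)
                    counts[0] = group
                    for t, c in zip(times, counts):
                        rows.append(
                            {
                                "site_id": site.site_id,
                                "timestamp": t0 + pd.Timedelta(seconds=float(t)),
                                "species": sp.name,
                                "animal_count": int(c),
                            }
                        )
                    placed += 1
                    t_min = times[-1] + 61.0
            truth_rows.append({"site_id": site.site_id, "species": sp.name, "n_events": placed})
    records = pd.DataFrame(rows, columns=["site_id", "timestamp", "species", "animal_count"])
    return records, pd.DataFrame(truth_rows)
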