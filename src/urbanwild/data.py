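"""Detection records, independent sequences, and daily detection histories.

Raw camera-trap data arrive as one row per photo (site, timestamp, species,
count of animals in frame).  Consecutive photos of the same species at the
same site are grouped into one *independent sequence* whenever the gap
between them is under 60 s; sequences are the unit of "detection" for
detection-rate indices, and are further collapsed to daily
detection/non-detection for occupancy modelling.

All deterministic reductions live here: sequence collapsing, the
housing-density development-level classification, detection-history
construction, per-site detection rates, naive occupancy, and the
effort-weighted per-gradient-level detection profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEVELOPMENT_LEVELS = ["urban", "suburban", "exurban", "rural", "wild"]
PLOT_TYPES = ["large_forest", "small_forest", "open", "yard"]

#: housing-density bin edges (houses/km^2), half-open convention closing the
#: gaps between the published bins: wild [0, 0.5), rural [0.5, 12.64),
#: exurban [12.64, 147.048), suburban [147.048, 1000], urban (1000, inf).
_DENSITY_EDGES = (0.5, 12.64, 147.048, 1000.0)

DETECTIONS_COLUMNS = ["site_id", "timestamp", "species", "animal_count"]
SITES_REQUIRED_COLUMNS = [
    "site_id",
    "city",
    "housing_density",
    "development_level",
    "plot_type",
    "deploy_start",
    "deploy_end",
]


def classify_development(housing_density: float) -> str:
    """Map housing density (houses/km^2) to a development level.

    Bins follow the Silvis housing-density stratification; printed bins do
    not tile the real line, so the gaps are closed half-open (documented in
    the methods note).
    """
    d = float(housing_density)
    if not np.isfinite(d) or d < 0:
        raise ValueError(f"housing density must be finite and >= 0, got {housing_density}")
    if d < _DENSITY_EDGES[0]:
        return "wild"
    if d < _DENSITY_EDGES[1]:
        return "rural"
    if d < _DENSITY_EDGES[2]:
        return "exurban"
    if d <= _DENSITY_EDGES[3]:
        return "suburban"
    return "urban"


@dataclass
class DetectionHistory:
    """Species x site x day binary detection array with an effort mask.

    ``Y[s, i, d]`` is 1 iff at least one independent sequence of species ``s``
    was recorded at site ``i`` on day ``d`` of that site's deployment.
    ``effort[i, d]`` is 1 while the camera was operating; Y is structurally
    zero wherever effort is zero.
    """

    species: list[str]
    sites: list
    Y: np.ndarray          # (S, N, D) uint8
    effort: np.ndarray     # (N, D) bool

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.uint8)
        self.effort = np.asarray(self.effort, dtype=bool)
        S, N, D = self.Y.shape
        if (len(self.species), len(self.sites)) != (S, N) or self.effort.shape != (N, D):
            raise ValueError("inconsistent DetectionHistory shapes")
        if np.any(self.Y & ~self.effort[None, :, :]):
            raise ValueError("detections present outside the effort mask")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_days(self) -> int:
        return self.Y.shape[2]

    def camera_nights(self) -> np.ndarray:
        """Nights of effort per site."""
        return self.effort.sum(axis=1)

    def detections(self, species: str) -> np.ndarray:
        """Site x day slice for one species."""
        return self.Y[self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (species, site_id, day, detected, effort) table."""
        S, N, D = self.Y.shape
        sp, si, dy = np.meshgrid(range(S), range(N), range(D), indexing="ij")
        return pd.DataFrame(
            {
                "species": np.asarray(self.species)[sp.ravel()],
                "site_id": np.asarray(self.sites, dtype=object)[si.ravel()],
                "day": dy.ravel(),
                "detected": self.Y.ravel(),
                "effort": self.effort[si.ravel(), dy.ravel()].astype(int),
            }
        )


def load_detections(path_or_df) -> pd.DataFrame:
    """Load and validate a detections table (CSV path or DataFrame).

    Required columns: site_id, timestamp (ISO-8601), species, animal_count.
    Rows with unparseable timestamps are dropped with a logged warning;
    animal_count must be >= 1.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in DETECTIONS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detections table missing columns: {missing}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    if bad.any():
        logger.warning("dropping %d detection rows with unparseable timestamps", int(bad.sum()))
        df, ts = df.loc[~bad], ts.loc[~bad]
    df = df.assign(timestamp=ts)
    if (df["animal_count"] < 1).any():
        raise ValueError("animal_count must be >= 1 for every record")
    return df.reset_index(drop=True)


def load_sites(path_or_df) -> pd.DataFrame:
    """Load and validate a site table.

    Required columns include deployment dates, city, housing density and the
    stratum labels; any extra numeric columns are treated as covariates.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in SITES_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing columns: {missing}")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicated site_id values: {dupes}")
    for col in ("deploy_start", "deploy_end"):
        df[col] = pd.to_datetime(df[col], errors="raise")
    if (df["deploy_end"] < df["deploy_start"]).any():
        raise ValueError("deploy_end earlier than deploy_start for some sites")
    return df.reset_index(drop=True)


def collapse_sequences(
    records: pd.DataFrame,
    gap_seconds: int = 60,
    presorted: bool = False,
) -> pd.DataFrame:
    """Group photos into independent sequences.

    Consecutive records of the same species at the same site whose
    inter-record gap is strictly less than ``gap_seconds`` (default 60 s)
    are merged into one sequence.  The sequence keeps the first photo's
    timestamp and the maximum simultaneous animal count.

    Idempotent: applying it to its own output changes nothing, because
    surviving gaps are all >= ``gap_seconds``.

    Parameters
    ----------
    records
        Detections table (photo level).  Sorted internally unless
        ``presorted`` is set, in which case out-of-order timestamps within a
        site/species group raise an error naming the site.
    """
    if gap_seconds <= 0:
        raise ValueError("gap_seconds must be positive")
    df = load_detections(records)
    if df.empty:
        return df
    if presorted:
        gaps = df.groupby(["site_id", "species"], sort=False)["timestamp"].diff()
        neg = gaps.dt.total_seconds() < 0
        if neg.any():
            site = df.loc[neg.idxmax(), "site_id"]
            raise ValueError(f"timestamps out of order (negative gap) at site {site!r}")
    else:
        df = df.sort_values(["site_id", "species", "timestamp"], kind="stable").reset_index(drop=True)

    gap = df.groupby(["site_id", "species"], sort=False)["timestamp"].diff().dt.total_seconds()
    # a new sequence starts at each group head or whenever the gap is not < gap_seconds
    new_seq = gap.isna() | (gap >= gap_seconds)
    seq_id = new_seq.cumsum()
    out = (
        df.groupby(seq_id)
        .agg(
            site_id=("site_id", "first"),
            timestamp=("timestamp", "first"),
            species=("species", "first"),
            animal_count=("animal_count", "max"),
        )
        .reset_index(drop=True)
    )
    return out


def _deployment_grid(sites: pd.DataFrame) -> tuple[list, np.ndarray, pd.Series]:
    """Effort mask (site x day) from deployment windows; day 0 = deploy_start date."""
    site_ids = sites["site_id"].tolist()
    start = sites["deploy_start"].dt.normalize()
    nights = (sites["deploy_end"].dt.normalize() - start).dt.days.to_numpy() + 1
    D = int(nights.max())
    effort = np.arange(D)[None, :] < nights[:, None]
    return site_ids, effort, start


def build_detection_history(
    sequences: pd.DataFrame,
    sites: pd.DataFrame,
    species: list[str] | None = None,
) -> DetectionHistory:
    """Collapse independent sequences into daily detection/non-detection.

    Day boundaries are local midnight; day ``d`` for a site is the ``d``-th
    calendar day of its deployment.  Records outside a site's deployment
    window are dropped with a logged warning.
    """
    sites = load_sites(sites)
    seqs = load_detections(sequences)
    site_ids, effort, start = _deployment_grid(sites)
    if species is None:
        species = sorted(seqs["species"].unique())
    site_index = {s: i for i, s in enumerate(site_ids)}
    sp_index = {s: j for j, s in enumerate(species)}
    start_by_site = dict(zip(site_ids, start))

    S, (N, D) = len(species), effort.shape
    Y = np.zeros((S, N, D), dtype=np.uint8)
    n_dropped = 0
    for row in seqs.itertuples(index=False):
        i = site_index.get(row.site_id)
        j = sp_index.get(row.species)
        if i is None:
            raise ValueError(f"sequence references unknown site {row.site_id!r}")
        if j is None:
            continue  # species outside the requested list
        day = (row.timestamp.normalize() - start_by_site[row.site_id]).days
        if day < 0 or day >= D or not effort[i, day]:
            n_dropped += 1
            continue
        Y[j, i, day] = 1
    if n_dropped:
        logger.warning("dropped %d sequences outside deployment windows", n_dropped)
    return DetectionHistory(species=list(species), sites=site_ids, Y=Y, effort=effort)


def detection_rates(
    sequences: pd.DataFrame,
    sites: pd.DataFrame,
    species: list[str] | str = "all",
    per_animal: bool = False,
) -> pd.DataFrame:
    """Per-site detection rates (independent sequences per camera-night).

    ``species="all"`` pools every species into a total-mammal rate; a list
    restricts and reports per species.  ``per_animal`` weights each sequence
    by its animal count instead of counting sequences.

    Returns a table with columns site_id, [species,] detections,
    camera_nights, rate, where rate = detections / camera_nights exactly.
    """
    sites = load_sites(sites)
    seqs = load_detections(sequences)
    nights = (
        (sites["deploy_end"].dt.normalize() - sites["deploy_start"].dt.normalize()).dt.days + 1
    ).astype(float)
    if (nights <= 0).any():
        bad = sites.loc[nights <= 0, "site_id"].tolist()
        raise ValueError(f"zero camera-nights at sites: {bad}")
    nights_by_site = pd.Series(nights.to_numpy(), index=sites["site_id"])

    weight = seqs["animal_count"] if per_animal else pd.Series(1, index=seqs.index)
    seqs = seqs.assign(_w=weight)
    if isinstance(species, str) and species == "all":
        counts = seqs.groupby("site_id")["_w"].sum()
        out = pd.DataFrame({"site_id": sites["site_id"]})
        out["detections"] = out["site_id"].map(counts).fillna(0).astype(float)
    else:
        keep = seqs[seqs["species"].isin(list(species))]
        counts = keep.groupby(["site_id", "species"])["_w"].sum()
        grid = pd.MultiIndex.from_product([sites["site_id"], list(species)], names=["site_id", "species"])
        out = counts.reindex(grid, fill_value=0).rename("detections").reset_index()
        out["detections"] = out["detections"].astype(float)
    out["camera_nights"] = out["site_id"].map(nights_by_site)
    out["rate"] = out["detections"] / out["camera_nights"]
    return out


def naive_occupancy(history: DetectionHistory) -> pd.DataFrame:
    """Fraction of sites with >= 1 detection, per species.

    Uncorrected for imperfect detection.  Returns per-species values; use
    :func:`naive_occupancy_summary` for the community mean/min/max.
    """
    if history.n_sites == 0:
        raise ValueError("empty detection history")
    detected = history.Y.max(axis=2)  # (S, N)
    return pd.DataFrame(
        {"species": history.species, "naive_occupancy": detected.mean(axis=1)}
    )


def naive_occupancy_summary(history: DetectionHistory) -> dict[str, float]:
    """Community mean / min / max naive occupancy across species."""
    occ = naive_occupancy(history)["naive_occupancy"]
    return {"mean": float(occ.mean()), "min": float(occ.min()), "max": float(occ.max())}


def effort_weighted_detection_profile(
    sequences: pd.DataFrame,
    sites: pd.DataFrame,
    levels: list[str] = DEVELOPMENT_LEVELS,
) -> pd.DataFrame:
    """Percent of effort-corrected detections per development level, per species.

    Within each gradient level the species' detections are divided by the
    level's total camera-nights; the resulting rates are normalized across
    levels to percentages summing to 100.  Species never detected have an
    undefined profile and are returned with NaN rows and ``defined=False``.
    """
    sites = load_sites(sites)
    seqs = load_detections(sequences)
    nights = (
        (sites["deploy_end"].dt.normalize() - sites["deploy_start"].dt.normalize()).dt.days + 1
    ).astype(float)
    effort_by_level = nights.groupby(sites["development_level"].to_numpy()).sum()
    sampled = [lv for lv in levels if effort_by_level.get(lv, 0) > 0]
    if not sampled:
        raise ValueError("no development level with nonzero effort")

    level_of_site = dict(zip(sites["site_id"], sites["development_level"]))
    seqs = seqs.assign(level=seqs["site_id"].map(level_of_site))
    counts = seqs.groupby(["species", "level"]).size()

    rows = []
    for sp in sorted(seqs["species"].unique()) or []:
        rates = np.array([counts.get((sp, lv), 0) / effort_by_level[lv] for lv in sampled])
        total = rates.sum()
        if total == 0:
            rows.append({"species": sp, "defined": False, **{lv: np.nan for lv in sampled}})
            continue
        pct = 100.0 * rates / total
        rows.append({"species": sp, "defined": True, **dict(zip(sampled, pct))})
    return pd.DataFrame(rows)
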