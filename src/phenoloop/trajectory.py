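"""Daily time-series construction and temporal phenotype analytics.

Raw imaging observations (root-scan pixels, three-view shoot pixels, health
fractions, NDVI) are reduced to per-plant daily series for days 4-25 by
Savitzky-Golay smoothing of the observation sequence followed by cubic
spline interpolation onto integer days.  On those series the module runs
the study's temporal screens: per-day Pearson correlation between dose and
each feature with percentile-bootstrap confidence intervals, per-day
ANOVA + Tukey contrasts of each dose arm against the 0 uM control with
Benjamini-Hochberg correction across the retained (day x dose) family, and
unsupervised trajectory clustering (UMAP embedding of the scaled days 11-25
feature block, HDBSCAN labels, noise = -1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .evaluation import anova_tukey, ComparisonResult
from .spectral import euclidean_size, weighted_health

__all__ = [
    "SmoothingSpec",
    "DEFAULT_POLYORDER",
    "smooth_interpolate",
    "build_daily_panel",
    "daily_correlation",
    "daily_dose_tests",
    "first_significant_day",
    "build_trajectory_matrix",
    "TrajectoryClusterer",
    "ClusterReport",
    "embed_cluster",
    "cluster_statistics",
]

#: Savitzky-Golay polyorder per feature (window 7 throughout): pixel-count
#: features use 3; health fraction and NDVI use 5.
DEFAULT_POLYORDER = {"root_px": 3, "shoot_px": 3, "health": 5, "ndvi": 5}


@dataclass(frozen=True)
class SmoothingSpec:
    window_length: int = 7
    polyorder: int = 3
    day_range: tuple[int, int] = (4, 25)

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.polyorder >= self.window_length:
            raise ValueError("polyorder must be < window_length")


def smooth_interpolate(days, values, spec: SmoothingSpec | None = None) -> pd.Series:
    """Savitzky-Golay smooth, then cubic-spline to integer days.

    The filter runs on the observation sequence (irregular sampling is
    treated as evenly indexed, matching the source protocol); the spline is
    evaluated on integer days within ``day_range``, clamped to the observed
    day span (no extrapolation).
    """
    spec = spec or SmoothingSpec()
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(days)
    days, values = days[order], values[order]
    if days.size < spec.window_length:
        raise ValueError(
            f"{days.size} observations < window_length {spec.window_length}; "
            "use a smaller window")
    smoothed = savgol_filter(values, spec.window_length, spec.polyorder)
    spline = make_interp_spline(days, smoothed, k=3)
    grid = np.arange(spec.day_range[0], spec.day_range[1] + 1)
    out = spline(np.clip(grid, days[0], days[-1]))
    return pd.Series(out, index=pd.Index(grid, name="day"))


def build_daily_panel(observations: pd.DataFrame,
                      specs: dict | None = None) -> pd.DataFrame:
    """Per-plant daily feature series from the raw observation table.

    Features: ``root_px`` (root-scan pixels), ``shoot_px`` (Euclidean norm of
    the three shoot views), ``health`` (count-weighted mean of per-view
    health fractions), ``ndvi`` (mean over views).  Returns a tidy frame
    (plant_id, feature, day, value).
    """
    specs = specs or {}
    rows = []
    for pid, sub in observations.groupby("plant_id", sort=True):
        per_day: dict[str, list] = {"day": [], "root_px": [], "shoot_px": [],
                                    "health": [], "ndvi": []}
        for day, dsub in sub.groupby("day", sort=True):
            root = dsub.loc[dsub.modality == "root_scan", "pixel_count"]
            shoots = dsub.loc[dsub.modality != "root_scan"]
            if root.empty or len(shoots) != 3:
                continue
            counts = shoots.pixel_count.to_numpy(dtype=float)
            per_day["day"].append(day)
            per_day["root_px"].append(float(root.iloc[0]))
            per_day["shoot_px"].append(euclidean_size(counts))
            per_day["health"].append(
                weighted_health(shoots.health_fraction.to_numpy(dtype=float), counts))
            per_day["ndvi"].append(float(shoots.mean_ndvi.mean()))
        days = np.asarray(per_day["day"], dtype=float)
        for feature in ("root_px", "shoot_px", "health", "ndvi"):
            spec = specs.get(feature,
                             SmoothingSpec(polyorder=DEFAULT_POLYORDER[feature]))
            series = smooth_interpolate(days, per_day[feature], spec)
            rows.append(pd.DataFrame(dict(plant_id=pid, feature=feature,
                                          day=series.index, value=series.to_numpy())))
    return pd.concat(rows, ignore_index=True)


def _pivot(panel: pd.DataFrame, feature: str) -> pd.DataFrame:
    mat = panel.loc[panel.feature == feature].pivot(index="plant_id", columns="day",
                                                    values="value")
    return mat.sort_index()


def daily_correlation(doses: pd.Series, daily_matrix: pd.DataFrame,
                      n_boot: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Per-day Pearson r between dose and a feature, with bootstrap 95% CI.

    ``doses`` is indexed by plant_id; ``daily_matrix`` is plants x days.
    The CI is the 2.5th/97.5th percentile of r over ``n_boot`` resamples of
    plant rows.
    """
    daily_matrix = daily_matrix.sort_index()
    d = doses.reindex(daily_matrix.index).to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("doses missing for some plants")
    M = daily_matrix.to_numpy(dtype=float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 plants")
    if np.std(d) == 0:
        raise ValueError("zero variance in dose")
    if np.any(M.std(axis=0) == 0):
        raise ValueError("zero variance in the feature on some day")

    def _corr(dv, mat):  # noqa: ANN001 - columns of mat vs dv
        dvc = dv - dv.mean()
        mc = mat - mat.mean(axis=0)
        num = dvc @ mc
        den = np.sqrt((dvc @ dvc) * np.sum(mc * mc, axis=0))
        return num / den

    r = _corr(d, M)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, M.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        db, Mb = d[idx], M[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            boots[b] = _corr(db, Mb)
    lo = np.nanpercentile(boots, 2.5, axis=0)
    hi = np.nanpercentile(boots, 97.5, axis=0)
    return pd.DataFrame(dict(day=daily_matrix.columns.to_numpy(), r=r,
                             ci_low=lo, ci_high=hi))


def daily_dose_tests(daily_matrix: pd.DataFrame, doses: pd.Series,
                     control_dose: float = 0.0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-day dose-vs-control screen.

    Per day: one-way ANOVA across dose arms and Tukey HSD pairs; only pairs
    containing the control are retained, then Benjamini-Hochberg correction
    is applied across the whole retained (day x dose) family.  Returns a
    tidy frame (day, dose, p_tukey, p_adj, significant).
    """
    daily_matrix = daily_matrix.sort_index()
    d = doses.reindex(daily_matrix.index).to_numpy(dtype=float)
    if control_dose not in d:
        raise ValueError("control arm missing")
    arms = np.unique(d)
    rows = []
    for day in daily_matrix.columns:
        vals = daily_matrix[day].to_numpy(dtype=float)
        stats.f_oneway(*(vals[d == a] for a in arms))
        tukey = pairwise_tukeyhsd(vals, d)
        pairs = [(a, b) for i, a in enumerate(tukey.groupsunique)
                 for b in tukey.groupsunique[i + 1:]]
        for (a, b), p in zip(pairs, tukey.pvalues):
            if control_dose in (a, b):
                dose = b if a == control_dose else a
                if dose == control_dose:
                    continue
                rows.append(dict(day=day, dose=float(dose), p_tukey=float(p)))
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out.p_tukey.to_numpy(), alpha=alpha,
                                        method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out


def first_significant_day(tests: pd.DataFrame) -> pd.Series:
    """Earliest significant day per dose (inf where never significant)."""
    out = {}
    for dose, sub in tests.groupby("dose"):
        sig = sub.loc[sub.significant, "day"]
        out[float(dose)] = float(sig.min()) if not sig.empty else float("inf")
    return pd.Series(out).sort_index()


def build_trajectory_matrix(panel: pd.DataFrame, day_window: tuple[int, int] = (11, 25),
                            features: tuple[str, ...] = ("root_px", "shoot_px", "health"),
                            ) -> pd.DataFrame:
    """Plants x (features x days) block, each feature globally MinMax-scaled.

    Scaling is across all plants and days of the combined experiments, so
    repeated application is idempotent; values lie in [0, 1].
    """
    lo, hi = day_window
    blocks = []
    for feature in features:
        mat = _pivot(panel, feature)
        missing = mat.index[mat.isna().any(axis=1)]
        if len(missing):
            raise ValueError(f"plants missing feature {feature!r}: {list(missing)[:5]}")
        mat = mat.loc[:, [c for c in mat.columns if lo <= c <= hi]]
        vmin, vmax = mat.to_numpy().min(), mat.to_numpy().max()
        if vmax - vmin <= 0:
            raise ValueError(f"zero range for feature {feature!r}")
        scaled = (mat - vmin) / (vmax - vmin)
        scaled.columns = [f"{feature}_d{int(c)}" for c in scaled.columns]
        blocks.append(scaled)
    out = pd.concat(blocks, axis=1)
    if out.isna().any().any():
        raise ValueError("plants missing one or more features over the window")
    return out


class TrajectoryClusterer(ClusterMixin, BaseEstimator):
    """UMAP embedding + HDBSCAN labels of phenotype trajectory rows.

    Embeds the trajectory matrix in 2-D (UMAP, seeded for determinism) and
    clusters the embedding by density (HDBSCAN; label -1 = noise).
    Defaults follow the study: n_neighbors=5, min_dist=0.05,
    min_cluster_size=8, min_samples=3.
    """

    def __init__(self, n_neighbors: int = 5, min_dist: float = 0.05,
                 min_cluster_size: int = 8, min_samples: int = 3,
                 random_state: int = 0):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        import umap  # heavy import deferred

        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.min_cluster_size:
            warnings.warn("fewer rows than min_cluster_size: all points labeled noise",
                          stacklevel=2)
            self.embedding_ = np.zeros((X.shape[0], 2))
            self.labels_ = np.full(X.shape[0], -1)
            return self
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=UserWarning)
            reducer = umap.UMAP(n_components=2, n_neighbors=self.n_neighbors,
                                min_dist=self.min_dist, random_state=self.random_state,
                                n_jobs=1)
            self.embedding_ = reducer.fit_transform(X)
        clus = HDBSCAN(min_cluster_size=self.min_cluster_size,
                       min_samples=self.min_samples, copy=True)
        self.labels_ = clus.fit_predict(self.embedding_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


@dataclass
class ClusterReport:
    """Embedding, labels and per-cluster summaries (noise excluded)."""

    embedding: pd.DataFrame          # plant_id, x, y, label
    labels: pd.Series                # indexed by plant_id, -1 = noise
    cluster_summary: pd.DataFrame    # label, n, dose_mean, dose_sd + final-day features
    n_clusters: int
    n_noise: int


def embed_cluster(matrix: pd.DataFrame, doses: pd.Series | None = None,
                  final_day_features: pd.DataFrame | None = None,
                  seed: int = 0, **params) -> ClusterReport:
    """Cluster trajectory rows and summarize clusters by dose and endpoints."""
    clusterer = TrajectoryClusterer(random_state=seed, **params)
    labels = pd.Series(clusterer.fit_predict(matrix.to_numpy()),
                       index=matrix.index, name="label")
    embedding = pd.DataFrame(clusterer.embedding_, columns=["x", "y"],
                             index=matrix.index)
    embedding["label"] = labels
    embedding = embedding.reset_index()
    non_noise = sorted(l for l in labels.unique() if l >= 0)
    rows = []
    for lab in non_noise:
        members = labels.index[labels == lab]
        row = dict(label=int(lab), n=len(members))
        if doses is not None:
            dv = doses.reindex(members).to_numpy(dtype=float)
            row["dose_mean"] = float(np.mean(dv))
            row["dose_sd"] = float(np.std(dv, ddof=1)) if len(dv) > 1 else 0.0
        if final_day_features is not None:
            for col in final_day_features.columns:
                row[f"{col}_mean"] = float(final_day_features.loc[members, col].mean())
        rows.append(row)
    summary = pd.DataFrame(rows)
    return ClusterReport(embedding=embedding, labels=labels, cluster_summary=summary,
                         n_clusters=len(non_noise), n_noise=int((labels == -1).sum()))


def cluster_statistics(report: ClusterReport, doses: pd.Series,
                       final_day_features: pd.DataFrame | None = None,
                       ) -> dict[str, ComparisonResult]:
    """ANOVA + Tukey across clusters for dose and each final-day feature."""
    labels = report.labels
    non_noise = sorted(l for l in labels.unique() if l >= 0)
    if len(non_noise) < 2:
        raise ValueError("need at least 2 non-noise clusters")
    members = {lab: labels.index[labels == lab] for lab in non_noise}
    out = {"dose": anova_tukey({lab: doses.reindex(m).to_numpy(dtype=float)
                                for lab, m in members.items()})}
    if final_day_features is not None:
        for col in final_day_features.columns:
            out[col] = anova_tukey(
                {lab: final_day_features.loc[m, col].to_numpy(dtype=float)
                 for lab, m in members.items()})
    return out
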