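"""Eye-movement analytics: features, selection scores, scan-path comparison.

Operates on :class:`~gazeblind.synthetic.GazeRecord` objects, whether
generated synthetically, converted from simulator output, or read from
an eye-tracker-style CSV.  Quantiles throughout use linear
interpolation (numpy default).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.linear_model import RidgeClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .synthetic import GazeRecord

FEATURE_NAMES = ["mu_fd", "var_fd", "mu_sa", "var_sa",
                 "mu_sd", "var_sd", "mu_sps", "var_sps"]
FIXATION_FEATURES = ["mu_fd", "var_fd"]
SACCADE_FEATURES = ["mu_sa", "var_sa", "mu_sd", "var_sd", "mu_sps", "var_sps"]

_CLUSTER_ALPHABET = string.ascii_uppercase + string.ascii_lowercase
SPARSE_LABEL = "#"


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------

def remove_outliers(values: Sequence[float], w: float = 1.5) -> np.ndarray:
    """Drop boxplot outliers: values outside [q1 - w*IQR, q3 + w*IQR].

    Quartiles are computed with linear interpolation.  With fewer than
    four values the data pass through unchanged (with a warning); an
    all-equal sample has zero IQR and is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; outlier removal skipped",
                      stacklevel=2)
        return values
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    keep = (values >= q1 - w * iqr) & (values <= q3 + w * iqr)
    return values[keep]


def strip_final_dwell(record: GazeRecord,
                      min_dwell_ms: float = 3000.0) -> GazeRecord:
    """Remove the terminal detection dwell from a hit trial.

    On hit trials the last fixation (a >= 3 s dwell at the change
    location) reflects the response, not search, and is removed before
    feature computation.  Other trials are returned unchanged.
    """
    if record.outcome != "hit" or len(record.fixations) == 0:
        return record
    if record.fixations["duration_ms"].iloc[-1] < min_dwell_ms:
        return record
    fix = record.fixations.iloc[:-1].reset_index(drop=True)
    sac = record.saccades.iloc[:-1].reset_index(drop=True) \
        if len(record.saccades) >= len(record.fixations) - 1 else record.saccades
    out = GazeRecord(**{**record.__dict__})
    out.fixations, out.saccades = fix, sac
    return out


def compute_features(records: Sequence[GazeRecord], w: float = 1.5,
                     strip_hits: bool = True) -> pd.DataFrame:
    """Per-trial eight-feature summary table.

    Columns: mean and variance of fixation duration (FD), saccade
    amplitude (SA), saccade duration (SD) and saccade peak speed (SPS),
    plus subject/trial identifiers and the group label.  Boxplot
    outliers (w = 1.5) are removed from each raw metric within a trial
    before the summary statistics are taken.
    """
    rows = []
    for rec in records:
        if strip_hits:
            rec = strip_final_dwell(rec)
        metrics = {
            "fd": rec.fixations["duration_ms"].to_numpy(),
            "sa": rec.saccades["amplitude_deg"].to_numpy(),
            "sd": rec.saccades["duration_ms"].to_numpy(),
            "sps": rec.saccades["peak_speed_deg_s"].to_numpy(),
        }
        row = {"subject_id": rec.subject_id, "trial_id": rec.trial_id,
               "image_id": rec.image_id, "group": rec.group,
               "outcome": rec.outcome}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, vals in metrics.items():
                vals = remove_outliers(vals, w=w)
                row[f"mu_{name}"] = float(np.mean(vals)) if vals.size else np.nan
                row[f"var_{name}"] = (float(np.var(vals, ddof=1))
                                      if vals.size > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# feature-selection scores
# --------------------------------------------------------------------------

def fisher_score(values: Sequence[float], labels: Sequence) -> float:
    """Two-class Fisher score of one feature.

    Squared deviations of the two class means from the grand mean,
    divided by the sum of the unbiased within-class variances.  A zero
    denominator with separated means signals infinite separation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("fisher_score requires exactly two classes")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each class needs at least two samples")
    grand = values.mean()
    num = (a.mean() - grand) ** 2 + (b.mean() - grand) ** 2
    den = a.var(ddof=1) + b.var(ddof=1)
    if den == 0:
        return np.inf if num > 0 else 0.0
    return float(num / den)


def _entropy(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    p = np.bincount(labels).astype(float) / labels.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(values: Sequence[float], labels: Sequence) -> float:
    """Entropy reduction (bits) of the best single threshold split.

    Candidate split points are midpoints of adjacent sorted distinct
    feature values; the gain is the class entropy minus the minimal
    size-weighted entropy of the two sides.  A constant feature yields 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("information_gain requires binary labels")
    y = (labels == classes[1]).astype(int)
    base = _entropy(y)
    distinct = np.unique(values)
    if distinct.size < 2:
        return 0.0
    best = base
    for div in (distinct[:-1] + distinct[1:]) / 2.0:
        hi = y[values > div]
        lo = y[values < div]
        n = hi.size + lo.size
        child = (hi.size * _entropy(hi) + lo.size * _entropy(lo)) / n
        best = min(best, child)
    return float(base - best)


def _default_classifier(x_train: np.ndarray, y_train: np.ndarray,
                        x_test: np.ndarray) -> np.ndarray:
    """Ridge-regularised linear discriminant scores on held-out rows."""
    model = RidgeClassifier(alpha=1.0)
    model.fit(x_train, y_train)
    return model.decision_function(x_test)


def cross_validated_auc(features: np.ndarray, labels: np.ndarray,
                        classifier: Callable = _default_classifier,
                        n_folds: int = 5, seed: int = 0) -> float:
    """AUC of out-of-fold scores (rank / Mann-Whitney estimator)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(labels.size)
    y = (labels == np.unique(labels)[1]).astype(int)
    for train, test in skf.split(features, y):
        scores[test] = classifier(features[train], y[train], features[test])
    return float(roc_auc_score(y, scores))


def auc_change(features: np.ndarray, labels: np.ndarray, feature_index: int,
               classifier: Callable = _default_classifier,
               n_folds: int = 5, seed: int = 0) -> float:
    """Drop in cross-validated AUC when one feature is removed.

    Positive values mean the feature carried unique discriminative
    information; a redundant feature changes the AUC by about zero.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("need at least two features to remove one")
    full = cross_validated_auc(features, labels, classifier, n_folds, seed)
    reduced = np.delete(features, feature_index, axis=1)
    part = cross_validated_auc(reduced, labels, classifier, n_folds, seed)
    return full - part


def rank_features(table: pd.DataFrame, label_col: str = "group",
                  features: Sequence[str] = FEATURE_NAMES) -> pd.DataFrame:
    """Fisher score and information gain for each feature column."""
    sub = table.dropna(subset=list(features))
    labels = sub[label_col].to_numpy()
    rows = []
    for f in features:
        vals = sub[f].to_numpy()
        rows.append({"feature": f,
                     "fisher": fisher_score(vals, labels),
                     "info_gain": information_gain(vals, labels)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fixation density and clustering
# --------------------------------------------------------------------------

def uniform_reference(n: int, image_size: Tuple[int, int]) -> np.ndarray:
    """Deterministic near-square lattice of n points over the image.

    Used as the uniform-sampling reference U in the fixation-density
    normalisation; row-major, cell-centered, first n points kept.
    """
    w, h = image_size
    n_rows = max(int(round(np.sqrt(n * h / w))), 1)
    n_cols = int(np.ceil(n / n_rows))
    xs = (np.arange(n_cols) + 0.5) * (w / n_cols)
    ys = (np.arange(n_rows) + 0.5) * (h / n_rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])[:n]


def _mean_neighbour_distance(point: np.ndarray, others: np.ndarray,
                             r: float, fallback_nearest: bool = False
                             ) -> float:
    d = np.hypot(*(others - point).T)
    within = d[(d > 0) & (d <= r)]
    if within.size:
        return float(within.mean())
    if fallback_nearest:
        # reference lattice sparser than the radius: its natural spacing
        # stands in for the local mean distance
        positive = d[d > 0]
        return float(positive.min()) if positive.size else np.inf
    return np.inf


def fixation_density(points: np.ndarray, r: float = 40.0,
                     image_size: Tuple[int, int] = (864, 648)) -> np.ndarray:
    """Local fixation density relative to a uniform sampling strategy.

    rho(x_i) = (mean distance to fixations within radius r of x_i)^-1,
    normalised by the same quantity for the nearest point of a uniform
    reference lattice of equal cardinality (computed within U).  Points
    with no neighbour within r get rho = 0; rho < 1 marks regions
    sampled more sparsely than uniform.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least two fixation points")
    uniform = uniform_reference(points.shape[0], image_size)
    rho = np.empty(points.shape[0])
    for i, p in enumerate(points):
        d_x = _mean_neighbour_distance(p, points, r)
        if not np.isfinite(d_x):
            rho[i] = 0.0
            continue
        j = np.argmin(np.hypot(*(uniform - p).T))
        d_u = _mean_neighbour_distance(uniform[j], uniform, r,
                                       fallback_nearest=True)
        rho[i] = 0.0 if not np.isfinite(d_u) else (1.0 / d_x) / (1.0 / d_u)
    return rho


@dataclass
class ClusterModel:
    """Fixation clusters of one image: k-means centers + sparse bucket."""

    centers: np.ndarray                 # (k, 2) pixel coordinates
    sparse_points: np.ndarray           # indices of low-density points
    bic_profile: pd.DataFrame           # columns k, bic, bic_smooth
    k: int

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-center label per point (0..k-1)."""
        points = np.asarray(points, dtype=float)
        d = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return d.argmin(axis=1)

    def label_char(self, index: int) -> str:
        return _CLUSTER_ALPHABET[index % len(_CLUSTER_ALPHABET)]


def _spherical_bic(points: np.ndarray, labels: np.ndarray,
                   centers: np.ndarray) -> float:
    """x-means style BIC under identical spherical Gaussian clusters."""
    n, d = points.shape
    k = centers.shape[0]
    if n <= k:
        return -np.inf
    sq = ((points - centers[labels]) ** 2).sum()
    var = sq / (d * (n - k))
    var = max(var, 1e-12)
    loglik = 0.0
    for j in range(k):
        nj = int((labels == j).sum())
        if nj == 0:
            continue
        loglik += (nj * np.log(nj) - nj * np.log(n)
                   - nj * d / 2.0 * np.log(2.0 * np.pi * var)
                   - (nj - 1) * d / 2.0)
    n_params = (k - 1) + k * d + 1
    return loglik - n_params / 2.0 * np.log(n)


def _smooth_bic(ks: np.ndarray, bic: np.ndarray) -> np.ndarray:
    """Bi-exponential fit of the BIC profile (fallback: moving average).

    Model: f(k) = a * (1 - exp(-k/t1)) - b * (exp(k/t2) - 1); rising
    saturation minus a slow penalty term, giving a smooth unimodal
    curve whose peak selects k.
    """
    b0 = bic - bic.min()

    def f(k, a, t1, b, t2):
        return a * (1.0 - np.exp(-k / t1)) - b * (np.expm1(k / t2))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                f, ks.astype(float), b0,
                p0=[b0.max() + 1.0, max(ks.max() / 5.0, 1.0), 1.0, ks.max()],
                bounds=([0, 1e-3, 0, 1e-3], [np.inf] * 4), maxfev=5000)
        return f(ks.astype(float), *popt) + bic.min()
    except Exception:
        kernel = np.array([0.25, 0.5, 0.25])
        return np.convolve(np.pad(bic, 1, mode="edge"), kernel, mode="valid")


def cluster_fixations(points: np.ndarray, r: float = 40.0,
                      image_size: Tuple[int, int] = (864, 648),
                      k_max: int = 50, n_init: int = 5,
                      seed: int = 0) -> ClusterModel:
    """Density-filtered k-means clustering with BIC model selection.

    Points with fixation density rho < 1 go into a single "sparse"
    bucket.  The remainder are k-means clustered (k-means++ init,
    ``n_init`` restarts keeping the best inertia) for k = 1..k_max; the
    spherical-Gaussian BIC profile is smoothed with a bi-exponential fit
    and the k at its peak is selected.  Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least two fixation points")
    if np.allclose(points, points[0]):
        return ClusterModel(centers=points[:1].copy(),
                            sparse_points=np.array([], dtype=int),
                            bic_profile=pd.DataFrame({"k": [1]}), k=1)
    rho = fixation_density(points, r=r, image_size=image_size)
    sparse_idx = np.flatnonzero(rho < 1.0)
    dense = points[rho >= 1.0]
    if dense.shape[0] < 2:   # degenerate: nearly everything is sparse
        dense = points
        sparse_idx = np.array([], dtype=int)

    ks, bics, fits = [], [], {}
    for k in range(1, min(k_max, dense.shape[0] - 1) + 1):
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                    random_state=seed)
        labels = km.fit_predict(dense)
        bic = _spherical_bic(dense, labels, km.cluster_centers_)
        if not np.isfinite(bic):
            continue
        ks.append(k)
        bics.append(bic)
        fits[k] = km.cluster_centers_
    ks = np.array(ks)
    bics = np.array(bics)
    # the bi-exponential smoothing needs a long profile to be meaningful;
    # short profiles use the raw argmax
    smooth = _smooth_bic(ks, bics) if ks.size > 10 else bics
    k_best = int(ks[np.argmax(smooth)])
    profile = pd.DataFrame({"k": ks, "bic": bics, "bic_smooth": smooth})
    return ClusterModel(centers=fits[k_best], sparse_points=sparse_idx,
                        bic_profile=profile, k=k_best)


def encode_scanpath(record: GazeRecord, model: ClusterModel,
                    r: float = 40.0,
                    image_size: Tuple[int, int] = (864, 648)) -> str:
    """Scan path as a string of cluster labels, order preserved.

    Each fixation is mapped to its nearest cluster center; fixations in
    low-density regions (density < 1 within the trial's own points, when
    computable) use the sparse label.
    """
    pts = record.fixations[["x_px", "y_px"]].to_numpy(dtype=float)
    if pts.shape[0] == 0:
        return ""
    labels = model.assign(pts)
    chars = [model.label_char(i) for i in labels]
    if pts.shape[0] >= 2 and model.sparse_points.size:
        rho = fixation_density(pts, r=r, image_size=image_size)
        chars = [SPARSE_LABEL if rho[i] < 1.0 else chars[i]
                 for i in range(len(chars))]
    return "".join(chars)


# --------------------------------------------------------------------------
# scan-path comparison
# --------------------------------------------------------------------------

def edit_distance(s1: str, s2: str) -> int:
    """Levenshtein distance with unit insert/delete/substitute costs."""
    if len(s1) < len(s2):
        s1, s2 = s2, s1
    prev = list(range(len(s2) + 1))
    for i, c1 in enumerate(s1, start=1):
        cur = [i]
        for j, c2 in enumerate(s2, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (c1 != c2)))
        prev = cur
    return prev[-1]


def edit_distance_normalized(s1: str, s2: str) -> float:
    """Edit distance divided by the longer string's length (in [0, 1])."""
    longer = max(len(s1), len(s2))
    if longer == 0:
        return 0.0
    return edit_distance(s1, s2) / longer


# --------------------------------------------------------------------------
# saccade probability matrices
# --------------------------------------------------------------------------

def _cluster_durations(scanpaths: Sequence[Sequence[int]],
                       durations: Sequence[Sequence[float]],
                       n_clusters: int) -> np.ndarray:
    total = np.zeros(n_clusters)
    for labels, durs in zip(scanpaths, durations):
        for lab, d in zip(labels, durs):
            total[lab] += d
    return total


def _transition_matrix(scanpaths: Sequence[Sequence[int]],
                       group_of: np.ndarray, n_groups: int) -> np.ndarray:
    """Column-normalised saccade matrix over cluster groups.

    Entry (i, j) = P(saccade lands in group i | it started in group j);
    transitions involving a cluster outside the grouping (group < 0)
    are excluded.
    """
    counts = np.zeros((n_groups, n_groups))
    for labels in scanpaths:
        for a, b in zip(labels[:-1], labels[1:]):
            gi, gj = group_of[b], group_of[a]
            if gi >= 0 and gj >= 0:
                counts[gi, gj] += 1
    col = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(col > 0, counts / col, 0.0)
    return out


def saccade_matrix_domains(scanpaths: Sequence[Sequence[int]],
                           durations: Sequence[Sequence[float]],
                           n_clusters: int) -> np.ndarray:
    """4x4 saccade probability matrix over fixation-duration domains.

    Clusters are ranked by cumulative fixation duration (descending,
    ties broken by cluster index) and split into four near-equal
    quartile domains, domain 0 holding the most-fixated clusters.
    Columns sum to 1 wherever the start domain has outgoing saccades;
    an empty domain leaves a zero column.
    """
    total = _cluster_durations(scanpaths, durations, n_clusters)
    order = np.lexsort((np.arange(n_clusters), -total))
    group_of = np.empty(n_clusters, dtype=int)
    for d, chunk in enumerate(np.array_split(order, 4)):
        group_of[chunk] = d
    return _transition_matrix(scanpaths, group_of, 4)


def saccade_matrix_topk(scanpaths: Sequence[Sequence[int]],
                        durations: Sequence[Sequence[float]],
                        n_clusters: int, k: int = 10) -> np.ndarray:
    """k x k saccade matrix among the k most-fixated clusters.

    Clusters are ranked by cumulative fixation duration; saccades that
    touch any other cluster are excluded.  Columns are normalised.
    """
    total = _cluster_durations(scanpaths, durations, n_clusters)
    order = np.lexsort((np.arange(n_clusters), -total))[:k]
    group_of = np.full(n_clusters, -1, dtype=int)
    group_of[order] = np.arange(len(order))
    return _transition_matrix(scanpaths, group_of, len(order))


# --------------------------------------------------------------------------
# fixation maps and change-proximity summaries
# --------------------------------------------------------------------------

def fixation_map(record: GazeRecord, image_size: Tuple[int, int],
                 tiles: Tuple[int, int] = (13, 18)) -> np.ndarray:
    """2-D histogram of fixation counts over a tiles[0] x tiles[1] grid."""
    w, h = image_size
    x = record.fixations["x_px"].to_numpy(dtype=float)
    y = record.fixations["y_px"].to_numpy(dtype=float)
    hist, _, _ = np.histogram2d(y, x, bins=tiles, range=[[0, h], [0, w]])
    return hist


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Pearson correlation of two vectorised fixation maps."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant fixation map")
    return float(pearsonr(a, b)[0])


def change_proximity_profile(record: GazeRecord,
                             change_center: Tuple[float, float],
                             bin_px: float = 50.0,
                             normalize: bool = False
                             ) -> Tuple[np.ndarray, np.ndarray]:
    """Fixation counts and total durations in concentric annuli.

    Annulus ``i`` covers distances [i*bin_px, (i+1)*bin_px) from the
    change center; counts conserve the total number of fixations.  With
    ``normalize`` both profiles are divided by their totals.
    """
    pts = record.fixations[["x_px", "y_px"]].to_numpy(dtype=float)
    durs = record.fixations["duration_ms"].to_numpy(dtype=float)
    d = np.hypot(pts[:, 0] - change_center[0], pts[:, 1] - change_center[1])
    idx = np.floor(d / bin_px).astype(int)
    n_bins = int(idx.max()) + 1 if idx.size else 1
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    total_dur = np.bincount(idx, weights=durs, minlength=n_bins)
    if normalize:
        if counts.sum() > 0:
            counts = counts / counts.sum()
        if total_dur.sum() > 0:
            total_dur = total_dur / total_dur.sum()
    return counts, total_dur


def latency_metrics(record: GazeRecord, change_center: Tuple[float, float],
                    change_radius: float
                    ) -> Tuple[Optional[float], Optional[float]]:
    """(time to first fixation in the change region, time to detect), s.

    The first latency is the onset of the earliest fixation within
    ``change_radius`` of the change center (None if gaze never entered
    the region); the second is the onset of the terminal detection
    dwell on hit trials (None otherwise).
    """
    pts = record.fixations[["x_px", "y_px"]].to_numpy(dtype=float)
    onsets = record.fixations["onset_ms"].to_numpy(dtype=float)
    d = np.hypot(pts[:, 0] - change_center[0], pts[:, 1] - change_center[1])
    inside = np.flatnonzero(d <= change_radius)
    t_first = float(onsets[inside[0]] / 1000.0) if inside.size else None
    t_detect = (float(onsets[-1] / 1000.0)
                if record.outcome == "hit" and onsets.size else None)
    return t_first, t_detect


# --------------------------------------------------------------------------
# simulator bridge
# --------------------------------------------------------------------------

def record_from_trial(result, pair_id: str = "sim",
                      subject_id: str = "model",
                      px_per_deg: float = 30.0) -> GazeRecord:
    """Convert a simulated TrialResult into a GazeRecord for analytics."""
    centers = result.grid.centers_px()
    regions = np.array([r for r, _, _ in result.scanpath])
    onsets = np.array([o for _, o, _ in result.scanpath]) * result.dt * 1000.0
    durs = np.array([d for _, _, d in result.scanpath]) * result.dt * 1000.0
    pts = centers[regions]
    fixations = pd.DataFrame({"x_px": pts[:, 0], "y_px": pts[:, 1],
                              "duration_ms": durs, "onset_ms": onsets})
    amp_px = (np.hypot(*np.diff(pts, axis=0).T) if len(pts) > 1
              else np.array([]))
    amp_deg = amp_px / px_per_deg
    sd, sps = (21.0 + 2.2 * amp_deg, 75.0 * amp_deg ** 0.6)
    saccades = pd.DataFrame({"amplitude_deg": amp_deg, "duration_ms": sd,
                             "peak_speed_deg_s": sps})
    return GazeRecord(subject_id=subject_id, trial_id=f"{pair_id}-s{result.seed}",
                      image_id=pair_id, fixations=fixations, saccades=saccades,
                      outcome=result.outcome)
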