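"""Synthetic stimuli and gaze data.

Everything the simulator and the analytics need can be generated here:
flicker image pairs with a single localized change (and identical catch
pairs), two-group human-like gaze logs whose groups differ in mean
fixation duration and saccade-amplitude variance, and a parametric
saccade amplitude/turn-angle bias table.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .policy import BiasDistribution
from .simulate import ImagePair

PX_PER_DEG = 30.0   # screen geometry assumed when converting amplitudes


# --------------------------------------------------------------------------
# flicker image pairs
# --------------------------------------------------------------------------

@dataclass
class SyntheticPairSpec:
    """Recipe for a textured scene with one localized change.

    ``contrast`` scales the magnitude of the change (0 produces a
    bitwise-identical catch pair); ``change_kind`` picks what changes:
    the size of an object, its color, or its appearance (presence).
    """

    width: int = 432
    height: int = 324
    change_kind: str = "color"          # 'size' | 'color' | 'appearance'
    change_center: Optional[Tuple[int, int]] = None   # (x, y); None = random
    change_radius: int = 18
    contrast: float = 0.25
    n_objects: int = 14
    texture_sigma: float = 12.0
    texture_amplitude: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.change_kind not in ("size", "color", "appearance"):
            raise ValueError(f"unknown change kind {self.change_kind!r}")
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float,
                color: np.ndarray) -> None:
    m = _disk_mask(img.shape[0], img.shape[1], cx, cy, r)
    img[m] = color


def make_change_pair(spec: SyntheticPairSpec) -> ImagePair:
    """A cluttered synthetic scene and its altered twin.

    The background is band-limited noise; a set of colored disks and
    rectangles provides saliency structure.  A target disk sits at the
    change center; A' modifies only that disk (never pixels outside the
    change region), and the returned mask marks exactly the altered
    pixels.  With ``contrast = 0`` the two images are bitwise identical.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # band-limited noise background around mid-gray
    noise = rng.normal(size=(h, w, 3))
    for c in range(3):
        noise[..., c] = ndimage.gaussian_filter(noise[..., c],
                                                spec.texture_sigma)
    noise /= max(np.abs(noise).max(), 1e-9)
    img = np.clip(0.5 + spec.texture_amplitude * noise, 0.0, 1.0)

    # clutter objects
    margin = 2 * spec.change_radius
    if spec.change_center is None:
        cx = float(rng.integers(margin, w - margin))
        cy = float(rng.integers(margin, h - margin))
    else:
        cx, cy = map(float, spec.change_center)
    if not (spec.change_radius <= cx < w - spec.change_radius
            and spec.change_radius <= cy < h - spec.change_radius):
        raise ValueError("change region must lie fully inside the image")

    for _ in range(spec.n_objects):
        for _attempt in range(50):
            ox = rng.uniform(0, w)
            oy = rng.uniform(0, h)
            orad = rng.uniform(4, 14)
            if np.hypot(ox - cx, oy - cy) > spec.change_radius + orad + 4:
                break
        # clutter stays mid-range so the change target can dominate saliency
        color = rng.uniform(0.2, 0.8, size=3)
        if rng.random() < 0.5:
            _paint_disk(img, ox, oy, orad, color)
        else:
            x0, y0 = int(ox), int(oy)
            dx, dy = int(orad), int(rng.uniform(4, 14))
            img[max(y0 - dy, 0):y0 + dy, max(x0 - dx, 0):x0 + dx] = color

    # the target object, centered in the change region: a saturated disk
    # far from the scene's mean color, hence highly salient
    scene_mean = img.reshape(-1, 3).mean(axis=0)
    base_r = 0.75 * spec.change_radius
    base_color = np.array([0.98, 0.04, 0.04])
    _paint_disk(img, cx, cy, base_r, base_color)

    a = img
    a_prime = a.copy()
    # every change kind moves the target's saliency (its conspicuity
    # against the scene) by an amount scaled by `contrast`
    k = min(spec.contrast, 1.0)
    if spec.contrast > 0:
        if spec.change_kind == "size":
            new_r = base_r * max(1.0 - 0.6 * k, 0.05)
            m = _disk_mask(h, w, cx, cy, base_r)
            keep = _disk_mask(h, w, cx, cy, new_r)
            ring = _disk_mask(h, w, cx, cy, spec.change_radius) & ~m
            bg = a[ring].mean(axis=0) if ring.any() else np.array([0.5] * 3)
            a_prime[m & ~keep] = bg
        elif spec.change_kind == "color":
            # shift toward the scene mean: the object stays but loses
            # conspicuity in proportion to the contrast
            new_color = (1.0 - k) * base_color + k * scene_mean
            _paint_disk(a_prime, cx, cy, base_r, new_color)
        else:  # appearance: fade the object into the local background
            m = _disk_mask(h, w, cx, cy, base_r)
            ring = _disk_mask(h, w, cx, cy, spec.change_radius) & ~m
            bg = a[ring].mean(axis=0) if ring.any() else np.array([0.5] * 3)
            a_prime[m] = (1.0 - k) * a[m] + k * bg

    mask = np.any(a != a_prime, axis=-1)
    if spec.contrast > 0 and not mask.any():
        import warnings
        warnings.warn("contrast too small to alter any pixel; pair is a "
                      "catch pair", stacklevel=2)
    return ImagePair(a=a, a_prime=a_prime, mask=mask,
                     pair_id=f"synt-{spec.change_kind}-{spec.seed}")


def make_catch_pair(spec: SyntheticPairSpec) -> ImagePair:
    """Identical image pair (contrast forced to zero)."""
    spec = SyntheticPairSpec(**{**spec.__dict__, "contrast": 0.0})
    return make_change_pair(spec)


def make_pair_battery(n_pairs: int, seed: int = 0,
                      contrast: float = 0.25,
                      width: int = 432, height: int = 324) -> list:
    """A mixed battery of change pairs cycling through the three kinds."""
    kinds = ("size", "color", "appearance")
    return [make_change_pair(SyntheticPairSpec(
        width=width, height=height, change_kind=kinds[i % 3],
        contrast=contrast, seed=seed + i)) for i in range(n_pairs)]


# --------------------------------------------------------------------------
# gaze logs
# --------------------------------------------------------------------------

@dataclass
class GazeRecord:
    """Eye-tracker-style log of one trial.

    ``fixations``: DataFrame (x_px, y_px, duration_ms, onset_ms);
    ``saccades``: DataFrame (amplitude_deg, duration_ms, peak_speed_deg_s).
    """

    subject_id: str
    trial_id: str
    image_id: str
    fixations: pd.DataFrame
    saccades: pd.DataFrame
    outcome: str = "miss"
    group: Optional[str] = None
    change_center: Optional[Tuple[float, float]] = None
    change_radius: Optional[float] = None


@dataclass
class SyntheticGazeSpec:
    """Two-group gaze-log generator settings.

    Group differences are confined to mean fixation duration (good
    performers fixate longer) and saccade-amplitude variance (poor
    performers saccade more erratically), mirroring the two gaze metrics
    that predict change-detection success.  Saccade duration and peak
    speed are tied to amplitude through a noisy main-sequence
    relationship, so they carry only diluted copies of the amplitude
    signal.
    """

    fd_mean_ms: Tuple[float, float] = (450.0, 350.0)     # (good, poor)
    fd_cv: float = 0.3
    sa_mean_deg: float = 10.0
    sa_var_deg2: Tuple[float, float] = (12.0, 24.0)      # (good, poor)
    sd_noise_ms: float = 15.0
    sps_noise_deg_s: float = 70.0
    n_subjects: Tuple[int, int] = (9, 12)
    n_trials: int = 19
    n_fixations_mean: int = 50
    image_size: Tuple[int, int] = (864, 648)             # (w, h) px
    seed: int = 0


def _reflect(v: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [0, upper] (triangular wrap)."""
    period = 2.0 * upper
    v = np.mod(v, period)
    return np.where(v > upper, period - v, v)


def _main_sequence(amplitude_deg: np.ndarray, rng: np.random.Generator,
                   sd_noise: float, sps_noise: float
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Saccade duration and peak speed from amplitude (main sequence).

    Duration grows linearly with amplitude; peak speed follows the
    saturating main-sequence law V = Vmax (1 - exp(-A / A0)) with
    Vmax = 500 deg/s and A0 = 6 deg, plus independent scatter.
    """
    dur = 21.0 + 2.2 * amplitude_deg + rng.normal(0, sd_noise,
                                                  amplitude_deg.size)
    spd = 500.0 * (1.0 - np.exp(-amplitude_deg / 6.0)) \
        + rng.normal(0, sps_noise, amplitude_deg.size)
    return np.maximum(dur, 1.0), np.maximum(spd, 1.0)


def make_gaze_logs(spec: SyntheticGazeSpec) -> List[GazeRecord]:
    """Two-group synthetic gaze logs (group labels 'good' / 'poor').

    Fixation durations are log-normal; saccade amplitudes gamma; gaze
    positions follow a bounded random walk whose step sizes are the
    saccade amplitudes (30 px per degree of visual angle).
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    records: List[GazeRecord] = []
    for g, group in enumerate(("good", "poor")):
        fd_mean = spec.fd_mean_ms[g]
        sa_var = spec.sa_var_deg2[g]
        sigma2 = np.log(1.0 + spec.fd_cv ** 2)
        mu_log = np.log(fd_mean) - sigma2 / 2.0
        shape = spec.sa_mean_deg ** 2 / sa_var
        scale = sa_var / spec.sa_mean_deg
        for s in range(spec.n_subjects[g]):
            sid = f"{group}{s:02d}"
            for tr in range(spec.n_trials):
                n_fix = max(int(rng.poisson(spec.n_fixations_mean)), 4)
                fd = rng.lognormal(mu_log, np.sqrt(sigma2), n_fix)
                sa = rng.gamma(shape, scale, n_fix - 1)
                sd, sps = _main_sequence(sa, rng, spec.sd_noise_ms,
                                         spec.sps_noise_deg_s)
                # random-walk positions driven by the amplitudes
                xy = np.empty((n_fix, 2))
                xy[0] = (w / 2.0, h / 2.0)
                angles = rng.uniform(0, 2 * np.pi, n_fix - 1)
                steps = np.column_stack([np.cos(angles), np.sin(angles)])
                for i in range(1, n_fix):
                    step = steps[i - 1] * sa[i - 1] * PX_PER_DEG
                    xy[i] = _reflect(xy[i - 1] + step,
                                     np.array([w - 1.0, h - 1.0]))
                onsets = np.concatenate([[0.0], np.cumsum(fd[:-1] + sd)])
                fixations = pd.DataFrame({
                    "x_px": xy[:, 0], "y_px": xy[:, 1],
                    "duration_ms": fd, "onset_ms": onsets,
                })
                saccades = pd.DataFrame({
                    "amplitude_deg": sa, "duration_ms": sd,
                    "peak_speed_deg_s": sps,
                })
                records.append(GazeRecord(
                    subject_id=sid, trial_id=f"{sid}-t{tr:02d}",
                    image_id=f"img{tr:02d}", fixations=fixations,
                    saccades=saccades, group=group))
    return records


GAZE_CSV_COLUMNS = ["subject_id", "trial_id", "image_id", "event_type",
                    "x_px", "y_px", "duration_ms", "onset_ms",
                    "amplitude_deg", "peak_speed_deg_s", "group"]


def write_gaze_csv(records: List[GazeRecord], path) -> None:
    """Tidy event-stream CSV: one row per fixation or saccade."""
    rows = []
    for rec in records:
        for _, f in rec.fixations.iterrows():
            rows.append([rec.subject_id, rec.trial_id, rec.image_id,
                         "fixation", f.x_px, f.y_px, f.duration_ms,
                         f.get("onset_ms", np.nan), np.nan, np.nan, rec.group])
        for _, s in rec.saccades.iterrows():
            rows.append([rec.subject_id, rec.trial_id, rec.image_id,
                         "saccade", np.nan, np.nan, s.duration_ms, np.nan,
                         s.amplitude_deg, s.peak_speed_deg_s, rec.group])
    pd.DataFrame(rows, columns=GAZE_CSV_COLUMNS).to_csv(path, index=False)


def read_gaze_csv(path) -> List[GazeRecord]:
    df = pd.read_csv(path)
    records = []
    for (sid, tid, iid), grp in df.groupby(["subject_id", "trial_id",
                                            "image_id"], sort=False):
        fix = grp[grp.event_type == "fixation"]
        sac = grp[grp.event_type == "saccade"]
        group = grp["group"].iloc[0] if "group" in grp else None
        records.append(GazeRecord(
            subject_id=str(sid), trial_id=str(tid), image_id=str(iid),
            fixations=fix[["x_px", "y_px", "duration_ms",
                           "onset_ms"]].reset_index(drop=True),
            saccades=sac[["amplitude_deg", "duration_ms",
                          "peak_speed_deg_s"]].reset_index(drop=True),
            group=None if pd.isna(group) else str(group)))
    return records


# --------------------------------------------------------------------------
# saccade bias
# --------------------------------------------------------------------------

def make_bias_distribution(short_amplitude_weight: float = 0.15,
                           forward_backward_weight: float = 0.6,
                           max_amplitude: float = 40.0,
                           n_amplitude_bins: int = 20,
                           n_angle_bins: int = 24) -> BiasDistribution:
    """Parametric stand-in for the human saccade amplitude/angle bias.

    Amplitude mass decays exponentially (rate = short_amplitude_weight
    per grid unit; 0 gives a flat marginal); the turn-angle marginal is
    1 + w*cos(2*theta), bimodal at 0 deg (forward) and 180 deg (return
    saccades) with a trough at +-90 deg.  Zero weights give a uniform
    density.  The tabulated masses sum to 1.
    """
    if short_amplitude_weight < 0 or forward_backward_weight < 0:
        raise ValueError("bias weights must be >= 0")
    amp_edges = np.linspace(0.0, max_amplitude, n_amplitude_bins + 1)
    ang_edges = np.linspace(-180.0, 180.0, n_angle_bins + 1)
    amp_mid = 0.5 * (amp_edges[:-1] + amp_edges[1:])
    ang_mid = 0.5 * (ang_edges[:-1] + ang_edges[1:])
    f_amp = np.exp(-short_amplitude_weight * amp_mid)
    w = forward_backward_weight
    f_ang = 1.0 + (w / (1.0 + w)) * np.cos(2.0 * np.radians(ang_mid))
    density = np.outer(f_amp, f_ang)
    return BiasDistribution(amp_edges, ang_edges, density)
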