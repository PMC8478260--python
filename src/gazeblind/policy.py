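"""Saccade target selection.

The next fixation is drawn from a temperature-controlled softmax over
the accumulated evidence map.  Following the model, the exponential is
replaced by its third-order Taylor polynomial (clipped below at zero),
which saturates more softly than the true exponential; human saccade
amplitude/turn-angle biases can be imposed multiplicatively on the
resulting weights.  A separate inhibition-of-return (IOR) sampler turns
a bare saliency map into a saccade policy for baseline comparisons with
saliency-only gaze models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .image_pipeline import GridSpec


def taylor_exp(x: np.ndarray) -> np.ndarray:
    """Third-order Taylor approximation of exp, clipped below at 0."""
    x = np.asarray(x, dtype=float)
    return np.clip(1.0 + x + x ** 2 / 2.0 + x ** 3 / 6.0, 0.0, None)


def softmax_probabilities(evidence: np.ndarray, temperature: float) -> np.ndarray:
    """Saccade probabilities p_i from evidence via the clipped-Taylor softmax.

    Weights w_i = taylor3(E_i / T); if every weight clips to zero the
    distribution falls back to uniform (the observer has no positive
    evidence anywhere and explores at random).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    w = taylor_exp(np.asarray(evidence, dtype=float) / temperature)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        return np.full(w.shape, 1.0 / w.size)
    return w / total


@dataclass
class BiasDistribution:
    """Tabulated joint density of saccade amplitude and turn angle.

    ``density[i, j]`` is the probability mass of amplitude bin ``i``
    (grid units, edges in ``amplitude_edges``) and turn-angle bin ``j``
    (degrees in (-180, 180], edges in ``angle_edges``); masses sum to 1.
    """

    amplitude_edges: np.ndarray
    angle_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude_edges = np.asarray(self.amplitude_edges, dtype=float)
        self.angle_edges = np.asarray(self.angle_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("bias density must be non-negative")
        total = self.density.sum()
        if total > 0:
            self.density = self.density / total

    def density_at(self, amplitude: np.ndarray,
                   angle_deg: Optional[np.ndarray]) -> np.ndarray:
        """Look up bin mass at the given amplitudes (and angles).

        With ``angle_deg=None`` the amplitude marginal is used (first
        saccade of a trial, when no previous direction exists).
        Amplitudes outside the tabulated range get zero mass.
        """
        amplitude = np.asarray(amplitude, dtype=float)
        ai = np.searchsorted(self.amplitude_edges, amplitude, side="right") - 1
        valid = (ai >= 0) & (ai < self.density.shape[0]) & (amplitude > 0)
        ai = np.clip(ai, 0, self.density.shape[0] - 1)
        if angle_deg is None:
            marg = self.density.sum(axis=1)
            out = marg[ai]
        else:
            angle = np.asarray(angle_deg, dtype=float)
            # wrap into (-180, 180]
            angle = np.mod(angle + 180.0, 360.0) - 180.0
            angle[angle == -180.0] = 180.0
            ji = np.searchsorted(self.angle_edges, angle, side="right") - 1
            ji = np.clip(ji, 0, self.density.shape[1] - 1)
            out = self.density[ai, ji]
        return np.where(valid, out, 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (amplitude_bin, angle_bin, density)."""
        amp_idx, ang_idx = np.meshgrid(
            np.arange(self.density.shape[0]),
            np.arange(self.density.shape[1]), indexing="ij")
        return pd.DataFrame({
            "amplitude_lo": self.amplitude_edges[:-1][amp_idx.ravel()],
            "amplitude_hi": self.amplitude_edges[1:][amp_idx.ravel()],
            "angle_lo": self.angle_edges[:-1][ang_idx.ravel()],
            "angle_hi": self.angle_edges[1:][ang_idx.ravel()],
            "density": self.density.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiasDistribution":
        df = pd.read_csv(path)
        amp_edges = np.unique(np.concatenate([df["amplitude_lo"], df["amplitude_hi"]]))
        ang_edges = np.unique(np.concatenate([df["angle_lo"], df["angle_hi"]]))
        density = np.zeros((amp_edges.size - 1, ang_edges.size - 1))
        ai = np.searchsorted(amp_edges, df["amplitude_lo"].to_numpy())
        ji = np.searchsorted(ang_edges, df["angle_lo"].to_numpy())
        density[ai, ji] = df["density"].to_numpy()
        return cls(amp_edges, ang_edges, density)


def saccade_geometry(grid: GridSpec, current_fix: int,
                     prev_fix: Optional[int]) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Amplitude (grid units) and turn angle (deg) of every candidate saccade.

    The turn angle is measured between the previous saccade vector
    (prev_fix -> current_fix) and the candidate vector
    (current_fix -> candidate), in (-180, 180].  Without a previous
    fixation the angles are undefined and ``None`` is returned.
    """
    centers = grid.centers_grid()
    vec = centers - centers[current_fix]
    amplitude = np.hypot(vec[:, 0], vec[:, 1])
    if prev_fix is None or prev_fix == current_fix:
        return amplitude, None
    prev_vec = centers[current_fix] - centers[prev_fix]
    prev_angle = np.arctan2(prev_vec[1], prev_vec[0])
    cand_angle = np.arctan2(vec[:, 1], vec[:, 0])
    turn = np.degrees(cand_angle - prev_angle)
    turn = np.mod(turn + 180.0, 360.0) - 180.0
    turn[turn == -180.0] = 180.0
    return amplitude, turn


def apply_saccade_bias(weights: np.ndarray, grid: GridSpec, current_fix: int,
                       prev_fix: Optional[int],
                       bias: BiasDistribution) -> np.ndarray:
    """Multiply saccade weights by the human amplitude/turn-angle bias.

    The bias multiplies the post-Taylor softmax weights (multiplying the
    signed evidence itself by a density would flip signs); the result is
    renormalised.  If the bias annihilates every candidate the original
    weights are returned unchanged.
    """
    amplitude, turn = saccade_geometry(grid, current_fix, prev_fix)
    dens = bias.density_at(amplitude, turn)
    out = np.asarray(weights, dtype=float) * dens
    total = out.sum()
    if total <= 0:
        return np.asarray(weights, dtype=float)
    return out / total


def sample_next_fixation(probabilities: np.ndarray,
                         rng: np.random.Generator) -> int:
    """Draw a region index from a categorical saccade distribution."""
    p = np.asarray(probabilities, dtype=float)
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("degenerate saccade probabilities")
    return int(rng.choice(p.size, p=p / total))


def ior_saliency_step(saliency: np.ndarray, ior: np.ndarray,
                      fixation_xy: Tuple[float, float], t: int,
                      temperature: float, sigma_px: float = 20.0,
                      ramp_rate: float = 0.05,
                      discount: float = 0.25) -> Tuple[np.ndarray, np.ndarray]:
    """One step of the saliency + inhibition-of-return baseline sampler.

    The IOR map accumulates a Gaussian patch (sigma 20 px) at the
    current fixation, scaled by a tanh ramp in trial time and discounted
    by 0.25 per step, then is clipped to [0, 1]:

        IOR(t) = clip(0.25 * IOR(t-1) + tanh(0.05 t) * G, 0, 1)

    Saccade weights are (1 - IOR) * saliency, passed through the same
    clipped-Taylor softmax (same temperature) as the SPRT model.
    Returns (per-pixel probabilities flattened row-major, new IOR map).
    """
    saliency = np.asarray(saliency, dtype=float)
    h, w = saliency.shape
    x0, y0 = fixation_xy
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma_px ** 2))
    new_ior = np.clip(discount * np.asarray(ior, dtype=float)
                      + np.tanh(ramp_rate * t) * g, 0.0, 1.0)
    weights = (1.0 - new_ior) * saliency
    probs = softmax_probabilities(weights.ravel(), temperature)
    return probs, new_ior
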