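"""Model parameter container for the SPRT change-detection observer.

All temporal quantities are expressed in discrete time bins of ``dt``
seconds (25 ms by default), matching the flicker schedule of the task:
each image and each intervening blank is shown for ``image_bins`` bins
(250 ms at defaults) and a trial lasts ``trial_bins`` bins (60 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml


@dataclass(frozen=True)
class ModelParams:
    """Default parameters of the neurally-constrained SPRT observer.

    Attributes
    ----------
    dt : float
        Duration of one time bin, seconds.
    image_bins : int
        Number of bins each image (A or A') is displayed per epoch.
    blank_bins : int
        Number of bins of each intervening blank.
    trial_bins : int
        Total trial length in bins (2400 bins = 60 s at defaults).
    temperature : float
        Softmax temperature T controlling saccade stochasticity.
    gamma : float
        Peak evidence decay factor at the fixated region (larger =
        faster decay, i.e. leakier accumulation).
    beta_decay : float
        Spatial scale (grid units) of the Gaussian decay field.
    noise_half_width : float
        Half-width w of the uniform accumulation noise W ~ U(-w, w).
    prior_odds : float
        Prior odds ratio P of change to no change.
    f_c : float
        Positive evidence threshold for signalling a change.
    f_n : float
        Negative evidence threshold for terminating a fixation.
    zeta : float
        Exponential decay rate of the no-change threshold within a
        fixation (0 keeps F_n constant).
    fmf : float
        Foveal magnification factor (the CVR constant beta).
    lambda_min, lambda_max : float
        Firing-rate bounds, spikes per bin, mapped linearly from mean
        region saliency.
    mu_f : float
        Prior expected firing-rate difference at the change region,
        spikes per bin.
    patch_px : int
        Side of one square grid region, pixels.
    cvr_scale : float or None
        CVR scale factors S_fx = S_fy.  ``None`` derives the value from
        the image width as 200 * width / 864, which keeps the foveal
        coverage fraction of the warp invariant when simulating at
        reduced image sizes.
    saliency_sigma : float
        Gaussian blur sigma (pixels) of the frequency-tuned saliency
        computation.
    prior_every_bin : bool
        If True, add log P on every bin instead of only on bins where a
        likelihood is evaluated.
    check_all_regions : bool
        If True, test the change threshold at every region each bin
        instead of only at the fixated region.
    noise_shared : bool
        If True, draw a single noise value per bin shared by all
        regions instead of independent per-region draws.
    """

    dt: float = 0.025
    image_bins: int = 10
    blank_bins: int = 10
    trial_bins: int = 2400
    temperature: float = 0.01
    gamma: float = 0.004
    beta_decay: float = 4.0
    noise_half_width: float = 5.0
    prior_odds: float = 0.1
    f_c: float = 100.0
    f_n: float = -20.0
    zeta: float = 0.0
    fmf: float = 0.05
    lambda_min: float = 5.0
    lambda_max: float = 120.0
    mu_f: float = 3.0
    patch_px: int = 12
    cvr_scale: Optional[float] = None
    saliency_sigma: float = 1.6
    prior_every_bin: bool = False
    check_all_regions: bool = False
    noise_shared: bool = False

    def __post_init__(self) -> None:
        if not self.f_n < 0 < self.f_c:
            raise ValueError("thresholds must satisfy F_n < 0 < F_c")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.prior_odds <= 0:
            raise ValueError("prior odds must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.lambda_min >= self.lambda_max:
            raise ValueError("lambda_min must be below lambda_max")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def cvr_scale_for_width(self, width_px: int) -> float:
        """CVR scale factor for an image of the given width."""
        if self.cvr_scale is not None:
            return self.cvr_scale
        return 200.0 * width_px / 864.0

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
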