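"""Foveated image representation: grid partition, CVR warp, saliency, rates.

The observer never sees raw pixels.  At each fixation the image is
warped by a Cartesian variable resolution (CVR) transform that magnifies
the fixated region and compresses the periphery, a bottom-up saliency
map is computed on the warped image, and the mean saliency of each grid
region is mapped linearly onto a Poisson firing rate.  Evidence computed
on the warped grid is projected back to the original image grid by
mapping each original region center through the forward warp.

Conventions (used everywhere in the package): pixel coordinates are
0-based with origin at the top-left, ``x`` runs along image width
(columns) and ``y`` along height (rows); grid regions are indexed
row-major, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab


# --------------------------------------------------------------------------
# grid partition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A uniform partition of an image into square, non-overlapping patches."""

    patch_px: int
    n_cols: int
    n_rows: int

    @property
    def n_regions(self) -> int:
        return self.n_cols * self.n_rows

    def region_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def region_rowcol(self, index: int) -> Tuple[int, int]:
        return divmod(index, self.n_cols)

    def centers_px(self) -> np.ndarray:
        """(n_regions, 2) array of (x, y) region-center pixel coordinates."""
        rows, cols = np.divmod(np.arange(self.n_regions), self.n_cols)
        x = (cols + 0.5) * self.patch_px
        y = (rows + 0.5) * self.patch_px
        return np.column_stack([x, y])

    def centers_grid(self) -> np.ndarray:
        """(n_regions, 2) array of (col, row) centers in grid units."""
        rows, cols = np.divmod(np.arange(self.n_regions), self.n_cols)
        return np.column_stack([cols, rows]).astype(float)


def partition_grid(width_px: int, height_px: int, patch_px: int = 12) -> GridSpec:
    """Partition a ``width_px`` x ``height_px`` image into square patches.

    The number of columns/rows is ``floor(width/patch)`` /
    ``floor(height/patch)``; an 864x648 image with 12-px patches yields
    the default 72x54 grid (3888 regions).  Portrait images naturally
    obtain the swapped grid resolution.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    if width_px < patch_px or height_px < patch_px:
        raise ValueError(
            f"patch ({patch_px}px) larger than image ({width_px}x{height_px})"
        )
    return GridSpec(patch_px=patch_px,
                    n_cols=width_px // patch_px,
                    n_rows=height_px // patch_px)


# --------------------------------------------------------------------------
# Cartesian variable resolution (CVR) transform
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVRParams:
    """Parameters of the CVR (foveal magnification) warp.

    ``beta`` is the foveal magnification constant (FMF); ``s_fx``/``s_fy``
    scale the warped offsets; ``center`` is the fixated pixel (x0, y0).
    The local magnification at the center is beta * s_f.
    """

    beta: float
    s_fx: float
    s_fy: float
    center: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.s_fx <= 0 or self.s_fy <= 0:
            raise ValueError("beta and scale factors must be positive")


def cvr_offset(d: np.ndarray, beta: float, s_f: float) -> np.ndarray:
    """Forward CVR offset: dv = sign(d) * ln(beta*|d| + 1) * s_f.

    Odd in ``d`` and strictly increasing in |d|; dv(0) = 0 and the
    derivative at the origin equals beta * s_f (the central
    magnification).
    """
    d = np.asarray(d, dtype=float)
    return np.sign(d) * np.log(beta * np.abs(d) + 1.0) * s_f


def cvr_offset_inverse(dv: np.ndarray, beta: float, s_f: float) -> np.ndarray:
    """Inverse of :func:`cvr_offset`: |d| = (exp(|dv|/s_f) - 1) / beta."""
    dv = np.asarray(dv, dtype=float)
    return np.sign(dv) * (np.expm1(np.abs(dv) / s_f)) / beta


def cvr_forward(image: np.ndarray, params: CVRParams) -> np.ndarray:
    """Warp an image so the region around ``params.center`` is magnified.

    The output is resampled onto the original pixel lattice by inverse
    mapping with bilinear interpolation; source coordinates outside the
    image are clipped to its bounds (the far periphery is therefore
    compressed into the frame border).
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    x0, y0 = params.center
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError(f"fixation center {params.center} outside image bounds")

    # inverse-map each output pixel to its source location
    dv_x = np.arange(w, dtype=float) - x0
    dv_y = np.arange(h, dtype=float) - y0
    src_x = np.clip(x0 + cvr_offset_inverse(dv_x, params.beta, params.s_fx), 0, w - 1)
    src_y = np.clip(y0 + cvr_offset_inverse(dv_y, params.beta, params.s_fy), 0, h - 1)
    grid_y, grid_x = np.meshgrid(src_y, src_x, indexing="ij")
    coords = np.stack([grid_y.ravel(), grid_x.ravel()])

    if image.ndim == 2:
        out = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        return out.reshape(h, w)
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            image[..., c], coords, order=1, mode="nearest"
        ).reshape(h, w)
    return out


def cvr_projection_map(params: CVRParams, grid: GridSpec,
                       return_support: bool = False):
    """Index map from original-space regions into CVR-space regions.

    Entry ``i`` is the index of the warped-grid region into which the
    center of original region ``i`` falls under the forward transform
    (coordinates clipped to the frame).  Used to project per-region
    quantities computed on the warped image back into original image
    space; the fixated region is a fixed point of this map.

    With ``return_support`` a boolean mask is also returned marking the
    regions whose centers project strictly inside the frame: because
    the warp magnifies the fovea, content beyond a coverage radius is
    pushed past the frame border and is not represented in the warped
    image at all.  Those unsupported regions carry no likelihood
    evidence (L = 1) during a fixation at this center.
    """
    centers = grid.centers_px()
    x0, y0 = params.center
    vx = x0 + cvr_offset(centers[:, 0] - x0, params.beta, params.s_fx)
    vy = y0 + cvr_offset(centers[:, 1] - y0, params.beta, params.s_fy)
    w = grid.n_cols * grid.patch_px
    h = grid.n_rows * grid.patch_px
    support = (vx >= 0) & (vx < w) & (vy >= 0) & (vy < h)
    col = np.clip((vx // grid.patch_px).astype(int), 0, grid.n_cols - 1)
    row = np.clip((vy // grid.patch_px).astype(int), 0, grid.n_rows - 1)
    proj = row * grid.n_cols + col
    if return_support:
        return proj, support
    return proj


def cvr_inverse_project(values_cvr: np.ndarray, params: CVRParams,
                        grid: GridSpec) -> np.ndarray:
    """Project a per-region map from CVR space back to original space.

    Each original-space region receives the value of the CVR-space
    region its center maps into under the forward transform.  A constant
    map is therefore projected onto itself.
    """
    flat = np.asarray(values_cvr).reshape(-1)
    if flat.size != grid.n_regions:
        raise ValueError("values_cvr size does not match grid")
    proj = cvr_projection_map(params, grid)
    return flat[proj].reshape(np.shape(values_cvr))


# --------------------------------------------------------------------------
# frequency-tuned saliency and firing rates
# --------------------------------------------------------------------------

def compute_saliency(image: np.ndarray, sigma: float = 1.6) -> np.ndarray:
    """Frequency-tuned salient-region detection.

    Per-pixel saliency is the Euclidean distance, in CIE-Lab space,
    between the image's global mean Lab vector and the Gaussian-blurred
    Lab image, min-max normalised to [0, 1].  A uniform image (where the
    blurred image equals the mean everywhere) yields all-zero saliency.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    lab = rgb2lab(np.clip(image, 0.0, 1.0))
    mean_vec = lab.reshape(-1, 3).mean(axis=0)
    blurred = np.empty_like(lab)
    for c in range(3):
        blurred[..., c] = ndimage.gaussian_filter(lab[..., c], sigma=sigma,
                                                  mode="nearest")
    sal = np.sqrt(((blurred - mean_vec) ** 2).sum(axis=-1))
    lo, hi = sal.min(), sal.max()
    if hi - lo < 1e-12:
        return np.zeros_like(sal)
    return (sal - lo) / (hi - lo)


def region_means(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Mean of a per-pixel map over each grid region (row-major flat)."""
    p = grid.patch_px
    v = values[: grid.n_rows * p, : grid.n_cols * p]
    blocks = v.reshape(grid.n_rows, p, grid.n_cols, p)
    return blocks.mean(axis=(1, 3)).reshape(-1)


def read_image(path) -> np.ndarray:
    """Load a PNG/JPEG image as an H x W x 3 float array in [0, 1]."""
    from PIL import Image
    return np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0


def save_map_png(values: np.ndarray, path) -> None:
    """Write a scalar map as an 8-bit grayscale PNG (min-max scaled)."""
    from PIL import Image
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    Image.fromarray((scaled * 255).astype(np.uint8)).save(path)


def region_map_to_csv(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write a per-region map as CSV with columns row, col, value."""
    flat = np.asarray(values).reshape(-1)
    if flat.size != grid.n_regions:
        raise ValueError("map size does not match grid")
    rows, cols = np.divmod(np.arange(grid.n_regions), grid.n_cols)
    with open(path, "w") as fh:
        fh.write("row,col,value\n")
        for r, c, v in zip(rows, cols, flat):
            fh.write(f"{r},{c},{float(v)!r}\n")


def region_map_from_csv(path, grid: GridSpec) -> np.ndarray:
    """Read a per-region map written by :func:`region_map_to_csv`."""
    out = np.zeros(grid.n_regions)
    with open(path) as fh:
        next(fh)
        for line in fh:
            r, c, v = line.strip().split(",")
            out[int(r) * grid.n_cols + int(c)] = float(v)
    return out


def saliency_to_rates(saliency: np.ndarray, grid: GridSpec,
                      lambda_min: float = 5.0,
                      lambda_max: float = 120.0) -> np.ndarray:
    """Map mean region saliency linearly onto Poisson rates (spikes/bin).

    lambda_i = lambda_min + (lambda_max - lambda_min) * <S_ik>, where the
    angle brackets average saliency over the pixels of region i.
    """
    if lambda_min >= lambda_max:
        raise ValueError("lambda_min must be below lambda_max")
    means = region_means(np.asarray(saliency, dtype=float), grid)
    return lambda_min + (lambda_max - lambda_min) * means
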