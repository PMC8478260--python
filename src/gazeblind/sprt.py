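"""Poisson spike generation, change/no-change likelihood ratio, evidence.

The observer compares spike counts X (first image of the current cycle,
m bins) and Y (second image, q bins) via their difference Z = Y - X.
Under "no change" both counts share the estimated rate lambda, so Z is
Skellam-distributed with means (q*lambda, m*lambda).  Under "change" the
two rates differ by an a-priori expected amount mu_f with unknown sign,
giving an equal-probability mixture of two Skellam laws.  The Skellam
pmf requires the modified Bessel function of the first kind; it is
evaluated through the exponentially scaled ``scipy.special.ive`` with
asymptotic fallbacks where the scaled form underflows.

The accumulated log posterior odds at region i evolves as

    E_i(t) = (1 - gamma_i) E_i(t-1) + log L_i(t) + log P + W_i(t)

with a Gaussian spatial decay field gamma_i peaked at the fixated
region and uniform accumulation noise W.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, ive

from .image_pipeline import GridSpec

_LOG2 = np.log(2.0)
_RATE_FLOOR = 1e-6  # clamp for the change-hypothesis rate lambda - mu_f


# --------------------------------------------------------------------------
# Bessel evaluation
# --------------------------------------------------------------------------

def log_iv_large_x(order: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log I_order(x) for large argument x:

    I_z(x) ~ e^x / sqrt(2 pi x) * (1 - (4 z^2 - 1) / (8 x)).
    """
    order = np.asarray(order, dtype=float)
    x = np.asarray(x, dtype=float)
    corr = 1.0 - (4.0 * order ** 2 - 1.0) / (8.0 * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        return x - 0.5 * np.log(2.0 * np.pi * x) + np.log(np.maximum(corr, 1e-300))


def log_iv_large_order(order: np.ndarray, x: np.ndarray) -> np.ndarray:
    """log I_order(x) for order dominating argument:

    I_z(x) ~ (x/2)^z / Gamma(z + 1).
    """
    order = np.asarray(order, dtype=float)
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return order * np.log(x / 2.0) - gammaln(order + 1.0)


def log_iv(order, x) -> np.ndarray:
    """log of the modified Bessel function I_order(x), order >= 0, x >= 0.

    Primary path is the exponentially scaled evaluation
    ``log(ive(order, x)) + x``, which is stable for large x.  Where the
    scaled value underflows to 0 (order overwhelmingly larger than x)
    the asymptotic forms take over: the large-order form when
    order^2 > x, the large-x form otherwise.
    """
    order = np.asarray(order, dtype=float)
    x = np.asarray(x, dtype=float)
    order, x = np.broadcast_arrays(order, x)
    scaled = ive(order, x)
    out = np.full(scaled.shape, -np.inf)
    ok = scaled > 0
    with np.errstate(divide="ignore"):
        out[ok] = np.log(scaled[ok]) + x[ok]
    bad = ~ok & (x > 0)
    if np.any(bad):
        use_order = bad & (order ** 2 > x)
        use_x = bad & ~use_order
        out[use_order] = log_iv_large_order(order[use_order], x[use_order])
        out[use_x] = log_iv_large_x(order[use_x], x[use_x])
    # x == 0: I_0(0) = 1, I_z(0) = 0 for z > 0
    zero = (x == 0) & (order == 0)
    out[zero] = 0.0
    return out


def bessel_series(c, z) -> np.ndarray:
    """Closed form of the series sum_{y>=0} c^y / (y! (y+z)!).

    Equals c^(-z/2) * I_z(2 sqrt(c)); this is the identity used to
    collapse the infinite sums in the likelihood-ratio closed forms.
    """
    c = np.asarray(c, dtype=float)
    z = np.asarray(z, dtype=float)
    return np.exp(-0.5 * z * np.log(c) + log_iv(z, 2.0 * np.sqrt(c)))


# --------------------------------------------------------------------------
# Skellam and the change/no-change log-likelihood ratio
# --------------------------------------------------------------------------

def log_skellam_pmf(z, mu1, mu2) -> np.ndarray:
    """log P(N1 - N2 = z) for independent N1~Poisson(mu1), N2~Poisson(mu2).

    log pmf = -(mu1+mu2) + (z/2) (log mu1 - log mu2) + log I_|z|(2 sqrt(mu1 mu2))
    """
    z = np.asarray(z, dtype=float)
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    x = 2.0 * np.sqrt(mu1 * mu2)
    return (-(mu1 + mu2)
            + 0.5 * z * (np.log(mu1) - np.log(mu2))
            + log_iv(np.abs(z), x))


def log_likelihood_ratio(z, lam, mu_f: float, m: int, q: int) -> np.ndarray:
    """log likelihood ratio of change vs no change for count difference z.

    ``z`` is the (integer) spike-count difference Y - X between the q
    bins on the second image and the m bins on the first; ``lam`` is the
    running rate estimate (X + Y) / (m + q) in spikes per bin.  The
    change hypothesis is an equal mixture of the rate pairs
    (lam+mu_f, lam-mu_f) and (lam-mu_f, lam+mu_f); a change-hypothesis
    rate below zero is clamped at a small positive floor.
    With mu_f = 0 the hypotheses coincide and the result is exactly 0.
    """
    z_arr = np.asarray(z)
    if not np.issubdtype(z_arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(z_arr, 1), 0)):
            raise ValueError("spike-count difference z must be integer")
    z_arr = z_arr.astype(float)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rate estimate lambda must be positive")
    if m < 1 or q < 1:
        raise ValueError("need at least one bin on each image (m, q >= 1)")

    lam_hi = lam + mu_f
    lam_lo = np.maximum(lam - mu_f, _RATE_FLOOR)
    log_p_null = log_skellam_pmf(z_arr, q * lam, m * lam)
    # branch 1: first image at lam+mu_f, second at lam-mu_f (Z = Y - X)
    log_p1 = log_skellam_pmf(z_arr, q * lam_lo, m * lam_hi)
    log_p2 = log_skellam_pmf(z_arr, q * lam_hi, m * lam_lo)
    return np.logaddexp(log_p1, log_p2) - _LOG2 - log_p_null


# --------------------------------------------------------------------------
# spikes, decay field, evidence update, thresholds
# --------------------------------------------------------------------------

def draw_spikes(rates: np.ndarray, n_bins: int,
                rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts, shape (n_bins, n_regions)."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("firing rates must be non-negative")
    return rng.poisson(rates, size=(n_bins, rates.size))


def decay_field(fixated_region: int, gamma: float, beta_decay: float,
                grid: GridSpec) -> np.ndarray:
    """Per-region decay gamma_i = gamma * exp(-d^2 / (2 beta^2)).

    ``d`` is the Euclidean distance in grid units from the fixated
    region's center; the field peaks (value gamma) at the fixated
    region and vanishes far away, so evidence leaks fastest where the
    observer is currently looking.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if beta_decay <= 0:
        raise ValueError("beta_decay must be positive")
    centers = grid.centers_grid()
    fx = centers[fixated_region]
    d2 = ((centers - fx) ** 2).sum(axis=1)
    return gamma * np.exp(-d2 / (2.0 * beta_decay ** 2))


def update_evidence(evidence: np.ndarray, log_l: np.ndarray | float,
                    prior_odds: float, decay: np.ndarray,
                    noise_half_width: float,
                    rng: np.random.Generator | None = None,
                    shared_noise: bool = False,
                    include_prior: bool = True) -> np.ndarray:
    """One Euler step of leaky, noisy log-posterior-odds accumulation.

    E <- (1 - gamma_i) E + log L_i + log P + W_i,  W_i ~ U(-w, w).

    ``log_l`` may be 0 (no likelihood support this bin); in that case
    callers normally also pass ``include_prior=False`` so that the prior
    only enters on bins where a likelihood is evaluated.
    """
    evidence = np.asarray(evidence, dtype=float)
    out = (1.0 - np.asarray(decay, dtype=float)) * evidence
    out = out + log_l
    if include_prior:
        out = out + np.log(prior_odds)
    if noise_half_width > 0 and rng is not None:
        if shared_noise:
            out = out + rng.uniform(-noise_half_width, noise_half_width)
        else:
            out = out + rng.uniform(-noise_half_width, noise_half_width,
                                    size=out.shape)
    return out


def threshold_schedule(f_n: float, zeta: float, t_bins: int) -> float:
    """No-change threshold after ``t_bins`` bins of the current fixation.

    |F_n(t)| = |F_n| * exp(-zeta * t); zeta = 0 keeps the threshold
    constant, larger zeta collapses it toward zero, breaking fixations
    sooner.
    """
    if zeta < 0:
        raise ValueError("zeta must be non-negative")
    return f_n * np.exp(-zeta * t_bins)


def check_thresholds(e_fixated: float, f_c: float, f_n_t: float) -> str:
    """Classify the fixated-region evidence against the decision bounds."""
    if not f_n_t < 0 < f_c:
        raise ValueError("thresholds must satisfy F_n(t) < 0 < F_c")
    if e_fixated >= f_c:
        return "detect"
    if e_fixated <= f_n_t:
        return "break_fixation"
    return "continue"
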