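"""Full flicker-trial simulation, control models and parameter sweeps.

A trial presents alternating images A and A' separated by blanks (the
flicker schedule).  At each fixation the pair is foveally warped and
converted to per-region Poisson rates; spikes accumulate into per-cycle
counts X (first image) and Y (second image); each second-image bin
contributes a change/no-change log-likelihood ratio that is projected
back to original image space and accumulated as leaky, noisy evidence.
Crossing the positive bound F_c at the fixated region signals the
change; crossing the negative bound F_n(t) breaks the fixation and the
softmax policy picks the next target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .image_pipeline import (CVRParams, GridSpec, cvr_forward,
                             cvr_projection_map, partition_grid, region_means)
from .params import ModelParams
from .policy import (BiasDistribution, apply_saccade_bias,
                     sample_next_fixation, softmax_probabilities)
from .sprt import (check_thresholds, decay_field, log_likelihood_ratio,
                   threshold_schedule)
from scipy import ndimage
from skimage.color import rgb2lab


# --------------------------------------------------------------------------
# stimuli
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagePair:
    """An original image, its altered version, and the ground-truth mask.

    ``mask`` marks the changed pixels (all-False for catch pairs).
    Images are H x W x 3 float arrays with intensities in [0, 1].
    """

    a: np.ndarray
    a_prime: np.ndarray
    mask: Optional[np.ndarray] = None
    pair_id: str = "pair"

    def __post_init__(self) -> None:
        if self.a.shape != self.a_prime.shape:
            raise ValueError("image pair must have matching shapes")

    @property
    def width(self) -> int:
        return self.a.shape[1]

    @property
    def height(self) -> int:
        return self.a.shape[0]

    @property
    def is_catch(self) -> bool:
        return self.mask is None or not bool(self.mask.any())


@dataclass(frozen=True)
class StimulusSchedule:
    """Flicker schedule: A, blank, A', blank, repeated for trial_bins."""

    image_bins: int
    blank_bins: int
    trial_bins: int

    def kinds(self) -> np.ndarray:
        """Per-bin stimulus code: 0 = A, 1 = blank, 2 = A', for the trial."""
        cycle = ([0] * self.image_bins + [1] * self.blank_bins
                 + [2] * self.image_bins + [1] * self.blank_bins)
        if not cycle:
            raise ValueError("empty stimulus cycle")
        reps = int(np.ceil(self.trial_bins / len(cycle)))
        return np.tile(np.array(cycle, dtype=np.int8), reps)[: self.trial_bins]


# --------------------------------------------------------------------------
# per-fixation foveated representation, cached per fixation center
# --------------------------------------------------------------------------

def _saliency_from_lab(lab: np.ndarray, sigma: float) -> np.ndarray:
    """Frequency-tuned saliency from a Lab image (see compute_saliency)."""
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


class FoveationCache:
    """Per-fixation rate maps and back-projection maps for one image pair.

    For a fixation at a region center the cache stores the Poisson rate
    vectors of both images (computed from the saliency of the
    CVR-warped image) and the index map projecting warped-grid values
    back to original-grid regions.  Entries are computed lazily; the Lab
    conversion of each image is done once up front so each fixation only
    costs two warps and two blurs (the model's own precompute shortcut).
    """

    def __init__(self, pair: ImagePair, grid: GridSpec, params: ModelParams,
                 beta: Optional[float] = None):
        self.pair = pair
        self.grid = grid
        self.params = params
        self.beta = params.fmf if beta is None else beta
        self.scale = params.cvr_scale_for_width(pair.width)
        self._lab_a = rgb2lab(np.clip(pair.a, 0.0, 1.0))
        self._identical = np.array_equal(pair.a, pair.a_prime)
        self._lab_ap = (self._lab_a if self._identical
                        else rgb2lab(np.clip(pair.a_prime, 0.0, 1.0)))
        self._store: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]] = {}

    def _raw_saliency(self, lab: np.ndarray, cvr: CVRParams) -> np.ndarray:
        warped = cvr_forward(lab, cvr)
        mean_vec = warped.reshape(-1, 3).mean(axis=0)
        blurred = np.empty_like(warped)
        for c in range(3):
            blurred[..., c] = ndimage.gaussian_filter(
                warped[..., c], sigma=self.params.saliency_sigma,
                mode="nearest")
        return np.sqrt(((blurred - mean_vec) ** 2).sum(axis=-1))

    def get(self, region: int
            ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(rates_a, rates_a_prime, projection_map, support_mask).

        The support mask marks original-space regions represented in
        the warped frame (non-clipped projection); only these receive
        likelihood evidence during a fixation at this center.  The two
        saliency maps of a fixation are normalised jointly (a shared
        gain across the 250 ms frames), so that a localized change
        cannot rescale the firing rates of unchanged regions.
        """
        hit = self._store.get(region)
        if hit is not None:
            return hit
        cx, cy = self.grid.centers_px()[region]
        cvr = CVRParams(beta=self.beta, s_fx=self.scale, s_fy=self.scale,
                        center=(float(cx), float(cy)))
        p = self.params
        sal_a = self._raw_saliency(self._lab_a, cvr)
        sal_ap = sal_a if self._identical else self._raw_saliency(self._lab_ap,
                                                                  cvr)
        lo = min(sal_a.min(), sal_ap.min())
        hi = max(sal_a.max(), sal_ap.max())
        span = hi - lo if hi - lo > 1e-12 else 1.0
        rates = []
        for sal in (sal_a, sal_ap):
            means = region_means((sal - lo) / span, self.grid)
            rates.append(p.lambda_min + (p.lambda_max - p.lambda_min) * means)
        proj, support = cvr_projection_map(cvr, self.grid, return_support=True)
        entry = (rates[0], rates[1], proj, support)
        self._store[region] = entry
        return entry


# --------------------------------------------------------------------------
# trial result container
# --------------------------------------------------------------------------

@dataclass
class TrialResult:
    """Outcome and gaze record of one simulated flicker trial."""

    outcome: str                     # 'hit' | 'miss' | 'false_alarm'
    detection_bin: Optional[int]
    detection_region: Optional[int]
    scanpath: List[Tuple[int, int, int]]   # (region, onset_bin, duration_bins)
    seed: int
    dt: float
    grid: GridSpec
    evidence_trace: Optional[np.ndarray] = None   # (trial_bins, n_regions)

    @property
    def n_fixations(self) -> int:
        return len(self.scanpath)

    @property
    def detection_time_s(self) -> Optional[float]:
        if self.detection_bin is None:
            return None
        return (self.detection_bin + 1) * self.dt

    def fixation_durations_bins(self) -> np.ndarray:
        return np.array([d for _, _, d in self.scanpath], dtype=float)

    def saccade_amplitudes_grid(self) -> np.ndarray:
        """Amplitude of each saccade in grid units."""
        centers = self.grid.centers_grid()
        regions = [r for r, _, _ in self.scanpath]
        if len(regions) < 2:
            return np.array([])
        pts = centers[np.array(regions)]
        return np.hypot(*(np.diff(pts, axis=0).T))

    def evidence_frame(self, trial_id: str = "trial") -> pd.DataFrame:
        """Long-format evidence traces (trial_id, bin, region, evidence).

        Requires the trial to have been run with ``record_evidence``.
        """
        if self.evidence_trace is None:
            raise ValueError("trial was run without record_evidence")
        n_bins, n_regions = self.evidence_trace.shape
        bins = np.repeat(np.arange(n_bins), n_regions)
        regions = np.tile(np.arange(n_regions), n_bins)
        return pd.DataFrame({"trial_id": trial_id, "bin": bins,
                             "region": regions,
                             "evidence": self.evidence_trace.ravel()})

    def scanpath_frame(self) -> pd.DataFrame:
        rows = []
        for k, (region, onset, dur) in enumerate(self.scanpath):
            r, c = self.grid.region_rowcol(region)
            rows.append({"fix_idx": k, "region": region, "region_row": r,
                         "region_col": c, "onset_s": onset * self.dt,
                         "duration_s": dur * self.dt})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# the trial loop
# --------------------------------------------------------------------------

def _region_hits_mask(region: int, grid: GridSpec,
                      mask: Optional[np.ndarray]) -> bool:
    if mask is None:
        return False
    row, col = grid.region_rowcol(region)
    p = grid.patch_px
    patch = mask[row * p:(row + 1) * p, col * p:(col + 1) * p]
    return bool(patch.any())


def run_trial(pair: ImagePair, params: ModelParams, seed: int,
              bias: Optional[BiasDistribution] = None,
              cache: Optional[FoveationCache] = None,
              start_region: Optional[int] = None,
              fixation_schedule: Optional[Sequence[int]] = None,
              decision: str = "sprt",
              decision_threshold: Optional[float] = None,
              uniform_decay: bool = False,
              record_evidence: bool = False,
              record_statistic: bool = False):
    """Simulate one flicker change-detection trial.

    Fully reproducible from ``seed``.  ``decision`` selects the stopping
    rule: ``"sprt"`` (accumulated evidence against F_c),
    ``"instantaneous"`` (instantaneous log posterior odds at the fixated
    region against ``decision_threshold``) or ``"derivative"`` (one-bin
    difference of the instantaneous log posterior odds against
    ``decision_threshold``).  ``fixation_schedule`` replaces the F_n
    break rule with externally imposed fixation durations (used to match
    the control models' fixation timing to a paired main-model run).
    ``uniform_decay`` forces gamma_i = gamma at every region (control 1).
    With ``record_statistic`` the function returns
    ``(TrialResult, max_statistic)`` where the statistic is the decision
    variable of the selected rule (used for threshold calibration).
    """
    if decision not in ("sprt", "instantaneous", "derivative"):
        raise ValueError(f"unknown decision rule {decision!r}")
    if decision != "sprt" and decision_threshold is None and not record_statistic:
        raise ValueError("control decision rules require a calibrated threshold")

    grid = partition_grid(pair.width, pair.height, params.patch_px)
    if cache is None:
        cache = FoveationCache(pair, grid, params)
    rng = np.random.default_rng(seed)
    schedule = StimulusSchedule(params.image_bins, params.blank_bins,
                                params.trial_bins)
    kinds = schedule.kinds()
    n = grid.n_regions
    log_prior = np.log(params.prior_odds)

    evidence = np.zeros(n)
    trace = np.zeros((params.trial_bins, n)) if record_evidence else None
    max_stat = -np.inf
    prev_inst = None          # previous instantaneous log posterior odds

    fix = (n // 2) if start_region is None else int(start_region)
    prev_fix: Optional[int] = None
    fix_onset = 0
    fix_count = 0
    rates_a, rates_ap, proj, support = cache.get(fix)
    gamma_f = (np.full(n, params.gamma) if uniform_decay
               else decay_field(fix, params.gamma, params.beta_decay, grid))

    # per-cycle spike bookkeeping (warped-grid space)
    x_counts: Optional[np.ndarray] = None
    m = 0
    cur = np.zeros(n)
    ncur = 0
    prev_kind = 1  # treat pre-trial as blank

    scanpath: List[Tuple[int, int, int]] = []
    outcome = "miss"
    detection_bin = None
    detection_region = None

    for t in range(params.trial_bins):
        kind = kinds[t]
        # commit the completed image epoch when entering a blank
        if kind == 1 and prev_kind != 1 and ncur > 0:
            x_counts, m = cur, ncur
            cur, ncur = np.zeros(n), 0

        log_l_orig = None
        if kind != 1:
            rates = rates_a if kind == 0 else rates_ap
            cur = cur + rng.poisson(rates)
            ncur += 1
            if m >= 1:
                z = (cur - x_counts).astype(int)
                lam = np.maximum((cur + x_counts) / (m + ncur), 1e-6)
                log_l = log_likelihood_ratio(z, lam, params.mu_f, m, ncur)
                log_l_orig = log_l[proj]
        prev_kind = kind

        # evidence update (original image space); likelihood, prior and
        # accumulation noise enter only at supported regions on bins
        # where a likelihood is evaluated, everything decays every bin.
        # The noise, like the likelihood, lives in the warped neural
        # representation and is projected back: peripheral regions that
        # share a pooled channel receive correlated noise, foveal
        # regions independent draws.
        evidence = (1.0 - gamma_f) * evidence
        if log_l_orig is not None:
            evidence[support] += log_l_orig[support]
            # the prior odds enter the sequential test the observer is
            # actually running, i.e. at the fixated location; peripheral
            # accumulations are likelihood-only
            evidence[fix] += log_prior
            if params.noise_half_width > 0:
                if params.noise_shared:
                    evidence[support] += rng.uniform(
                        -params.noise_half_width, params.noise_half_width)
                else:
                    noise = rng.uniform(-params.noise_half_width,
                                        params.noise_half_width, n)[proj]
                    evidence[support] += noise[support]
        else:
            # the fixated accumulator is monitored continuously; its
            # noise runs every bin even when no likelihood is available
            if params.noise_half_width > 0:
                evidence[fix] += rng.uniform(-params.noise_half_width,
                                             params.noise_half_width)
            if params.prior_every_bin:
                evidence = evidence + log_prior
        if trace is not None:
            trace[t] = evidence

        # decision statistic of the active stopping rule
        detected = False
        if decision == "sprt":
            if params.check_all_regions:
                stat = float(evidence.max())
                region_at_max = int(evidence.argmax())
            else:
                stat = float(evidence[fix])
                region_at_max = fix
            detected = stat >= params.f_c
        else:
            inst = (float(log_l_orig[fix]) + log_prior
                    if log_l_orig is not None else None)
            if decision == "instantaneous":
                stat = inst
            else:  # derivative
                stat = (inst - prev_inst
                        if inst is not None and prev_inst is not None else None)
            prev_inst = inst if log_l_orig is not None else None
            region_at_max = fix
            if stat is not None:
                max_stat = max(max_stat, stat)
                if decision_threshold is not None and stat >= decision_threshold:
                    detected = True
        if decision == "sprt" and record_statistic:
            max_stat = max(max_stat, stat)

        if detected and not (record_statistic and decision_threshold is None):
            detection_bin = t
            detection_region = region_at_max
            outcome = ("hit" if _region_hits_mask(region_at_max, grid, pair.mask)
                       else "false_alarm")
            scanpath.append((fix, fix_onset, t - fix_onset + 1))
            break

        # fixation termination
        bins_in_fix = t - fix_onset + 1
        if fixation_schedule is not None:
            sched_dur = fixation_schedule[min(fix_count,
                                              len(fixation_schedule) - 1)]
            terminate = bins_in_fix >= sched_dur
        else:
            f_n_t = threshold_schedule(params.f_n, params.zeta, bins_in_fix)
            terminate = (check_thresholds(float(evidence[fix]), params.f_c,
                                          min(f_n_t, -1e-9))
                         == "break_fixation")
        if terminate and t + 1 < params.trial_bins:
            scanpath.append((fix, fix_onset, bins_in_fix))
            probs = softmax_probabilities(evidence, params.temperature)
            if bias is not None:
                probs = apply_saccade_bias(probs, grid, fix, prev_fix, bias)
            prev_fix, fix = fix, sample_next_fixation(probs, rng)
            fix_count += 1
            fix_onset = t + 1
            # fresh foveal examination supersedes previously accumulated
            # peripheral conclusions at the new fixation target: the local
            # sequential test restarts no lower than the log prior odds
            # (the posterior before any data), and positive evidence is
            # capped just below threshold so that a change is only
            # signalled after foveal confirmation
            evidence[fix] = min(max(evidence[fix], log_prior),
                                0.9 * params.f_c)
            rates_a, rates_ap, proj, support = cache.get(fix)
            gamma_f = (np.full(n, params.gamma) if uniform_decay
                       else decay_field(fix, params.gamma, params.beta_decay,
                                        grid))
            x_counts, m, cur, ncur = None, 0, np.zeros(n), 0
            prev_inst = None

    if detection_bin is None:
        scanpath.append((fix, fix_onset, params.trial_bins - fix_onset))

    result = TrialResult(outcome=outcome, detection_bin=detection_bin,
                         detection_region=detection_region, scanpath=scanpath,
                         seed=seed, dt=params.dt, grid=grid,
                         evidence_trace=trace)
    if record_statistic:
        return result, max_stat
    return result


# --------------------------------------------------------------------------
# control models
# --------------------------------------------------------------------------

_CONTROL_DECISIONS = {1: "instantaneous", 2: "derivative", 3: "sprt"}


def run_control(control_id: int, pair: ImagePair, params: ModelParams,
                seed: int, calibrated_threshold: Optional[float] = None,
                cache: Optional[FoveationCache] = None,
                main_result: Optional[TrialResult] = None) -> TrialResult:
    """Run one of the three control observers on a trial.

    Control 1 decides on the instantaneous posterior odds (no evidence
    memory, gamma forced to 1 everywhere); control 2 on the one-bin
    derivative of the instantaneous log posterior odds; control 3 is the
    main model with temperature 10^4 (near-uniform saccades).  All three
    reuse the fixation-duration schedule of a paired main-model run with
    the same seed (run here if ``main_result`` is not supplied), so that
    only the search/stopping rule differs.
    """
    if control_id not in (1, 2, 3):
        raise ValueError("control_id must be 1, 2 or 3")
    if control_id in (1, 2) and calibrated_threshold is None:
        raise ValueError(f"control {control_id} requires a calibrated threshold")
    if main_result is None:
        main_result = run_trial(pair, params, seed, cache=cache)
    schedule = [d for _, _, d in main_result.scanpath]

    if control_id == 3:
        return run_trial(pair, params.with_(temperature=1e4), seed,
                         cache=cache, fixation_schedule=schedule)
    decision = _CONTROL_DECISIONS[control_id]
    return run_trial(pair, params, seed, cache=cache,
                     fixation_schedule=schedule, decision=decision,
                     decision_threshold=calibrated_threshold,
                     uniform_decay=(control_id == 1))


def calibrate_threshold(control_id: int, catch_pairs: Sequence[ImagePair],
                        max_false_alarm_rate: float, params: ModelParams,
                        seeds: Sequence[int]) -> float:
    """Smallest threshold whose catch-trial false-alarm rate meets the bound.

    Runs the control observer on the catch pairs recording the maximum
    decision statistic of each trial; the threshold is placed just above
    the order statistic that leaves at most ``max_false_alarm_rate`` of
    the trials exceeding it.  Larger thresholds can only lower the
    false-alarm rate, so the returned value is minimal by construction.
    """
    if control_id not in (1, 2):
        raise ValueError("only controls 1 and 2 use a calibrated threshold")
    if not catch_pairs:
        raise ValueError("catch pairs required for calibration")
    decision = _CONTROL_DECISIONS[control_id]
    maxima = []
    for pair in catch_pairs:
        cache = None
        for seed in seeds:
            main = run_trial(pair, params, seed)
            sched = [d for _, _, d in main.scanpath]
            _, stat = run_trial(pair, params, seed, fixation_schedule=sched,
                                decision=decision,
                                uniform_decay=(control_id == 1),
                                record_statistic=True)
            maxima.append(stat)
    maxima = np.sort(np.asarray(maxima))
    n_allowed = int(np.floor(max_false_alarm_rate * maxima.size))
    pivot = maxima[maxima.size - n_allowed - 1]
    if not np.isfinite(pivot):
        raise RuntimeError(
            f"calibration failed: statistic maxima {maxima} not finite")
    return float(np.nextafter(pivot, np.inf))


# --------------------------------------------------------------------------
# scoring and parameter sweeps
# --------------------------------------------------------------------------

def success_rate(results: Sequence[TrialResult]) -> Tuple[float, float]:
    """Proportion of hits with its binomial standard error."""
    if not results:
        raise ValueError("no trial results to score")
    n = len(results)
    p = sum(r.outcome == "hit" for r in results) / n
    return p, float(np.sqrt(p * (1.0 - p) / n))


@dataclass
class SweepSpec:
    """One-parameter sweep: which knob, which values, how many trials."""

    parameter: str
    values: Sequence[float]
    n_trials: int = 5
    flicker_total_bins: int = 50   # image+blank budget for blank_fraction

    _KNOWN = ("gamma", "temperature", "T", "mu_f", "fmf", "blank_fraction",
              "prior_odds", "zeta")

    def __post_init__(self) -> None:
        if self.parameter not in self._KNOWN:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if self.n_trials < 1:
            raise ValueError("repetitions must be >= 1")

    def apply(self, params: ModelParams, value: float) -> ModelParams:
        name = self.parameter
        if name == "T":
            name = "temperature"
        if name == "blank_fraction":
            total = self.flicker_total_bins // 2
            blank = int(round(value * total))
            blank = min(max(blank, 0), total)
            return params.with_(image_bins=total - blank, blank_bins=blank)
        return params.with_(**{name: value})


def run_sweep(spec: SweepSpec, pairs: Sequence[ImagePair],
              params: ModelParams, seed: int = 0,
              bias: Optional[BiasDistribution] = None) -> pd.DataFrame:
    """Success-rate curve over one parameter, with emergent gaze metrics.

    For every swept value, ``n_trials`` trials are distributed over the
    image pairs with seeds derived from ``seed``; seeds are matched
    across values (paired comparisons).  Returns one row per value with
    columns value, success, sem, mean_fd_bins (mean fixation duration)
    and var_sa_grid (saccade amplitude variance in grid units squared).
    The blank_fraction sweep keeps image+blank fixed at
    ``spec.flicker_total_bins`` bins.
    """
    if not pairs and spec.values:
        raise ValueError("image set must be non-empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.generate_state(spec.n_trials).astype(np.int64) % (2 ** 31)
    caches: Dict[Tuple[str, float], FoveationCache] = {}
    for value in spec.values:
        p = spec.apply(params, value)
        results = []
        fds: List[float] = []
        sas: List[float] = []
        for k in range(spec.n_trials):
            pair = pairs[k % len(pairs)]
            key = (pair.pair_id, p.fmf)
            if key not in caches:
                grid = partition_grid(pair.width, pair.height, p.patch_px)
                caches[key] = FoveationCache(pair, grid, p, beta=p.fmf)
            res = run_trial(pair, p, int(trial_seeds[k]), bias=bias,
                            cache=caches[key])
            results.append(res)
            fds.extend(res.fixation_durations_bins())
            sas.extend(res.saccade_amplitudes_grid())
        rate, sem = success_rate(results)
        rows.append({
            "parameter": spec.parameter, "value": value,
            "success": rate, "sem": sem,
            "mean_fd_bins": float(np.mean(fds)) if fds else np.nan,
            "var_sa_grid": float(np.var(sas)) if len(sas) > 1 else np.nan,
            "n_trials": spec.n_trials,
        })
    return pd.DataFrame(rows)
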