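# Methods

## The model

`gazeblind` simulates a rational observer searching a flickering image
pair for a single localized change.  The stimulus schedule alternates
the original image A, a blank, the altered image A′ and a blank, each
shown for 10 time bins of 25 ms (250 ms), for up to 2400 bins (60 s).

### Neural representation

At each fixation the image pair is passed through a Cartesian variable
resolution (CVR) warp centred on the fixated location,

    dv = sign(d) · ln(β·|d| + 1) · S_f ,

which magnifies the fovea (local magnification β·S_f at the centre) and
compresses the periphery.  β is the foveal magnification factor
(default 0.05); S_f defaults to 200 for an 864×648 image and is scaled
proportionally with image width at reduced sizes so the warp geometry is
unchanged under downscaling.  Content beyond the coverage radius
(β·|d|+1 > e^{W/(2 S_f)}) falls outside the warped frame and is not
represented at all; the set of image regions that do land inside the
frame is the *likelihood support* of the fixation.

A frequency-tuned saliency map is computed on the warped image: the
Euclidean Lab-space distance between the Gaussian-blurred image
(σ = 1.6 px) and the image's mean Lab vector.  Within a fixation the two
maps (A, A′) are normalised jointly to [0, 1] — a shared gain across
the 250 ms frames — so a localized change cannot rescale the rates of
unchanged regions.  The image is partitioned into non-overlapping 12-px
square regions (72×54 = 3888 at full scale; 36×27 = 972 at the reduced
432×324 default used for simulation studies), and each region's mean
saliency maps linearly onto a Poisson rate
λ = λ_min + (λ_max−λ_min)·⟨S⟩ with λ_min = 5, λ_max = 120 spikes/bin.

### Evidence

During image bins each warped-grid region emits Poisson spikes.  Within
a fixation, X counts spikes from the most recent completed image epoch
(m bins) and Y from the current one (q bins); blanks emit nothing and
delimit the epochs.  On every second-image bin the observer evaluates
the log likelihood ratio of "change" versus "no change" for the count
difference Z = Y − X.  Under no change Z is Skellam with means
(q·λ̂, m·λ̂), λ̂ = (X+Y)/(m+q) updated every bin; under change the rates
differ by ±μ_f (an equal mixture of both signs, μ_f = 3 spikes/bin; a
change-hypothesis rate below zero is clamped at 10⁻⁶).  The Skellam
log-pmf is evaluated through the exponentially scaled modified Bessel
function `scipy.special.ive`; where the scaled value underflows, the
large-order asymptote (x/2)^z/Γ(z+1) (when z² > x) or the large-argument
asymptote e^x/√(2πx)·(1−(4z²−1)/(8x)) takes over.

Evidence accumulates per region of the *original* image (the warped-grid
log L is projected back by mapping each region centre through the
forward warp):

    E_i(t) = (1 − γ_i) E_i(t−1) + log L_i(t) [+ log P at the fixated
             region] + W_i(t)

* decay: γ_i = γ·exp(−d²/2β_d²) is a Gaussian field peaked (γ = 0.004)
  at the fixated region, spatial scale β_d = 4 grid units; decay applies
  every bin to every region.
* prior: the prior odds P = 0.1 enter the sequential test the observer
  is running, i.e. at the fixated region, once per likelihood
  evaluation.  Peripheral supported regions accumulate projected
  likelihood only; unsupported regions receive L = 1 and only decay.
  (A config switch `prior_every_bin` restores a literal per-bin global
  prior.)
* noise: W ~ U(−5, 5) is drawn per warped-grid channel and projected
  back with the likelihood, so pooled peripheral regions receive
  correlated noise while foveal regions get independent draws; it is
  applied on likelihood bins at supported regions.  The fixated
  accumulator is monitored continuously, so it additionally receives a
  noise draw on every bin without likelihood support (blanks and the
  first image epoch of a fixation).

These three placement choices are what make the published phenomenology
emerge: unfixated regions hover near baseline (so fixation durations are
stationary and human-like, ~20–30 bins), catch trials essentially never
cross the detection bound, previously examined neighbourhoods carry
negative evidence (emergent inhibition of return), and — because higher
magnification devotes more independent channels to the proximal field —
saccade-amplitude variance falls as the foveal magnification factor
rises.

### Decisions

If E at the fixated region reaches F_c = 100 the model signals the
change there (a hit when the region intersects the ground-truth change
mask, a false alarm otherwise).  If it falls below the no-change bound
F_n(t) = −20·e^{−ζt} (ζ = 0 by default; t in bins since fixation onset)
the fixation ends and the next target is drawn from a softmax over the
evidence map with temperature T = 0.01, using the third-order Taylor
polynomial of the exponential clipped below at zero (uniform fallback
when every weight clips).  Optionally the post-softmax weights are
multiplied by a tabulated human saccade amplitude/turn-angle bias
(short amplitudes favoured; turn angles bimodal at 0°/180°).

On arrival at a new fixation target the target's evidence is clamped
into [log P, 0.9·F_c]: a fresh foveal examination restarts the local
sequential test no lower than the prior odds (the posterior before any
data), so previously rejected regions do not break fixations
instantly, while the cap means a change is only signalled after at
least one foveal likelihood evaluation (mirroring the task's
dwell-to-respond rule).  No other region is touched.

### Controls

1. No memory: γ forced to 1 everywhere; detection when the
   instantaneous posterior odds at fixation crosses a calibrated bound.
2. Differentiator: detection when the one-bin difference of the
   instantaneous log posterior odds crosses a calibrated bound.
3. Random searcher: the full model with T = 10⁴ (near-uniform saccades).

All controls replay the fixation-duration schedule of a paired
main-model run with the same seed, so only the search/stopping rule
differs.  Calibration records the per-trial maximum decision statistic
on synthetic catch trials and places the bound just above the order
statistic that meets the requested false-alarm rate — minimal and
monotone by construction.

A separate saliency-plus-inhibition-of-return sampler
(`ior_saliency_step`) provides the baseline for comparisons with
saliency-only gaze models: IOR(t) = clip(0.25·IOR(t−1) +
tanh(0.05·t)·G(σ=20 px), 0, 1), saccade weights (1−IOR)·saliency through
the same softmax.

## Synthetic data

The generator is the package's source of study conditions, not a test
dial.

* **Flicker pairs** — band-limited noise background (Gaussian-filtered
  white noise, σ = 12 px, amplitude 0.25 around mid-gray) with ~14
  mid-saturation clutter objects and one saturated target disk.  The
  three change kinds (size, color, appearance) all modulate the
  target's *conspicuity against the scene*, because the model detects
  saliency-driven rate differences: a hue swap between two equally
  conspicuous colors is invisible to it by construction.  `contrast`
  scales the saliency step; 0 yields a bitwise-identical catch pair.
  The default contrast (0.25) puts default-parameter success at
  ~75–90% with detection times spread over 2–50 s, inside the human
  success band (45–90%).
* **Gaze logs** — two groups ("good"/"poor" performers) differing only
  in mean fixation duration (lognormal, 450 vs 350 ms, cv 0.3) and
  saccade-amplitude variance (gamma, mean 10°, variance 12 vs 24 deg²).
  Saccade duration is 21 + 2.2·A ms (±15 ms scatter); peak speed
  follows the saturating main sequence 500·(1−e^{−A/6}) °/s (±70 °/s
  scatter) appropriate for the wide-field display geometry.  The
  saturation matters: a non-saturating map would transmit the planted
  amplitude-variance signal into peak-speed variance at full strength
  while suppressing its estimator noise, letting the derived feature
  outrank the planted one.  Positions follow a bounded random walk at
  30 px/°.
* **Saccade bias** — tabulated polar density with an exponential
  amplitude marginal and a 1 + w·cos 2θ turn-angle marginal (bimodal at
  0°/180°, trough at ±90°); zero weights give a uniform table.

What the generator does *not* emulate: photographic scene content and
semantics, measurement noise and blinks, calibration drift, and the
image-to-image variability of real change targets.  Passing tests
therefore establish internal consistency and the model's parameter
dependence under controlled conditions, not performance on natural
photographs.

## Analytics

Boxplot outlier removal (w = 1.5, linear-interpolation quartiles) is
applied to the raw per-trial metric samples before the eight summary
features (mean/variance of fixation duration, saccade amplitude,
duration, peak speed) are computed; the terminal ≥3-s detection dwell of
hit trials is stripped first.  Fisher score and information gain follow
their textbook two-class forms (entropy in bits; candidate splits at
midpoints of adjacent distinct values).  ΔAUC uses 5-fold
cross-validated out-of-fold scores (ridge linear discriminant default;
any scorer honouring the train→held-out-score contract can be passed)
and the rank (Mann–Whitney) AUC estimator.

Fixation density ρ normalises each point's inverse mean neighbour
distance (radius 40 px) by the same quantity at the nearest point of a
deterministic near-square reference lattice of equal cardinality; when
the lattice is sparser than the radius its nearest-neighbour spacing is
used.  Points with ρ < 1 form a single "sparse" cluster; the rest are
k-means clustered (k-means++ init, best-inertia restarts) for k = 1..50
with a spherical-Gaussian (x-means) BIC.  Long BIC profiles (> 10
points) are smoothed with a bi-exponential fit
a(1−e^{−k/t₁}) − b(e^{k/t₂}−1) before the peak is taken; short profiles
use the raw argmax.

Scan paths become label strings (nearest cluster centre per fixation;
sparse label `#`); dissimilarity is Levenshtein distance divided by the
longer length.  Saccade probability matrices are column-normalised
transition matrices, either over four fixation-duration "domains"
(clusters ranked by cumulative duration and split into quartile groups,
ties broken by cluster index) or over the top-k clusters with all other
transitions excluded.  Fixation maps are 13×18-tile histograms compared
by Pearson correlation; change-proximity profiles bin fixations into
50-px annuli around the change centre.

## Numerical and scale choices

* Simulation studies run at 432×324 px (36×27 grid) with 30-s trials
  and 20 matched-seed trials per swept value; the catch-trial
  false-alarm estimate uses 25 pairs at the full 60-s duration.  These
  sizes keep a full sweep battery in the minutes range on one core
  while leaving binomial noise at ≤ ~0.11 s.e. per point.
* Empirical success curves at 20 trials/point are judged as trends:
  steps up to 0.10 (two trials) are within noise; the end-to-end drop
  must be decisive.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; per-fixation foveated representations are
  cached per (pair, β) and shared across trials, mirroring the model's
  own grid-centre precompute.
* Degenerate inputs are defined, not fatal: uniform images give
  all-zero saliency; an all-blank schedule accrues no evidence and
  never breaks fixation; all-clipped softmax weights fall back to
  uniform; a bias table that annihilates every candidate leaves the
  weights unchanged.

## Known limitations

* The evidence bookkeeping (likelihood support, prior localisation,
  warped-channel noise, onset clamp) is one consistent reconstruction
  of an under-specified update rule; alternatives (e.g. a literal
  global per-bin prior) are exposed as switches but produce degenerate
  gaze behaviour.
* Decaying the no-change bound (ζ > 0) shortens fixations as intended,
  but does not reduce success in this reconstruction: evidence
  accumulated at the change region persists losslessly across visits,
  so segmenting dwell time does not starve detection, and faster
  scanning compensates on the reduced image.  The corresponding
  success-direction test is expected to fail and documents this.
* Success collapses somewhat below γ ≈ 0.1 at the reduced scale,
  slightly earlier than the ~0.2 reported for full-scale natural
  images.
* The saccade-bias table is a parametric stand-in, not an estimate from
  human data; user-supplied tables are accepted in the same CSV format.
* Absolute success rates depend on the synthetic contrast calibration;
  only directions of parameter effects, not absolute rates, should be
  compared across studies.
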