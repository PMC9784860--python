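# Methods

## Scoring model

A session is a grayscale frame stream (converted on ingest with ITU-R
BT.601 luma weights 0.299/0.587/0.114, the convention of consumer capture
hardware) plus an annotation log. Frames are never resized; every
percentage is relative to the native frame area, so scores are
resolution-independent by construction.

**Sampling.** The differencing interval is Δt = 0.3 s. Pairs are formed by
disjoint stepping: for t = k·Δt the frame nearest t is paired with the
frame nearest t − Δt (nearest-frame rounding bounds the timestamp error by
half a native frame period). A sliding 0.3 s window (every frame paired
with the frame 0.3 s earlier) would be an equally defensible reading; the
disjoint stepping was chosen because it makes each pixel change count
exactly once and keeps the per-interval samples independent. The
visualization metric samples single frames at the same cadence so the two
traces align; full-rate evaluation is a config flag.

**Fine Movement.** Absolute difference, strict binarization at
D_Th = 50 gray levels, coverage percent A_i, band score
100·[ε_low ≤ A_i ≤ ε_high], session mean including zero-score pairs. The
band cutoffs are deployment calibration parameters (defaults ε_low = 0.5 %,
ε_high = 20 % of frame area): they encode what "appropriate speed" means
for a given scope, optics and frame rate, and should be re-calibrated per
rig. The binarization is strictly greater-than; the band is inclusive at
both ends.

**Visualization.** Saturation mask (intensity strictly > 245), then a
denoise step: 3×3 binary opening followed by discarding connected
components (8-connectivity) smaller than 0.02 % of the frame. Pixels
outside the frame count as unsaturated, so the opening trims blobs at the
frame edge. Blob centroids are unweighted pixel means; the distance d from
the frame centre (pixel-centre coordinates) is compared with the
half-diagonal r = hypot(width−1, height−1)/2, which guarantees 0 ≤ d ≤ r
for any in-frame centroid. Weights are 1, 2/3, 1/3 on the three annuli
with the inner boundary closed upward (d ≤ r/3 → 1) and the outer boundary
closed downward (d ≥ 2r/3 → 1/3). Per frame the maximum weighted blob area
is taken (not the sum), and the session score is (1 − mean(wA)/100)·100,
clamped to [0, 100] — so a saturation-free video scores exactly 100.

**Target Detection and Efficiency.** Both come from the annotation log,
not from pixels; automated stone recognition is out of scope. Duration is
100·(T_max − T)/T_max with T_max = 5 min. As printed this goes negative
for long procedures (a 15.4 min session gives −208 %); the score is
clamped at 0 by default so all four metrics live on [0, 100], with the
unclamped value retained in the scorecard. Efficiency is read as the
two-term mean of Target Detection and the (per-trial averaged) Duration
score — both operands are percentages and a plain sum would exceed 100.
Note this composition cannot produce an Efficiency of ~97 % from a perfect
detection score and a 4.3 min mean time (which gives Duration = 14 %); the
raw sum is reported alongside for transparency rather than tuning the
formula toward any particular headline number.

**Group statistics.** Kolmogorov–Smirnov normality per group at α = 0.05,
tested against a normal with sample-estimated parameters — approximate;
the Lilliefors correction is available via config. The significance test
is an unpaired two-tailed t-test at p < 0.01. Welch's variant is the
default (safer for n = 8 groups of possibly unequal variance); the
pooled-variance t and the Wilcoxon rank-sum test are config options. With
bit-identical groups the statistic is reported as 0 with p = 1. The
movement histogram pools per-interval coverages and fits a normal by
maximum likelihood; an all-equal sample is flagged degenerate rather than
fitted.

## Synthetic sessions and what they show

The generator emulates the *measurement content* of an endoscopy
recording, not its appearance: a vessel-textured background (dark random
curves, gray levels confined to [60, 185]) in which

- motion is realized by toggling exactly round(f·N/100) pixels by ±70 gray
  levels at each interval boundary (always beyond D_Th, never into
  saturation), with the scene piecewise-constant within an interval;
- over-exposure is injected as solid 255-valued elliptical blobs whose
  pixel sets are the round(area·N/100) pixels nearest an elliptical
  distance from a centroid commanded as a fraction of the half-diagonal;
- stones are small bright (220, below saturation) sprites appearing at
  known times, with the background beneath them capped at 160 so their
  appearance always crosses the difference threshold.

Event times snap to interval boundaries, interval·fps must be integral,
and blob/stone pixels are excluded from motion toggling, so the expected
coverage per interval (commanded fraction plus any blob/stone transition
area) and the expected weighted area per sampled frame are exact closed
forms computed from the scene spec alone. This makes parameter-recovery
tests sharp: the only measured-vs-expected slack is the few boundary
pixels the opening can shave off a blob, well under half a percentage
point for the blob sizes used.

What passing these tests does **not** show: robustness to real-video
phenomena — irrigation turbulence, specular highlights that are genuine
glare rather than wall contact, compression artifacts, illumination drift,
camera auto-exposure. The generator produces none of these, so the
pipeline's validity on real recordings rests on the simplicity of the
operations themselves, not on these tests.

**Preset groups.** The professional preset commands smooth in-band motion
with occasional sub-band pauses, a rare small central washout, all three
stones detected, and a procedure time drawn around the 4.3 min group mean.
The trainee preset alternates near-static and abrupt out-of-band motion
(with ~10 % of intervals accidentally in-band), carries a large
mid-annulus washout for half the session plus a smaller peripheral one,
misses a stone in three trials out of four on average, and draws its time
around the 15.4 min mean — over the 5 min budget, so its Duration clamps
to 0. Per-trial jitter is seeded, giving groups nonzero within-group
variance so the t-test is well-posed. Preset clips are 12 s of 160×120 at
10 fps: long enough for 40 differencing intervals per session, small
enough that a 16-session comparison runs in seconds; the annotation log
carries the procedure time T separately from the clip length, as real
sessions separate wall-clock time from analyzed footage.

## Numerical choices and degenerate inputs

- Binarization and saturation thresholds are strict inequalities; the
  motion band and the outer weight band are inclusive as defined.
- Grayscale conversion rounds half-up after the luma dot product and is
  idempotent on already-gray input.
- A stream shorter than one interval yields zero pairs: the motion score
  is then undefined and raises, rather than returning a silent 0.
- A frame with no surviving blob contributes wA = 0; a blob whose weighted
  area would exceed 100 (impossible for physical input, possible under
  hand-built masks) is capped.
- Distances d > r raise a domain error in the weight function; inside the
  blob pipeline a floating-point guard clamps centroid distances to r.
- Annotation logs validate strictly (unique target ids, detections ≤
  placed targets, positive times) with field-level error messages; the
  session time may be given directly in minutes or derived from start/end
  timestamps.

## Known limitations

- Container decoding depends on an ffmpeg-capable imageio plugin; frame
  directories are the always-available path.
- The KS normality test with estimated parameters is anticonservative;
  for publication-grade normality claims use the Lilliefors option.
- Frame differencing measures *image* change, not tool-tip kinematics:
  irrigation flow or lighting changes in a real video count as motion.
- The Efficiency composition is documented above; its absolute values are
  sensitive to T_max and to the clamping choice.
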