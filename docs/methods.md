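# Methods

This note documents the models, estimators, numerical choices and
limitations of the gelswitch pipeline. It is the package's own account of
its methods; every number quoted here is computed by the test suite, the
analysis drivers or `scripts/acceptance.py`.

## Synthetic data model

**Temperature protocols.** Piecewise-linear trajectories built from ramps at
a fixed rate joined by constant dwells. Defaults mirror the two
characterization protocols: a single 30→45→30 °C excursion at 0.04 °C/s, and
a 28–42 °C protocol of twenty cycles with 5-minute dwells at each extreme.

**Contraction traces.** The projected gel area follows

    A(t) = A0 · r(t) · [1 − s · S((T(t) − T_t)/w)],

with S the logistic sigmoid, s the area stroke (default 0.8, matching the
observed >80 % area decrease), T_t the transition midpoint (36–43 °C
depending on the emulated dose), and w the transition width in °C. The
logistic was chosen because its derivative is symmetric, matching the
near-symmetric first derivative used to define T_t. Cooling retraces the
sigmoid (the reversible branch); r(t) multiplies in a factor (1 − ℓ) each
time a heating cycle completes (temperature returns to the protocol minimum
after crossing the midpoint of its range), so only the per-cycle loss ℓ
(default 0.34 %) stays unrecovered. Measurement noise is multiplicative
Gaussian on the area.

**Rendered videos.** Each frame holds an anti-aliased bright disk of the
trace's area on a darker background, an optional dark calibration square of
known physical size, optional centroid drift (a Gaussian random walk,
≤1 px/frame, off by default) and additive pixel noise. Camera resolution and
contrast are not specified by any protocol; the defaults (192² px, levels
30/220, 0.02 cm/px) are free fixture choices. Anti-aliasing makes the
thresholded pixel count track the analytic area to well under 2 % for disk
radii ≥ 20 px.

**Network images.** Two fixtures with different roles:

- `make_fibril_image`: n random straight fibers of fixed width with crisp
  edges, so any threshold between the two intensity levels recovers the
  truth mask exactly. Used for segmentation tests and for exercising the
  pore decomposition on irregular geometry. Its pore-radius distribution is
  monotone-decaying (a Poisson line process has exponential-like gaps), so
  its KDE mode sits at the smallest admissible radius.
- `make_foam_image`: a dense matrix punctured by non-overlapping circular
  pores with radii from a normal law (default mean 26 µm, the pre-transition
  modal pore size). Each interstitial space is a single round pore, so the
  decomposition recovers exactly the placed radii. This is the fixture for
  distribution-level claims (mode recovery, shrink ratios), because its
  modal size is intrinsic rather than pinned at the detection floor.

**CD spectra.** Weighted sums of fixed Gaussian basis bands on the
250→190 nm, 0.2 nm acquisition grid. Band centers sit at the canonical
diagnostic wavelengths — 197 nm (coil), 203 nm (elastin negative Cotton
effect, drifting to 207 nm at +0.2 nm/°C on heating), 208 nm (β-turn),
222 nm (collagen triple helix / elastin helical plateau) — with documented
temperature-dependent amplitudes. These constants are fixtures for testing
the processing chain, not claims about real protein spectra. The HT channel
rises monotonically toward 190 nm and stays below 600 V down to 195 nm under
the default shape.

All generators are bit-reproducible under a fixed seed.

## Estimators

**Area per frame.** Two measures, selectable per run: (a) a gradient-method
circle fit — Sobel gradient magnitude, a centroid/equivalent-radius seed, a
coarse radius scan, then Nelder–Mead refinement of (center, radius)
maximizing the perimeter-mean gradient; (b) Otsu (or fixed) thresholding
with white-pixel counting, polarity auto-detected from the border pixels.
On noiseless rendered disks the two agree within 3 % across radii
20–100 px. Frames whose measurement fails are flagged and linearly
interpolated; more than 20 % failures aborts the trace.

**Smoothing.** Gaussian convolution with reflect boundaries; σ is in
samples. The default σ = 50 is the value used for switching traces recorded
at 0.9 frames/s, i.e. a ≈55 s time constant. Synthetic videos in the tests
and acceptance runs are sampled every 5 s to keep rendering tractable, and
use σ = 11 to preserve that time constant; this is a sampling choice, not a
change of method.

**Transition temperature.** On the heating branch (start to the temperature
maximum), dA/dT is computed by central differences of the smoothed signal;
T_t is the temperature of the most negative value. The branch is smoothed in
isolation with constant ("nearest") extension: at the segment ends the
signal sits on or near a plateau, which constant extension matches, whereas
reflection mirrors residual descent into ascent and biases the peak toward
lower temperatures when T_t lies near the ramp top (the bias reached
−0.8 °C for T_t = 43 °C on a 45 °C ramp before this choice). A transition
requires a negative excursion exceeding 3× the derivative noise floor
(1.4826·MAD of dA/dT outside the excursion); constant traces therefore
raise a no-transition error rather than returning noise. T_t is defined on
heating only — recovery on cooling is slower and its midpoint is not the
same observable.

**Stroke.** Plateau medians over the first and last 5 % of the heating
segment (≥3 samples each), on the raw signal: the medians provide the
robustness, and the smoothed signal would bleed transition samples into
short plateaus. The volume stroke 1 − (1 − s)^{3/2} assumes isotropic
shrinkage and is always reported as a model-based estimate, separate from
the measured area stroke.

**Cycles.** Dwell windows are recovered from the profile's plateau
structure (runs at the protocol extremes, ≥2 samples). Per-cycle loss is
1 − A_cool(k+1)/A_cool(k) over consecutive cool-end dwell medians — the
cool-end baseline is a choice (the hot-end alternative measures the same ℓ
under the model but mixes in amplitude drift if the stroke changes);
amplitudes are (A_cool − A_hot)/A_cool per cycle; inflection points are the
extrema of dA/dt inside each ramp interval between dwells.

**Dose response.** Ordinary least squares of T_t on dose with residual sd;
at the printed endpoints (43 °C at 50 kGy, 36 °C at 90 kGy) the two-point
slope is −0.175 °C/kGy.

**Pores.** A pore is the largest circle fitting in the space between
segmented fibrils; its radius is the pore size. The decomposition is
greedy: the Euclidean distance transform of the unclaimed pore space
(fibrils and previously accepted circles are obstacles) is recomputed, the
circle at the global maximum accepted, until the maximum falls below r_min
(default 2 px, suppressing quantization pores). Ties break to the smallest
(row, column) center. Circle semantics are exact: the radius at a center is
the Euclidean distance to the nearest obstacle pixel, and a circle claims
the pixels strictly inside it. The default border policy excludes circles
that would cover a border pixel (truncated by the field of view); the
`include` policy caps radii at the frame boundary instead, so an empty
W×H mask yields a first pore of radius min(W, H)/2 (followed by
progressively smaller corner circles until r_min — a decomposition, not a
single-circle fit). An exhaustive reference implementation (per-center
minimum-distance scan, no distance transform) shares only the circle
semantics; greedy and reference agree exactly — radii to the last bit,
centers including tie-breaks — on every tested mask. The analysis is 2D
throughout.

**Pore-size distribution.** Gaussian KDE over radii (Silverman bandwidth by
default, absolute bandwidth settable), renormalized to integrate to one on
its grid; P_max is the grid argmax; raw histogram counts are kept. Fewer
than 5 pores yields radii and histogram only, flagged. Zero-variance radii
are represented as a narrow peak at the common radius.

**CD processing.** Fixed order: replicate mean → reference subtraction →
HT mask (≥600 V invalid; a violation above 195 nm sets a QC-fail flag
rather than an error) → Gaussian smoothing (σ = 10 samples, small enough to
move a synthetic band center by <0.2 nm) → optional division by the
Euclidean norm of the valid samples. The order is a documented choice; with
σ = 0, a zero reference and normalization the pipeline is idempotent after
the first application. Band features are local extrema via first-difference
sign changes with a prominence floor (2 % of the valid peak-to-peak
amplitude) plus values read off the grid at 197/203/207/220/222 nm.
Superposition fits are unconstrained least squares over the common valid
support (non-negative option; fixed weights evaluable directly);
rank-deficient component sets are rejected. Ellipticity stays in measured
mdeg — no mean-residue conversion, since chain concentrations of filtered
gel suspensions are unknown.

## Problem sizes

Synthetic switching videos: 151 frames of 192² px (5 s sampling of a
750 s ramp). Transition-recovery checks: 4 truth midpoints × 20 seeds
through the full image pipeline. Cyclic analysis: 20-cycle traces of
13 001 samples, 50 seeds. Oracle equivalence: 20 random 64×64 masks. Foam
images: 384² px, ≈45 pores. CD: 301-sample spectra, 50-seed Monte Carlo for
averaging and weight recovery.

## What passing tests do and do not show

The generators emulate the statistical structure of the measurements —
sigmoidal area collapse, per-cycle ratcheting, round pores, superposable
band spectra — under ideal imaging: no illumination gradients, no gel
asymmetry or fragmentation, no stage drift (unless enabled), no optical
sectioning artifacts, no instrument baseline drift in CD. Recovery under
these conditions validates the estimators' correctness and calibration, not
their robustness to every laboratory artifact. In particular, real confocal
networks are 3D and anisotropic; the 2D pore analysis here quantifies a
planar section, and the foam fixture's "one circle per pore" structure is
an idealization that real fibrous interstices only approximate.

## Known limitations

- The circle fit assumes one dominant, roughly circular gel per frame.
- T_t detection needs a heating segment spanning ≥2 °C and a stroke well
  above the noise floor; gels whose transition lies above the ramp maximum
  report a truncated stroke (visible as the lower stroke at the highest
  T_t in the dose series driver).
- Per-cycle loss assumes dwells long enough for the trace to settle; dwell
  medians are biased if the dwell is shorter than the settling time.
- KDE modes within ~a bandwidth of r_min are detection-floor artifacts;
  distribution-level claims should use networks whose modal pore size is
  well above r_min.
- No video-container decoding, tile stitching, 3D pore analysis, fibril
  orientation statistics, drift correction, or secondary-structure
  deconvolution against reference basis sets.
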