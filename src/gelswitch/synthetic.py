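"""Synthetic-data generators with known ground truth.

The raw laboratory recordings behind the gel-actuation experiments (top-view
videos, confocal stacks, CD runs) are not deposited, so every analysis stage
in this package is exercised against phenomenological generators whose
parameters mirror the study conditions: a disk-shaped gel whose projected
area drops sigmoidally by ~80-90 % at a dose-dependent transition temperature
in the 36-43 degC range, cyclic traces with a small per-cycle irreversible
contraction (~0.34 %), binary fibrous networks with interstitial pores of
known geometry, and CD spectra as weighted sums of fixed basis bands.

All generators are bit-reproducible under a fixed seed.
"""
from __future__ import annotations

import numpy as np
from scipy.special import expit

from .datatypes import AreaTrace, CDSpectrum, FrameSeries, SyntheticTruth, TemperatureProfile
from .errors import InvalidParameterError

__all__ = [
    "make_temperature_profile",
    "make_contraction_trace",
    "render_contraction_frames",
    "make_fibril_image",
    "make_foam_image",
    "make_cd_spectrum",
    "CD_BASIS_BANDS",
    "cd_wavelength_grid",
]

# Study-condition defaults: ramp 30->45 degC and 20-cycle 28-42 degC protocols
# at ~0.04 degC/s with 5-min dwells.
DEFAULT_RATE = 0.04  # degC/s
DEFAULT_DWELL = 300.0  # s


def make_temperature_profile(
    kind: str,
    t_low: float,
    t_high: float,
    rate: float = DEFAULT_RATE,
    n_cycles: int = 1,
    dwell: float = 0.0,
    sampling_dt: float = 1.0,
) -> TemperatureProfile:
    """Piecewise-linear stage-temperature trajectory.

    ``ramp`` produces one up-then-down excursion (heat to ``t_high``, cool back
    to ``t_low``); ``cyclic`` repeats ramp-dwell-ramp-dwell for ``n_cycles``.
    Ramps run at ``rate`` and are joined by constant dwells of ``dwell`` s.
    """
    if sampling_dt <= 0:
        raise InvalidParameterError("sampling_dt must be positive")
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if t_low > t_high:
        raise InvalidParameterError("t_low must not exceed t_high")
    if kind not in ("ramp", "cyclic"):
        raise InvalidParameterError(f"unknown profile kind {kind!r}")
    if kind == "cyclic" and n_cycles < 1:
        raise InvalidParameterError("cyclic profiles need n_cycles >= 1")
    if dwell < 0:
        raise InvalidParameterError("dwell must be non-negative")

    ramp_dur = (t_high - t_low) / rate
    bk_t = [0.0]
    bk_T = [t_low]

    def _add(duration: float, temp: float) -> None:
        if duration > 0:
            bk_t.append(bk_t[-1] + duration)
            bk_T.append(temp)

    reps = n_cycles if kind == "cyclic" else 1
    for _ in range(reps):
        _add(ramp_dur, t_high)
        _add(dwell, t_high)
        _add(ramp_dur, t_low)
        if kind == "cyclic":
            _add(dwell, t_low)

    total = bk_t[-1]
    times = np.arange(0.0, total, sampling_dt)
    if times.size == 0 or total - times[-1] > 1e-9:
        times = np.append(times, total)
    if times.size < 2:  # degenerate zero-span protocol: emit a flat 2-sample trace
        times = np.array([0.0, sampling_dt])
    temps = np.interp(times, bk_t, bk_T) if len(bk_t) > 1 else np.full_like(times, t_low)
    label = f"{kind} {t_low:g}-{t_high:g}degC rate={rate:g}"
    if kind == "cyclic":
        label += f" x{n_cycles} dwell={dwell:g}s"
    return TemperatureProfile(times=times, temps=temps, protocol_label=label)


def _completed_cycles(temps: np.ndarray) -> np.ndarray:
    """Number of completed heating cycles at each sample.

    A cycle counts as completed when the temperature returns to the protocol
    minimum after having crossed the midpoint of its range.
    """
    low = temps.min()
    high = temps.max()
    if high - low <= 0:
        return np.zeros(temps.size, dtype=int)
    mid = 0.5 * (low + high)
    eps = 1e-9 * (high - low) + 1e-12
    counts = np.zeros(temps.size, dtype=int)
    k = 0
    armed = False
    for i, T in enumerate(temps):
        if T > mid:
            armed = True
        elif armed and T <= low + eps:
            k += 1
            armed = False
        counts[i] = k
    return counts


def make_contraction_trace(
    profile: TemperatureProfile,
    truth: SyntheticTruth,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[AreaTrace, SyntheticTruth]:
    """Projected-area response of a gel traversing a temperature protocol.

    Model: ``A(t) = A0 * r(t) * [1 - stroke_area * S((T(t) - T_t)/width_w)]``
    with ``S`` the logistic sigmoid.  Cooling retraces the sigmoid (the
    reversible branch); ``r(t)`` multiplies in a step of ``1 - loss_per_cycle``
    at each completed heating cycle, so only that fraction stays unrecovered.
    Multiplicative Gaussian noise of relative scale ``noise_sd`` is applied.
    """
    if len(profile.times) < 2:
        raise InvalidParameterError("profile must contain at least 2 samples")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    S = expit((profile.temps - truth.T_t) / truth.width_w)
    r = (1.0 - truth.loss_per_cycle) ** _completed_cycles(profile.temps)
    area = truth.A0 * r * (1.0 - truth.stroke_area * S)
    if noise_sd > 0:
        area = area * (1.0 + rng.normal(0.0, noise_sd, size=area.size))
        area = np.maximum(area, 0.0)
    trace = AreaTrace(
        times=profile.times.copy(),
        temps=profile.temps.copy(),
        area_raw=area,
        method_label="synthetic",
    )
    return trace, truth


def render_contraction_frames(
    trace: AreaTrace,
    image_shape: tuple[int, int] = (192, 192),
    pixel_size: float = 0.02,  # cm/px
    background_level: float = 30.0,
    gel_level: float = 220.0,
    noise_sd: float = 0.0,
    include_reference_object: bool = False,
    reference_extent: float = 0.5,  # cm, side of the dark reference square
    drift_px: float = 0.0,  # per-frame random-walk step, off by default
    seed: int = 0,
) -> FrameSeries:
    """Render an area trace as a top-view video of a contracting disk.

    Each frame holds a filled bright disk (the gel) of the trace's area on a
    contrasting background, optionally a dark square reference object of known
    physical size in the upper-left corner, and additive Gaussian pixel noise.
    Disk edges are anti-aliased so the pixel-count area tracks the analytic
    area closely.
    """
    h, w = image_shape
    rng = np.random.default_rng(seed)
    radii = np.sqrt(np.asarray(trace.area_raw) / np.pi) / pixel_size
    margin = 2.0 + drift_px * np.sqrt(len(trace)) * 3
    if radii.max() + margin > min(h, w) / 2:
        raise InvalidParameterError(
            f"disk radius {radii.max():.1f} px does not fit in a {h}x{w} frame"
        )
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    frames = np.empty((len(trace), h, w), dtype=np.uint8)
    cy, cx = cy0, cx0
    ref_px = int(round(reference_extent / pixel_size))
    for i, r in enumerate(radii):
        if drift_px > 0:
            cy += rng.normal(0.0, drift_px)
            cx += rng.normal(0.0, drift_px)
        d = np.hypot(yy - cy, xx - cx)
        cover = np.clip(r + 0.5 - d, 0.0, 1.0)  # anti-aliased edge
        img = background_level + (gel_level - background_level) * cover
        if include_reference_object:
            img[2:2 + ref_px, 2:2 + ref_px] = 0.0
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    meta = {"seed": seed, "reference_extent": reference_extent if include_reference_object else None}
    return FrameSeries(frames=frames, times=trace.times.copy(), pixel_size=pixel_size, meta=meta)


def make_fibril_image(
    image_shape: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,  # um/px
    n_fibers: int = 25,
    fiber_width: float = 3.0,  # um
    seed: int = 0,
    foreground: float = 200.0,
    background: float = 10.0,
    return_mask: bool = False,
):
    """Random straight bright fibers of given width on a dark background.

    Fibers are line segments spanning the frame with random position and
    orientation; edges are crisp so any threshold between the two intensity
    levels recovers the ground-truth mask exactly.  Deterministic per seed.
    """
    if fiber_width < pixel_size:
        raise InvalidParameterError("fiber_width must be at least one pixel")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    half_w = 0.5 * fiber_width / pixel_size
    mask = np.zeros((h, w), dtype=bool)
    diag = float(np.hypot(h, w))
    for _ in range(n_fibers):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        theta = rng.uniform(0, np.pi)
        dy, dx = np.sin(theta), np.cos(theta)
        p0 = np.array([cy - dy * diag, cx - dx * diag])
        p1 = np.array([cy + dy * diag, cx + dx * diag])
        seg = p1 - p0
        t = ((yy - p0[0]) * seg[0] + (xx - p0[1]) * seg[1]) / (seg @ seg)
        t = np.clip(t, 0.0, 1.0)
        d = np.hypot(yy - (p0[0] + t * seg[0]), xx - (p0[1] + t * seg[1]))
        mask |= d <= half_w
    img = np.where(mask, foreground, background).astype(np.uint8)
    if return_mask:
        return img, mask
    return img


def make_foam_image(
    image_shape: tuple[int, int] = (384, 384),
    pixel_size: float = 1.5,  # um/px
    n_pores: int = 45,
    radius_mean: float = 26.0,  # um, emulating the pre-transition modal pore size
    radius_sd: float = 3.0,  # um
    seed: int = 0,
    foreground: float = 200.0,
    background: float = 10.0,
    max_attempts: int = 20000,
    return_truth: bool = False,
):
    """Dense matrix punctured by non-overlapping circular pores of known radii.

    This is the ground-truth fixture for distribution-level pore analysis: a
    network so dense that each interstitial space is a single round pore, so
    the maximal-inscribed-circle decomposition recovers exactly the placed
    radii (drawn from a normal law peaked at ``radius_mean``).  Deterministic
    per seed.  With ``return_truth`` also returns the placed radii (um).
    """
    if radius_mean <= 0 or radius_sd < 0:
        raise InvalidParameterError("radius_mean must be positive, radius_sd >= 0")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pore = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_pores and attempts < max_attempts:
        attempts += 1
        r_um = rng.normal(radius_mean, radius_sd)
        r = r_um / pixel_size
        if r < 2:
            continue
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        # keep >= 2 px of matrix between pores so each stays a separate bubble
        if any(np.hypot(cy - py, cx - px) < r + pr + 2.0 for py, px, pr in placed):
            continue
        placed.append((cy, cx, r))
        pore |= np.hypot(yy - cy, xx - cx) <= r
    img = np.where(pore, background, foreground).astype(np.uint8)
    if return_truth:
        return img, np.array([pr * pixel_size for _, _, pr in placed])
    return img


# ---------------------------------------------------------------------------
# CD spectra

# Fixed Gaussian basis bands used by the generator.  These are fixtures that
# place diagnostic features at the canonical wavelengths (197 nm coil,
# 203->207 nm elastin negative Cotton effect, 222 nm collagen triple helix /
# elastin helical plateau); they are not claims about real protein spectra.
# Each band: (center nm, width nm, amplitude mdeg at 25 degC,
#             amplitude drift mdeg/degC, center drift nm/degC).
CD_BASIS_BANDS: dict[str, list[tuple[float, float, float, float, float]]] = {
    "collagen": [
        (197.0, 5.0, -9.0, 0.0, 0.0),
        (222.0, 6.0, 3.2, -0.02, 0.0),
    ],
    "elastin": [
        (203.0, 6.0, -7.0, 0.12, 0.2),  # decreases and shifts toward 207 nm on heating
        (222.0, 12.0, -1.2, 0.0, 0.0),
    ],
    "coil": [
        (197.0, 5.0, -10.0, 0.0, 0.0),
    ],
    "beta_turn": [
        (208.0, 5.0, 1.6, 0.04, 0.0),
    ],
}

_REF_TEMP = 25.0  # degC at which band tables are specified


def cd_wavelength_grid() -> np.ndarray:
    """Canonical acquisition grid: 250 -> 190 nm in 0.2 nm steps (301 samples)."""
    return np.round(np.linspace(250.0, 190.0, 301), 6)


def _component_spectrum(name: str, wavelengths: np.ndarray, temperature: float) -> np.ndarray:
    try:
        bands = CD_BASIS_BANDS[name]
    except KeyError:
        raise InvalidParameterError(f"unknown CD component {name!r}") from None
    dT = temperature - _REF_TEMP
    y = np.zeros_like(wavelengths)
    for center, width, amp, damp, dcenter in bands:
        a = amp + damp * dT
        c = center + dcenter * dT
        y = y + a * np.exp(-0.5 * ((wavelengths - c) / width) ** 2)
    return y


def make_cd_spectrum(
    weights: dict[str, float],
    temperature: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    dose: float = 0.0,
    label: str = "",
) -> CDSpectrum:
    """CD spectrum as a weighted sum of fixed basis bands plus noise.

    The HT channel rises monotonically toward 190 nm, staying below 600 V
    down to 195 nm under the default shape.
    """
    for name, f in weights.items():
        if f < 0:
            raise InvalidParameterError(f"negative weight for component {name!r}")
    wl = cd_wavelength_grid()
    y = np.zeros_like(wl)
    for name, f in weights.items():
        y = y + f * _component_spectrum(name, wl, temperature)
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    ht = 250.0 + 320.0 * expit((196.0 - wl) / 1.5)
    return CDSpectrum(
        wavelengths=wl,
        ellipticity=y,
        ht=ht,
        temperature=temperature,
        dose=dose,
        label=label,
    )
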