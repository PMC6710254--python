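"""Transition temperature, stroke, dose response and cyclic-actuation metrics.

The transition temperature T_t is defined on the heating branch as the
temperature at the most negative derivative dA/dT of the smoothed area
signal — the symmetric-derivative criterion.  The stroke is the fractional
plateau-to-plateau area decrease; an isotropic-shrinkage volume estimate
``1 - (1 - stroke_area)^(3/2)`` is reported alongside and labeled as
model-based.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .area_tracking import DEFAULT_SIGMA, smooth
from .datatypes import AreaTrace, CycleMetrics, DoseResponse, TemperatureProfile, TransitionResult
from .errors import AlignmentError, InvalidParameterError, NoTransitionError

__all__ = [
    "find_transition",
    "compute_stroke",
    "analyze_cycles",
    "dose_response",
    "area_to_volume_stroke",
]


def area_to_volume_stroke(stroke_area: float) -> float:
    """Volume stroke under isotropic shrinkage: 1 - (1 - s_area)^(3/2)."""
    return float(1.0 - (1.0 - stroke_area) ** 1.5)


def _heating_segment(trace: AreaTrace, window: Optional[tuple[float, float]]) -> np.ndarray:
    """Indices of the heating branch: start to the temperature maximum."""
    if trace.temps is None:
        raise InvalidParameterError("trace has no temperatures; align frames first")
    if window is not None:
        t0, t1 = window
        idx = np.where((trace.times >= t0) & (trace.times <= t1))[0]
    else:
        idx = np.arange(0, int(np.argmax(trace.temps)) + 1)
    if idx.size < 10:
        raise InvalidParameterError("heating segment too short")
    return idx


def _segment_smoothed(trace: AreaTrace, idx: np.ndarray, sigma: Optional[float]) -> tuple[np.ndarray, float]:
    """Smooth the heating segment in isolation, with constant extension.

    The segment is smoothed separately from the cooling branch so the
    recovery does not bleed into the descent, and with ``nearest`` boundary
    handling: at the segment ends the signal sits on (or close to) a
    plateau, which constant extension matches, whereas reflection mirrors
    any residual descent into an ascent and biases the derivative peak
    toward lower temperatures when the transition lies near the ramp top.
    """
    from scipy.ndimage import gaussian_filter1d

    if sigma is None:
        sigma = trace.sigma_used if trace.sigma_used and np.isfinite(trace.sigma_used) else DEFAULT_SIGMA
    sigma = float(sigma)
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    y = trace.area_raw[idx]
    return (y.copy() if sigma == 0 else gaussian_filter1d(y, sigma, mode="nearest")), sigma


def find_transition(
    trace: AreaTrace,
    heating_segment: Union[str, tuple[float, float]] = "auto",
    sigma: Optional[float] = None,
    dose: float = float("nan"),
) -> TransitionResult:
    """Locate the transition on the heating branch of an area trace.

    dA/dT is computed by central finite differences of the smoothed signal;
    T_t is the temperature of its most negative value.  A transition requires
    a negative excursion exceeding 3x the derivative noise floor
    (1.4826 * MAD of dA/dT outside the transition window).
    """
    window = None if heating_segment == "auto" else heating_segment
    idx = _heating_segment(trace, window)
    A, sigma_used = _segment_smoothed(trace, idx, sigma)
    T = trace.temps[idx]
    t = trace.times[idx]
    if T.max() - T.min() < 2.0:
        raise InvalidParameterError("heating segment must span at least 2 degC")

    dT = np.gradient(T)
    dA = np.gradient(A)
    rate_scale = np.median(np.abs(dT[np.abs(dT) > 0])) if np.any(np.abs(dT) > 0) else 0.0
    live = np.abs(dT) > 1e-3 * rate_scale
    deriv = np.full(T.size, np.nan)
    deriv[live] = dA[live] / dT[live]
    if not np.any(np.isfinite(deriv)):
        raise NoTransitionError("no temperature change on the heating segment")

    peak_i = int(np.nanargmin(deriv))
    peak = deriv[peak_i]
    # Noise floor from the derivative outside the transition excursion.
    finite = np.isfinite(deriv)
    outside = finite & ~(deriv < 0.25 * peak) if peak < 0 else finite
    rest = deriv[outside]
    floor = 1.4826 * float(np.median(np.abs(rest - np.median(rest)))) if rest.size else 0.0
    if not (peak < 0) or not (abs(peak) > 3 * floor) or abs(peak) <= 0:
        raise NoTransitionError("no negative-derivative excursion above the noise floor")

    stroke_area, stroke_vol = compute_stroke(
        AreaTrace(times=t, temps=T, area_raw=trace.area_raw[idx],
                  area_smooth=A, sigma_used=sigma_used, method_label=trace.method_label)
    )
    heating_rate = float(np.polyfit(t, T, 1)[0])
    return TransitionResult(
        T_t=float(T[peak_i]),
        derivative_peak=float(peak),
        heating_rate=heating_rate,
        stroke_area=stroke_area,
        stroke_volume_est=stroke_vol,
        dose=dose,
    )


def compute_stroke(trace: AreaTrace) -> tuple[float, float]:
    """Plateau-median stroke of a trace (fraction of area lost).

    The start and end plateaus are the medians of the first and last 5 % of
    samples (at least 3 each), taken on the raw signal — the medians provide
    the robustness, and the smoothed signal would bleed transition samples
    into short plateaus.  The volume estimate assumes isotropic shrinkage and
    is reported separately.
    """
    n = len(trace)
    if n < 10:
        raise InvalidParameterError("trace too short for stroke estimation")
    y = trace.area_raw
    k = max(3, n // 20)
    a_start = float(np.median(y[:k]))
    a_end = float(np.median(y[-k:]))
    if a_start <= 0:
        raise InvalidParameterError("non-positive start plateau")
    stroke = (a_start - a_end) / a_start
    stroke = float(np.clip(stroke, 0.0, 1.0))
    return stroke, area_to_volume_stroke(stroke)


def _dwell_windows(profile: TemperatureProfile) -> tuple[list, list]:
    """Hot- and cool-dwell time windows from the profile's plateau structure."""
    T = profile.temps
    low, high = T.min(), T.max()
    span = high - low
    if span <= 0:
        raise AlignmentError("profile has no temperature span")
    eps = 1e-6 * span

    def runs(sel: np.ndarray) -> list[tuple[float, float]]:
        out = []
        i = 0
        n = sel.size
        while i < n:
            if sel[i]:
                j = i
                while j + 1 < n and sel[j + 1]:
                    j += 1
                if j > i:  # at least 2 samples => an actual dwell, not a ramp apex
                    out.append((profile.times[i], profile.times[j]))
                i = j + 1
            else:
                i += 1
        return out

    hot = runs(T >= high - eps)
    cool = runs(T <= low + eps)
    # Drop a cool "dwell" at t=0 (the pre-protocol baseline before the first ramp).
    cool = [wdw for wdw in cool if wdw[0] > profile.times[0]]
    return hot, cool


def analyze_cycles(trace: AreaTrace, profile: TemperatureProfile) -> CycleMetrics:
    """Per-cycle amplitudes, inflection points and irreversible loss.

    Dwell areas are medians over the dwell windows.  The per-cycle loss is
    ``1 - A_cool(k+1)/A_cool(k)`` over consecutive cool-end dwells; the
    amplitude of cycle k is ``(A_cool(k) - A_hot(k))/A_cool(k)``.
    """
    hot, cool = _dwell_windows(profile)
    n_cycles = min(len(hot), len(cool))
    if n_cycles < 2:
        raise InvalidParameterError("cyclic analysis needs at least 2 cycles with dwells")

    def dwell_median(window: tuple[float, float]) -> float:
        t0, t1 = window
        sel = (trace.times >= t0) & (trace.times <= t1)
        if not np.any(sel):
            raise AlignmentError(f"no trace samples inside dwell [{t0:g}, {t1:g}] s")
        return float(np.median(trace.area_raw[sel]))

    a_hot = np.array([dwell_median(wdw) for wdw in hot[:n_cycles]])
    a_cool = np.array([dwell_median(wdw) for wdw in cool[:n_cycles]])

    losses = 1.0 - a_cool[1:] / a_cool[:-1]
    loss_mean = float(losses.mean()) if losses.size else 0.0
    loss_sd = float(losses.std(ddof=1)) if losses.size > 1 else 0.0
    amplitudes = np.clip((a_cool - a_hot) / a_cool, 0.0, 1.0)

    # Inflection points: extrema of dA/dt inside each ramp (the intervals
    # between successive dwells); dwell windows themselves are excluded.
    infl_t, infl_T = [], []
    if trace.temps is not None and len(trace) > 4:
        dA = np.gradient(trace.best, trace.times)
        dwells = sorted(hot[:n_cycles] + cool[:n_cycles])
        edges = [trace.times[0]]
        for s, e in dwells:
            edges += [s, e]
        edges.append(trace.times[-1])
        ramps = [(edges[i], edges[i + 1]) for i in range(0, len(edges) - 1, 2)]
        for t0, t1 in ramps:
            sel = np.where((trace.times > t0) & (trace.times < t1))[0]
            if sel.size < 3:
                continue
            seg = dA[sel]
            if np.all(seg == 0):
                continue
            i_ext = sel[int(np.argmax(np.abs(seg)))]
            infl_t.append(trace.times[i_ext])
            infl_T.append(trace.temps[i_ext])

    return CycleMetrics(
        n_cycles=n_cycles,
        inflection_times=np.array(infl_t),
        inflection_temps=np.array(infl_T),
        amplitude_per_cycle=amplitudes,
        loss_per_cycle=loss_mean,
        loss_per_cycle_sd=loss_sd,
        losses=losses,
    )


def dose_response(results: Iterable[TransitionResult]) -> DoseResponse:
    """Ordinary least-squares line of transition temperature vs dose."""
    results = list(results)
    doses = np.array([r.dose for r in results], dtype=float)
    tts = np.array([r.T_t for r in results], dtype=float)
    if np.unique(doses).size < 2:
        raise InvalidParameterError("dose response needs at least 2 distinct doses")
    fit = stats.linregress(doses, tts)
    resid = tts - (fit.intercept + fit.slope * doses)
    dof = max(1, doses.size - 2)
    return DoseResponse(
        doses=doses,
        T_ts=tts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=float(np.sqrt((resid ** 2).sum() / dof)),
    )
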