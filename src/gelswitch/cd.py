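"""Circular-dichroism spectra: parsing, preprocessing and band analysis.

Preprocessing follows a fixed, documented order: replicate averaging ->
water-reference subtraction -> HT validity masking (photomultiplier voltage
below 600 V, protected down to 195 nm) -> Gaussian smoothing (sigma = 10
samples by default, chosen to preserve curve shape) -> optional division by
the Euclidean norm of the valid ellipticity samples.

File dialect: header lines starting with '#' carrying ``key=value`` metadata
(temperature_C, dose_kGy, replicate, label), then columns
``wavelength_nm,ellipticity_mdeg[,ht_V]`` (comma- or whitespace-separated).
"""
from __future__ import annotations

import io
import os
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .datatypes import BandFeatures, CDSpectrum, SuperpositionFit
from .errors import (
    AlignmentError,
    FeatureExtractionError,
    FitError,
    FormatError,
    InvalidParameterError,
)

__all__ = [
    "read_cd",
    "write_cd",
    "preprocess",
    "ht_mask",
    "band_features",
    "fit_superposition",
    "DEFAULT_SIGMA_CD",
    "HT_MAX_V",
    "HT_LAMBDA_FLOOR_NM",
    "CANONICAL_BANDS_NM",
]

DEFAULT_SIGMA_CD = 10.0  # samples; shape-preserving smoothing for spectra
HT_MAX_V = 600.0  # photomultiplier voltage above which absorbance is unreliable
HT_LAMBDA_FLOOR_NM = 195.0  # HT must stay below HT_MAX_V down to this wavelength
CANONICAL_BANDS_NM = (197.0, 203.0, 207.0, 220.0, 222.0)

_GRID_START, _GRID_STOP, _GRID_STEP = 250.0, 190.0, 0.2


def _expected_rows() -> int:
    return int(round((_GRID_START - _GRID_STOP) / _GRID_STEP)) + 1  # 301


def read_cd(path: str, strict_grid: bool = True) -> list[CDSpectrum]:
    """Parse one or more spectra from a CD CSV file.

    Blocks of '#'-metadata followed by data rows; a blank line (or a new
    metadata block after data) starts the next spectrum.  With
    ``strict_grid`` the wavelength column must be the full acquisition grid
    (250 -> 190 nm in 0.2 nm steps, 301 rows).
    """
    with open(path) as fh:
        lines = fh.readlines()
    spectra: list[CDSpectrum] = []
    meta: dict = {}
    rows: list[tuple[int, list[float]]] = []

    def flush() -> None:
        nonlocal meta, rows
        if not rows:
            meta = {}
            return
        wl = np.array([r[1][0] for r in rows])
        el = np.array([r[1][1] for r in rows])
        ht = np.array([r[1][2] for r in rows]) if len(rows[0][1]) > 2 else None
        d = np.diff(wl)
        if wl.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            bad = int(np.where(np.sign(d) != np.sign(d[0]))[0][0])
            raise FormatError(
                f"{path}: non-monotone wavelength column at line {rows[bad + 1][0]}"
            )
        if strict_grid:
            expect = _expected_rows()
            grid = np.round(np.linspace(_GRID_START, _GRID_STOP, expect), 6)
            if wl.size != expect or not np.allclose(np.sort(wl)[::-1], grid, atol=1e-6):
                raise FormatError(
                    f"{path}: expected the {expect}-row 250->190 nm grid in "
                    f"{_GRID_STEP} nm steps, got {wl.size} rows"
                )
        spectra.append(CDSpectrum(
            wavelengths=wl,
            ellipticity=el,
            ht=ht,
            temperature=float(meta.get("temperature_C", "nan")),
            dose=float(meta.get("dose_kGy", "nan")),
            n_replicates=int(meta.get("replicate", 1)),
            label=str(meta.get("label", "")),
        ))
        meta = {}
        rows = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            if rows:
                flush()
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.replace(",", " ").split()
        if parts[0].lower().startswith("wavelength"):
            continue  # column header
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable data at line {lineno}") from exc
        if len(vals) < 2:
            raise FormatError(f"{path}: expected >= 2 columns at line {lineno}")
        rows.append((lineno, vals[:3]))
    flush()
    if not spectra:
        raise FormatError(f"{path}: no spectra found")
    return spectra


def write_cd(path: str, spectrum: CDSpectrum) -> str:
    """Write one spectrum in the '#'-metadata CSV dialect."""
    buf = io.StringIO()
    if np.isfinite(spectrum.temperature):
        buf.write(f"# temperature_C={spectrum.temperature:g}\n")
    if np.isfinite(spectrum.dose):
        buf.write(f"# dose_kGy={spectrum.dose:g}\n")
    if spectrum.label:
        buf.write(f"# label={spectrum.label}\n")
    buf.write(f"# replicate={spectrum.n_replicates}\n")
    cols = "wavelength_nm,ellipticity_mdeg" + (",ht_V" if spectrum.ht is not None else "")
    buf.write(cols + "\n")
    for i in range(spectrum.wavelengths.size):
        row = f"{spectrum.wavelengths[i]:.6g},{spectrum.ellipticity[i]:.10g}"
        if spectrum.ht is not None:
            row += f",{spectrum.ht[i]:.10g}"
        buf.write(row + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return path


def ht_mask(
    spectrum: CDSpectrum,
    v_max: float = HT_MAX_V,
    lambda_floor: float = HT_LAMBDA_FLOOR_NM,
) -> CDSpectrum:
    """Mask wavelengths where the HT voltage reaches ``v_max``.

    Masked samples are excluded from norms, features and fits.  If the
    criterion is violated above ``lambda_floor`` the spectrum is flagged as
    failing acquisition QC (flag, not error).
    """
    if spectrum.ht is None:
        return spectrum.copy()
    invalid = spectrum.ht >= v_max
    qc = not np.any(invalid & (spectrum.wavelengths > lambda_floor))
    return spectrum.copy(valid=spectrum.valid & ~invalid, qc_pass=bool(qc and spectrum.qc_pass))


def _check_grid(a: CDSpectrum, b: CDSpectrum, what: str) -> None:
    if a.wavelengths.shape != b.wavelengths.shape or not np.allclose(
        a.wavelengths, b.wavelengths, atol=1e-9
    ):
        raise AlignmentError(f"{what} not on the same wavelength grid")


def preprocess(
    spectrum: Optional[CDSpectrum] = None,
    reference: Optional[CDSpectrum] = None,
    replicates: Optional[Sequence[CDSpectrum]] = None,
    normalize: bool = False,
    sigma: float = DEFAULT_SIGMA_CD,
    v_max: float = HT_MAX_V,
    lambda_floor: float = HT_LAMBDA_FLOOR_NM,
) -> CDSpectrum:
    """Standard CD preprocessing pipeline (fixed order).

    mean over replicates -> subtract water reference -> HT mask -> Gaussian
    smooth (``sigma`` samples) -> optional division by the Euclidean norm of
    the valid ellipticity samples.
    """
    if replicates:
        base = replicates[0]
        for rep in replicates[1:]:
            _check_grid(base, rep, "replicates")
        el = np.mean([r.ellipticity for r in replicates], axis=0)
        hts = [r.ht for r in replicates if r.ht is not None]
        ht = np.mean(hts, axis=0) if hts else None
        spec = base.copy(ellipticity=el, ht=ht, n_replicates=len(replicates))
    elif spectrum is not None:
        spec = spectrum.copy()
    else:
        raise InvalidParameterError("need a spectrum or replicates")
    if reference is not None:
        _check_grid(spec, reference, "reference")
        spec = spec.copy(ellipticity=spec.ellipticity - reference.ellipticity)
    spec = ht_mask(spec, v_max=v_max, lambda_floor=lambda_floor)
    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    if sigma > 0:
        spec = spec.copy(ellipticity=gaussian_filter1d(spec.ellipticity, sigma, mode="reflect"))
    if normalize:
        norm = float(np.linalg.norm(spec.ellipticity[spec.valid]))
        if norm == 0:
            raise InvalidParameterError("cannot normalize an all-zero spectrum")
        spec = spec.copy(ellipticity=spec.ellipticity / norm)
    return spec


def band_features(spectrum: CDSpectrum, prominence: Optional[float] = None) -> BandFeatures:
    """Local extrema and canonical band values of a spectrum.

    Extrema come from sign changes of the first difference with a prominence
    floor (default: 2 % of the valid peak-to-peak amplitude).  Values at the
    canonical wavelengths (197/203/207/220/222 nm) are read off the grid.
    """
    valid = spectrum.valid
    if not np.any(valid):
        raise FeatureExtractionError("fully masked spectrum")
    wl = spectrum.wavelengths[valid]
    y = spectrum.ellipticity[valid]
    order = np.argsort(wl)
    wl, y = wl[order], y[order]
    if prominence is None:
        ptp = float(np.ptp(y))
        prominence = 0.02 * ptp if ptp > 0 else None
    if prominence == 0:
        prominence = None
    maxima_i, _ = find_peaks(y, prominence=prominence)
    minima_i, _ = find_peaks(-y, prominence=prominence)
    maxima = [(float(wl[i]), float(y[i])) for i in maxima_i]
    minima = [(float(wl[i]), float(y[i])) for i in minima_i]
    value_at = {}
    for lam in CANONICAL_BANDS_NM:
        if wl.min() - 0.11 <= lam <= wl.max() + 0.11:
            j = int(np.argmin(np.abs(wl - lam)))
            value_at[lam] = float(y[j])
    return BandFeatures(minima=minima, maxima=maxima, value_at=value_at)


def fit_superposition(
    target: CDSpectrum,
    components: Sequence[CDSpectrum],
    nonnegative: bool = False,
    weights: Optional[Sequence[float]] = None,
) -> SuperpositionFit:
    """Least-squares weights expressing the target as a component sum.

    The fit runs over the common valid wavelength support.  Passing
    ``weights`` skips fitting and evaluates the fixed superposition (e.g. a
    2:1 collagen:elastin mass ratio) instead.
    """
    if not components:
        raise InvalidParameterError("need at least one component")
    support = target.valid.copy()
    for c in components:
        _check_grid(target, c, "components")
        support &= c.valid
    if not np.any(support):
        raise AlignmentError("no common valid wavelength support")
    A = np.column_stack([c.ellipticity[support] for c in components])
    b = target.ellipticity[support]
    labels = [c.label or f"component_{i}" for i, c in enumerate(components)]
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.size != len(components):
            raise InvalidParameterError("one weight per component required")
    else:
        if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, float(np.abs(A).max()))) < A.shape[1]:
            raise FitError("component set is rank-deficient")
        if nonnegative:
            from scipy.optimize import nnls

            w, _ = nnls(A, b)
        else:
            w, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ w
    return SuperpositionFit(
        weights=w,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
        components=labels,
    )
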