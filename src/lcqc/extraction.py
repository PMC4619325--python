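"""Extracted ion chromatograms and targeted chromatographic peak detection.

The peak picker follows the continuous-wavelet-transform ridge-line approach
familiar from MS peak detection: the intensity trace is convolved with Ricker
(Mexican-hat) wavelets over a geometric range of scales, local CWT maxima are
linked across scales into ridge lines, and ridges of sufficient length and
signal-to-noise ratio become peak candidates. Among the candidates whose apex
falls inside the retention-time tolerance window, the one nearest the
expected retention time wins (ties: higher apex intensity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d, maximum_filter1d

from .chem import C13_C12_DELTA
from .io_formats import CentroidRun, TargetFeature

__all__ = [
    "EIC",
    "ChromPeak",
    "PeakPickingSettings",
    "FeatureMeasurement",
    "extract_eic",
    "detect_peak",
    "integrate_area",
    "measure_feature",
]


@dataclass
class EIC:
    """Per-scan summed intensity within a ±ppm window around a target m/z.

    ``matched_mz[i]`` is the intensity-weighted mean m/z of the matched
    centroids of scan ``i`` (NaN where no centroid fell inside the window).
    """

    rt: np.ndarray
    intensity: np.ndarray
    matched_mz: np.ndarray
    target_mz: float
    ppm_window: float


@dataclass
class ChromPeak:
    """A detected chromatographic peak on an EIC."""

    apex_rt: float
    left_rt: float
    right_rt: float
    apex_index: int
    left_index: int
    right_index: int
    apex_intensity: float
    area: float
    snr: float
    best_scale: float


@dataclass
class PeakPickingSettings:
    """Knobs of the CWT-ridge peak picker.

    Scales are in scan units; the defaults (2–32, 10 geometric steps) cover
    chromatographic peaks from a few scans up to a minute at typical 1 Hz
    full-scan rates.
    """

    scales: np.ndarray = field(
        default_factory=lambda: np.unique(np.round(np.geomspace(2, 32, 10))).astype(float)
    )
    min_ridge_length: int = 3
    min_snr: float = 3.0
    max_ridge_gap: int = 2
    boundary_cap_scales: float = 3.0  # boundaries capped at apex ± cap × best_scale scans


def extract_eic(run: CentroidRun, target_mz: float, ppm: float) -> EIC:
    """Build the EIC of ``target_mz`` ± ``ppm`` (closed window) over all scans.

    Each scan contributes the sum of intensities of every centroid with
    ``|mz − target| / target × 1e6 ≤ ppm``; the window test is inclusive on
    both edges. Relies on the per-scan m/z arrays being sorted ascending.
    """
    if ppm <= 0:
        raise ValueError("ppm window must be positive")
    if run.n_scans == 0:
        raise ValueError("empty run")
    half = target_mz * ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    n = run.n_scans
    intensity = np.zeros(n)
    matched = np.full(n, np.nan)
    for i in range(n):
        mz = run.mzs[i]
        a = np.searchsorted(mz, lo, side="left")
        b = np.searchsorted(mz, hi, side="right")
        if b > a:
            iy = run.intensities[i][a:b]
            s = iy.sum()
            intensity[i] = s
            if s > 0:
                matched[i] = float(np.dot(mz[a:b], iy) / s)
            else:
                matched[i] = float(mz[a:b].mean())
    return EIC(rt=run.rts, intensity=intensity, matched_mz=matched, target_mz=target_mz, ppm_window=ppm)


# ---------------------------------------------------------------------------
# CWT machinery


def ricker(points: int, a: float) -> np.ndarray:
    """Ricker (Mexican-hat) wavelet, the negative normalised second derivative
    of a Gaussian of width ``a`` sampled at ``points`` integer positions."""
    A = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    x = np.arange(points) - (points - 1) / 2.0
    u2 = (x / a) ** 2
    return A * (1.0 - u2) * np.exp(-u2 / 2.0)


def cwt_ricker(signal: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """CWT matrix (scales × samples) of ``signal`` with the Ricker wavelet."""
    out = np.empty((len(scales), len(signal)))
    for k, a in enumerate(scales):
        width = min(10 * int(np.ceil(a)) + 1, len(signal))
        out[k] = np.convolve(signal, ricker(width, a), mode="same")
    return out


def _local_maxima(row: np.ndarray, order: int) -> np.ndarray:
    """Indices of points that are maximal within ±order neighbours."""
    order = max(order, 1)
    mx = maximum_filter1d(row, size=2 * order + 1, mode="constant", cval=-np.inf)
    return np.nonzero((row == mx) & (row > 0))[0]


@dataclass
class _Ridge:
    scales_idx: List[int]
    positions: List[int]
    coeffs: List[float]
    gap: int = 0


def _link_ridges(coefs: np.ndarray, scales: np.ndarray, max_gap: int) -> List[_Ridge]:
    """Link per-scale CWT maxima from the largest scale down into ridge lines."""
    order = len(scales) - 1
    ridges: List[_Ridge] = []
    closed: List[_Ridge] = []
    for k in range(len(scales) - 1, -1, -1):
        row = coefs[k]
        window = max(1, int(scales[k] // 4))
        maxima = list(_local_maxima(row, window))
        # extend existing ridges with the nearest unclaimed maximum
        for ridge in ridges:
            last = ridge.positions[-1]
            best, best_d = None, None
            for m in maxima:
                d = abs(m - last)
                if d <= window * 2 and (best_d is None or d < best_d):
                    best, best_d = m, d
            if best is not None:
                maxima.remove(best)
                ridge.scales_idx.append(k)
                ridge.positions.append(best)
                ridge.coeffs.append(row[best])
                ridge.gap = 0
            else:
                ridge.gap += 1
        still_open = []
        for ridge in ridges:
            (closed if ridge.gap > max_gap else still_open).append(ridge)
        ridges = still_open
        # unclaimed maxima start new ridges
        for m in maxima:
            ridges.append(_Ridge([k], [m], [row[m]]))
    closed.extend(ridges)
    return closed


def detect_peak(
    eic: EIC,
    expected_rt: float,
    rt_tol: float,
    settings: Optional[PeakPickingSettings] = None,
) -> Optional[ChromPeak]:
    """Find the target chromatographic peak near ``expected_rt``.

    Returns ``None`` (not an exception) when no ridge-line candidate of
    sufficient length and SNR has its apex inside
    ``[expected_rt − rt_tol, expected_rt + rt_tol]``.

    The apex is refined to the raw-intensity maximum within ± best scale of
    the ridge position; peak boundaries are the nearest local minima of a
    Gaussian-smoothed trace flanking the apex, capped at
    ``apex ± boundary_cap_scales × best_scale`` scan spacings.
    """
    if rt_tol <= 0:
        raise ValueError("retention-time tolerance must be positive")
    s = settings or PeakPickingSettings()
    y = eic.intensity
    n = len(y)
    if n < 3 or not np.any(y > 0):
        return None
    scales = np.asarray(s.scales, dtype=float)
    coefs = cwt_ricker(y, scales)
    noise_row = np.abs(coefs[0])
    ridges = _link_ridges(coefs, scales, s.max_ridge_gap)

    candidates: List[ChromPeak] = []
    for ridge in ridges:
        if len(ridge.positions) < s.min_ridge_length:
            continue
        k_best = int(np.argmax(ridge.coeffs))
        best_scale = scales[ridge.scales_idx[k_best]]
        pos = ridge.positions[-1]  # position at the smallest scale reached
        half = int(best_scale)
        lo, hi = max(0, pos - half), min(n, pos + half + 1)
        # refine the apex on a lightly smoothed trace: the raw maximum of a
        # flat-topped noisy peak jitters by a scan or two
        y_smooth = gaussian_filter1d(y, sigma=max(best_scale / 4.0, 1.0))
        apex = lo + int(np.argmax(y_smooth[lo:hi]))
        if y[apex] <= 0:
            continue
        wlo = max(0, apex - 5 * int(best_scale))
        whi = min(n, apex + 5 * int(best_scale) + 1)
        noise = np.percentile(noise_row[wlo:whi], 95)
        snr = float(ridge.coeffs[k_best] / noise) if noise > 0 else np.inf
        if snr < s.min_snr:
            continue
        if abs(eic.rt[apex] - expected_rt) > rt_tol:
            continue
        left, right = _peak_boundaries(y, apex, best_scale, s.boundary_cap_scales)
        if left >= right:
            continue
        area = integrate_area_indices(eic, left, right)
        candidates.append(
            ChromPeak(
                apex_rt=float(eic.rt[apex]),
                left_rt=float(eic.rt[left]),
                right_rt=float(eic.rt[right]),
                apex_index=apex,
                left_index=left,
                right_index=right,
                apex_intensity=float(y[apex]),
                area=area,
                snr=snr,
                best_scale=float(best_scale),
            )
        )
    if not candidates:
        return None
    candidates.sort(key=lambda p: (abs(p.apex_rt - expected_rt), -p.apex_intensity))
    return candidates[0]


def _peak_boundaries(
    y: np.ndarray, apex: int, scale: float, cap_scales: float
) -> Tuple[int, int]:
    """Nearest flanking local minima of the smoothed trace, capped in width."""
    n = len(y)
    smooth = gaussian_filter1d(y.astype(float), sigma=max(scale / 2.0, 1.0))
    cap = max(2, int(round(cap_scales * scale)))
    left = max(0, apex - cap)
    for i in range(apex - 1, left, -1):
        if y[i] == 0 or (smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]):
            left = i
            break
    right = min(n - 1, apex + cap)
    for i in range(apex + 1, right):
        if y[i] == 0 or (smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]):
            right = i
            break
    return left, right


def integrate_area_indices(eic: EIC, left: int, right: int) -> float:
    """Trapezoidal area (counts · seconds) between two scan indices."""
    if right <= left:
        return 0.0
    return float(np.trapezoid(eic.intensity[left : right + 1], eic.rt[left : right + 1]))


def integrate_area(eic: EIC, peak: ChromPeak) -> float:
    """Trapezoidal integral of the EIC between the peak boundaries."""
    if peak.right_index <= peak.left_index:
        import warnings

        warnings.warn("degenerate peak boundaries; area is zero", stacklevel=2)
        return 0.0
    return integrate_area_indices(eic, peak.left_index, peak.right_index)


@dataclass
class FeatureMeasurement:
    """Everything measured for one target feature in one run."""

    peak: ChromPeak
    eic: EIC
    measured_mz: float
    measured_ria: Optional[float] = None


def measure_feature(
    run: CentroidRun,
    target: TargetFeature,
    ppm: float,
    rt_tol: float,
    settings: Optional[PeakPickingSettings] = None,
    compute_ria: bool = False,
) -> Optional[FeatureMeasurement]:
    """Measure retention time, m/z, area and (optionally) RIA of one target.

    The measured m/z is the intensity-weighted mean of the per-scan matched
    m/z values inside the peak boundaries. The RIA divides the area of the
    M+1 EIC (target m/z + 1.00336 Da, same ppm window, same boundaries) by
    the monoisotopic peak area. Returns ``None`` when the peak is not found.
    """
    mz0 = target.theoretical_mz
    eic = extract_eic(run, mz0, ppm)
    peak = detect_peak(eic, target.expected_rt_s, rt_tol, settings)
    if peak is None:
        return None
    sl = slice(peak.left_index, peak.right_index + 1)
    iy = eic.intensity[sl]
    mzv = eic.matched_mz[sl]
    ok = np.isfinite(mzv) & (iy > 0)
    if not np.any(ok):
        return None
    measured_mz = float(np.dot(mzv[ok], iy[ok]) / iy[ok].sum())
    ria = None
    if compute_ria:
        eic1 = extract_eic(run, mz0 + C13_C12_DELTA, ppm)
        area0 = peak.area
        area1 = integrate_area_indices(eic1, peak.left_index, peak.right_index)
        if area0 > 0:
            ria = float(area1 / area0)
    return FeatureMeasurement(peak=peak, eic=eic, measured_mz=measured_mz, measured_ria=ria)
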