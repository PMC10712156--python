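"""Raw-spectrum conditioning: smoothing, baseline subtraction, normalization,
peak picking, flatline detection, replicate-outlier removal and mass
calibration against a bundled protein standard.

The vendor software behind the original acquisitions does not disclose its
algorithms, so standard open equivalents are used: Savitzky-Golay (order 2)
or moving-average smoothing, SNIP or rolling-minimum baseline estimation,
and a robust MAD-based noise scale for peak picking.  Mass calibration fits
a single multiplicative (constant-ppm) correction to the eight reference
masses of the bacterial test standard (BTS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .types import (
    DEFAULT_TOLERANCE,
    MassTolerance,
    Peak,
    PeakList,
    Spectrum,
)

#: The eight reference masses (Da) of the bacterial test standard used to
#: verify and correct the mass axis.
BTS_MASSES: tuple[float, ...] = (
    3637.8, 5096.8, 5381.4, 6255.4, 7274.5, 10300.2, 13683.2, 16952.3,
)


@dataclass(frozen=True)
class CalibrationStandard:
    """Reference masses plus the ppm window used to locate them."""

    reference_masses: tuple[float, ...] = BTS_MASSES
    ppm_tolerance: float = 300.0

    def __post_init__(self) -> None:
        masses = self.reference_masses
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("reference masses must be strictly increasing")


BTS_STANDARD = CalibrationStandard()


@dataclass(frozen=True)
class CalibrationReport:
    matched: int
    shift_ppm: float
    passed: bool


# ---------------------------------------------------------------------------
# smoothing and baseline
# ---------------------------------------------------------------------------

def smooth(spectrum: Spectrum, window_points: int = 7, method: str = "savgol") -> Spectrum:
    """Smooth the intensity trace on its existing m/z grid.

    ``savgol`` fits local quadratics (preserves symmetric peak apices);
    ``moving_average`` is a plain boxcar.  The window must be odd, ≥3 and
    no longer than the spectrum.
    """
    n = len(spectrum)
    if window_points % 2 == 0:
        raise ValueError(f"window_points must be odd, got {window_points}")
    if window_points < 3 or window_points > n:
        raise ValueError(f"window_points must be in [3, {n}], got {window_points}")
    y = spectrum.intensity
    if method == "savgol":
        out = savgol_filter(y, window_points, polyorder=2, mode="interp")
    elif method == "moving_average":
        out = uniform_filter1d(y, size=window_points, mode="reflect")
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return spectrum.replace_intensity(np.clip(out, 0.0, None))


def _snip_baseline(y: np.ndarray, half_window: int) -> np.ndarray:
    # SNIP with the usual log-log-sqrt (LLS) compression so that tall peaks
    # do not drag the estimate upward.
    v = np.log(np.log(np.sqrt(y + 1.0) + 1.0) + 1.0)
    w = v.copy()
    n = len(w)
    for m in range(1, min(half_window, (n - 1) // 2) + 1):
        avg = 0.5 * (w[: n - 2 * m] + w[2 * m :])
        w[m : n - m] = np.minimum(w[m : n - m], avg)
    return (np.exp(np.exp(w) - 1.0) - 1.0) ** 2 - 1.0


def subtract_baseline(
    spectrum: Spectrum, method: str = "snip", half_window: int = 40
) -> Spectrum:
    """Estimate and remove the slowly varying baseline; output is clipped ≥0.

    ``half_window`` is in grid points and should exceed the half-width of the
    widest genuine peak.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    y = spectrum.intensity
    if method == "snip":
        baseline = _snip_baseline(y, half_window)
    elif method == "rolling_min":
        size = 2 * half_window + 1
        baseline = minimum_filter1d(y, size=size, mode="nearest")
        baseline = np.minimum(uniform_filter1d(baseline, size=size, mode="nearest"), y)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return spectrum.replace_intensity(np.clip(y - baseline, 0.0, None))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(obj: Union[Spectrum, PeakList], mode: str = "base_peak"):
    """Scale intensities: ``base_peak`` → max = 100; ``tic`` → sum = 1."""
    if isinstance(obj, Spectrum):
        values = obj.intensity
    else:
        values = obj.intensities
    if len(values) == 0 or np.max(values) <= 0:
        raise ValueError("cannot normalize: no positive intensity")
    if mode == "base_peak":
        scale = 100.0 / np.max(values)
    elif mode == "tic":
        scale = 1.0 / np.sum(values)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if isinstance(obj, Spectrum):
        return obj.replace_intensity(values * scale)
    return PeakList(
        [Peak(p.mz, p.intensity * scale, p.snr) for p in obj.peaks],
        meta=obj.meta,
        flatline=obj.flatline,
    )


# ---------------------------------------------------------------------------
# peak picking and flatline detection
# ---------------------------------------------------------------------------

def noise_scale(intensity: np.ndarray) -> float:
    """Robust noise estimate: 1.4826 × MAD of the signal."""
    med = np.median(intensity)
    return float(1.4826 * np.median(np.abs(intensity - med)))


def pick_peaks(
    spectrum: Spectrum,
    snr_min: float = 3.0,
    min_separation: Optional[float] = None,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    min_rel_height: float = 0.02,
    flatline_min_peaks: int = 5,
) -> PeakList:
    """Pick local maxima with SNR ≥ ``snr_min`` from a preprocessed spectrum.

    The noise scale is 1.4826 × MAD of the (baseline-subtracted) trace, and
    SNR is measured above the median background (baseline estimators leave a
    small positive offset on noisy traces).  Peaks closer than
    ``min_separation`` (default: the matching window at that mass) are
    thinned keeping the more intense; peaks below ``min_rel_height`` of the
    base peak are discarded — protein-fingerprint peaks below 2% of the base
    peak are indistinguishable from baseline ripple.
    """
    y = spectrum.intensity
    if len(y) < 3 or np.max(y) <= 0:
        return PeakList([], meta=spectrum.meta, flatline=True)
    noise = max(noise_scale(y), 1e-12)
    background = float(np.median(y))
    idx, _ = find_peaks(y)
    heights = y[idx]
    snr_values = (heights - background) / noise
    keep = (snr_values >= snr_min) & (heights >= min_rel_height * np.max(y))
    idx, heights = idx[keep], heights[keep]

    # thin peaks closer than the separation window, most intense first
    order = np.argsort(-heights, kind="stable")
    accepted: list[int] = []
    for j in order:
        mz_j = spectrum.mz[idx[j]]
        sep = min_separation if min_separation is not None else tolerance.window(mz_j)
        if all(abs(mz_j - spectrum.mz[idx[k]]) >= sep for k in accepted):
            accepted.append(j)
    accepted_idx = sorted(idx[j] for j in accepted)

    peaks = [
        Peak(float(spectrum.mz[i]), float(y[i]), float((y[i] - background) / noise))
        for i in accepted_idx
    ]
    pl = PeakList(peaks, meta=spectrum.meta)
    pl.flatline = detect_flatline(pl, min_peaks=flatline_min_peaks, snr_min=snr_min)
    return pl


def detect_flatline(peaklist: PeakList, min_peaks: int = 5, snr_min: float = 3.0) -> bool:
    """True iff fewer than ``min_peaks`` peaks reach ``snr_min``.

    Peaks without an SNR annotation are assumed to have passed picking and
    count toward the total.
    """
    n_good = sum(1 for p in peaklist.peaks if p.snr is None or p.snr >= snr_min)
    return n_good < min_peaks


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    spectrum: Union[Spectrum, PeakList],
    standard: CalibrationStandard = BTS_STANDARD,
    pass_min: Optional[int] = None,
    snr_min: float = 3.0,
) -> tuple[Union[Spectrum, PeakList], CalibrationReport]:
    """Verify the mass axis against a calibration standard and correct it.

    Each reference mass is searched among the picked peaks within the
    standard's ±ppm window.  If at least ``pass_min`` (default: all) are
    found, a constant relative shift ``s`` (observed ≈ reference × (1+s)) is
    fit by least squares and removed multiplicatively from the m/z axis.
    With fewer matches the input is returned uncalibrated and the report is
    marked failed; rejection is the caller's policy.
    """
    if pass_min is None:
        pass_min = len(standard.reference_masses)
    peaklist = spectrum if isinstance(spectrum, PeakList) else pick_peaks(spectrum, snr_min=snr_min)
    observed = peaklist.mz

    pairs: list[tuple[float, float]] = []
    used: set[int] = set()
    for ref in standard.reference_masses:
        if len(observed) == 0:
            break
        window = standard.ppm_tolerance * 1e-6 * ref
        dist = np.abs(observed - ref)
        if used:
            dist[list(used)] = np.inf
        j = int(np.argmin(dist))
        if dist[j] <= window:
            pairs.append((ref, float(observed[j])))
            used.add(j)

    if len(pairs) < max(pass_min, 1):
        # too few anchors to fit a shift; passed only if the caller asked
        # for nothing (pass_min=0, report-only mode)
        return spectrum, CalibrationReport(
            matched=len(pairs), shift_ppm=0.0, passed=len(pairs) >= pass_min
        )

    refs = np.array([r for r, _ in pairs])
    obs = np.array([o for _, o in pairs])
    s = float(np.sum(refs * (obs - refs)) / np.sum(refs**2))

    if isinstance(spectrum, PeakList):
        corrected: Union[Spectrum, PeakList] = PeakList(
            [Peak(p.mz / (1.0 + s), p.intensity, p.snr) for p in spectrum.peaks],
            meta=spectrum.meta,
            flatline=spectrum.flatline,
        )
    else:
        corrected = Spectrum(spectrum.mz / (1.0 + s), spectrum.intensity, spectrum.meta)
    return corrected, CalibrationReport(matched=len(pairs), shift_ppm=1e6 * s, passed=True)


# ---------------------------------------------------------------------------
# replicate outlier removal
# ---------------------------------------------------------------------------

def peaklist_similarity(
    a: PeakList, b: PeakList, tolerance: MassTolerance = DEFAULT_TOLERANCE
) -> float:
    """Match-fraction between two peak lists: shared / union (Jaccard)."""
    from .scoring import match_peaks  # local import to avoid a cycle

    if len(a) == 0 or len(b) == 0:
        return 0.0
    shared = len(match_peaks(a, b, tolerance))
    return shared / (len(a) + len(b) - shared)


def filter_outlier_replicates(
    peaklists: Sequence[PeakList],
    min_similarity: float = 0.5,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
) -> tuple[list[PeakList], list[PeakList]]:
    """Drop flatline replicates and replicates dissimilar from their peers.

    A replicate is removed when its mean pairwise match-fraction against all
    other (non-flatline) replicates falls below ``min_similarity``.  Returns
    ``(retained, removed)``; the retained set may be empty.
    """
    removed = [pl for pl in peaklists if pl.flatline or len(pl) == 0]
    candidates = [pl for pl in peaklists if not (pl.flatline or len(pl) == 0)]
    if len(candidates) <= 1:
        return candidates, removed

    sims = np.zeros((len(candidates), len(candidates)))
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            sims[i, j] = sims[j, i] = peaklist_similarity(
                candidates[i], candidates[j], tolerance
            )
    mean_sim = sims.sum(axis=1) / (len(candidates) - 1)
    retained = [pl for pl, s in zip(candidates, mean_sim) if s >= min_similarity]
    removed += [pl for pl, s in zip(candidates, mean_sim) if s < min_similarity]
    return retained, removed
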