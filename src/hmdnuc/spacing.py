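"""Nucleosome spacing estimation from metaprofile autocorrelation.

The autocorrelation is computed lag by lag as the Pearson correlation of
the series with its shifted self (each lag centered and scaled on its own
overlap), so a profile with exact period p has ACF exactly 1 at lag p.
Spacing is the lag of the highest local ACF maximum within a configurable
window, which excludes the trivial lag-0 peak and higher harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .metaprofile import MetaProfile

HMD_RANGE = (0, 1000)
METH_RANGE = (-1000, -100)


@dataclass
class SpacingEstimate:
    spacing: int  # bp == peak_lag
    acf: np.ndarray  # lags 0..max_lag, acf[0] == 1
    peak_lag: int
    peak_acf: float
    side: str  # "hmd" | "methylated"
    confident: bool


def sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Lag-by-lag Pearson autocorrelation; acf[0] = 1.

    Each lag correlates x[:n-k] with x[k:], centering and scaling on the
    overlapping segments, so exact periodicity yields an ACF of exactly 1
    at the period.  Zero-variance overlaps give 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if max_lag >= n:
        raise ValueError("max_lag must be < series length")
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        a = x[: n - k]
        b = x[k:]
        ac = a - a.mean()
        bc = b - b.mean()
        denom = np.sqrt(np.dot(ac, ac) * np.dot(bc, bc))
        acf[k] = float(np.dot(ac, bc) / denom) if denom > 0 else 0.0
    return acf


def estimate_spacing(
    profile: MetaProfile,
    side: str,
    offset_range: tuple[int, int] | None = None,
    min_lag: int = 100,
    max_lag: int = 400,
    prominence_threshold: float = 0.2,
) -> SpacingEstimate:
    """Spacing = lag of the highest local ACF maximum in [min_lag, max_lag].

    ``side`` selects the default offset range: "hmd" uses offsets 0..1000
    (domain interior), "methylated" uses -1000..-100.  Ties are broken by
    the smaller lag; ``confident`` requires a positive peak with prominence
    above the threshold.
    """
    if side not in ("hmd", "methylated"):
        raise ValueError(f"unknown side: {side}")
    if offset_range is None:
        offset_range = HMD_RANGE if side == "hmd" else METH_RANGE
    lo, hi = offset_range
    if hi - lo + 1 < 2 * max_lag:
        raise ValueError(
            f"offset range [{lo},{hi}] shorter than 2*max_lag ({2 * max_lag})"
        )
    series = profile.slice(lo, hi)
    if np.any(~np.isfinite(series)):
        raise ValueError("profile undefined within the requested range")
    acf = sample_acf(series, max_lag)

    peaks, props = find_peaks(acf, prominence=0.0)
    in_window = [(int(p), acf[p], props["prominences"][i])
                 for i, p in enumerate(peaks) if min_lag <= p <= max_lag]
    if not in_window:
        # no local maximum: fall back to argmax in window, not confident
        window = acf[min_lag : max_lag + 1]
        lag = min_lag + int(np.argmax(window))
        return SpacingEstimate(lag, acf, lag, float(acf[lag]), side, False)
    # harmonic rejection: a peak whose half-lag is itself a comparable
    # local maximum is the 2x harmonic of that peak, not the spacing
    fundamental = [
        t
        for t in in_window
        if not any(
            abs(2 * other[0] - t[0]) <= 5 and other[1] >= t[1] - 0.15
            for other in in_window
        )
    ]
    if fundamental:
        in_window = fundamental
    # highest local max; numerically tied peaks resolve to the smaller lag
    best = max(v for _, v, _ in in_window)
    lag, value, prominence = min(
        (t for t in in_window if t[1] >= best - 1e-9), key=lambda t: t[0]
    )
    confident = bool(value > 0 and prominence > prominence_threshold)
    return SpacingEstimate(lag, acf, lag, float(value), side, confident)


def boundary_linker_gap(
    profile: MetaProfile, max_gap: int = 400, min_prominence_frac: float = 0.05
) -> int:
    """Distance from the offset-0 maximum to the next local maximum at
    positive offsets (the linker-to-linker gap at a domain boundary).

    Noise bumps are rejected by requiring a peak prominence of at least
    ``min_prominence_frac`` of the segment's dynamic range.
    """
    zero_idx = int(-profile.offsets[0])
    segment = profile.mean[zero_idx : zero_idx + max_gap + 1]
    if np.any(~np.isfinite(segment)):
        raise ValueError("profile undefined in (0, max_gap]")
    if not (segment[0] >= segment[1]):
        raise ValueError("profile does not peak at offset 0")
    prominence = min_prominence_frac * (np.max(segment) - np.min(segment))
    peaks, _ = find_peaks(segment, prominence=prominence)
    peaks = peaks[peaks > 0]
    if len(peaks) == 0:
        raise ValueError(f"no local maximum in (0, {max_gap}]")
    return int(peaks[0])
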