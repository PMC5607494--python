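"""Cut-position processing, coverage tracks, and a lightweight summit caller.

The summit caller is a deterministic stand-in for an FDR-calibrated peak
caller: local maxima filtered by absolute height and fold enrichment over the
global median of nonzero signal, greedily selected with an exclusion radius.
Externally called summits (narrowPeak) are accepted anywhere summits are
needed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import GenomicInterval, SignalTrack
from .hmd import HMD

DEFAULT_SMOOTH_BW = 73  # half a nucleosome footprint


@dataclass(frozen=True)
class CutPosition:
    """5' end of a sequenced cut/insertion, with read strand."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand: {self.strand!r}")


@dataclass(frozen=True)
class Summit:
    chrom: str
    pos: int
    height: float
    enclosing_peak: GenomicInterval

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("summit height must be > 0")
        if not self.enclosing_peak.contains(self.chrom, self.pos):
            raise ValueError("summit outside its enclosing peak")


def shift_cuts(
    cuts: Sequence[CutPosition],
    shift: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
    toward_five_prime: bool = True,
) -> list[CutPosition]:
    """Shift read 5' positions along the read orientation.

    With ``toward_five_prime`` (default), plus-strand positions move upstream
    (pos - shift) and minus-strand positions move downstream (pos + shift);
    the opposite sign convention is available via the flag.  Positions are
    clipped to chromosome bounds when lengths are provided.
    """
    sign = 1 if toward_five_prime else -1
    out: list[CutPosition] = []
    for c in cuts:
        delta = -sign * shift if c.strand == "+" else sign * shift
        pos = c.pos + delta
        if chrom_lengths is not None:
            pos = min(max(pos, 0), chrom_lengths[c.chrom] - 1)
        else:
            pos = max(pos, 0)
        out.append(CutPosition(c.chrom, pos, c.strand))
    return out


def coverage(
    cuts: Sequence[CutPosition],
    chrom_lengths: Mapping[str, int],
    smooth_bw: int = DEFAULT_SMOOTH_BW,
) -> SignalTrack:
    """Per-base cut counts, boxcar-smoothed, scaled to counts per million.

    The boxcar kernel is mass-conserving away from chromosome edges; the
    total signal equals 1e6 up to edge truncation.
    """
    if smooth_bw < 0:
        raise ValueError("smooth_bw must be >= 0")
    if not cuts:
        raise ValueError("empty cut list")
    per_chrom: dict[str, np.ndarray] = {
        c: np.zeros(n) for c, n in chrom_lengths.items()
    }
    for cut in cuts:
        per_chrom[cut.chrom][cut.pos] += 1.0
    scale = 1e6 / len(cuts)
    track = SignalTrack(chrom_lengths)
    for chrom, counts in per_chrom.items():
        counts *= scale
        if smooth_bw > 1:
            kernel = np.ones(smooth_bw) / smooth_bw
            counts = np.convolve(counts, kernel, mode="same")
        track.set_values(chrom, 0, counts)
    return track


def _local_maxima(arr: np.ndarray) -> list[tuple[int, float]]:
    """Leftmost positions of strict local maxima (plateau-aware).

    Plateaus are collapsed to runs; a run is a maximum when both flanking
    runs are strictly lower (array edges count as lower)."""
    x = np.nan_to_num(arr, nan=-np.inf)
    n = len(x)
    if n == 0:
        return []
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(change)
    vals = x[starts]
    left = np.concatenate([[-np.inf], vals[:-1]])
    right = np.concatenate([vals[1:], [-np.inf]])
    ok = (vals > left) & (vals > right) & np.isfinite(vals)
    return [(int(s), float(v)) for s, v in zip(starts[ok], vals[ok])]


def call_summits(
    track: SignalTrack,
    min_height: float,
    min_separation: int = 150,
    fold_enrichment: float = 5.0,
) -> list[Summit]:
    """Greedy local-maxima summit calling with an exclusion radius.

    Candidates are local maxima with height >= ``min_height`` and
    >= ``fold_enrichment`` times the global median of nonzero signal.
    Selection is greedy by height (ties to the leftmost position); accepted
    summits exclude further candidates within ``min_separation`` bp.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    nonzero: list[np.ndarray] = []
    for arr in track.data.values():
        vals = arr[np.isfinite(arr) & (arr != 0)]
        if len(vals):
            nonzero.append(vals)
    floor = fold_enrichment * float(np.median(np.concatenate(nonzero))) if nonzero else 0.0
    threshold = max(min_height, floor)

    candidates: list[tuple[float, str, int]] = []
    for chrom in sorted(track.chroms):
        for pos, height in _local_maxima(track.data[chrom]):
            if height >= threshold:
                candidates.append((height, chrom, pos))
    # greedy: highest first, ties leftmost (then chrom lexicographic)
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    accepted: dict[str, list[int]] = {}
    summits: list[Summit] = []
    for height, chrom, pos in candidates:
        taken = accepted.setdefault(chrom, [])
        if any(abs(pos - p) < min_separation for p in taken):
            continue
        taken.append(pos)
        summits.append(
            Summit(chrom, pos, height, _enclosing_peak(track, chrom, pos, threshold))
        )
    summits.sort(key=lambda s: (s.chrom, s.pos))
    return summits


def _enclosing_peak(
    track: SignalTrack, chrom: str, pos: int, threshold: float
) -> GenomicInterval:
    """Maximal contiguous run of signal >= threshold around the summit."""
    arr = track.data[chrom]
    lo = pos
    while lo > 0 and np.isfinite(arr[lo - 1]) and arr[lo - 1] >= threshold:
        lo -= 1
    hi = pos + 1
    while hi < len(arr) and np.isfinite(arr[hi]) and arr[hi] >= threshold:
        hi += 1
    return GenomicInterval(chrom, lo, hi)


def overlap_stats(
    summits: Sequence[Summit],
    hmds: Sequence[HMD],
    genome_length: int,
) -> dict[str, float]:
    """HMD/DHS co-occurrence fractions.

    Returns ``frac_hmds_with_dhs`` (HMDs containing >=1 summit),
    ``frac_dhs_in_hmd`` (summits inside any HMD) and ``frac_genome_hmd``.
    """
    by_chrom: dict[str, list[HMD]] = {}
    for h in hmds:
        by_chrom.setdefault(h.chrom, []).append(h)
    hit_hmds: set[int] = set()
    n_in = 0
    for s in summits:
        for h in by_chrom.get(s.chrom, []):
            if h.interval.contains(s.chrom, s.pos):
                n_in += 1
                hit_hmds.add(id(h))
                break
    hmd_bp = sum(len(h.interval) for h in hmds)
    return {
        "frac_hmds_with_dhs": len(hit_hmds) / len(hmds) if hmds else 0.0,
        "frac_dhs_in_hmd": n_in / len(summits) if summits else 0.0,
        "frac_genome_hmd": hmd_bp / genome_length if genome_length else 0.0,
    }
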