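"""Boundary anchors and anchor-aligned average profiles.

Anchors are in-domain summits nearest each HMD boundary CpG, oriented so
that the methylated flank maps to negative offsets and the domain interior
to positive offsets for both boundary sides.  The 5'/3' side label comes
from the transcription direction of the nearest TSS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .genome_io import BedRecord, GenomeSequence, GenomicInterval, SignalTrack
from .accessibility import Summit
from .hmd import HMD


@dataclass(frozen=True)
class BoundaryAnchor:
    chrom: str
    pos: int
    side: str  # "5p" | "3p"
    orientation: str  # "+" if domain interior lies to the right of pos
    hmd_id: int

    def __post_init__(self) -> None:
        if self.side not in ("5p", "3p"):
            raise ValueError(f"bad side: {self.side}")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation: {self.orientation}")


@dataclass
class MetaProfile:
    """Per-offset mean of a track over oriented anchor windows."""

    offsets: np.ndarray  # bp, [-flank .. +flank]
    mean: np.ndarray  # NaN where n == 0
    n: np.ndarray  # contributing anchors per offset
    track_name: str = ""

    def value_at(self, offset: int) -> float:
        idx = int(offset - self.offsets[0])
        return float(self.mean[idx])

    def slice(self, lo: int, hi: int) -> np.ndarray:
        """Mean values over offsets lo..hi inclusive."""
        i0 = int(lo - self.offsets[0])
        i1 = int(hi - self.offsets[0])
        return self.mean[i0 : i1 + 1]


def select_anchors(
    hmds: Sequence[HMD],
    summits: Sequence[Summit],
    tss: Sequence[BedRecord],
    max_tss_dist: int = 1000,
) -> list[BoundaryAnchor]:
    """Pick the in-HMD summit nearest each boundary CpG as the anchor.

    HMDs without any internal summit contribute no anchors, and only HMDs
    with a TSS within ``max_tss_dist`` of the domain are used.  The side
    label is 5p when the nearest TSS transcribes from the methylated flank
    into the domain at that boundary, 3p otherwise.
    """
    tss_by_chrom: dict[str, list[BedRecord]] = {}
    for t in tss:
        if t.strand not in ("+", "-"):
            raise ValueError("TSS records need a strand")
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    summits_by_chrom: dict[str, list[Summit]] = {}
    for s in summits:
        summits_by_chrom.setdefault(s.chrom, []).append(s)

    anchors: list[BoundaryAnchor] = []
    for hmd_id, hmd in enumerate(hmds):
        inside = [
            s
            for s in summits_by_chrom.get(hmd.chrom, [])
            if hmd.interval.contains(s.chrom, s.pos)
        ]
        if not inside:
            continue
        chrom_tss = tss_by_chrom.get(hmd.chrom, [])
        if not any(
            _distance_to_interval(t.start, hmd.interval) <= max_tss_dist
            for t in chrom_tss
        ):
            continue
        for boundary_pos, interior_right in (
            (hmd.boundary_cpg_5p, True),
            (hmd.boundary_cpg_3p, False),
        ):
            anchor_summit = min(
                inside,
                key=lambda s: (abs(s.pos - boundary_pos), s.pos),
            )
            nearest_tss = _nearest_tss(chrom_tss, anchor_summit.pos, interior_right)
            into_domain = (nearest_tss.strand == "+") == interior_right
            anchors.append(
                BoundaryAnchor(
                    chrom=hmd.chrom,
                    pos=anchor_summit.pos,
                    side="5p" if into_domain else "3p",
                    orientation="+" if interior_right else "-",
                    hmd_id=hmd_id,
                )
            )
    return anchors


def _distance_to_interval(pos: int, iv: GenomicInterval) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - iv.end + 1
    return 0


def _nearest_tss(tss: list[BedRecord], pos: int, interior_right: bool) -> BedRecord:
    # ties broken toward the domain interior
    def key(t: BedRecord) -> tuple[int, int]:
        d = abs(t.start - pos)
        toward_interior = (t.start >= pos) == interior_right
        return (d, 0 if toward_interior else 1)

    return min(tss, key=key)


def metaprofile(
    track: SignalTrack,
    anchors: Sequence[BoundaryAnchor],
    flank: int = 1000,
    orient: bool = True,
    track_name: str = "",
) -> MetaProfile:
    """Average a track over anchor-centered windows.

    With ``orient`` true, windows whose anchor orientation is "-" are
    reversed so the domain interior always maps to positive offsets.
    Undefined track positions are excluded from both the numerator and the
    per-offset count.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if not anchors:
        raise ValueError("no anchors")
    width = 2 * flank + 1
    total = np.zeros(width)
    n = np.zeros(width, dtype=np.int64)
    for a in anchors:
        window = track.values(a.chrom, a.pos - flank, a.pos + flank + 1)
        if orient and a.orientation == "-":
            window = window[::-1]
        ok = np.isfinite(window)
        total[ok] += window[ok]
        n += ok
    mean = np.full(width, np.nan)
    mean[n > 0] = total[n > 0] / n[n > 0]
    return MetaProfile(np.arange(-flank, flank + 1), mean, n, track_name)


# ---------------------------------------------------------------------------
# Per-base feature tracks


def kmer_occurrence_track(genome: GenomeSequence, kmer: str) -> SignalTrack:
    """1.0 at the start of every forward-strand occurrence, 0 elsewhere."""
    kmer = kmer.upper()
    if set(kmer) - set("ACGT"):
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer}")
    track = SignalTrack(genome.lengths())
    for chrom in genome.chroms:
        seq = genome[chrom]
        arr = np.zeros(len(seq))
        start = seq.find(kmer)
        while start != -1:
            arr[start] = 1.0
            start = seq.find(kmer, start + 1)  # overlapping matches count
        track.set_values(chrom, 0, arr)
    return track


def snp_rate_track(
    snps: Sequence[BedRecord], chrom_lengths: dict[str, int], binsize: int = 10
) -> SignalTrack:
    """SNPs per bp in non-overlapping bins, broadcast to per-base values."""
    if binsize <= 0:
        raise ValueError("binsize must be > 0")
    track = SignalTrack(chrom_lengths)
    counts: dict[str, np.ndarray] = {
        c: np.zeros(-(-n // binsize)) for c, n in chrom_lengths.items()
    }
    for s in snps:
        counts[s.chrom][s.start // binsize] += 1
    for chrom, length in chrom_lengths.items():
        per_base = np.repeat(counts[chrom] / binsize, binsize)[:length]
        track.set_values(chrom, 0, per_base)
    return track


def position_count_track(
    records: Sequence[BedRecord], chrom_lengths: dict[str, int]
) -> SignalTrack:
    """Counts of record start positions per base (TSS or dyad counts)."""
    track = SignalTrack(chrom_lengths)
    arrays = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for r in records:
        if 0 <= r.start < chrom_lengths[r.chrom]:
            arrays[r.chrom][r.start] += 1.0
    for chrom, arr in arrays.items():
        track.set_values(chrom, 0, arr)
    return track
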