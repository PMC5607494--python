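"""Periodicity of high-weight k-mers inside HMDs.

Occurrences of the top-weight k-mers are pooled per domain (forward strand)
and all within-domain pairwise distances are histogrammed; self-overlap
artifacts are removed by excluding distances below a minimum (3 bp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import GenomeSequence
from .hmd import HMD
from .svm import KmerModel, code_to_kmer


@dataclass
class MotifOccurrenceSet:
    kmers: list[str]
    occurrences: list[np.ndarray]  # per-HMD sorted start positions, pooled


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    min_dist: int
    mode_bin_center: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def top_kmers(model: KmerModel, n: int = 10) -> list[str]:
    """The n k-mers with the largest signed weights; ties lexicographic."""
    if n > len(model.weights):
        raise ValueError("n exceeds number of k-mers")
    order = np.argsort(-model.weights, kind="stable")
    return [code_to_kmer(int(i), model.k) for i in order[:n]]


def reverse_kmer(kmer: str) -> str:
    """String reversal (not reverse complement): same base composition,
    different base ordering."""
    if set(kmer.upper()) - set("ACGT"):
        raise ValueError(f"non-ACGT base in k-mer: {kmer}")
    return kmer[::-1]


def scan_occurrences(
    hmds: Sequence[HMD], genome: GenomeSequence, kmers: Sequence[str]
) -> MotifOccurrenceSet:
    """Forward-strand occurrence starts of any listed k-mer, pooled and
    sorted within each HMD (absolute coordinates)."""
    occ: list[np.ndarray] = []
    for h in hmds:
        seq = genome.fetch_interval(h.interval)
        starts: list[int] = []
        for kmer in kmers:
            i = seq.find(kmer)
            while i != -1:
                starts.append(h.interval.start + i)
                i = seq.find(kmer, i + 1)
        occ.append(np.array(sorted(starts), dtype=np.int64))
    return MotifOccurrenceSet(list(kmers), occ)


def pairwise_distance_histogram(
    occ: MotifOccurrenceSet,
    min_dist: int = 3,
    max_dist: int = 1000,
    binwidth: int = 10,
) -> DistanceHistogram:
    """Histogram of |start_i - start_j| over all unordered within-HMD pairs.

    Distances < min_dist (self-overlap artifacts) and > max_dist are
    excluded.  Bins are [min_dist + m*binwidth, min_dist + (m+1)*binwidth).
    Cross-domain pairs never form: occurrences are pooled per domain.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be > 0")
    edges = np.arange(min_dist, max_dist + binwidth, binwidth)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for positions in occ.occurrences:
        if len(positions) < 2:
            continue
        diffs = np.abs(positions[:, None] - positions[None, :])
        d = diffs[np.triu_indices(len(positions), k=1)]
        d = d[(d >= min_dist) & (d <= max_dist)]
        if len(d):
            idx = np.minimum((d - min_dist) // binwidth, len(counts) - 1)
            counts += np.bincount(idx, minlength=len(counts))
    if counts.sum():
        mode = int(np.argmax(counts))
        center = float(edges[mode]) + binwidth / 2.0
    else:
        center = float("nan")
    return DistanceHistogram(edges, counts, min_dist, center)
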