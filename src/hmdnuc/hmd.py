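"""Segmentation of a methylome into hypomethylated domains (HMDs).

An HMD is a maximal run of at least ``min_cpgs`` consecutive CpGs whose
methylation ratio is strictly below ``ratio_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomeSequence, GenomicInterval, MethylationRecord


@dataclass(frozen=True)
class HMD:
    """A called hypomethylated domain and its CpG support."""

    interval: GenomicInterval
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.cpg_positions
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be sorted")
        if pos and not (
            self.interval.start <= pos[0] and pos[-1] < self.interval.end
        ):
            raise ValueError("cpg_positions outside interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def boundary_cpg_5p(self) -> int:
        """First (leftmost) low-methylated CpG."""
        return self.cpg_positions[0]

    @property
    def boundary_cpg_3p(self) -> int:
        """Last (rightmost) low-methylated CpG."""
        return self.cpg_positions[-1]


def call_hmds(
    meth: Sequence[MethylationRecord],
    min_cpgs: int = 10,
    ratio_threshold: float = 0.4,
    max_gap: int | None = None,
) -> list[HMD]:
    """Call HMDs as maximal runs of consecutive low-methylated CpGs.

    Parameters
    ----------
    meth:
        Records sorted by (chrom, pos), one per CpG.
    min_cpgs:
        Minimum run length; shorter runs are discarded.
    ratio_threshold:
        CpGs with ratio strictly below this belong to a run.
    max_gap:
        Optional cap on the genomic distance between consecutive run
        members; ``None`` (default) imposes no cap.

    The HMD interval spans from the first to the last CpG of the run, with
    end = last position + 2 so the closing CpG dinucleotide is covered.
    """
    if not 0.0 <= ratio_threshold <= 1.0:
        raise ValueError("ratio_threshold must be in [0,1]")
    prev: MethylationRecord | None = None
    for r in meth:
        if prev is not None and (r.chrom, r.pos) < (prev.chrom, prev.pos):
            raise ValueError(
                f"methylation records unsorted at {r.chrom}:{r.pos}"
            )
        prev = r

    hmds: list[HMD] = []
    run: list[int] = []
    run_chrom: str | None = None

    def flush() -> None:
        if run_chrom is not None and len(run) >= min_cpgs:
            hmds.append(
                HMD(
                    GenomicInterval(run_chrom, run[0], run[-1] + 2),
                    tuple(run),
                )
            )

    for rec in meth:
        low = rec.ratio < ratio_threshold
        broke_gap = (
            max_gap is not None and run and rec.pos - run[-1] > max_gap
        )
        if rec.chrom != run_chrom or not low or broke_gap:
            flush()
            run = []
            run_chrom = rec.chrom if low else None
        if low:
            run.append(rec.pos)
            run_chrom = rec.chrom
    flush()
    return hmds


def genome_fraction(hmds: Iterable[HMD], genome: GenomeSequence) -> float:
    """Fraction of genome bp covered by (non-overlapping) HMDs."""
    ivs = sorted((h.interval for h in hmds), key=lambda i: (i.chrom, i.start))
    total = 0
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping HMDs: {a} / {b}")
    for iv in ivs:
        total += len(iv)
    return total / genome.total_length()
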