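"""Domain types and readers/writers for the standard formats used throughout.

All coordinates are 0-based, half-open ([start, end)), matching BED/bedGraph.
Any 1-based convention in external material is converted at this boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGTN")
_TRANSLATE_TO_N = str.maketrans(
    {c: "N" for c in map(chr, range(65, 91)) if c not in "ACGT"}
)


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class BedRecord(GenomicInterval):
    """BED/narrowPeak record: interval plus the optional annotation columns."""

    name: str | None = None
    score: float | None = None
    strand: str | None = None
    summit_offset: int | None = None  # narrowPeak col 10, relative to start

    @property
    def summit(self) -> int | None:
        """Absolute summit position, if the record carries one."""
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset


@dataclass(frozen=True)
class MethylationRecord:
    """Per-CpG methylation level; pos points at the C of the CpG."""

    chrom: str
    pos: int
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"methylation ratio outside [0,1]: {self.ratio}")


class GenomeSequence:
    """In-memory genome: uppercase sequences over {A,C,G,T,N}."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("empty genome")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper().translate(_TRANSLATE_TO_N)
            if set(seq) - _VALID_BASES:
                raise ValueError(f"invalid characters in sequence {name}")
            self._seqs[name] = seq

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self._seqs[chrom]):
            raise IndexError(
                f"{chrom}:{start}-{end} out of bounds (len {len(self._seqs[chrom])})"
            )
        return self._seqs[chrom][start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.chrom, iv.start, iv.end)


class SignalTrack:
    """Per-base float signal with explicit undefined regions (stored as NaN).

    Undefined positions are distinct from zeros: they are excluded from
    means and metaprofile denominators.
    """

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.data: dict[str, np.ndarray] = {
            c: np.full(n, np.nan, dtype=np.float64) for c, n in chrom_lengths.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    def set_values(self, chrom: str, start: int, values: np.ndarray) -> None:
        arr = self.data[chrom]
        end = start + len(values)
        if start < 0 or end > len(arr):
            raise IndexError(f"{chrom}:{start}-{end} outside track bounds")
        arr[start:end] = values

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions outside the chromosome are NaN."""
        arr = self.data[chrom]
        out = np.full(end - start, np.nan)
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean_over(self, iv: GenomicInterval) -> float:
        v = self.values(iv.chrom, iv.start, iv.end)
        if np.all(np.isnan(v)):
            return np.nan
        return float(np.nanmean(v))

    def defined_fraction(self) -> float:
        total = sum(len(a) for a in self.data.values())
        defined = sum(int(np.sum(~np.isnan(a))) for a in self.data.values())
        return defined / total if total else 0.0


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read FASTA; uppercases and maps non-ACGT letters to N."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in sorted(genome.chroms)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path, chrom_lengths: Mapping[str, int] | None = None
) -> SignalTrack:
    """Read a 4-column bedGraph into a dense track; gaps stay undefined.

    Intervals must be non-overlapping within each chromosome.  If
    ``chrom_lengths`` is omitted, each chromosome is sized to its last
    interval end.
    """
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            start, end = int(start), int(end)
            if start < 0:
                raise ValueError(f"{path}:{ln}: negative coordinate")
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty interval")
            rows.append((chrom, start, end, float(value)))

    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, _, end, _ in rows:
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), end)

    track = SignalTrack(chrom_lengths)
    last_end: dict[str, int] = {}
    for chrom, start, end, value in sorted(rows, key=lambda r: (r[0], r[1])):
        if start < last_end.get(chrom, 0):
            raise ValueError(f"overlapping bedGraph intervals on {chrom} at {start}")
        last_end[chrom] = end
        track.set_values(chrom, start, np.full(end - start, value))
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write defined runs; adjacent runs of equal value are merged."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            arr = track.data[chrom]
            defined = ~np.isnan(arr)
            if not defined.any():
                continue
            # run-length encode over (defined, value) change points
            change = np.empty(len(arr), dtype=bool)
            change[0] = True
            same = (arr[1:] == arr[:-1]) | (np.isnan(arr[1:]) & np.isnan(arr[:-1]))
            change[1:] = ~same
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], len(arr))
            for s, e in zip(starts, ends):
                if np.isnan(arr[s]):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak


def read_intervals(path: str | Path, format: str = "bed") -> list[BedRecord]:
    """Read BED (>=3 columns) or narrowPeak (10 columns) records.

    narrowPeak column 10 is the summit offset from start; strand and summit
    are preserved on the returned records.
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown interval format: {format}")
    records: list[BedRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if format == "narrowPeak" and len(parts) != 10:
                raise ValueError(
                    f"{path}:{ln}: narrowPeak needs 10 columns, got {len(parts)}"
                )
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = (
                float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            )
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            summit_offset = None
            if format == "narrowPeak":
                summit_offset = int(parts[9])
                if summit_offset < 0:
                    summit_offset = None  # -1 means "no summit"
            records.append(
                BedRecord(chrom, start, end, name, score, strand, summit_offset)
            )
    return records


def write_intervals(
    records: Iterable[BedRecord], path: str | Path, format: str = "bed"
) -> None:
    """Write records in deterministic order (chrom, start)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            if format == "narrowPeak":
                fh.write(
                    "\t".join(
                        [
                            r.chrom,
                            str(r.start),
                            str(r.end),
                            r.name or ".",
                            str(int(r.score)) if r.score is not None else "0",
                            r.strand or ".",
                            "0",
                            "-1",
                            "-1",
                            str(r.summit_offset if r.summit_offset is not None else -1),
                        ]
                    )
                    + "\n"
                )
            else:
                cols = [r.chrom, str(r.start), str(r.end)]
                if r.name is not None or r.score is not None or r.strand is not None:
                    cols.append(r.name or ".")
                    cols.append(f"{r.score:.6g}" if r.score is not None else ".")
                    cols.append(r.strand or ".")
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Methylation TSV (chrom, pos, ratio)


def read_methylation(path: str | Path) -> list[MethylationRecord]:
    records: list[MethylationRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns")
            records.append(
                MethylationRecord(parts[0], int(parts[1]), float(parts[2]))
            )
    return records


def write_methylation(records: Iterable[MethylationRecord], path: str | Path) -> None:
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ratio:.6g}\n")
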