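"""Synthetic chromatin generator with known ground truth.

Produces a toy genome in which every statistical assumption of the analysis
holds by construction: a mostly methylated genome with hypomethylated
domains (HMDs), phased nucleosome arrays with distinct spacing inside
(200 bp) and outside (180 bp) domains, a wide linker at the 5' domain
boundary carrying the TSS, linker-planted 6-mers inside domains only,
linker-peaked accessibility cuts, dyad-peaked nucleosome reads genome-wide,
and depressed SNP density in domain linkers.  All randomness flows from one
seed through named per-track generators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import (
    BedRecord,
    GenomeSequence,
    GenomicInterval,
    MethylationRecord,
    write_fasta,
    write_intervals,
    write_methylation,
)
from .accessibility import CutPosition

_STREAMS = (
    "layout",
    "sequence",
    "cpg",
    "methylation",
    "motif",
    "dnase",
    "mnase",
    "snp",
    "degrade",
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 1_250_000  # 5 Mb total at defaults
    n_hmds: int = 200
    hmd_len_min: int = 1000
    hmd_len_max: int = 3000
    cpg_spacing_mean: int = 50
    meth_beta_hmd: tuple[float, float] = (2.0, 18.0)  # mean 0.1
    meth_beta_background: tuple[float, float] = (17.0, 3.0)  # mean 0.85
    spacing_hmd: int = 200
    spacing_meth: int = 180
    boundary_gap_5p: int = 250
    linker_offset: int = 30  # first linker center, bp inside the boundary
    # chosen so that no motif's reversal shares a 5-mer with any planted
    # motif (reversals must stay unpredictive) and none contains a CpG
    linker_motifs: tuple[str, ...] = (
        "GCTAAC",
        "AAGAGG",
        "ACTTGG",
        "TCCTTA",
        "TTGTCA",
    )
    motif_plant_prob: float = 0.9
    # start offsets of planted sites relative to each linker center; each
    # site is planted independently with motif_plant_prob
    motif_offsets: tuple[int, ...] = (-3, 9)
    dyad_jitter_sd: float = 15.0
    cut_jitter_sd: float = 10.0
    cut_shift: int = 50  # emitted read 5' ends sit this far from the cut
    cuts_per_linker: float = 60.0
    background_cut_rate: float = 0.002  # cuts per bp outside linkers
    reads_per_dyad: float = 20.0
    snp_rate_core: float = 0.01
    snp_rate_linker: float = 0.002
    linker_zone_halfwidth: int = 30
    tss_at_5p: bool = True
    gc_content: float = 0.5
    holdout_chrom: str = "chr4"

    def __post_init__(self) -> None:
        if self.spacing_hmd <= 147 or self.spacing_meth <= 147:
            raise ValueError("nucleosome spacing must exceed the 147-bp footprint")
        for p in (self.motif_plant_prob, self.gc_content):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        for m in self.linker_motifs:
            if set(m) - set("ACGT"):
                raise ValueError(f"motif contains non-ACGT base: {m}")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class SyntheticTruth:
    """Generator ground truth for parameter-recovery tests."""

    hmds: list[BedRecord]  # strand = transcription orientation
    linker_centers: list[list[int]]  # per HMD, 5' boundary first
    dyad_positions: dict[str, np.ndarray]
    motif_sites: list[tuple[str, int, str]]  # (chrom, start, motif)
    tss: list[BedRecord]
    snps: list[BedRecord]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeSequence
    methylation: list[MethylationRecord]
    dnase_cuts: list[CutPosition]
    mnase_midpoints: list[BedRecord]
    tss: list[BedRecord]
    snps: list[BedRecord]
    truth: SyntheticTruth


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_STREAMS, children)}


def _place_hmds(config: SyntheticConfig, rng: np.random.Generator) -> list[BedRecord]:
    """Slot-based placement: non-overlapping, well separated, away from
    chromosome edges; strand (transcription orientation) is random."""
    per_chrom = -(-config.n_hmds // config.n_chroms)
    margin = 3000
    hmds: list[BedRecord] = []
    for chrom in config.chroms:
        slot = config.chrom_length // per_chrom
        if slot < config.hmd_len_max + 2 * margin:
            raise ValueError("chromosome too short for requested HMD layout")
        for i in range(per_chrom):
            if len(hmds) >= config.n_hmds:
                break
            length = int(rng.integers(config.hmd_len_min, config.hmd_len_max + 1))
            lo = i * slot + margin
            hi = (i + 1) * slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            hmds.append(BedRecord(chrom, start, start + length, strand=strand))
    return hmds


def _linker_centers(hmd: BedRecord, config: SyntheticConfig) -> list[int]:
    """Linker centers, 5'-boundary linker first, then the wide gap, then
    regular spacing; linkers stay clear of the far domain edge."""
    inner_margin = 50
    centers: list[int] = []
    if hmd.strand == "+":
        c = hmd.start + config.linker_offset
        limit = hmd.end - inner_margin
        centers.append(c)
        c += config.boundary_gap_5p
        while c < limit:
            centers.append(c)
            c += config.spacing_hmd
    else:
        c = hmd.end - 1 - config.linker_offset
        limit = hmd.start + inner_margin
        centers.append(c)
        c -= config.boundary_gap_5p
        while c > limit:
            centers.append(c)
            c -= config.spacing_hmd
    return centers


def generate(config: SyntheticConfig) -> SyntheticDataset:
    rng = _rngs(config.seed)
    chrom_len = config.chrom_length
    chroms = config.chroms

    hmds = _place_hmds(config, rng["layout"])
    hmds_by_chrom: dict[str, list[BedRecord]] = {c: [] for c in chroms}
    for h in hmds:
        hmds_by_chrom[h.chrom].append(h)
    linkers = [_linker_centers(h, config) for h in hmds]

    # --- nucleosome dyads -------------------------------------------------
    # Inside each domain: dyads at midpoints between adjacent linkers.
    # Methylated space: arrays spaced `spacing_meth`, phased outward from the
    # 5' boundary linker of the adjacent domain when one abuts the gap.
    dyads: dict[str, list[int]] = {c: [] for c in chroms}
    half = config.spacing_hmd // 2
    for h, centers in zip(hmds, linkers):
        # one dyad between each adjacent linker pair, on the regular
        # spacing grid anchored at the post-gap linker (the wide 5'
        # boundary gap therefore carries an off-center dyad)
        sign = -1 if h.strand == "+" else +1
        for c in centers[1:]:
            dyads[h.chrom].append(c + sign * half)

    for chrom in chroms:
        chrom_hmds = sorted(hmds_by_chrom[chrom], key=lambda h: h.start)
        edges = [0] + [x for h in chrom_hmds for x in (h.start, h.end)] + [chrom_len]
        gaps = [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2)]
        for gi, (glo, ghi) in enumerate(gaps):
            left = chrom_hmds[gi - 1] if gi > 0 else None
            right = chrom_hmds[gi] if gi < len(chrom_hmds) else None
            anchors: list[tuple[int, int]] = []  # (phase origin, direction)
            if right is not None and right.strand == "+":
                c0 = right.start + config.linker_offset
                anchors.append((c0, -1))
            if left is not None and left.strand == "-":
                c0 = left.end - 1 - config.linker_offset
                anchors.append((c0, +1))
            if not anchors:
                anchors.append((glo + 90, +1))
            if len(anchors) == 1:
                regions = [(glo, ghi)]
            else:
                # gap claimed from both sides: split at the midpoint, each
                # array phased from its own boundary linker
                mid = (glo + ghi) // 2
                regions = [
                    (mid, ghi) if direction == -1 else (glo, mid)
                    for _, direction in anchors
                ]
            for (origin, direction), (lo, hi) in zip(anchors, regions):
                pos = origin + direction * 90
                while lo <= pos < hi:
                    dyads[chrom].append(pos)
                    pos += direction * config.spacing_meth
    dyad_positions = {c: np.array(sorted(set(v)), dtype=np.int64) for c, v in dyads.items()}

    # --- CpGs and methylation ratios -------------------------------------
    cpg_rng = rng["cpg"]
    motif_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    motif_rng = rng["motif"]
    planted: list[tuple[str, int, str]] = []
    for h, centers in zip(hmds, linkers):
        for c in centers:
            for off in config.motif_offsets:
                if motif_rng.random() < config.motif_plant_prob:
                    motif = config.linker_motifs[
                        int(motif_rng.integers(len(config.linker_motifs)))
                    ]
                    start = c + off
                    planted.append((h.chrom, start, motif))
                    motif_spans[h.chrom].append((start, start + 6))

    cpg_positions: dict[str, np.ndarray] = {}
    for chrom in chroms:
        gaps = cpg_rng.geometric(1.0 / config.cpg_spacing_mean, size=2 * chrom_len // config.cpg_spacing_mean)
        pos = np.cumsum(gaps)
        pos = pos[pos < chrom_len - 2]
        forced = []
        for h in hmds_by_chrom[chrom]:
            forced.extend([h.start, h.end - 2])
        pos = np.unique(np.concatenate([pos, np.array(forced, dtype=np.int64)]))
        # keep CpGs clear of planted motifs and of each other
        spans = motif_spans[chrom]
        if spans:
            bad = np.zeros(len(pos), dtype=bool)
            for mlo, mhi in spans:
                bad |= (pos >= mlo - 1) & (pos < mhi)
            pos = pos[~bad]
        keep = np.ones(len(pos), dtype=bool)
        keep[1:] = np.diff(pos) >= 2
        cpg_positions[chrom] = pos[keep]

    meth_rng = rng["methylation"]
    methylation: list[MethylationRecord] = []
    for chrom in chroms:
        pos = cpg_positions[chrom]
        in_hmd = np.zeros(len(pos), dtype=bool)
        for h in hmds_by_chrom[chrom]:
            in_hmd |= (pos >= h.start) & (pos < h.end)
        a_h, b_h = config.meth_beta_hmd
        a_b, b_b = config.meth_beta_background
        ratios = np.where(
            in_hmd,
            meth_rng.beta(a_h, b_h, size=len(pos)),
            meth_rng.beta(a_b, b_b, size=len(pos)),
        )
        methylation.extend(
            MethylationRecord(chrom, int(p), float(r)) for p, r in zip(pos, ratios)
        )

    # --- genome sequence --------------------------------------------------
    seq_rng = rng["sequence"]
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    for chrom in chroms:
        arr = seq_rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=chrom_len, p=base_p)
        for p in cpg_positions[chrom]:
            arr[p] = ord("C")
            arr[p + 1] = ord("G")
        for mchrom, mstart, motif in planted:
            if mchrom == chrom:
                arr[mstart : mstart + 6] = np.frombuffer(motif.encode(), dtype=np.uint8)
        sequences[chrom] = arr.tobytes().decode("ascii")
    genome = GenomeSequence(sequences)

    # --- DNase cuts (5' read ends, offset by cut_shift along the strand) --
    dnase_rng = rng["dnase"]
    cuts: list[CutPosition] = []
    for h, centers in zip(hmds, linkers):
        for c in centers:
            n = int(dnase_rng.poisson(config.cuts_per_linker))
            offs = dnase_rng.normal(0.0, config.cut_jitter_sd, size=n)
            strands = dnase_rng.random(n) < 0.5
            for off, plus in zip(offs, strands):
                cut = int(round(c + off))
                pos = cut + config.cut_shift if plus else cut - config.cut_shift
                pos = min(max(pos, 0), chrom_len - 1)
                cuts.append(CutPosition(h.chrom, pos, "+" if plus else "-"))
    n_bg = int(dnase_rng.poisson(config.background_cut_rate * chrom_len * len(chroms)))
    bg_chrom = dnase_rng.integers(0, len(chroms), size=n_bg)
    bg_pos = dnase_rng.integers(0, chrom_len, size=n_bg)
    bg_strand = dnase_rng.random(n_bg) < 0.5
    for ci, p, plus in zip(bg_chrom, bg_pos, bg_strand):
        cuts.append(CutPosition(chroms[int(ci)], int(p), "+" if plus else "-"))

    # --- MNase midpoints --------------------------------------------------
    mnase_rng = rng["mnase"]
    midpoints: list[BedRecord] = []
    for chrom in chroms:
        d = dyad_positions[chrom]
        n_reads = mnase_rng.poisson(config.reads_per_dyad, size=len(d))
        centers = np.repeat(d, n_reads).astype(float)
        centers += mnase_rng.normal(0.0, config.dyad_jitter_sd, size=len(centers))
        centers = np.clip(np.round(centers), 0, chrom_len - 1).astype(np.int64)
        midpoints.extend(BedRecord(chrom, int(p), int(p) + 1) for p in centers)

    # --- TSS --------------------------------------------------------------
    tss: list[BedRecord] = []
    if config.tss_at_5p:
        for h, centers in zip(hmds, linkers):
            tss.append(BedRecord(h.chrom, centers[0], centers[0] + 1, strand=h.strand))

    # --- SNPs -------------------------------------------------------------
    snp_rng = rng["snp"]
    snps: list[BedRecord] = []
    for chrom in chroms:
        rate = np.full(chrom_len, config.snp_rate_core)
        for h, centers in zip(hmds, linkers):
            if h.chrom != chrom:
                continue
            for c in centers:
                lo = max(0, c - config.linker_zone_halfwidth)
                hi = min(chrom_len, c + config.linker_zone_halfwidth + 1)
                rate[lo:hi] = config.snp_rate_linker
        hit = np.flatnonzero(snp_rng.random(chrom_len) < rate)
        snps.extend(BedRecord(chrom, int(p), int(p) + 1) for p in hit)

    truth = SyntheticTruth(
        hmds=hmds,
        linker_centers=linkers,
        dyad_positions=dyad_positions,
        motif_sites=planted,
        tss=tss,
        snps=snps,
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        methylation=methylation,
        dnase_cuts=cuts,
        mnase_midpoints=midpoints,
        tss=tss,
        snps=snps,
        truth=truth,
    )


def degrade(dataset: SyntheticDataset, level: float) -> SyntheticDataset:
    """Return a noisier copy: cut/read counts scaled down and positional
    jitter scaled up with ``level`` in [0,1]; level 0 is the identity."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0,1]")
    if level == 0.0:
        return dataset
    rng = _rngs(dataset.config.seed)["degrade"]
    keep = 1.0 - 0.9 * level
    extra_sd = 60.0 * level
    chrom_len = dataset.config.chrom_length

    kept_cuts = [c for c in dataset.dnase_cuts if rng.random() < keep]
    cuts = [
        CutPosition(
            c.chrom,
            int(min(max(round(c.pos + rng.normal(0.0, extra_sd)), 0), chrom_len - 1)),
            c.strand,
        )
        for c in kept_cuts
    ]
    kept_mid = [m for m in dataset.mnase_midpoints if rng.random() < keep]
    mids = []
    for m in kept_mid:
        p = int(min(max(round(m.start + rng.normal(0.0, extra_sd)), 0), chrom_len - 1))
        mids.append(BedRecord(m.chrom, p, p + 1))
    return replace(dataset, dnase_cuts=cuts, mnase_midpoints=mids)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all tracks in their standard formats plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "methylation": outdir / "meth.tsv",
        "dnase_cuts": outdir / "dnase_cuts.bed",
        "mnase_dyads": outdir / "mnase_dyads.bed",
        "tss": outdir / "tss.bed",
        "snps": outdir / "snps.bed",
        "truth": outdir / "truth.json",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_methylation(dataset.methylation, paths["methylation"])
    cut_records = [
        BedRecord(c.chrom, c.pos, c.pos + 1, strand=c.strand)
        for c in dataset.dnase_cuts
    ]
    write_intervals(cut_records, paths["dnase_cuts"])
    write_intervals(dataset.mnase_midpoints, paths["mnase_dyads"])
    write_intervals(dataset.tss, paths["tss"])
    write_intervals(dataset.snps, paths["snps"])
    truth = dataset.truth
    payload = {
        "hmds": [
            [h.chrom, h.start, h.end, h.strand] for h in truth.hmds
        ],
        "linker_centers": truth.linker_centers,
        "dyad_positions": {c: v.tolist() for c, v in truth.dyad_positions.items()},
        "motif_sites": truth.motif_sites,
        "tss": [[t.chrom, t.start, t.strand] for t in truth.tss],
        "n_snps": len(truth.snps),
        "config": {
            k: v for k, v in asdict(dataset.config).items()
        },
    }
    paths["truth"].write_text(json.dumps(payload))
    return paths
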