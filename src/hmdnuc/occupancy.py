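"""Equilibrium nucleosome occupancy from sequence via a hard-rod model.

Non-overlapping rods of a fixed footprint populate the sequence under a
Boltzmann distribution with per-start binding energies and a fugacity
(effective concentration).  The exact marginal placement probabilities are
obtained by forward/backward dynamic programming in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

FOOTPRINT = 147


@dataclass
class EnergyModel:
    """Per-start binding energies (lower = tighter binding)."""

    footprint: int
    energies: Callable[[str], np.ndarray]  # seq -> E over starts 0..L-footprint
    source: str = ""

    def __post_init__(self) -> None:
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1")


@dataclass
class OccupancyProfile:
    occupancy: np.ndarray  # per-base, in [0,1]
    p_start: np.ndarray  # per-start placement probability
    fugacity: float
    log_partition: float


def gc_energy_model(weight: float, footprint: int = FOOTPRINT) -> EnergyModel:
    """E(i) = -weight * (GC fraction of the footprint window starting at i).

    Positive weight makes GC-rich windows favorable for the rod (core), the
    global tendency this model family was built to capture."""

    def energies(seq: str) -> np.ndarray:
        is_gc = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(gc)])
        window_gc = (cum[footprint:] - cum[:-footprint]) / footprint
        return -weight * window_gc

    return EnergyModel(footprint, energies, source=f"gc:{weight}")


def tabulated_energy_model(path: str | Path, footprint: int = FOOTPRINT) -> EnergyModel:
    """Load per-position dinucleotide log-probabilities from a TSV table.

    Rows: ``pos<TAB>dinuc<TAB>logp``; rows with pos = -1 give the background
    dinucleotide log-probabilities.  The rod energy at start i is
    -sum_j [logp(dinuc at offset j) - logbg(dinuc)] over the footprint's
    dinucleotide offsets j = 0..footprint-2.
    """
    table: dict[tuple[int, str], float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected pos<TAB>dinuc<TAB>logp")
            table[(int(parts[0]), parts[1].upper())] = float(parts[2])
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    bg = {d: table.get((-1, d), np.log(1 / 16)) for d in dinucs}
    n_pos = footprint - 1
    for j in range(n_pos):
        for d in dinucs:
            if (j, d) not in table:
                raise ValueError(f"missing table entry pos={j} dinuc={d}")

    def energies(seq: str) -> np.ndarray:
        seq = seq.upper()
        L = len(seq)
        out = np.zeros(L - footprint + 1)
        for i in range(L - footprint + 1):
            e = 0.0
            for j in range(n_pos):
                d = seq[i + j : i + j + 2]
                e -= table[(j, d)] - bg[d]
            out[i] = e
        return out

    return EnergyModel(footprint, energies, source=str(path))


def occupancy(seq: str, model: EnergyModel, fugacity: float = 1.0) -> OccupancyProfile:
    """Exact per-base expected occupancy of the hard-rod ensemble.

    Forward sums F and backward sums R give the placement probability of a
    rod at start i as F[i] * z * exp(-E[i]) * R[i+footprint] / Z; occupancy
    is the prefix-sum of placement probabilities over covering starts.
    Rods must lie fully inside the sequence.
    """
    if fugacity <= 0:
        raise ValueError("fugacity must be > 0")
    f = model.footprint
    L = len(seq)
    if L < f:
        raise ValueError(f"sequence length {L} < footprint {f}")
    E = np.asarray(model.energies(seq), dtype=float)
    if len(E) != L - f + 1 or not np.all(np.isfinite(E)):
        raise ValueError("energy model returned invalid energies")
    logw = np.log(fugacity) - E  # log statistical weight of each rod

    logF = np.zeros(L + 1)
    for i in range(1, L + 1):
        logF[i] = logF[i - 1]
        if i >= f:
            logF[i] = np.logaddexp(logF[i], logF[i - f] + logw[i - f])
    logR = np.zeros(L + 2)
    for i in range(L - 1, -1, -1):
        logR[i] = logR[i + 1]
        if i <= L - f:
            logR[i] = np.logaddexp(logR[i], logw[i] + logR[i + f])
    logZ = logF[L]

    p_start = np.exp(logF[: L - f + 1] + logw + logR[f : L + 1] - logZ)
    cum = np.concatenate([[0.0], np.cumsum(p_start)])
    occ = np.empty(L)
    for j in range(L):
        lo = max(0, j - f + 1)
        hi = min(j, L - f)
        occ[j] = cum[hi + 1] - cum[lo] if hi >= lo else 0.0
    occ = np.clip(occ, 0.0, 1.0)
    return OccupancyProfile(occ, p_start, fugacity, float(logZ))
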