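"""Linear k-mer spectrum classifiers for linker and domain prediction.

Two classifiers are built from the same machinery: one discriminating
accessible-linker sequences from nucleosome-core sequences inside HMDs
(100-bp windows around summits vs. midpoints of adjacent summit pairs),
and one discriminating whole HMD sequences from length-matched methylated
background placements.  Both expose per-k-mer weights; train/test splits
are by holdout chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.svm import LinearSVC

from .genome_io import BedRecord, GenomeSequence, GenomicInterval, SignalTrack
from .accessibility import Summit
from .hmd import HMD

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Per-base codes A=0 C=1 G=2 T=3; anything else becomes -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_window_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of each overlapping k-mer; -1 where a window contains N."""
    codes = encode_bases(seq)
    n = len(codes) - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        out = out * 4 + np.where(c < 0, 0, c)
        bad |= c < 0
    out[bad] = -1
    return out


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer.upper():
        i = _BASES.find(b)
        if i < 0:
            raise ValueError(f"non-ACGT base in k-mer: {kmer}")
        code = code * 4 + i
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


@lru_cache(maxsize=8)
def _revcomp_permutation(k: int) -> np.ndarray:
    """Map each k-mer code to the code of its reverse complement."""
    n = 4**k
    codes = np.arange(n)
    rc = np.zeros(n, dtype=np.int64)
    for _ in range(k):
        rc = rc * 4 + (3 - codes % 4)
        codes //= 4
    return rc


def kmer_features(
    seq: str, k: int, normalize: bool = True, revcomp_collapse: bool = False
) -> np.ndarray:
    """Spectrum feature vector: counts of overlapping k-mers on the given
    strand, optionally pooled with reverse complements, optionally scaled
    to unit Euclidean norm.  Sequences containing N are rejected."""
    codes = kmer_window_codes(seq, k)
    if np.any(codes < 0):
        raise ValueError("sequence contains N")
    counts = np.bincount(codes, minlength=4**k).astype(np.float64)
    if revcomp_collapse:
        rc = _revcomp_permutation(k)
        pooled = counts + counts[rc]
        canonical = np.minimum(np.arange(4**k), rc)
        counts = np.where(np.arange(4**k) == canonical, pooled, 0.0)
        # palindromes were doubled by the pooling
        counts[rc == np.arange(4**k)] /= 2.0
    if normalize:
        norm = np.linalg.norm(counts)
        if norm > 0:
            counts = counts / norm
    return counts


@dataclass
class LabeledSequenceSet:
    """Positive/negative sequences with their origin intervals and the
    holdout chromosome defining the train/test partition."""

    positives: list[tuple[str, GenomicInterval]]
    negatives: list[tuple[str, GenomicInterval]]
    holdout_chrom: str
    n_dropped: int = 0  # windows discarded for containing N or clipping

    def _split(self, records, train: bool):
        return [
            (s, iv)
            for s, iv in records
            if (iv.chrom != self.holdout_chrom) == train
        ]

    def train_positives(self):
        return self._split(self.positives, True)

    def train_negatives(self):
        return self._split(self.negatives, True)

    def test_positives(self):
        return self._split(self.positives, False)

    def test_negatives(self):
        return self._split(self.negatives, False)


@dataclass
class KmerModel:
    k: int
    weights: np.ndarray  # 4^k entries (non-canonical zero when collapsed)
    bias: float
    C: float = 1.0
    normalize: bool = True
    revcomp_collapse: bool = False
    training_meta: dict = field(default_factory=dict)

    def weight_of(self, kmer: str) -> float:
        return float(self.weights[kmer_to_code(kmer)])

    def features(self, seq: str) -> np.ndarray:
        return kmer_features(seq, self.k, self.normalize, self.revcomp_collapse)

    def decision(self, seq: str) -> float:
        return float(self.weights @ self.features(seq) + self.bias)

    def decisions(self, seqs: Iterable[str]) -> np.ndarray:
        return np.array([self.decision(s) for s in seqs])

    def kmer_weight_table(self) -> list[tuple[str, float]]:
        return [
            (code_to_kmer(i, self.k), float(w)) for i, w in enumerate(self.weights)
        ]

    # -- serialization: TSV of (kmer, weight) + JSON sidecar ----------------

    def save(self, tsv_path: str | Path, json_path: str | Path) -> None:
        with open(tsv_path, "w") as fh:
            for kmer, w in self.kmer_weight_table():
                fh.write(f"{kmer}\t{w:.10g}\n")
        meta = {
            "k": self.k,
            "bias": self.bias,
            "C": self.C,
            "normalize": self.normalize,
            "revcomp_collapse": self.revcomp_collapse,
            "training_meta": self.training_meta,
        }
        Path(json_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, tsv_path: str | Path, json_path: str | Path) -> "KmerModel":
        meta = json.loads(Path(json_path).read_text())
        k = meta["k"]
        weights = np.zeros(4**k)
        with open(tsv_path) as fh:
            for line in fh:
                kmer, w = line.split("\t")
                weights[kmer_to_code(kmer)] = float(w)
        return cls(
            k=k,
            weights=weights,
            bias=meta["bias"],
            C=meta["C"],
            normalize=meta["normalize"],
            revcomp_collapse=meta["revcomp_collapse"],
            training_meta=meta.get("training_meta", {}),
        )


# ---------------------------------------------------------------------------
# Training-set construction


def build_linker_core_sets(
    hmds: Sequence[HMD],
    summits: Sequence[Summit],
    genome: GenomeSequence,
    seq_len: int = 100,
    min_summit_gap: int = 150,
    holdout_chrom: str = "",
) -> LabeledSequenceSet:
    """Positives: seq_len windows centered on in-HMD summits (linkers).
    Negatives: windows centered on midpoints of adjacent summit pairs whose
    gap exceeds ``min_summit_gap`` (nucleosome cores).  Windows crossing
    HMD or chromosome edges, or containing N, are dropped and counted."""
    if seq_len % 2 != 0:
        raise ValueError("seq_len must be even (windows are [c-L/2, c+L/2))")
    half = seq_len // 2
    positives: list[tuple[str, GenomicInterval]] = []
    negatives: list[tuple[str, GenomicInterval]] = []
    dropped = 0

    summits_by_chrom: dict[str, list[Summit]] = {}
    for s in summits:
        summits_by_chrom.setdefault(s.chrom, []).append(s)
    for lst in summits_by_chrom.values():
        lst.sort(key=lambda s: s.pos)

    def grab(chrom: str, center: int, hmd: HMD) -> tuple[str, GenomicInterval] | None:
        nonlocal dropped
        start, end = center - half, center + half
        if start < hmd.interval.start or end > hmd.interval.end:
            dropped += 1
            return None
        seq = genome.fetch(chrom, start, end)
        if "N" in seq:
            dropped += 1
            return None
        return seq, GenomicInterval(chrom, start, end)

    for hmd in hmds:
        inside = [
            s
            for s in summits_by_chrom.get(hmd.chrom, [])
            if hmd.interval.contains(s.chrom, s.pos)
        ]
        for s in inside:
            rec = grab(hmd.chrom, s.pos, hmd)
            if rec:
                positives.append(rec)
        for a, b in zip(inside, inside[1:]):
            if b.pos - a.pos > min_summit_gap:
                rec = grab(hmd.chrom, (a.pos + b.pos) // 2, hmd)
                if rec:
                    negatives.append(rec)
    return LabeledSequenceSet(positives, negatives, holdout_chrom, dropped)


def build_hmd_vs_methylated_sets(
    hmds: Sequence[HMD],
    genome: GenomeSequence,
    max_len: int = 3000,
    neg_copies: int = 10,
    seed: int = 0,
    holdout_chrom: str = "",
    max_tries: int = 1000,
) -> LabeledSequenceSet:
    """Positives: HMD sequences shorter than ``max_len``.  Negatives: for
    each positive, ``neg_copies`` intervals of identical length placed
    uniformly on the methylated space (never intersecting any HMD),
    reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chroms)
    lengths = genome.lengths()
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    hmd_by_chrom: dict[str, list[GenomicInterval]] = {}
    for h in hmds:
        hmd_by_chrom.setdefault(h.chrom, []).append(h.interval)

    positives: list[tuple[str, GenomicInterval]] = []
    negatives: list[tuple[str, GenomicInterval]] = []
    dropped = 0
    for h in hmds:
        if len(h.interval) >= max_len:
            continue
        seq = genome.fetch_interval(h.interval)
        if "N" in seq:
            dropped += 1
            continue
        positives.append((seq, h.interval))
        length = len(h.interval)
        for _ in range(neg_copies):
            for _try in range(max_tries):
                chrom = chroms[int(rng.choice(len(chroms), p=probs))]
                if lengths[chrom] < length:
                    continue
                start = int(rng.integers(0, lengths[chrom] - length + 1))
                iv = GenomicInterval(chrom, start, start + length)
                if any(iv.overlaps(other) for other in hmd_by_chrom.get(chrom, [])):
                    continue
                nseq = genome.fetch_interval(iv)
                if "N" in nseq:
                    continue
                negatives.append((nseq, iv))
                break
            else:
                raise RuntimeError(
                    f"could not place negative of length {length} "
                    f"after {max_tries} tries"
                )
    return LabeledSequenceSet(positives, negatives, holdout_chrom, dropped)


# ---------------------------------------------------------------------------
# Training and scoring


def train(
    sets: LabeledSequenceSet,
    k: int = 6,
    C: float = 1.0,
    normalize: bool = True,
    revcomp_collapse: bool = False,
    random_state: int = 0,
) -> KmerModel:
    """Fit a linear soft-margin classifier on k-mer spectrum features.

    Training uses only sequences off the holdout chromosome; the model's
    weight/bias pair reproduces the solver's decision values exactly
    (decision(x) = w . features(x) + b).
    """
    pos = sets.train_positives()
    neg = sets.train_negatives()
    if not pos or not neg:
        raise ValueError("both classes must be non-empty for training")
    X = np.vstack(
        [kmer_features(s, k, normalize, revcomp_collapse) for s, _ in pos + neg]
    )
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    clf = LinearSVC(
        C=C,
        loss="squared_hinge",
        dual=True,
        tol=1e-8,
        max_iter=100_000,
        random_state=random_state,
    )
    clf.fit(X, y)
    return KmerModel(
        k=k,
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        C=C,
        normalize=normalize,
        revcomp_collapse=revcomp_collapse,
        training_meta={
            "n_train_pos": len(pos),
            "n_train_neg": len(neg),
            "n_dropped": sets.n_dropped,
            "holdout_chrom": sets.holdout_chrom,
            "random_state": random_state,
        },
    )


@dataclass
class ScoredHMD:
    """Sliding-window SVM scores along one HMD, with optional signal and
    score-signal correlation."""

    hmd_id: int
    interval: GenomicInterval
    step: int
    step_positions: np.ndarray  # start of each step segment
    score: np.ndarray  # NaN where every overlapping window contained N
    signal: np.ndarray | None = None
    r: float | None = None
    p: float | None = None


def score_hmd(
    hmd: HMD,
    genome: GenomeSequence,
    model: KmerModel,
    window: int = 100,
    step: int = 20,
    hmd_id: int = 0,
) -> ScoredHMD:
    """Decision values of 100-bp windows on a 20-bp grid, averaged per step.

    Each step's score is the mean decision value of all windows overlapping
    that step (5 in the interior at defaults, fewer near edges).  Windows
    containing N contribute nothing; steps with no valid window are NaN.
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    iv = hmd.interval
    length = len(iv)
    if length < window:
        raise ValueError(f"HMD length {length} shorter than window {window}")
    win_starts = np.arange(iv.start, iv.end - window + 1, step)
    decisions = np.full(len(win_starts), np.nan)
    for i, ws in enumerate(win_starts):
        seq = genome.fetch(iv.chrom, int(ws), int(ws) + window)
        if "N" in seq:
            continue
        decisions[i] = model.decision(seq)

    n_steps = -(-length // step)
    step_starts = iv.start + step * np.arange(n_steps)
    scores = np.full(n_steps, np.nan)
    for j, ss in enumerate(step_starts):
        se = min(ss + step, iv.end)
        mask = (win_starts < se) & (win_starts + window > ss)
        vals = decisions[mask]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            scores[j] = vals.mean()
    return ScoredHMD(hmd_id, iv, step, step_starts, scores)


def correlate(scored: ScoredHMD, signal: SignalTrack) -> ScoredHMD:
    """Fill in per-step signal means and the Pearson r / two-sided P value
    (t-distributed null, df = n - 2) between score and signal."""
    sig = np.array(
        [
            signal.mean_over(
                GenomicInterval(
                    scored.interval.chrom,
                    int(ss),
                    min(int(ss) + scored.step, scored.interval.end),
                )
            )
            for ss in scored.step_positions
        ]
    )
    scored.signal = sig
    ok = np.isfinite(scored.score) & np.isfinite(sig)
    if ok.sum() < 3:
        raise ValueError("need >= 3 steps with defined score and signal")
    x, y = scored.score[ok], sig[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        scored.r, scored.p = float("nan"), float("nan")
        return scored
    r, p = stats.pearsonr(x, y)
    scored.r, scored.p = float(r), float(p)
    return scored


def correlation_histogram(
    scoreds: Sequence[ScoredHMD], alpha: float = 0.05, bins: int = 20
) -> dict:
    """Count HMDs with significant score-signal correlation (raw P < alpha)."""
    rs = np.array([s.r for s in scoreds if s.r is not None and np.isfinite(s.r)])
    ps = np.array([s.p for s in scoreds if s.p is not None and np.isfinite(s.p)])
    counts, edges = np.histogram(rs, bins=bins, range=(-1.0, 1.0))
    return {
        "n_significant": int(np.sum(ps < alpha)),
        "n_significant_positive": int(np.sum((ps < alpha) & (rs > 0))),
        "n_total": len(rs),
        "hist_counts": counts,
        "hist_edges": edges,
    }


def evaluate(model: KmerModel, sets: LabeledSequenceSet) -> dict:
    """ROC (trapezoid AUC) and precision-recall on the holdout chromosome."""
    pos = sets.test_positives()
    neg = sets.test_negatives()
    if not pos or not neg:
        raise ValueError("holdout test set must contain both classes")
    scores = model.decisions([s for s, _ in pos + neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    precision, recall, pr_thr = precision_recall_curve(labels, scores)
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "pr": {"precision": precision, "recall": recall, "thresholds": pr_thr},
        "n_test_pos": len(pos),
        "n_test_neg": len(neg),
    }


def compare_weights(
    model_hypo: KmerModel, model_dnase: KmerModel, top_n: int = 20
) -> dict:
    """Scatter pairs of (hypo, dnase) weights for all k-mers and a two-sided
    rank-sum test of the hypo-weights of the top_n dnase k-mers vs all."""
    if model_hypo.k != model_dnase.k:
        raise ValueError("k mismatch between models")
    if model_hypo.revcomp_collapse != model_dnase.revcomp_collapse:
        raise ValueError("collapse-mode mismatch between models")
    w_h, w_d = model_hypo.weights, model_dnase.weights
    order = np.argsort(-w_d, kind="stable")
    top_idx = order[:top_n]
    stat, p = stats.ranksums(w_h[top_idx], w_h)
    return {
        "pairs": np.column_stack([w_h, w_d]),
        "top_kmers": [code_to_kmer(int(i), model_dnase.k) for i in top_idx],
        "rank_test_stat": float(stat),
        "rank_test_p": float(p),
    }
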