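import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hmdnuc.accessibility import Summit
from hmdnuc.genome_io import GenomeSequence, GenomicInterval, SignalTrack
from hmdnuc.hmd import HMD
from hmdnuc.svm import (
    KmerModel,
    LabeledSequenceSet,
    build_hmd_vs_methylated_sets,
    build_linker_core_sets,
    compare_weights,
    correlate,
    correlation_histogram,
    evaluate,
    kmer_features,
    kmer_to_code,
    code_to_kmer,
    score_hmd,
    train,
)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), n))


def make_hmd(chrom, start, end):
    return HMD(GenomicInterval(chrom, start, end), (start, end - 2))


def make_summit(chrom, pos):
    return Summit(chrom, pos, 5.0, GenomicInterval(chrom, pos - 10, pos + 10))


class TestKmerFeatures:
    def test_direct_count_example(self):
        v = kmer_features("ACGTAC", 2, normalize=False)
        counts = {code_to_kmer(i, 2): c for i, c in enumerate(v) if c}
        assert counts == {"AC": 2, "CG": 1, "GT": 1, "TA": 1}

    def test_unit_norm(self, rng):
        v = kmer_features(random_seq(rng, 100), 6, normalize=True)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_n_rejected(self):
        with pytest.raises(ValueError, match="N"):
            kmer_features("ACGNAC", 2)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=60), st.integers(1, 4))
    def test_matches_naive_sliding_window(self, seq, k):
        got = kmer_features(seq, k, normalize=False)
        naive = np.zeros(4**k)
        for i in range(len(seq) - k + 1):
            naive[kmer_to_code(seq[i : i + k])] += 1
        assert np.array_equal(got, naive)

    def test_revcomp_collapse_pools_counts(self):
        v = kmer_features("ACGT", 2, normalize=False, revcomp_collapse=True)
        # AC(+GT) pooled at AC; CG palindromic stays at CG; GT zeroed
        assert v[kmer_to_code("AC")] == 2
        assert v[kmer_to_code("GT")] == 0
        assert v[kmer_to_code("CG")] == 1

    def test_code_roundtrip(self, rng):
        for _ in range(50):
            kmer = random_seq(rng, 6)
            assert code_to_kmer(kmer_to_code(kmer), 6) == kmer


class TestBuildLinkerCoreSets:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.genome = GenomeSequence({"c1": random_seq(rng, 5000)})

    def test_negative_centered_on_midpoint(self):
        hmd = make_hmd("c1", 900, 1500)
        summits = [make_summit("c1", 1000), make_summit("c1", 1300)]
        sets = build_linker_core_sets([hmd], summits, self.genome)
        assert len(sets.positives) == 2
        (neg_seq, neg_iv) = sets.negatives[0]
        assert (neg_iv.start, neg_iv.end) == (1100, 1200)
        assert neg_seq == self.genome.fetch("c1", 1100, 1200)

    def test_gap_at_most_150_gives_no_negative(self):
        hmd = make_hmd("c1", 900, 1500)
        summits = [make_summit("c1", 1000), make_summit("c1", 1100)]
        sets = build_linker_core_sets([hmd], summits, self.genome)
        assert sets.negatives == []
        # boundary: exactly 150 is not "longer than 150"
        summits = [make_summit("c1", 1000), make_summit("c1", 1150)]
        assert build_linker_core_sets([hmd], summits, self.genome).negatives == []

    def test_windows_crossing_edges_dropped(self):
        hmd = make_hmd("c1", 980, 1500)
        summits = [make_summit("c1", 1000)]  # [950, 1050) crosses HMD start
        sets = build_linker_core_sets([hmd], summits, self.genome)
        assert sets.positives == []
        assert sets.n_dropped == 1

    def test_odd_seq_len_rejected(self):
        with pytest.raises(ValueError, match="even"):
            build_linker_core_sets([], [], self.genome, seq_len=99)

    def test_matches_brute_force_pair_enumeration(self, rng):
        hmds, summits = [], []
        for i in range(10):
            start = 100 + i * 450
            hmds.append(make_hmd("c1", start, start + 400))
            k = int(rng.integers(1, 5))
            pos = np.sort(rng.choice(np.arange(start + 60, start + 340), k, False))
            summits.extend(make_summit("c1", int(p)) for p in pos)
        sets = build_linker_core_sets(hmds, summits, self.genome)
        expected_negs = []
        for h in hmds:
            inside = sorted(
                s.pos for s in summits if h.interval.contains("c1", s.pos)
            )
            for a, b in zip(inside, inside[1:]):
                if b - a > 150:
                    c = (a + b) // 2
                    if c - 50 >= h.interval.start and c + 50 <= h.interval.end:
                        expected_negs.append((c - 50, c + 50))
        assert [(iv.start, iv.end) for _, iv in sets.negatives] == expected_negs


class TestBuildHmdVsMethylatedSets:
    def setup_method(self):
        rng = np.random.default_rng(6)
        self.genome = GenomeSequence(
            {"c1": random_seq(rng, 30_000), "c2": random_seq(rng, 30_000)}
        )

    def hmds(self):
        return [make_hmd("c1", 2000, 4000), make_hmd("c2", 10_000, 13_500)]

    def test_length_filter_and_copies(self):
        sets = build_hmd_vs_methylated_sets(self.hmds(), self.genome, seed=0)
        assert len(sets.positives) == 1  # the 3500-bp domain is excluded
        assert len(sets.negatives) == 10
        assert all(len(s) == 2000 for s, _ in sets.negatives)

    def test_determinism(self):
        a = build_hmd_vs_methylated_sets(self.hmds(), self.genome, seed=42)
        b = build_hmd_vs_methylated_sets(self.hmds(), self.genome, seed=42)
        assert [iv for _, iv in a.negatives] == [iv for _, iv in b.negatives]

    def test_negatives_never_intersect_hmds(self):
        hmds = self.hmds()
        sets = build_hmd_vs_methylated_sets(hmds, self.genome, seed=1)
        for _, iv in sets.negatives:
            for h in hmds:
                assert not iv.overlaps(h.interval)

    def test_placement_failure_raises(self):
        tiny = GenomeSequence({"c1": "ACGT" * 1000})
        hmds = [make_hmd("c1", 0, 3998)]
        with pytest.raises(RuntimeError):
            build_hmd_vs_methylated_sets(
                hmds, tiny, max_len=4000, seed=0, max_tries=50
            )


def separable_sets(rng, n=40, with_motif="AAAAAA"):
    positives, negatives = [], []
    for i in range(n):
        chrom = "c1" if i % 4 else "c9"  # a quarter held out
        s = random_seq(rng, 100)
        j = int(rng.integers(0, 94))
        pos_seq = s[:j] + with_motif + s[j + 6 :]
        positives.append((pos_seq, GenomicInterval(chrom, 100 * i + 1, 100 * i + 101)))
        neg = random_seq(rng, 100).replace(with_motif, "ACGTAC")
        negatives.append((neg, GenomicInterval(chrom, 100 * i + 1, 100 * i + 101)))
    return LabeledSequenceSet(positives, negatives, holdout_chrom="c9")


class TestTrain:
    def test_planted_kmer_gets_max_weight(self, rng):
        model = train(separable_sets(rng), k=6)
        assert np.argmax(model.weights) == kmer_to_code("AAAAAA")

    def test_label_swap_antisymmetry(self, rng):
        sets = separable_sets(rng)
        m1 = train(sets)
        m2 = train(LabeledSequenceSet(sets.negatives, sets.positives, "c9"))
        assert np.allclose(m1.weights, -m2.weights, atol=1e-6)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-6)

    def test_decision_self_consistency(self, rng):
        from sklearn.svm import LinearSVC

        sets = separable_sets(rng)
        model = train(sets)
        seqs = [s for s, _ in sets.train_positives() + sets.train_negatives()]
        X = np.vstack([kmer_features(s, 6) for s in seqs])
        y = np.concatenate(
            [np.ones(len(sets.train_positives())), -np.ones(len(sets.train_negatives()))]
        )
        clf = LinearSVC(
            C=1.0, loss="squared_hinge", dual=True, tol=1e-8,
            max_iter=100_000, random_state=0,
        ).fit(X, y)
        ours = X @ model.weights + model.bias
        assert np.max(np.abs(ours - clf.decision_function(X))) <= 1e-6

    def test_holdout_sequences_do_not_influence_weights(self, rng):
        sets = separable_sets(rng)
        mutated = LabeledSequenceSet(
            [
                (s if iv.chrom != "c9" else random_seq(rng, 100), iv)
                for s, iv in sets.positives
            ],
            [
                (s if iv.chrom != "c9" else random_seq(rng, 100), iv)
                for s, iv in sets.negatives
            ],
            "c9",
        )
        m1, m2 = train(sets), train(mutated)
        assert np.array_equal(m1.weights, m2.weights)

    def test_single_class_rejected(self, rng):
        sets = separable_sets(rng)
        with pytest.raises(ValueError):
            train(LabeledSequenceSet(sets.positives, [], "c9"))

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = train(separable_sets(rng))
        model.save(tmp_path / "m.tsv", tmp_path / "m.json")
        back = KmerModel.load(tmp_path / "m.tsv", tmp_path / "m.json")
        assert np.allclose(back.weights, model.weights, atol=1e-9)
        assert back.bias == pytest.approx(model.bias)
        assert back.k == 6 and back.normalize


class TestScoreHmd:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.genome = GenomeSequence({"c1": random_seq(rng, 3000)})

    def zero_model(self, bias=1.25):
        return KmerModel(k=6, weights=np.zeros(4**6), bias=bias)

    def test_zero_weight_model_gives_constant_bias(self):
        hmd = make_hmd("c1", 500, 1100)
        scored = score_hmd(hmd, self.genome, self.zero_model())
        assert np.allclose(scored.score, 1.25)

    def test_hmd_of_window_length_single_window(self, rng):
        hmd = make_hmd("c1", 500, 600)
        model = train(separable_sets(np.random.default_rng(2)))
        scored = score_hmd(hmd, self.genome, model)
        expected = model.decision(self.genome.fetch("c1", 500, 600))
        assert np.allclose(scored.score, expected)
        assert len(scored.score) == 5

    def test_window_step_divisibility(self):
        hmd = make_hmd("c1", 500, 1100)
        with pytest.raises(ValueError, match="multiple"):
            score_hmd(hmd, self.genome, self.zero_model(), window=100, step=30)

    def test_short_hmd_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            score_hmd(make_hmd("c1", 500, 560), self.genome, self.zero_model())

    def test_matches_brute_force_window_enumeration(self, rng):
        model = train(separable_sets(np.random.default_rng(3)))
        for _ in range(5):
            start = int(rng.integers(100, 500))
            length = int(rng.integers(100, 900))
            hmd = make_hmd("c1", start, start + length)
            scored = score_hmd(hmd, self.genome, model)
            # oracle: enumerate windows and steps explicitly
            windows = []
            ws = start
            while ws + 100 <= hmd.interval.end:
                windows.append((ws, model.decision(self.genome.fetch("c1", ws, ws + 100))))
                ws += 20
            for j, ss in enumerate(scored.step_positions):
                se = min(ss + 20, hmd.interval.end)
                overlapping = [d for w, d in windows if w < se and w + 100 > ss]
                if overlapping:
                    assert scored.score[j] == pytest.approx(np.mean(overlapping))
                else:
                    assert np.isnan(scored.score[j])


class TestCorrelate:
    def make_scored(self, scores, start=0):
        n = len(scores)
        iv = GenomicInterval("c1", start, start + 20 * n)
        from hmdnuc.svm import ScoredHMD

        return ScoredHMD(
            0, iv, 20, start + 20 * np.arange(n), np.asarray(scores, dtype=float)
        )

    def make_signal(self, per_step, start=0):
        track = SignalTrack({"c1": start + 20 * len(per_step)})
        for j, v in enumerate(per_step):
            track.set_values("c1", start + 20 * j, np.full(20, v))
        return track

    def test_affine_signal_gives_r_one(self):
        scored = self.make_scored([1.0, 2.0, 5.0, 3.0])
        scored = correlate(scored, self.make_signal([3.0, 5.0, 11.0, 7.0]))
        assert scored.r == pytest.approx(1.0)

    def test_reversed_scores_give_r_minus_one(self):
        scored = self.make_scored([1.0, 2.0, 3.0, 4.0])
        scored = correlate(scored, self.make_signal([4.0, 3.0, 2.0, 1.0]))
        assert scored.r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        scored = self.make_scored([2.0, 2.0, 2.0, 2.0])
        scored = correlate(scored, self.make_signal([1.0, 2.0, 3.0, 4.0]))
        assert np.isnan(scored.r) and np.isnan(scored.p)

    def test_matches_textbook_pearson(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        scored = correlate(self.make_scored(x), self.make_signal(y))
        xc, yc = x - x.mean(), y - y.mean()
        r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert scored.r == pytest.approx(r)
        t = r * np.sqrt(28 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 28)
        assert scored.p == pytest.approx(p, rel=1e-6)

    def test_too_few_steps_rejected(self):
        scored = self.make_scored([1.0, 2.0])
        with pytest.raises(ValueError):
            correlate(scored, self.make_signal([1.0, 2.0]))

    def test_histogram_counts_significant(self, rng):
        scoreds = []
        for i in range(10):
            x = rng.random(20)
            noise = rng.random(20)
            y = x + (0.01 if i < 7 else 100.0) * noise
            scoreds.append(correlate(self.make_scored(x), self.make_signal(y)))
        summary = correlation_histogram(scoreds)
        assert summary["n_total"] == 10
        assert summary["n_significant"] >= 7
        assert summary["hist_counts"].sum() == 10


class TestEvaluate:
    def model_with(self, weights_dict, k=3):
        w = np.zeros(4**k)
        for kmer, value in weights_dict.items():
            w[kmer_to_code(kmer)] = value
        return KmerModel(k=k, weights=w, bias=0.0)

    def holdout_sets(self, rng, n=50, separable=True):
        positives, negatives = [], []
        for i in range(n):
            if separable:
                pos = "AAA" + random_seq(rng, 30).replace("AAA", "CGT")
                neg = random_seq(rng, 30).replace("AAA", "CGT")
            else:
                pos, neg = random_seq(rng, 30), random_seq(rng, 30)
            positives.append((pos, GenomicInterval("c9", i + 1, i + 31)))
            negatives.append((neg, GenomicInterval("c9", i + 1, i + 31)))
        return LabeledSequenceSet(positives, negatives, "c9")

    def test_perfect_separation_auc_one(self, rng):
        model = self.model_with({"AAA": 1.0})
        result = evaluate(model, self.holdout_sets(rng))
        assert result["auc"] == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(20_000)
        labels = np.concatenate([np.ones(10_000), np.zeros(10_000)])
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, scores) == pytest.approx(0.5, abs=0.02)

    def test_auc_equals_mann_whitney_identity(self, rng):
        model = self.model_with({"AAA": 1.0, "ACG": 0.4, "TTT": -0.7})
        sets = self.holdout_sets(rng, separable=False)
        result = evaluate(model, sets)
        pos_scores = model.decisions([s for s, _ in sets.test_positives()])
        neg_scores = model.decisions([s for s, _ in sets.test_negatives()])
        u = stats.mannwhitneyu(pos_scores, neg_scores, alternative="two-sided")
        expected = u.statistic / (len(pos_scores) * len(neg_scores))
        assert result["auc"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_rejected(self, rng):
        model = self.model_with({"AAA": 1.0})
        sets = self.holdout_sets(rng)
        with pytest.raises(ValueError):
            evaluate(model, LabeledSequenceSet(sets.positives, [], "c9"))


class TestCompareWeights:
    def model_from(self, weights, k=3):
        return KmerModel(k=k, weights=np.asarray(weights, dtype=float), bias=0.0)

    def test_self_comparison_extreme(self, rng):
        w = rng.normal(size=4**3)
        model = self.model_from(w)
        result = compare_weights(model, model, top_n=20)
        assert result["rank_test_p"] < 1e-3

    def test_k_mismatch_rejected(self, rng):
        a = self.model_from(rng.normal(size=4**3), k=3)
        b = KmerModel(k=2, weights=rng.normal(size=16), bias=0.0)
        with pytest.raises(ValueError):
            compare_weights(a, b)

    def test_independent_weights_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            a = self.model_from(rng.normal(size=64))
            b = self.model_from(rng.normal(size=64))
            ps.append(compare_weights(a, b, top_n=10)["rank_test_p"])
        ps = np.array(ps)
        # uniformity at the resolution a KS test can see with 200 draws
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_rank_sum_matches_exhaustive_ranks(self, rng):
        n = 50
        w_h = rng.normal(size=n)
        w_d = rng.normal(size=n)
        k = 0
        while 4**k < n:
            k += 1
        wh = np.zeros(4**3)
        wd = np.zeros(4**3)
        wh[:n], wd[:n] = w_h, w_d
        a, b = self.model_from(wh), self.model_from(wd)
        result = compare_weights(a, b, top_n=10)
        top = np.argsort(-wd, kind="stable")[:10]
        x, y = wh[top], wh
        ranks = stats.rankdata(np.concatenate([x, y]))
        n1, n2 = len(x), len(y)
        expected = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        z = (expected - mu) / sigma
        assert result["rank_test_stat"] == pytest.approx(z)
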