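from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafnet import seqmodel as sm
from leafnet import synthetic as syn
from leafnet.types import GenomicInterval

MOTIF = "GATCGTA"


@pytest.fixture(scope="module")
def planted_model():
    seqs, labels, _ = syn.synthesize_motif_dataset(MOTIF, n_pos=150, n_sites=3,
                                                   seed=21)
    return sm.train_kmer_model(seqs, labels, tf="T1", seed=21)


class TestTokenize:
    def test_window_count(self):
        counts = sm.tokenize("ACGTACGTAC", k=7)
        assert sum(counts.values()) == 4

    def test_reverse_complement_collapse(self):
        assert sm.tokenize("AAAAAAA", k=7) == sm.tokenize("TTTTTTT", k=7)

    def test_n_windows_skipped(self):
        counts = sm.tokenize("ACGTNACGTACG", k=7)
        # windows 0-4 contain the N at index 4; only window 5 is N-free
        assert all("N" not in t for t in counts)
        assert sum(counts.values()) == 1

    def test_short_sequence_error(self):
        with pytest.raises(ValueError):
            sm.tokenize("ACG", k=7)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=7, max_size=100))
    def test_matches_enumeration_oracle(self, seq):
        oracle = Counter()
        for i in range(len(seq) - 6):
            w = seq[i : i + 7]
            rc = w.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            oracle[min(w, rc)] += 1
        assert sm.tokenize(seq, k=7) == oracle


class TestTfidf:
    def test_token_in_all_documents_zero_weight(self):
        docs = [Counter({"AAA": 1, f"X{i}": 1}) for i in range(5)]
        counts, vocab = sm.build_count_matrix(docs)
        X, df, n = sm.tfidf_transform(counts)
        assert np.all(X.toarray()[:, vocab["AAA"]] == 0)

    def test_idf_closed_form(self):
        docs = [Counter({"RARE": 1})] + [Counter({"COMMON": 1}) for _ in range(9)]
        counts, vocab = sm.build_count_matrix(docs)
        X, df, n = sm.tfidf_transform(counts)
        assert df[vocab["RARE"]] == 1
        # idf(ln 10) then L2 normalization leaves a single-token row at 1
        assert X.toarray()[0, vocab["RARE"]] == pytest.approx(1.0)
        raw_idf = np.log(10 / 1)
        assert raw_idf == pytest.approx(2.302585, rel=1e-6)

    def test_rows_l2_normalized(self, rng):
        docs = [
            Counter({f"t{int(t)}": int(c)})
            for t, c in zip(rng.integers(0, 5, 10), rng.integers(1, 4, 10))
        ]
        docs.append(Counter({"t0": 2, "t1": 3}))
        counts, _ = sm.build_count_matrix(docs)
        X, _, _ = sm.tfidf_transform(counts)
        norms = np.linalg.norm(X.toarray(), axis=1)
        for nrm in norms:
            assert nrm == pytest.approx(1.0) or nrm == 0.0

    def test_single_document_error(self):
        counts, _ = sm.build_count_matrix([Counter({"A": 1})])
        with pytest.raises(ValueError):
            sm.tfidf_transform(counts)


class TestExtractTrainingSet:
    def test_gc_matching_and_no_overlap(self, small_genome):
        loci = [iv for iv in small_genome.open_chromatin[:40]]
        seqs, labels = sm.extract_training_set(loci, small_genome, seed=0)
        assert (labels == 1).sum() == (labels == 0).sum() == 40
        gaps = [
            abs(sm.gc_content(seqs[2 * i]) - sm.gc_content(seqs[2 * i + 1]))
            for i in range(40)
        ]
        assert np.mean(gaps) <= 0.02 + 1e-9

    def test_impossible_matching_raises(self):
        genome = syn.generate_genome(n_chroms=1, chrom_length=100_000,
                                     n_genes=5, seed=1)
        locus = GenomicInterval("chr1", 0, 99_000)  # control cannot fit
        with pytest.raises(ValueError):
            sm.extract_training_set([locus], genome, seed=0, max_retries=10)


class TestTrainKmerModel:
    def test_planted_motif_learned(self, planted_model):
        assert planted_model.cv_accuracy >= 0.9
        top = planted_model.top_kmers(1.0)
        assert sm.canonical_kmer(MOTIF) in top

    def test_no_signal_accuracy_near_half(self):
        seqs, labels, _ = syn.synthesize_motif_dataset(
            MOTIF, n_pos=100, plant_rate=0.0, seed=3
        )
        model = sm.train_kmer_model(seqs, labels, seed=3)
        assert 0.35 <= model.cv_accuracy <= 0.65

    def test_label_shuffle_no_leakage(self):
        seqs, labels, _ = syn.synthesize_motif_dataset(MOTIF, n_pos=300, seed=4)
        rng = np.random.default_rng(4)
        shuffled = rng.permutation(labels)
        model = sm.train_kmer_model(seqs, shuffled, seed=4)
        assert 0.42 <= model.cv_auroc <= 0.58

    def test_single_class_error(self):
        seqs, _, _ = syn.synthesize_motif_dataset(MOTIF, n_pos=10, seed=5)
        with pytest.raises(ValueError):
            sm.train_kmer_model(seqs, np.ones(len(seqs)), seed=5)

    def test_default_folds(self):
        import inspect

        assert inspect.signature(sm.train_kmer_model).parameters[
            "folds"
        ].default == 5


class TestScoreSequence:
    def test_positive_scores_high(self, planted_model):
        seqs, labels, _ = syn.synthesize_motif_dataset(
            MOTIF, n_pos=20, n_sites=3, plant_rate=1.0, seed=99
        )
        scores = [sm.score_sequence(planted_model, s) for s in seqs[:20]]
        assert np.mean([s > 0.5 for s in scores]) >= 0.9

    def test_all_n_gives_intercept(self, planted_model):
        p = sm.score_sequence(planted_model, "N" * 50)
        expected = 1 / (1 + np.exp(-planted_model.intercept))
        assert p == pytest.approx(expected)

    def test_deterministic(self, planted_model):
        seq = "ACGT" * 50
        assert sm.score_sequence(planted_model, seq) == sm.score_sequence(
            planted_model, seq
        )


def occlusion_oracle(model, sequence):
    """Independent per-position recomputation via fresh tokenization."""
    base = sm.score_sequence(model, sequence)
    out = []
    for i in range(len(sequence)):
        masked = sequence[:i] + "N" + sequence[i + 1 :]
        out.append(base - sm.score_sequence(model, masked))
    return np.array(out)


class TestImportanceMaps:
    def test_occlusion_matches_oracle_exactly(self, planted_model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        track = sm.occlusion_map(planted_model, seq)
        np.testing.assert_array_equal(track.occlusion, occlusion_oracle(
            planted_model, seq))

    def test_no_vocabulary_overlap_all_zero(self):
        model = sm.SequenceModel(
            tf="x", k=7, vocabulary={"AAAAAAA": 0}, weights=np.array([2.0]),
            intercept=0.0, cv_accuracy=1.0, cv_auroc=1.0,
            df=np.array([1]), n_docs=10,
        )
        track = sm.occlusion_map(model, "CGCGCGCGCGCGCG")
        np.testing.assert_array_equal(track.occlusion, 0.0)

    def test_motif_positions_positive(self, planted_model):
        seq = "ACGTACGTAC" + MOTIF + "CATCATCATC"
        track = sm.occlusion_map(planted_model, seq)
        assert np.all(track.occlusion[10:17] > 0)

    def test_mutagenesis_matches_oracle(self, planted_model, rng):
        seq = "".join(rng.choice(list("ACGT"), size=40))
        track = sm.mutagenesis_map(planted_model, seq)
        base = sm.score_sequence(planted_model, seq)
        for i in range(len(seq)):
            for j, b in enumerate(track.mutagenesis_bases[i]):
                mutated = seq[:i] + b + seq[i + 1 :]
                expected = base - sm.score_sequence(planted_model, mutated)
                assert track.mutagenesis[i, j] == expected

    def test_motif_break_positive_score(self, planted_model):
        seq = "ACGTACGTAC" + MOTIF + "CATCATCATC"
        track = sm.mutagenesis_map(planted_model, seq)
        # breaking the first motif base should lower the probability
        assert track.mutagenesis[10].max() > 0


class TestClustering:
    def make_models(self, weight_rows, vocab_size=50):
        vocab = {f"KM{i}": i for i in range(vocab_size)}
        return [
            sm.SequenceModel(
                tf=f"tf{i}", k=7, vocabulary=vocab, weights=np.asarray(w),
                intercept=0.0, cv_accuracy=1.0, cv_auroc=1.0,
                df=np.ones(vocab_size), n_docs=10,
            )
            for i, w in enumerate(weight_rows)
        ]

    def test_identical_weights_same_cluster(self, rng):
        w = rng.random(50)
        models = self.make_models([w, w, rng.random(50), rng.random(50) * -1])
        _, labels = sm.tf_similarity_clustering(models)
        assert labels["tf0"] == labels["tf1"]

    def test_family_recovery(self, rng):
        fam_a = rng.random(50)
        fam_b = -rng.random(50)
        rows = [fam_a + 0.01 * rng.standard_normal(50) for _ in range(4)]
        rows += [fam_b + 0.01 * rng.standard_normal(50) for _ in range(4)]
        _, labels = sm.tf_similarity_clustering(self.make_models(rows))
        a_labels = {labels[f"tf{i}"] for i in range(4)}
        b_labels = {labels[f"tf{i}"] for i in range(4, 8)}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_vocabulary_mismatch_error(self, rng):
        models = self.make_models([rng.random(50), rng.random(50), rng.random(50)])
        models[2].vocabulary = {"OTHER": 0}
        with pytest.raises(ValueError):
            sm.tf_similarity_clustering(models)

    def test_too_few_models_error(self, rng):
        with pytest.raises(ValueError):
            sm.tf_similarity_clustering(self.make_models([rng.random(50)]))


class TestPWMMatch:
    def consensus_pwm(self, kmer, certainty=0.997):
        mat = np.full((4, len(kmer)), (1 - certainty) / 3)
        for j, b in enumerate(kmer):
            mat["ACGT".index(b), j] = certainty
        return sm.PWM(matrix=mat, name="consensus", family="FAM")

    def make_model_with_top(self, kmer):
        vocab = {kmer: 0, "CCCCCCC": 1}
        return sm.SequenceModel(
            tf="x", k=7, vocabulary=vocab, weights=np.array([5.0, -1.0]),
            intercept=0.0, cv_accuracy=1.0, cv_auroc=1.0,
            df=np.ones(2), n_docs=10,
        )

    def test_consensus_hit_above_13_28_bits(self):
        kmer = "GATCGTA"
        pwm = self.consensus_pwm(kmer)
        model = self.make_model_with_top(kmer)
        family, hits = sm.match_kmers_to_pwms(model, [pwm], top_percent=50.0)
        assert family == "FAM"
        [hit] = [h for h in hits if h.kmer == kmer]
        expected_bits = 7 * np.log2(0.997 / 0.25)
        assert hit.score_bits == pytest.approx(expected_bits, rel=0.01)
        assert hit.score_bits > 13.28
        assert hit.p < 1e-4

    def test_mismatched_kmer_no_hit(self):
        pwm = self.consensus_pwm("AAAAAAA")
        model = self.make_model_with_top("GGGGGGG")  # canonical CCCCCCC
        family, hits = sm.match_kmers_to_pwms(model, [pwm], top_percent=50.0)
        assert hits == []
        assert family is None

    def test_threshold_defaults(self):
        import inspect

        params = inspect.signature(sm.match_kmers_to_pwms).parameters
        assert params["min_bits"].default == 13.28
        assert params["max_p"].default == 1e-4

    def test_pvalue_exact_enumeration(self):
        """DP p-value equals brute-force enumeration over all 7-mers."""
        pwm = self.consensus_pwm("GATCGTA", certainty=0.7)
        lo = sm._log_odds(pwm)
        kmer = "GATCGTA"
        score, idx, cols = sm._best_alignment(kmer, lo)
        p = sm._exact_pvalue(lo[:, cols], idx)
        import itertools

        grid = 1e-3
        keys = np.round(lo / grid).astype(int)
        obs = int(keys[idx, np.arange(7)].sum())
        count = 0
        for word in itertools.product(range(4), repeat=7):
            if int(keys[list(word), np.arange(7)].sum()) >= obs:
                count += 1
        assert p == pytest.approx(count / 4**7, rel=1e-9)

    def test_pwm_column_validation(self):
        with pytest.raises(ValueError):
            sm.PWM(matrix=np.ones((4, 5)), name="bad")
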