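"""K-mer naive-Bayes classifier: profiles, posteriors, depth truncation."""

import itertools
import math

import numpy as np
import pytest

from refdbkit.classifier import (
    ClassifierModel,
    classify,
    fit,
    kmer_profile,
    posteriors,
)
from refdbkit.curate import SequenceSet
from refdbkit.taxonomy import (
    RankSchema,
    TaxonomyTable,
    parse_lineage,
)

SCHEMA2 = RankSchema(("g__", "s__"), ("genus", "species"))


def _db(pairs, schema=SCHEMA2):
    seqs = SequenceSet([(i, s) for i, s, _ in pairs])
    tax = TaxonomyTable(
        schema, {i: parse_lineage(t, schema) for i, _, t in pairs}
    )
    return seqs, tax


class TestKmerProfile:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("AAAA", 2, {"AA": 3}),
            ("ACGN", 2, {"AC": 1, "CG": 1}),
            ("ACG", 4, {}),
        ],
    )
    def test_examples(self, seq, k, expected):
        assert kmer_profile(seq, k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            kmer_profile("ACGT", 0)


class TestFitAndPosteriors:
    def test_single_class_posterior_one(self):
        seqs, tax = _db([("a", "ACGTACGTAC", "g__G; s__G x")])
        model = fit(seqs, tax, k=2)
        assert posteriors(model, "ACGTACGTAC") == pytest.approx([1.0])

    def test_disjoint_kmer_content_separates_as_alpha_shrinks(self):
        pairs = [
            ("a", "AAAAAAAA", "g__G; s__G a"),
            ("b", "CCCCCCCC", "g__G; s__G b"),
        ]
        seqs, tax = _db(pairs)
        post_small = posteriors(fit(seqs, tax, k=2, alpha=1e-6), "AAAAAA")
        post_tiny = posteriors(fit(seqs, tax, k=2, alpha=1e-9), "AAAAAA")
        idx = 0  # class order follows first appearance
        assert post_tiny[idx] >= post_small[idx] > 0.99

    def test_large_alpha_approaches_uniform(self):
        pairs = [
            ("a", "AAAAAAAA", "g__G; s__G a"),
            ("b", "CCCCCCCC", "g__G; s__G b"),
        ]
        seqs, tax = _db(pairs)
        post = posteriors(fit(seqs, tax, k=2, alpha=1e6), "AAAAAA")
        assert post == pytest.approx([0.5, 0.5], abs=1e-3)

    def test_posteriors_sum_to_one(self, small_db):
        seqs, tax, _ = small_db
        model = fit(seqs, tax, k=4)
        for ident, seq in itertools.islice(seqs, 10):
            assert posteriors(model, seq).sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_bayes(self):
        """Log-space path agrees with explicit likelihood products."""
        rng = np.random.default_rng(5)
        k = 2
        pairs = []
        for ci in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            pairs.append((f"r{ci}", seq, f"g__G{ci % 2}; s__G{ci % 2} sp{ci}"))
        seqs, tax = _db(pairs)
        model = fit(seqs, tax, k=k, alpha=0.001)
        query = "".join(rng.choice(list("ACGT"), size=25))
        got = posteriors(model, query)

        # oracle: explicit per-class probability products
        probs = []
        for ci, key in enumerate(model.classes):
            counts = {}
            for ident, seq, t in pairs:
                if tax[ident].labels == key:
                    for kmer, c in kmer_profile(seq, k).items():
                        counts[kmer] = counts.get(kmer, 0) + c
            total = sum(counts.values())
            p = 1.0
            for kmer, c in kmer_profile(query, k).items():
                theta = (counts.get(kmer, 0) + 0.001) / (total + 0.001 * 4 ** k)
                p *= theta ** c
            probs.append(p / len(model.classes))
        oracle = np.array(probs) / sum(probs)
        assert got == pytest.approx(oracle, abs=1e-9)

    def test_matches_sklearn_multinomial_nb(self):
        """Independent cross-check against scikit-learn's MultinomialNB."""
        from sklearn.naive_bayes import MultinomialNB

        rng = np.random.default_rng(6)
        k = 3
        pairs = []
        for ci in range(4):
            for m in range(2):
                seq = "".join(rng.choice(list("ACGT"), size=60))
                pairs.append((f"r{ci}_{m}", seq, f"g__G{ci}; s__G{ci} sp"))
        seqs, tax = _db(pairs)
        alpha = 0.01
        model = fit(seqs, tax, k=k, alpha=alpha)

        from refdbkit.classifier import _count_vector

        X = np.array([
            sum(
                (_count_vector(s, k) for i2, s, t in pairs
                 if tax[i2].labels == key),
                start=np.zeros(4 ** k),
            )
            for key in model.classes
        ])
        clf = MultinomialNB(alpha=alpha, fit_prior=False)
        clf.fit(X, np.arange(len(model.classes)))
        query = "".join(rng.choice(list("ACGT"), size=40))
        sk = clf.predict_proba(_count_vector(query, k).reshape(1, -1))[0]
        assert posteriors(model, query) == pytest.approx(sk, abs=1e-9)


class TestClassify:
    def test_exact_training_match_full_depth(self, small_db):
        seqs, tax, _ = small_db
        model = fit(seqs, tax, k=7)
        sub = SequenceSet(seqs.records[:5])
        result = classify(model, sub, confidence=0.7)
        for ident, _ in sub:
            assert result.taxonomy[ident].labels == tax[ident].labels
            assert result.confidence[ident] >= 0.7

    def test_symmetric_species_backs_off_to_genus(self):
        pairs = [
            ("a", "AAAAAAAA", "g__G; s__G a"),
            ("b", "CCCCCCCC", "g__G; s__G b"),
        ]
        seqs, tax = _db(pairs)
        model = fit(seqs, tax, k=2, alpha=0.5)
        # query with perfectly symmetric k-mer content between the classes
        result = classify(model, SequenceSet([("q", "AAAAACCCCC")]),
                          confidence=0.7)
        lin = result.taxonomy["q"]
        assert lin.labels == ("G", "")
        assert result.confidence["q"] == pytest.approx(1.0, abs=1e-9)

    def test_confidence_zero_returns_argmax_full_lineage(self):
        pairs = [
            ("a", "AAAAAAAA", "g__G; s__G a"),
            ("b", "CCCCCCCC", "g__H; s__H b"),
        ]
        seqs, tax = _db(pairs)
        model = fit(seqs, tax, k=2)
        result = classify(model, SequenceSet([("q", "AAACAAA")]), confidence=0.0)
        assert result.taxonomy["q"].labels == ("G", "G a")

    def test_unassignable_query_reported_at_depth_zero(self):
        pairs = [
            ("a", "AAAAAAAA", "g__G; s__G a"),
            ("b", "CCCCCCCC", "g__H; s__H b"),
        ]
        seqs, tax = _db(pairs)
        model = fit(seqs, tax, k=2, alpha=1.0)
        # symmetric query: each genus gets ~0.5, below the threshold
        result = classify(model, SequenceSet([("q", "AAAACCCC")]),
                          confidence=0.9)
        assert result.taxonomy["q"].depth == 0
        frame = result.to_frame()
        assert frame.loc[0, "Taxon"] == "Unassigned"

    def test_prefix_posterior_monotone_with_depth(self, small_db):
        seqs, tax, _ = small_db
        model = fit(seqs, tax, k=4)
        post = posteriors(model, seqs.records[0][1])
        # aggregated mass of the best chain never increases with depth
        labels = [c for c in model.classes]
        best = labels[int(np.argmax(post))]
        prev = 1.0
        for d in range(1, len(best) + 1):
            mass = sum(
                p for p, c in zip(post, labels) if c[:d] == best[:d]
            )
            assert mass <= prev + 1e-12
            prev = mass


class TestModelSerialization:
    def test_save_load_round_trip(self, tmp_path, small_db):
        seqs, tax, _ = small_db
        model = fit(seqs, tax, k=3)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.k == model.k
        assert loaded.classes == model.classes
        np.testing.assert_array_equal(
            loaded.feature_log_prob, model.feature_log_prob
        )
        q = seqs.records[0][1]
        np.testing.assert_array_equal(
            posteriors(loaded, q), posteriors(model, q)
        )
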