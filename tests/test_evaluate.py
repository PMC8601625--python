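"""Fold stratification, expected-label truncation, and P/R/F scoring."""

import itertools

import pytest

from refdbkit.evaluate import (
    evaluate_classifications,
    evaluate_cross_validate,
    evaluate_fit_classifier,
    expected_with_lca_truncation,
    stratified_kfold,
)
from refdbkit.curate import SequenceSet
from refdbkit.synth import FixtureSpec, generate_reference_db
from refdbkit.taxonomy import (
    Lineage,
    RankSchema,
    SYNTH_SCHEMA,
    TaxonomyError,
    TaxonomyTable,
    parse_lineage,
)

SCHEMA2 = RankSchema(("g__", "s__"), ("genus", "species"))


def _tab(entries, schema=SCHEMA2):
    return TaxonomyTable(
        schema, {i: parse_lineage(t, schema) for i, t in entries.items()}
    )


class TestStratifiedKfold:
    def test_balanced_classes_spread_one_per_fold(self):
        entries = {
            f"{g}{m}": f"g__{g}; s__{g} x" for g in "ABC" for m in range(3)
        }
        folds = stratified_kfold(_tab(entries), k=3, seed=0)
        for fold in range(3):
            test = folds.test_ids(fold)
            genera = sorted(i[0] for i in test)
            assert genera == ["A", "B", "C"]

    def test_singleton_class_in_exactly_one_fold(self):
        entries = {"a1": "g__A; s__A x", "a2": "g__A; s__A x",
                   "b1": "g__B; s__B y"}
        folds = stratified_kfold(_tab(entries), k=2, seed=1)
        appearances = [fold for fold in range(2) if "b1" in folds.test_ids(fold)]
        assert len(appearances) == 1

    def test_deterministic_for_seed(self, small_db):
        _, tax, _ = small_db
        a = stratified_kfold(tax, k=3, seed=42)
        b = stratified_kfold(tax, k=3, seed=42)
        assert a.assignment == b.assignment

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_partition_property(self, small_db, k):
        _, tax, _ = small_db
        folds = stratified_kfold(tax, k=k, seed=7)
        all_ids = [i for f in range(k) for i in folds.test_ids(f)]
        assert sorted(all_ids) == sorted(tax.entries)
        assert len(all_ids) == len(set(all_ids))

    def test_k_larger_than_table_errors(self):
        tax = _tab({"a": "g__A; s__A x"})
        with pytest.raises(ValueError):
            stratified_kfold(tax, k=2, seed=0)


class TestExpectedWithLcaTruncation:
    def test_lineage_present_in_training_unchanged(self):
        test = _tab({"q": "g__G; s__G x"})
        train = _tab({"t": "g__G; s__G x"})
        out = expected_with_lca_truncation(test, train)
        assert out["q"].labels == ("G", "G x")

    def test_singleton_species_truncated_at_genus(self):
        test = _tab({"q": "g__G; s__G x"})
        train = _tab({"t": "g__G; s__G y"})
        out = expected_with_lca_truncation(test, train)
        assert out["q"].labels == ("G", "")

    def test_fully_novel_lineage_truncated_to_empty(self):
        test = _tab({"q": "g__G; s__G x"})
        train = _tab({"t": "g__H; s__H y"})
        out = expected_with_lca_truncation(test, train)
        assert out["q"].labels == ("", "")

    def test_empty_training_errors(self):
        test = _tab({"q": "g__G; s__G x"})
        with pytest.raises(TaxonomyError):
            expected_with_lca_truncation(test, TaxonomyTable(SCHEMA2, {}))


def _prf_oracle(expected, observed, rank):
    """Direct confusion counting, independent of the scored implementation."""
    tp = fp = fn = 0
    for ident in expected.entries:
        e, o = expected[ident], observed[ident]
        e_inf, o_inf = e.informative[rank], o.informative[rank]
        match = e.labels[: rank + 1] == o.labels[: rank + 1]
        if e_inf and o_inf and match:
            tp += 1
        else:
            if o_inf:
                fp += 1
            if e_inf:
                fn += 1
    return tp, fp, fn


class TestEvaluateClassifications:
    def test_perfect_classification(self):
        tab = _tab({"a": "g__G; s__G x", "b": "g__H; s__H y"})
        rep = evaluate_classifications(tab, tab)
        assert (rep["precision"] == 1.0).all()
        assert (rep["recall"] == 1.0).all()
        assert (rep["f_measure"] == 1.0).all()

    def test_hand_counted_genus_confusion(self):
        """2 correct, 1 wrong genus, 1 unclassified: P=2/3, R=1/2, F=4/7."""
        expected = _tab({
            "q1": "g__A; s__", "q2": "g__B; s__",
            "q3": "g__C; s__", "q4": "g__D; s__",
        })
        observed = _tab({
            "q1": "g__A; s__", "q2": "g__B; s__",
            "q3": "g__X; s__", "q4": "g__; s__",
        })
        rep = evaluate_classifications(expected, observed)
        assert rep.loc["genus", "tp"] == 2
        assert rep.loc["genus", "fp"] == 1
        assert rep.loc["genus", "fn"] == 2
        assert rep.loc["genus", "precision"] == pytest.approx(2 / 3)
        assert rep.loc["genus", "recall"] == pytest.approx(1 / 2)
        assert rep.loc["genus", "f_measure"] == pytest.approx(4 / 7)

    def test_overclassification_counts_against_precision_only(self):
        expected = _tab({"q": "g__G; s__"})
        observed = _tab({"q": "g__G; s__G x"})
        rep = evaluate_classifications(expected, observed)
        assert rep.loc["species", "fp"] == 1
        assert rep.loc["species", "fn"] == 0
        assert rep.loc["genus", "tp"] == 1

    def test_underclassification_counts_against_recall_only(self):
        expected = _tab({"q": "g__G; s__G x"})
        observed = _tab({"q": "g__G; s__"})
        rep = evaluate_classifications(expected, observed)
        assert rep.loc["species", "fn"] == 1
        assert rep.loc["species", "fp"] == 0

    def test_identifier_mismatch_errors(self):
        with pytest.raises(TaxonomyError):
            evaluate_classifications(
                _tab({"a": "g__G; s__"}), _tab({"b": "g__G; s__"})
            )

    def test_exhaustive_two_query_configurations(self):
        """Scorer matches the brute-force oracle on all 2-query configs."""
        options = ["g__; s__", "g__A; s__", "g__A; s__A x",
                   "g__A; s__A y", "g__B; s__B x"]
        for exp_pair in itertools.product(options, repeat=2):
            for obs_pair in itertools.product(options, repeat=2):
                expected = _tab({"q0": exp_pair[0], "q1": exp_pair[1]})
                observed = _tab({"q0": obs_pair[0], "q1": obs_pair[1]})
                rep = evaluate_classifications(expected, observed)
                for r, rank in enumerate(("genus", "species")):
                    tp, fp, fn = _prf_oracle(expected, observed, r)
                    assert rep.loc[rank, "tp"] == tp
                    assert rep.loc[rank, "fp"] == fp
                    assert rep.loc[rank, "fn"] == fn


class TestEvaluationRegimes:
    def test_separable_database_fit_f_near_one(self, small_db):
        seqs, tax, _ = small_db
        rep = evaluate_fit_classifier(seqs, tax)
        assert rep.loc["species", "f_measure"] >= 0.99

    def test_identical_sequences_with_two_labels_confuse_species(self):
        seqs = SequenceSet([("a", "ACGTACGTACGT" * 4), ("b", "ACGTACGTACGT" * 4)])
        tax = _tab({"a": "g__G; s__G x", "b": "g__G; s__G y"})
        rep = evaluate_fit_classifier(seqs, tax, k=4)
        assert rep.loc["species", "f_measure"] <= 0.5

    def test_single_class_database_perfect_everywhere(self):
        seqs = SequenceSet([(f"r{i}", "ACGTACGTACGT" * 4) for i in range(3)])
        tax = _tab({f"r{i}": "g__G; s__G x" for i in range(3)})
        rep = evaluate_fit_classifier(seqs, tax, k=4)
        assert (rep["f_measure"] == 1.0).all()

    def test_fit_dominates_cross_validation(self):
        for seed in (3, 4):
            spec = FixtureSpec(seed=seed, n_genera_per_family=2,
                               n_species_per_genus=2, seqs_per_species=4)
            seqs, tax, _ = generate_reference_db(spec)
            fit_rep = evaluate_fit_classifier(seqs, tax)
            cv_rep = evaluate_cross_validate(seqs, tax, seed=seed)
            assert (
                fit_rep.loc["species", "f_measure"]
                >= cv_rep.loc["species", "f_measure"] - 1e-12
            )

    def test_singleton_species_yield_zero_species_recall_contribution(self):
        spec = FixtureSpec(seed=9, n_genera_per_family=2,
                           n_species_per_genus=3, seqs_per_species=1)
        seqs, tax, _ = generate_reference_db(spec)
        rep = evaluate_cross_validate(seqs, tax, k_folds=3, seed=1)
        # every lineage is a taxonomic singleton: expectations are truncated
        # to genus, so there are no species-level expected labels at all
        assert rep.loc["species", "tp"] == 0
        assert rep.loc["species", "fn"] == 0

    def test_cross_validation_deterministic(self, small_db):
        seqs, tax, _ = small_db
        a = evaluate_cross_validate(seqs, tax, seed=5)
        b = evaluate_cross_validate(seqs, tax, seed=5)
        assert a.equals(b)
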