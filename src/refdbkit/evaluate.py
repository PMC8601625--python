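"""Simulated classification accuracy under two evaluation regimes.

The *fit-classifier* regime trains and tests on the full database —
intentional data leakage that estimates best-case accuracy when every
query has an exact match in the reference. The *cross-validation*
regime splits the database into k folds stratified by full lineage so
each sequence is tested exactly once against a classifier trained on
the complement; taxonomic singletons (test lineages absent from the
training fold) have their expected label truncated to the LCA with the
nearest training lineage, since a deeper call cannot be "correct" when
the true label is unseen. Observed vs expected labels are scored per
rank as precision / recall / F-measure over a pooled (micro-averaged)
confusion tally: over-classification counts against precision,
under-classification against recall, misclassification against both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import classifier as _clf
from .curate import SequenceSet
from .taxonomy import TaxonomyError, TaxonomyTable, truncate_at_depth

__all__ = [
    "FoldAssignment",
    "stratified_kfold",
    "expected_with_lca_truncation",
    "evaluate_classifications",
    "evaluate_fit_classifier",
    "evaluate_cross_validate",
]


@dataclass
class FoldAssignment:
    """A k-fold split: identifier -> fold index, reproducible by seed."""

    k: int
    assignment: dict[str, int]
    seed: int

    def test_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f != fold]


def stratified_kfold(tax: TaxonomyTable, k: int = 3, seed: int = 0) -> FoldAssignment:
    """Split entries into k folds, stratified by full lineage.

    Members of each lineage group are distributed round-robin over folds
    in seeded-shuffled order, so groups are spread as evenly as possible
    and groups smaller than k appear in fewer folds. Deterministic for a
    given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(tax):
        raise ValueError(f"k={k} exceeds table size {len(tax)}")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, ...], list[str]] = {}
    for ident, lin in tax.entries.items():
        groups.setdefault(lin.labels, []).append(ident)
    assignment: dict[str, int] = {}
    offset = 0  # rotate the starting fold so small groups spread out
    for key in sorted(groups):
        members = sorted(groups[key])
        rng.shuffle(members)
        for j, ident in enumerate(members):
            assignment[ident] = (offset + j) % k
        offset += len(members)
    return FoldAssignment(k, assignment, seed)


def expected_with_lca_truncation(
    test_tax: TaxonomyTable, train_tax: TaxonomyTable
) -> TaxonomyTable:
    """Expected labels for a test fold, truncating taxonomic singletons.

    A test lineage present in the training set is expected unchanged; a
    lineage absent from training is truncated to its longest rank-wise
    prefix shared with any training lineage (the LCA with its nearest
    training taxon), which is the deepest label a classifier could
    correctly assign.
    """
    if len(train_tax) == 0:
        raise TaxonomyError("empty training taxonomy")
    train_set = {lin.labels for lin in train_tax.entries.values()}
    train_list = list(train_set)
    out = {}
    for ident, lin in test_tax.entries.items():
        if lin.labels in train_set:
            out[ident] = lin
            continue
        best = 0
        for cand in train_list:
            d = 0
            for a, b in zip(lin.labels, cand):
                if a == b:
                    d += 1
                else:
                    break
            best = max(best, d)
        out[ident] = truncate_at_depth(lin, best)
    return TaxonomyTable(test_tax.schema, out)


def evaluate_classifications(
    expected: TaxonomyTable, observed: TaxonomyTable
) -> pd.DataFrame:
    """Per-rank precision / recall / F-measure of observed vs expected.

    At rank r a query is a TP when expected and observed are both
    informative there and their depth-r label prefixes match exactly; an
    observed informative label that is not a TP is an FP
    (over-classification or misclassification); an expected informative
    label that is not a TP is an FN (under-classification or
    misclassification). Empty denominators yield 0 with a flag column.
    """
    if set(expected.entries) != set(observed.entries):
        raise TaxonomyError("expected and observed identifier sets differ")
    rows = []
    for r, rank_name in enumerate(expected.schema.names):
        tp = fp = fn = 0
        for ident, exp in expected.entries.items():
            obs = observed[ident]
            e_inf = exp.informative[r]
            o_inf = obs.informative[r]
            match = exp.labels[: r + 1] == obs.labels[: r + 1]
            if e_inf and o_inf and match:
                tp += 1
            else:
                if o_inf:
                    fp += 1
                if e_inf:
                    fn += 1
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        rows.append(
            {
                "rank": rank_name,
                "precision": precision,
                "recall": recall,
                "f_measure": f,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "undefined": (tp + fp == 0) or (tp + fn == 0),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


def evaluate_fit_classifier(
    seqs: SequenceSet,
    tax: TaxonomyTable,
    k: int = 7,
    alpha: float = 0.001,
    confidence: float = 0.7,
) -> pd.DataFrame:
    """Best-case accuracy: train and test on the full database.

    The intentional train/test leakage estimates the upper bound of
    classification accuracy for the database.
    """
    model = _clf.fit(seqs, tax, k=k, alpha=alpha)
    result = _clf.classify(model, seqs, confidence=confidence)
    return evaluate_classifications(tax, result.taxonomy)


def evaluate_cross_validate(
    seqs: SequenceSet,
    tax: TaxonomyTable,
    k_folds: int = 3,
    seed: int = 0,
    k: int = 7,
    alpha: float = 0.001,
    confidence: float = 0.7,
) -> pd.DataFrame:
    """K-fold cross-validated accuracy with singleton LCA truncation.

    Per fold: train on the complement, build the expected taxonomy for
    the test fold with :func:`expected_with_lca_truncation`, classify,
    then pool all per-query (expected, observed) pairs across folds and
    score once.
    """
    folds = stratified_kfold(tax, k=k_folds, seed=seed)
    pooled_exp: dict = {}
    pooled_obs: dict = {}
    for fold in range(k_folds):
        test_ids = folds.test_ids(fold)
        train_ids = folds.train_ids(fold)
        if not test_ids:
            continue
        train_seqs = seqs.subset(train_ids)
        train_tax = tax.subset(train_ids)
        test_seqs = seqs.subset(test_ids)
        expected = expected_with_lca_truncation(tax.subset(test_ids), train_tax)
        model = _clf.fit(train_seqs, train_tax, k=k, alpha=alpha)
        observed = _clf.classify(model, test_seqs, confidence=confidence)
        pooled_exp.update(expected.entries)
        pooled_obs.update(observed.taxonomy.entries)
    return evaluate_classifications(
        TaxonomyTable(tax.schema, pooled_exp),
        TaxonomyTable(tax.schema, pooled_obs),
    )
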