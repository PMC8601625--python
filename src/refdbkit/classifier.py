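"""K-mer multinomial naive-Bayes taxonomy classifier.

Each distinct full training lineage is one class. A sequence is reduced
to its forward-strand k-mer count vector (k-mers containing ambiguous
characters are skipped); per-class k-mer probabilities are additively
smoothed ((count + alpha) / (total + alpha * 4^k)) and priors are
uniform. Classification computes class posteriors in log space with
log-sum-exp normalization, then walks the taxonomy from the root:
posterior mass is aggregated over classes sharing each candidate label,
the best child is followed while its aggregated posterior stays at or
above the confidence threshold, and the deepest accepted prefix is
reported (depth 0 is "Unassigned"). This confidence-based depth
truncation trades depth of classification for reliability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .curate import SequenceSet
from .taxonomy import Lineage, RankSchema, TaxonomyError, TaxonomyTable, truncate_at_depth

__all__ = [
    "kmer_profile",
    "ClassifierModel",
    "ClassificationResult",
    "fit",
    "classify",
]

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

UNASSIGNED = "Unassigned"


def kmer_profile(seq: str, k: int) -> dict[str, int]:
    """Counts of all overlapping forward-strand k-mers of *seq*.

    K-mers containing ambiguous characters are skipped; sequences shorter
    than k yield an empty profile.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    acgt = frozenset("ACGT")
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if acgt.issuperset(kmer):
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _count_vector(seq: str, k: int) -> np.ndarray:
    """Dense 4^k count vector of unambiguous k-mers (vectorized)."""
    vec = np.zeros(4 ** k, dtype=np.float64)
    if len(seq) < k:
        return vec
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = (windows >= 0).all(axis=1)
    if not ok.any():
        return vec
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = (windows[ok] * powers).sum(axis=1)
    vec += np.bincount(idx, minlength=4 ** k).astype(np.float64)
    return vec


@dataclass
class ClassifierModel:
    """Fitted model: per-class smoothed log k-mer probabilities + priors."""

    k: int
    alpha: float
    schema: RankSchema
    classes: list[tuple[str, ...]]  # full-lineage label tuples
    class_lineages: list[Lineage]  # representative lineage per class
    feature_log_prob: np.ndarray  # (n_classes, 4^k)
    class_log_prior: np.ndarray  # (n_classes,)

    def save(self, path) -> None:
        """Serialize to a single versioned .npz archive (reload-stable)."""
        meta = {
            "format_version": 1,
            "k": self.k,
            "alpha": self.alpha,
            "schema_handles": list(self.schema.handles),
            "schema_names": list(self.schema.names),
            "classes": [list(c) for c in self.classes],
            "class_masks": [list(l.informative) for l in self.class_lineages],
        }
        np.savez(
            path,
            feature_log_prob=self.feature_log_prob,
            class_log_prior=self.class_log_prior,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"].tobytes()).decode())
            if meta.get("format_version") != 1:
                raise ValueError("unsupported model format version")
            schema = RankSchema(
                tuple(meta["schema_handles"]), tuple(meta["schema_names"])
            )
            classes = [tuple(c) for c in meta["classes"]]
            lineages = [
                Lineage(tuple(c), tuple(bool(b) for b in m))
                for c, m in zip(classes, meta["class_masks"])
            ]
            return cls(
                k=int(meta["k"]),
                alpha=float(meta["alpha"]),
                schema=schema,
                classes=classes,
                class_lineages=lineages,
                feature_log_prob=data["feature_log_prob"].copy(),
                class_log_prior=data["class_log_prior"].copy(),
            )


def fit(
    ref: SequenceSet,
    tax: TaxonomyTable,
    k: int = 7,
    alpha: float = 0.001,
) -> ClassifierModel:
    """Train on a reference set; one class per distinct full lineage."""
    if len(ref) == 0:
        raise ValueError("cannot fit on an empty reference set")
    missing = [i for i in ref.ids if i not in tax]
    if missing:
        raise TaxonomyError(f"reference records without taxonomy: {missing[:5]!r}")
    class_index: dict[tuple[str, ...], int] = {}
    class_lineages: list[Lineage] = []
    rows: list[np.ndarray] = []
    for ident, seq in ref:
        lin = tax[ident]
        key = lin.labels
        ci = class_index.get(key)
        if ci is None:
            ci = len(class_index)
            class_index[key] = ci
            class_lineages.append(lin)
            rows.append(np.zeros(4 ** k, dtype=np.float64))
        rows[ci] += _count_vector(seq, k)
    counts = np.vstack(rows)
    totals = counts.sum(axis=1, keepdims=True)
    feature_log_prob = np.log(counts + alpha) - np.log(totals + alpha * 4 ** k)
    n = counts.shape[0]
    return ClassifierModel(
        k=k,
        alpha=alpha,
        schema=tax.schema,
        classes=list(class_index),
        class_lineages=class_lineages,
        feature_log_prob=feature_log_prob,
        class_log_prior=np.full(n, -np.log(n)),
    )


@dataclass
class ClassificationResult:
    """Predicted taxonomy plus the accepted-prefix posterior per query."""

    taxonomy: TaxonomyTable
    confidence: dict[str, float]

    def to_frame(self) -> "object":
        import pandas as pd

        rows = []
        for ident, lin in self.taxonomy.entries.items():
            taxon = (
                lin.to_string(self.taxonomy.schema)
                if any(lin.labels)
                else UNASSIGNED
            )
            rows.append(
                {
                    "Feature ID": ident,
                    "Taxon": taxon,
                    "Confidence": self.confidence[ident],
                }
            )
        return pd.DataFrame(rows)


def posteriors(model: ClassifierModel, seq: str) -> np.ndarray:
    """Normalized class posterior distribution for one query sequence."""
    q = _count_vector(seq, model.k)
    scores = model.class_log_prior + model.feature_log_prob @ q
    return np.exp(scores - logsumexp(scores))


def classify(
    model: ClassifierModel,
    queries: SequenceSet,
    confidence: float = 0.7,
) -> ClassificationResult:
    """Classify queries, truncating depth by aggregated prefix posterior."""
    if not 0 <= confidence <= 1:
        raise ValueError("confidence must be in [0, 1]")
    n_ranks = len(model.schema)
    labels_by_depth = [
        np.array([c[d] for c in model.classes]) for d in range(n_ranks)
    ]
    out: dict[str, Lineage] = {}
    conf: dict[str, float] = {}
    for ident, seq in queries:
        post = posteriors(model, seq)
        if confidence == 0:
            # degenerate threshold: the argmax class's full lineage
            best = int(np.argmax(post))
            out[ident] = model.class_lineages[best]
            conf[ident] = float(post[best])
            continue
        active = np.ones(len(model.classes), dtype=bool)
        depth = 0
        accepted = 1.0
        for d in range(n_ranks):
            col = labels_by_depth[d]
            cand = {
                lab: post[active & (col == lab)].sum()
                for lab in np.unique(col[active])
            }
            # deterministic: highest mass, then lexicographically first
            lab, mass = min(cand.items(), key=lambda kv: (-kv[1], kv[0]))
            if mass >= confidence:
                active &= col == lab
                depth = d + 1
                accepted = float(mass)
            else:
                break
        rep_idx = int(np.argmax(np.where(active, post, -1.0)))
        rep = model.class_lineages[rep_idx]
        out[ident] = truncate_at_depth(rep, depth)
        conf[ident] = accepted
    return ClassificationResult(TaxonomyTable(model.schema, out), conf)
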