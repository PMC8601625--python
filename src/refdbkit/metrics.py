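"""Qualitative database evaluation metrics.

Shannon entropy (natural log) of taxonomic-label, sequence, and k-mer
frequency vectors measures both the richness and evenness of information
in a reference database. Per-rank reports additionally count unique
labels, unclassified entries, and "terminal" entries — those whose
taxonomic annotation stops exactly at that rank. Cross-database overlap
compares the bare label sets of two to four databases per rank after
collapsing prefix-related labels (so subclade suffixes like
"Lactobacillus_A" do not undercount sharing).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .curate import SequenceSet
from .taxonomy import TaxonomyError, TaxonomyTable, collapse_prefix_map

__all__ = [
    "shannon_entropy",
    "evaluate_taxonomy",
    "SeqReport",
    "evaluate_seqs",
    "ConsistencyResult",
    "genus_species_consistency",
    "taxonomy_overlap",
]

_ACGT = frozenset("ACGT")


def shannon_entropy(counts: Iterable[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i of a count vector, in nats.

    Zero counts are ignored; *base* switches the logarithm (e.g. 2 for
    bits) for display purposes.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("entropy requires a positive total count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(_scipy_entropy(arr, base=base))


def evaluate_taxonomy(tax: TaxonomyTable) -> pd.DataFrame:
    """Per-rank label metrics: unique labels, entropy, unclassified, terminal.

    At rank *r*, an entry is informative if its mask is set there; unique
    labels and entropy are computed over the distinct full lineage
    prefixes to depth *r* among informative entries; "unclassified"
    counts entries non-informative at *r*; "terminal" counts entries
    whose deepest informative rank is exactly *r*.
    """
    if len(tax) == 0:
        raise TaxonomyError("cannot evaluate an empty taxonomy table")
    n = len(tax)
    rows = []
    depths = Counter(lin.depth for lin in tax.entries.values())
    for r, rank_name in enumerate(tax.schema.names):
        prefixes = Counter(
            lin.labels[: r + 1]
            for lin in tax.entries.values()
            if lin.informative[r]
        )
        n_inf = sum(prefixes.values())
        rows.append(
            {
                "rank": rank_name,
                "unique_labels": len(prefixes),
                "entropy": shannon_entropy(prefixes.values()) if prefixes else 0.0,
                "unclassified": n - n_inf,
                "terminal": depths.get(r + 1, 0),
            }
        )
    return pd.DataFrame(rows).set_index("rank")


@dataclass
class SeqReport:
    """Sequence-level information summary for a database."""

    n_records: int
    unique_sequences: int
    length_summary: dict[str, float]  # min/q25/median/q75/max/mean
    sequence_entropy: float  # nats
    kmer_entropy: dict[int, float]  # k -> nats

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "n_records", "value": self.n_records},
            {"metric": "unique_sequences", "value": self.unique_sequences},
            {"metric": "sequence_entropy", "value": self.sequence_entropy},
        ]
        rows += [
            {"metric": f"length_{k}", "value": v}
            for k, v in self.length_summary.items()
        ]
        rows += [
            {"metric": f"kmer_entropy_k{k}", "value": v}
            for k, v in sorted(self.kmer_entropy.items())
        ]
        return pd.DataFrame(rows)


def _pooled_kmer_counts(seqs: SequenceSet, k: int) -> Counter:
    counts: Counter = Counter()
    for _, seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if _ACGT.issuperset(kmer):
                counts[kmer] += 1
    return counts


def evaluate_seqs(
    seqs: SequenceSet,
    kmer_lengths: Sequence[int] = (2, 4, 8, 16),
    unique_only: bool = False,
) -> SeqReport:
    """Sequence-information report: counts, length distribution, entropies.

    Sequence entropy uses occurrence frequencies of distinct sequence
    strings (``unique_only=True`` switches to richness-only, i.e. a flat
    count per distinct string). K-mer entropy pools all overlapping
    forward-strand k-mers across records; k-mers containing ambiguous
    characters are skipped.
    """
    if len(seqs) == 0:
        raise ValueError("cannot evaluate an empty sequence set")
    if any(k < 1 for k in kmer_lengths):
        raise ValueError("k-mer lengths must be >= 1")
    lengths = np.array([len(s) for _, s in seqs], dtype=float)
    seq_counts = Counter(s for _, s in seqs)
    freqs = (
        [1] * len(seq_counts) if unique_only else list(seq_counts.values())
    )
    kmer_entropy = {}
    for k in kmer_lengths:
        counts = _pooled_kmer_counts(seqs, k)
        kmer_entropy[k] = shannon_entropy(counts.values()) if counts else 0.0
    return SeqReport(
        n_records=len(seqs),
        unique_sequences=len(seq_counts),
        length_summary={
            "min": float(lengths.min()),
            "q25": float(np.percentile(lengths, 25)),
            "median": float(np.median(lengths)),
            "q75": float(np.percentile(lengths, 75)),
            "max": float(lengths.max()),
            "mean": float(lengths.mean()),
        },
        sequence_entropy=shannon_entropy(freqs),
        kmer_entropy=kmer_entropy,
    )


@dataclass
class ConsistencyResult:
    """Genus/species label agreement over species-informative entries."""

    fraction_inconsistent: float
    offenders: list[str]
    n_evaluated: int
    undefined: bool  # True when no entry was informative at both ranks


def genus_species_consistency(tax: TaxonomyTable) -> ConsistencyResult:
    """Check that each species label's first word matches the genus label."""
    gi = tax.schema.index_of_name("genus")
    si = tax.schema.index_of_name("species")
    offenders = []
    n_eval = 0
    for ident, lin in tax.entries.items():
        if not (lin.informative[gi] and lin.informative[si]):
            continue
        n_eval += 1
        first = lin.labels[si].split()[0] if lin.labels[si].split() else ""
        if first != lin.labels[gi]:
            offenders.append(ident)
    if n_eval == 0:
        return ConsistencyResult(0.0, [], 0, undefined=True)
    return ConsistencyResult(len(offenders) / n_eval, offenders, n_eval, False)


def taxonomy_overlap(tables: Mapping[str, TaxonomyTable]) -> pd.DataFrame:
    """Per-rank proportion of each database's labels shared with the others.

    For every reference database and rank, reports
    ``|reference ∩ S| / |reference|`` over the bare (informative) rank
    label sets for every subset S of the other databases — each single
    other, each pair, trio, and all together — after collapsing
    prefix-related labels across the union of all databases. The
    reference-alone proportion is 1.0 by construction.
    """
    if not 2 <= len(tables) <= 4:
        raise ValueError("taxonomy_overlap compares 2-4 tables")
    names = list(tables)
    depth = min(len(t.schema) for t in tables.values())
    rank_names = list(next(iter(tables.values())).schema.names[:depth])
    rows = []
    for r in range(depth):
        raw_sets = {
            name: {
                lin.labels[r]
                for lin in tbl.entries.values()
                if lin.informative[r]
            }
            for name, tbl in tables.items()
        }
        union = set().union(*raw_sets.values())
        canon = collapse_prefix_map(union)
        sets = {
            name: {canon[l] for l in labels}
            for name, labels in raw_sets.items()
        }
        for ref in names:
            others = [n for n in names if n != ref]
            ref_set = sets[ref]
            denom = len(ref_set)
            rows.append(
                {
                    "reference": ref,
                    "rank": rank_names[r],
                    "compared_with": "",
                    "proportion": 1.0,
                }
            )
            for size in range(1, len(others) + 1):
                for combo in combinations(others, size):
                    inter = ref_set.intersection(*(sets[o] for o in combo))
                    rows.append(
                        {
                            "reference": ref,
                            "rank": rank_names[r],
                            "compared_with": "+".join(combo),
                            "proportion": (len(inter) / denom) if denom else 0.0,
                        }
                    )
    return pd.DataFrame(rows)
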