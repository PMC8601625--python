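"""Sequence containers and quality / metadata-based record filtering.

Filtering follows the conventions of reference-database curation for
marker genes: sequences with excessive homopolymer runs or ambiguous
(non-ACGT IUPAC) bases are culled, length bounds are applied globally or
per taxonomic group (e.g. archaeal 16S < 900 nt, bacterial < 1200 nt),
and taxonomy entries can be required to carry annotation to a minimum
rank depth. Every filter returns the surviving records in input order
plus a :class:`CurationReport` accounting for each removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Optional

import pandas as pd

from .taxonomy import TaxonomyError, TaxonomyTable

__all__ = [
    "SequenceSet",
    "CurationReport",
    "AlphabetError",
    "cull_seqs",
    "filter_seqs_length",
    "filter_seqs_length_by_taxon",
    "filter_by_annotation_depth",
]

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
GAP_CHARS = frozenset(".-")
_UNAMBIGUOUS = frozenset("ACGT")


class AlphabetError(ValueError):
    """A sequence contains a character outside IUPAC DNA codes + gaps."""


@dataclass
class SequenceSet:
    """Ordered collection of (identifier, nucleotide string) records."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence identifier {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def get(self, ident: str) -> str:
        for i, s in self.records:
            if i == ident:
                return s
        raise KeyError(ident)

    def subset(self, idents: Iterable[str]) -> "SequenceSet":
        want = set(idents)
        return SequenceSet([(i, s) for i, s in self.records if i in want])

    def degapped(self) -> "SequenceSet":
        table = str.maketrans("", "", "".join(GAP_CHARS))
        return SequenceSet([(i, s.translate(table)) for i, s in self.records])


@dataclass
class CurationReport:
    """Bookkeeping for one filter pass: kept count + removals by reason.

    A record appears under at most one reason — the first failing rule in
    the filter's documented rule order claims it.
    """

    kept: int
    removed: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def removed_ids(self) -> set[str]:
        return {i for ids in self.removed.values() for i in ids}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": ident, "reason": reason}
            for reason, ids in self.removed.items()
            for ident in ids
        ]
        return pd.DataFrame(rows, columns=["id", "reason"])


def _longest_run(seq: str) -> int:
    return max((sum(1 for _ in g) for _, g in groupby(seq)), default=0)


def _validate_alphabet(ident: str, seq: str, allow_gaps: bool) -> None:
    allowed = IUPAC_DNA | (GAP_CHARS if allow_gaps else frozenset())
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise AlphabetError(
                f"record {ident!r}: non-IUPAC character {ch!r} at position {pos}"
            )


def cull_seqs(
    seqs: SequenceSet,
    max_homopolymer: int = 8,
    max_ambiguous: int = 5,
    degap: bool = True,
) -> tuple[SequenceSet, CurationReport]:
    """Remove low-quality records by homopolymer run and ambiguity count.

    After optional gap removal, a record is removed iff its longest
    single-base run is strictly greater than *max_homopolymer* OR its
    count of non-ACGT IUPAC characters is strictly greater than
    *max_ambiguous*. Homopolymer failure is attributed first.
    """
    if max_homopolymer < 1 or max_ambiguous < 1:
        raise ValueError("thresholds must be >= 1")
    gap_table = str.maketrans("", "", "".join(GAP_CHARS))
    kept: list[tuple[str, str]] = []
    removed: dict[str, list[str]] = {}
    for ident, raw in seqs:
        seq = raw.translate(gap_table) if degap else raw
        _validate_alphabet(ident, seq, allow_gaps=not degap)
        if _longest_run(seq) > max_homopolymer:
            removed.setdefault("homopolymer", []).append(ident)
        elif sum(1 for c in seq if c not in _UNAMBIGUOUS and c not in GAP_CHARS) > max_ambiguous:
            removed.setdefault("ambiguous_bases", []).append(ident)
        else:
            kept.append((ident, seq))
    return SequenceSet(kept), CurationReport(len(kept), removed)


def filter_seqs_length(
    seqs: SequenceSet,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
) -> tuple[SequenceSet, CurationReport]:
    """Keep records with min_len <= length <= max_len (inclusive)."""
    if min_len is None and max_len is None:
        warnings.warn("no length bounds given; filter is a no-op")
        return SequenceSet(list(seqs.records)), CurationReport(len(seqs), {})
    if min_len is not None and max_len is not None and min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept, removed = [], {}
    for ident, seq in seqs:
        n = len(seq)
        if (min_len is not None and n < min_len) or (
            max_len is not None and n > max_len
        ):
            removed.setdefault("length", []).append(ident)
        else:
            kept.append((ident, seq))
    return SequenceSet(kept), CurationReport(len(kept), removed)


def filter_seqs_length_by_taxon(
    seqs: SequenceSet,
    tax: TaxonomyTable,
    constraints: Mapping[str, tuple[Optional[int], Optional[int]]],
    at_rank: Optional[str] = None,
    missing_taxonomy: str = "error",
) -> tuple[SequenceSet, CurationReport]:
    """Apply per-taxon length bounds (most restrictive wins).

    A record matching a constrained label anywhere in its lineage must
    satisfy that label's (min, max) bounds; matching several constrained
    labels means satisfying all of them. Unmatched records pass. Set
    *at_rank* to restrict label matching to one named rank. Records
    without a taxonomy entry raise unless ``missing_taxonomy="pass"``.
    """
    rank_idx = tax.schema.index_of_name(at_rank) if at_rank else None
    kept, removed = [], {}
    for ident, seq in seqs:
        if ident not in tax:
            if missing_taxonomy == "pass":
                kept.append((ident, seq))
                continue
            raise TaxonomyError(f"record {ident!r} has no taxonomy entry")
        labels = (
            [tax[ident].labels[rank_idx]]
            if rank_idx is not None
            else list(tax[ident].labels)
        )
        lo: Optional[int] = None
        hi: Optional[int] = None
        for label, (mn, mx) in constraints.items():
            if label in labels:
                if mn is not None:
                    lo = mn if lo is None else max(lo, mn)
                if mx is not None:
                    hi = mx if hi is None else min(hi, mx)
        n = len(seq)
        if (lo is not None and n < lo) or (hi is not None and n > hi):
            removed.setdefault("taxon_length", []).append(ident)
        else:
            kept.append((ident, seq))
    return SequenceSet(kept), CurationReport(len(kept), removed)


def filter_by_annotation_depth(
    tax: TaxonomyTable, required_rank: str
) -> tuple[TaxonomyTable, CurationReport]:
    """Keep entries annotated at *required_rank* or deeper.

    Depth is judged by the informative mask, so propagated or ambiguous
    placeholder labels do not count as annotation.
    """
    need = tax.schema.index_of_name(required_rank) + 1
    kept: dict = {}
    removed: dict[str, list[str]] = {}
    for ident, lin in tax.entries.items():
        if lin.depth >= need:
            kept[ident] = lin
        else:
            removed.setdefault("shallow_annotation", []).append(ident)
    return TaxonomyTable(tax.schema, kept), CurationReport(len(kept), removed)
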