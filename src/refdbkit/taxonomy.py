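"""Ranked-lineage data model and consensus utilities.

A taxonomy is represented as a fixed ordered set of ranks (a
:class:`RankSchema`, e.g. ``d__`` domain through ``g__`` genus) and, per
record, a :class:`Lineage`: one label per rank plus a per-rank flag that
separates real annotations from empty placeholders or ambiguous
vocabulary ("uncultured", "unidentified", ...). All higher-level
operations — rank propagation (forward fill), last-common-ancestor and
majority consensus, prefix collapsing of subclade labels — work on this
representation.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TaxonomyError",
    "SchemaMismatchError",
    "RankSchema",
    "Lineage",
    "TaxonomyTable",
    "DEFAULT_AMBIGUOUS_VOCAB",
    "SILVA_SCHEMA",
    "NCBI_SCHEMA",
    "SYNTH_SCHEMA",
    "parse_lineage",
    "propagate_ranks",
    "consensus_lineage",
    "truncate_at_depth",
    "collapse_prefix_labels",
    "collapse_prefix_map",
]


class TaxonomyError(ValueError):
    """Base class for taxonomy-model errors."""


class SchemaMismatchError(TaxonomyError):
    """A lineage string or lineage does not fit the rank schema."""


#: Case-insensitive substring patterns marking labels that carry no real
#: taxonomic information (they name ignorance, not a taxon).
DEFAULT_AMBIGUOUS_VOCAB: tuple[str, ...] = (
    "unidentified",
    "uncultured",
    "unknown",
    "unclassified",
    "metagenome",
    "environmental",
)

_PREFIX_RE = re.compile(r"^([A-Za-z]{1,4}__)")


@dataclass(frozen=True)
class RankSchema:
    """Ordered rank prefixes ("handles") with parallel human rank names.

    Parameters
    ----------
    handles : tuple of str
        Rank prefixes such as ``"d__"``; each must end in ``"__"`` (or be
        empty for a prefix-free positional dialect).
    names : tuple of str
        Rank names such as ``"domain"``; same length as *handles*.
    """

    handles: tuple[str, ...]
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.handles) != len(self.names):
            raise SchemaMismatchError("handles and names must be parallel")
        if len(self.handles) < 1:
            raise SchemaMismatchError("a schema needs at least one rank")
        if len(set(self.handles)) != len(self.handles):
            raise SchemaMismatchError("rank handles must be unique")
        for h in self.handles:
            if h and not h.endswith("__"):
                raise SchemaMismatchError(f"rank handle {h!r} must end in '__'")

    def __len__(self) -> int:
        return len(self.handles)

    def index_of_name(self, name: str) -> int:
        """Index of a rank by case-insensitive rank name."""
        lowered = [n.lower() for n in self.names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise SchemaMismatchError(f"rank {name!r} not in schema") from None


#: SILVA-style seven ranks, species-less (species may be appended from the
#: organism name by the SILVA importer).
SILVA_SCHEMA = RankSchema(
    handles=("d__", "k__", "p__", "c__", "o__", "f__", "g__"),
    names=("domain", "kingdom", "phylum", "class", "order", "family", "genus"),
)

#: Greengenes/NCBI-style seven ranks from kingdom to species.
NCBI_SCHEMA = RankSchema(
    handles=("k__", "p__", "c__", "o__", "f__", "g__", "s__"),
    names=("kingdom", "phylum", "class", "order", "family", "genus", "species"),
)

#: Schema used by the synthetic database generator.
SYNTH_SCHEMA = RankSchema(
    handles=("d__", "p__", "c__", "o__", "f__", "g__", "s__"),
    names=("domain", "phylum", "class", "order", "family", "genus", "species"),
)


@dataclass(frozen=True)
class Lineage:
    """One label per schema rank plus an informativeness flag per rank.

    ``informative[i]`` is False for empty labels, labels matching the
    ambiguous vocabulary, and labels produced by rank propagation.
    """

    labels: tuple[str, ...]
    informative: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.informative):
            raise TaxonomyError("labels and informative mask must be parallel")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def depth(self) -> int:
        """Deepest informative rank plus one (0 if nothing is informative)."""
        for i in range(len(self.labels) - 1, -1, -1):
            if self.informative[i]:
                return i + 1
        return 0

    def to_string(self, schema: RankSchema) -> str:
        """Render as a semicolon-delimited string with rank handles."""
        if len(self) != len(schema):
            raise SchemaMismatchError("lineage length does not match schema")
        return "; ".join(h + l for h, l in zip(schema.handles, self.labels))


def _is_ambiguous(label: str, vocab: Sequence[str]) -> bool:
    low = label.lower()
    return any(pat.lower() in low for pat in vocab)


def parse_lineage(
    text: str,
    schema: RankSchema,
    ambiguous_vocab: Sequence[str] = DEFAULT_AMBIGUOUS_VOCAB,
) -> Lineage:
    """Parse a semicolon-delimited lineage string against a schema.

    Fields carrying a recognized rank handle are matched by handle; bare
    fields are matched by position. Missing trailing ranks become empty
    labels. A field with a handle-looking prefix absent from the schema
    raises :class:`SchemaMismatchError`; more fields than ranks raises
    :class:`TaxonomyError`.
    """
    labels = [""] * len(schema)
    stripped = text.strip()
    fields = [] if not stripped else [f.strip() for f in stripped.split(";")]
    if fields and fields[-1] == "" and len(fields) == len(schema) + 1:
        fields = fields[:-1]  # tolerate a trailing semicolon
    if len(fields) > len(schema):
        raise TaxonomyError(
            f"{len(fields)} lineage fields for a {len(schema)}-rank schema"
        )
    for pos, fld in enumerate(fields):
        m = _PREFIX_RE.match(fld)
        if m:
            handle = m.group(1)
            if handle not in schema.handles:
                raise SchemaMismatchError(
                    f"rank handle {handle!r} not in schema {schema.handles}"
                )
            labels[schema.handles.index(handle)] = fld[len(handle):].strip()
        else:
            labels[pos] = fld
    informative = tuple(
        bool(l) and not _is_ambiguous(l, ambiguous_vocab) for l in labels
    )
    return Lineage(tuple(labels), informative)


def propagate_ranks(lin: Lineage) -> Lineage:
    """Forward-fill empty ranks with the last observed label above.

    Only empty labels are filled; non-empty labels flagged non-informative
    (e.g. "uncultured") are kept as observed. The informative mask is
    unchanged, so propagated labels stay non-informative. Idempotent.
    """
    labels = list(lin.labels)
    last = ""
    for i, lab in enumerate(labels):
        if lab:
            last = lab
        elif last:
            labels[i] = last
    return Lineage(tuple(labels), lin.informative)


def _check_multiset(lins: Sequence[Lineage]) -> int:
    if not lins:
        raise TaxonomyError("consensus of an empty lineage multiset")
    n = len(lins[0])
    if any(len(l) != n for l in lins):
        raise SchemaMismatchError("lineages with mixed schema lengths")
    return n


def _lca(lins: Sequence[Lineage]) -> Lineage:
    n = _check_multiset(lins)
    labels: list[str] = []
    informative: list[bool] = []
    for i in range(n):
        col = {l.labels[i] for l in lins}
        if len(col) == 1 and lins[0].labels[i]:
            labels.append(lins[0].labels[i])
            informative.append(all(l.informative[i] for l in lins))
        else:
            break
    pad = n - len(labels)
    return Lineage(tuple(labels) + ("",) * pad, tuple(informative) + (False,) * pad)


def _majority(lins: Sequence[Lineage]) -> Lineage:
    counts = Counter(l.labels for l in lins)
    best = max(counts.values())
    tied = [t for t, c in counts.items() if c == best]
    if len(tied) == 1:
        winner = tied[0]
        for l in lins:
            if l.labels == winner:
                return l
    reps = []
    for t in tied:
        reps.append(next(l for l in lins if l.labels == t))
    return _lca(reps)


def _super(lins: Sequence[Lineage]) -> Lineage:
    n = _check_multiset(lins)
    candidates = list(lins)
    labels: list[str] = []
    informative: list[bool] = []
    for i in range(n):
        counts = Counter(l.labels[i] for l in candidates)
        best = max(counts.values())
        tied = [lab for lab, c in counts.items() if c == best]
        if len(tied) != 1:
            break
        winner = tied[0]
        candidates = [l for l in candidates if l.labels[i] == winner]
        labels.append(winner)
        informative.append(
            bool(winner) and all(l.informative[i] for l in candidates)
        )
    pad = n - len(labels)
    return Lineage(tuple(labels) + ("",) * pad, tuple(informative) + (False,) * pad)


def consensus_lineage(lins: Sequence[Lineage], mode: str = "lca") -> Lineage:
    """Consensus of a multiset of lineages.

    Modes
    -----
    ``lca``
        Longest rank-wise common prefix; deeper ranks left empty.
    ``majority``
        The single most frequent full lineage; ties fall back to the LCA
        of the tied lineages.
    ``super``
        Built top-down, at each rank taking the most frequent label among
        lineages consistent with the chosen prefix; stops at the first tie.
    """
    _check_multiset(lins)
    if mode == "lca":
        return _lca(lins)
    if mode == "majority":
        return _majority(lins)
    if mode == "super":
        return _super(lins)
    raise TaxonomyError(f"unknown consensus mode {mode!r}")


def truncate_at_depth(lin: Lineage, depth: int) -> Lineage:
    """Empty all ranks beyond *depth* (0 empties everything)."""
    if not 0 <= depth <= len(lin):
        raise TaxonomyError(f"depth {depth} out of range for {len(lin)} ranks")
    return Lineage(
        lin.labels[:depth] + ("",) * (len(lin) - depth),
        lin.informative[:depth] + (False,) * (len(lin) - depth),
    )


def collapse_prefix_map(labels: Iterable[str]) -> dict[str, str]:
    """Map each label to its group representative under prefix collapsing.

    Labels are grouped (transitively) whenever one is a prefix of another,
    so subclade suffixes such as ``"Lactobacillus_A"`` collapse onto
    ``"Lactobacillus"``. The representative is the shortest member of the
    group (ties broken lexicographically).
    """
    items = sorted(set(labels))
    parent = {l: l for l in items}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the shortest (then lexicographically first) as root
            keep, drop = sorted((ra, rb), key=lambda s: (len(s), s))
            parent[drop] = keep

    # sorted order puts prefixes adjacent to their extensions, but prefix
    # chains can interleave, so compare each label to all later ones that
    # share its first character block
    for i, a in enumerate(items):
        if not a:
            continue  # "" would be a prefix of everything
        for b in items[i + 1:]:
            if not b.startswith(a[0]):
                break
            if b.startswith(a):
                union(a, b)
    return {l: find(l) for l in items}


def collapse_prefix_labels(labels: Iterable[str]) -> set[str]:
    """Collapse prefix-related labels to one representative per group."""
    return set(collapse_prefix_map(labels).values())


@dataclass
class TaxonomyTable:
    """A rank schema plus a mapping record identifier -> :class:`Lineage`."""

    schema: RankSchema
    entries: dict[str, Lineage] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.schema)
        for ident, lin in self.entries.items():
            if len(lin) != n:
                raise SchemaMismatchError(
                    f"lineage of {ident!r} has {len(lin)} ranks, schema has {n}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, ident: str) -> bool:
        return ident in self.entries

    def __getitem__(self, ident: str) -> Lineage:
        return self.entries[ident]

    @classmethod
    def from_pairs(
        cls, schema: RankSchema, pairs: Iterable[tuple[str, Lineage]]
    ) -> "TaxonomyTable":
        entries: dict[str, Lineage] = {}
        for ident, lin in pairs:
            if ident in entries:
                raise TaxonomyError(f"duplicate identifier {ident!r}")
            entries[ident] = lin
        return cls(schema, entries)

    def subset(self, idents: Iterable[str]) -> "TaxonomyTable":
        return TaxonomyTable(
            self.schema, {i: self.entries[i] for i in idents}
        )

    def map(self, fn) -> "TaxonomyTable":
        """New table with *fn* applied to every lineage."""
        return TaxonomyTable(
            self.schema, {i: fn(l) for i, l in self.entries.items()}
        )

    def to_strings(self) -> dict[str, str]:
        return {i: l.to_string(self.schema) for i, l in self.entries.items()}
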