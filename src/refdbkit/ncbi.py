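"""NCBI taxdump-style taxonomy import.

Builds a rank-standardized taxonomy from local taxdump tables: *nodes*
(taxid -> parent taxid, rank name), *names* (taxid -> scientific name)
and an accession-to-taxid map. For each accession the parent chain is
ascended to the root, the collected (rank, name) pairs are projected
onto a fixed schema (NCBI's "superkingdom" aliases to the schema's top
kingdom/domain rank), and missing ranks are optionally forward-filled
from the nearest annotated ancestor. Ranks below species (strain,
subspecies, ...) are dropped.

Both the classic ``|``-delimited taxdump dialect and plain TSV are
accepted. Online retrieval is intentionally not implemented here; the
tables are read from local files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .io import open_maybe_gzip
from .silva import UnresolvableAccessionError, _project_path
from .taxonomy import (
    DEFAULT_AMBIGUOUS_VOCAB,
    Lineage,
    RankSchema,
    TaxonomyError,
    TaxonomyTable,
    _is_ambiguous,
)

__all__ = [
    "TaxdumpTables",
    "read_nodes",
    "read_names",
    "read_acc2taxid",
    "load_taxdump",
    "build_ncbi_taxonomy",
]

#: Ranks below species, excluded from projection and forward fill.
BELOW_SPECIES_RANKS = frozenset(
    {"subspecies", "strain", "varietas", "forma", "forma specialis",
     "isolate", "serotype", "serogroup", "biotype", "genotype"}
)

DEFAULT_RANK_ALIASES: Mapping[str, str] = {"superkingdom": "kingdom"}


@dataclass
class TaxdumpTables:
    """Parsed taxdump-style tables."""

    nodes: dict[int, tuple[int, str]]  # taxid -> (parent taxid, rank)
    names: dict[int, str]  # taxid -> scientific name
    acc2taxid: dict[str, int]  # accession -> taxid


def _dmp_fields(line: str) -> list[str]:
    if "|" in line:
        fields = [f.strip() for f in line.rstrip("\n").split("|")]
        if fields and fields[-1] == "":
            fields = fields[:-1]
        return fields
    return [f.strip() for f in line.rstrip("\n").split("\t")]


def read_nodes(path) -> dict[int, tuple[int, str]]:
    """Read nodes: columns (taxid, parent taxid, rank)."""
    out: dict[int, tuple[int, str]] = {}
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _dmp_fields(line)
            if lineno == 1 and not cols[0].isdigit():
                continue  # header
            if len(cols) < 3:
                raise TaxonomyError(f"{path}: line {lineno}: expected >=3 columns")
            out[int(cols[0])] = (int(cols[1]), cols[2])
    return out


def read_names(path) -> dict[int, str]:
    """Read names; in the 4-column taxdump dialect only scientific names count."""
    out: dict[int, str] = {}
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _dmp_fields(line)
            if lineno == 1 and not cols[0].isdigit():
                continue
            if len(cols) >= 4 and cols[3] != "scientific name":
                continue
            out[int(cols[0])] = cols[1]
    return out


def read_acc2taxid(path) -> dict[str, int]:
    """Read accession->taxid: 2-column TSV or the 4-column NCBI layout."""
    out: dict[str, int] = {}
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _dmp_fields(line)
            if lineno == 1 and not cols[-1].lstrip("-").isdigit():
                continue  # header
            if len(cols) >= 4:
                out[cols[1] or cols[0]] = int(cols[2])
            elif len(cols) == 2:
                out[cols[0]] = int(cols[1])
            else:
                raise TaxonomyError(f"{path}: line {lineno}: expected 2 or 4 columns")
    return out


def load_taxdump(nodes_path, names_path, acc2taxid_path) -> TaxdumpTables:
    return TaxdumpTables(
        nodes=read_nodes(nodes_path),
        names=read_names(names_path),
        acc2taxid=read_acc2taxid(acc2taxid_path),
    )


def _chain_to_root(tables: TaxdumpTables, taxid: int) -> list[int]:
    """Ascend parent pointers to the root; returns the root-first chain."""
    chain = []
    seen = set()
    cur = taxid
    while True:
        if cur in seen:
            raise TaxonomyError(f"cycle in parent chain at taxid {cur}")
        seen.add(cur)
        if cur not in tables.nodes:
            raise TaxonomyError(f"taxid {cur} missing from nodes table")
        chain.append(cur)
        parent = tables.nodes[cur][0]
        if parent == cur:  # root is its own parent
            break
        cur = parent
    chain.reverse()
    return chain


def build_ncbi_taxonomy(
    tables: TaxdumpTables,
    schema: RankSchema,
    propagate: bool = True,
    rank_aliases: Optional[Mapping[str, str]] = None,
    ambiguous_vocab: Sequence[str] = DEFAULT_AMBIGUOUS_VOCAB,
) -> TaxonomyTable:
    """Build a schema-standardized taxonomy from taxdump tables."""
    aliases = dict(DEFAULT_RANK_ALIASES if rank_aliases is None else rank_aliases)
    unresolvable = []
    entries: dict[str, Lineage] = {}
    for acc, taxid in tables.acc2taxid.items():
        if taxid not in tables.nodes:
            unresolvable.append(acc)
            continue
        chain = _chain_to_root(tables, taxid)
        names, ranks = [], []
        for node in chain:
            rank = tables.nodes[node][1].lower()
            if rank in BELOW_SPECIES_RANKS:
                continue
            names.append(tables.names.get(node, ""))
            ranks.append(aliases.get(rank, rank))
        labels = _project_path(names, ranks, schema, propagate)
        assigned = _project_path(names, ranks, schema, False)
        informative = tuple(
            bool(assigned[i]) and not _is_ambiguous(assigned[i], ambiguous_vocab)
            for i in range(len(schema))
        )
        entries[acc] = Lineage(tuple(labels), informative)
    if unresolvable:
        raise UnresolvableAccessionError(unresolvable)
    return TaxonomyTable(schema, entries)
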