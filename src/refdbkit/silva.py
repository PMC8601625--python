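"""SILVA-style three-file taxonomy import.

SILVA taxonomy releases ship as a triplet: a *taxrank* table (taxid ->
taxonomy path and rank name), a *taxmap* table (sequence accession ->
taxid and NCBI "organism name"), and a *taxtree* Newick file whose node
labels are taxids. This module parses the triplet and projects each
accession's root-to-leaf taxid path onto a fixed rank schema, optionally
forward-filling ranks that the path does not annotate with the last
observed name along the path (so an unmapped sub-phylum fills the empty
class/order/family/genus slots below it), and optionally deriving a
species label from the first two words of the organism name.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from typing import Optional, Sequence

from skbio import TreeNode

from .io import open_maybe_gzip
from .taxonomy import (
    DEFAULT_AMBIGUOUS_VOCAB,
    Lineage,
    RankSchema,
    TaxonomyError,
    TaxonomyTable,
    _is_ambiguous,
)

__all__ = [
    "SilvaTaxFiles",
    "UnresolvableAccessionError",
    "parse_taxtree",
    "read_taxrank",
    "read_taxmap",
    "load_silva_files",
    "build_silva_taxonomy",
    "derive_species_label",
]


class UnresolvableAccessionError(TaxonomyError):
    """Accessions whose taxid cannot be resolved against the tree."""

    def __init__(self, accessions: Sequence[str]):
        self.accessions = list(accessions)
        preview = ", ".join(self.accessions[:5])
        more = "" if len(self.accessions) <= 5 else f" (+{len(self.accessions) - 5} more)"
        super().__init__(f"unresolvable accessions: {preview}{more}")


@dataclass
class SilvaTaxFiles:
    """Parsed contents of a SILVA taxonomy triplet."""

    taxrank: dict[int, tuple[str, str]]  # taxid -> (path text, rank name)
    taxmap: dict[str, tuple[int, str]]  # accession -> (taxid, organism name)
    taxtree: dict[int, list[int]]  # taxid -> root-to-node taxid path


def parse_taxtree(newick_text: str) -> dict[int, list[int]]:
    """Map every taxid-labeled Newick node to its root-to-node taxid path."""
    try:
        tree = TreeNode.read(_stdio.StringIO(newick_text), format="newick")
    except Exception as exc:  # skbio raises its own NewickFormatError
        raise ValueError(f"Newick parse error: {exc}") from exc
    paths: dict[int, list[int]] = {}

    def walk(node, prefix: list[int]) -> None:
        here = prefix
        if node.name is not None and str(node.name).strip():
            taxid = int(str(node.name).strip())
            if taxid in paths:
                raise ValueError(f"duplicate taxid label {taxid} in tree")
            here = prefix + [taxid]
            paths[taxid] = here
        for child in node.children:
            walk(child, here)

    walk(tree, [])
    return paths


def _split_columns(line: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\n").split("\t")]


def read_taxrank(path) -> dict[int, tuple[str, str]]:
    """Read a taxrank TSV: columns (taxonomy path, taxid, rank name)."""
    out: dict[int, tuple[str, str]] = {}
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _split_columns(line)
            if lineno == 1 and cols[0].lower() in {"path", "taxonomy"}:
                continue  # optional header
            if len(cols) < 3:
                raise TaxonomyError(
                    f"{path}: line {lineno}: expected >=3 columns"
                )
            out[int(cols[1])] = (cols[0], cols[2])
    return out


def read_taxmap(path) -> dict[str, tuple[int, str]]:
    """Read a taxmap TSV.

    Accepts the SILVA release layout (primaryAccession, start, stop,
    path, organism name, taxid; feature id = accession.start.stop) or a
    compact 3-column layout (accession, organism name, taxid).
    """
    out: dict[str, tuple[int, str]] = {}
    with open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = _split_columns(line)
            if lineno == 1 and not cols[-1].isdigit():
                continue  # header
            if len(cols) >= 6:
                acc = f"{cols[0]}.{cols[1]}.{cols[2]}"
                out[acc] = (int(cols[5]), cols[4])
            elif len(cols) == 3:
                out[cols[0]] = (int(cols[2]), cols[1])
            else:
                raise TaxonomyError(
                    f"{path}: line {lineno}: expected 3 or >=6 columns"
                )
    return out


def load_silva_files(taxrank_path, taxmap_path, taxtree_path) -> SilvaTaxFiles:
    with open_maybe_gzip(taxtree_path) as fh:
        tree_text = fh.read()
    return SilvaTaxFiles(
        taxrank=read_taxrank(taxrank_path),
        taxmap=read_taxmap(taxmap_path),
        taxtree=parse_taxtree(tree_text),
    )


def derive_species_label(organism_name: str) -> str:
    """First two whitespace-delimited words of the organism name.

    Sub-species detail in organism names ("K-12 MG1655" etc.) degrades
    label consistency, so only the leading binomial is kept. Tokens are
    kept verbatim, including infraspecific markers such as "sp.".
    """
    return " ".join(organism_name.split()[:2])


def _project_path(
    names: Sequence[str],
    ranks: Sequence[str],
    schema: RankSchema,
    propagate: bool,
    n_assignable: Optional[int] = None,
) -> list[str]:
    """Project an ordered ranked path onto schema ranks, forward filling.

    ``names[i]`` / ``ranks[i]`` describe path node *i* from root to leaf.
    Nodes whose rank name matches a schema rank (case-insensitive) are
    assigned to that rank; with *propagate*, an unassigned schema rank
    takes the name of the last path node observed before the next
    assigned rank (the "last observed taxonomic value"). Ranks above the
    first assigned rank stay empty. *n_assignable* caps assignment to the
    first so-many schema ranks (used to reserve a species slot).
    """
    n = len(schema) if n_assignable is None else n_assignable
    rank_index = {schema.names[i].lower(): i for i in range(n)}
    labels = [""] * len(schema)
    assigned_pos: dict[int, int] = {}
    for pos, (name, rank) in enumerate(zip(names, ranks)):
        idx = rank_index.get(rank.lower())
        if idx is not None and idx not in assigned_pos:
            labels[idx] = name
            assigned_pos[idx] = pos
    if propagate and assigned_pos:
        order = sorted(assigned_pos)
        first = order[0]
        for j in range(first + 1, len(schema)):
            if labels[j]:
                continue
            nxt = [r for r in order if r > j]
            if nxt:
                fill_pos = assigned_pos[nxt[0]] - 1
            else:
                fill_pos = len(names) - 1
            if fill_pos >= 0:
                labels[j] = names[fill_pos]
    return labels


def build_silva_taxonomy(
    files: SilvaTaxFiles,
    schema: RankSchema,
    propagate: bool = True,
    include_species: bool = False,
    ambiguous_vocab: Sequence[str] = DEFAULT_AMBIGUOUS_VOCAB,
) -> TaxonomyTable:
    """Build a rank-standardized taxonomy from a SILVA triplet.

    With *include_species*, the schema's last rank must be "species" and
    receives :func:`derive_species_label` of the taxmap organism name;
    tree-path assignment is then restricted to the ranks above it.
    """
    n_assignable = len(schema)
    if include_species:
        if schema.names[-1].lower() != "species":
            raise TaxonomyError(
                "include_species requires a schema ending in a species rank"
            )
        n_assignable -= 1
    unresolvable = []
    entries: dict[str, Lineage] = {}
    for acc, (taxid, organism) in files.taxmap.items():
        path = files.taxtree.get(taxid)
        if path is None:
            unresolvable.append(acc)
            continue
        names, ranks = [], []
        missing = False
        for node in path:
            rec = files.taxrank.get(node)
            if rec is None:
                missing = True
                break
            ptext, rank = rec
            parts = [p for p in ptext.split(";") if p.strip()]
            names.append(parts[-1].strip() if parts else "")
            ranks.append(rank)
        if missing:
            unresolvable.append(acc)
            continue
        labels = _project_path(names, ranks, schema, propagate, n_assignable)
        informative = [False] * len(schema)
        assigned = _project_path(names, ranks, schema, False, n_assignable)
        for i, lab in enumerate(labels):
            informative[i] = bool(assigned[i]) and not _is_ambiguous(
                assigned[i], ambiguous_vocab
            )
        if include_species:
            sp = derive_species_label(organism)
            labels[-1] = sp
            informative[-1] = bool(sp) and not _is_ambiguous(sp, ambiguous_vocab)
        entries[acc] = Lineage(tuple(labels), tuple(informative))
    if unresolvable:
        raise UnresolvableAccessionError(unresolvable)
    return TaxonomyTable(schema, entries)
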