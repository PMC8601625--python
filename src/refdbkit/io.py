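"""Readers and writers for the plain-text formats the toolkit exchanges.

FASTA is read through Biopython and written deterministically at 80
columns; taxonomy tables are two-column TSV ("Feature ID<TAB>Taxon")
with lineage fields joined by "; ". All readers accept gzip-compressed
files transparently. Each CLI run writes a JSON provenance sidecar with
the effective parameters so outputs can be reproduced bit-for-bit.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .curate import SequenceSet
from .taxonomy import (
    DEFAULT_AMBIGUOUS_VOCAB,
    Lineage,
    RankSchema,
    TaxonomyError,
    TaxonomyTable,
    parse_lineage,
)

__all__ = [
    "open_maybe_gzip",
    "read_fasta",
    "write_fasta",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
    "write_provenance",
]

logger = logging.getLogger("refdbkit")

PathLike = Union[str, Path]

_RNA_TABLE = str.maketrans("Uu", "Tt")


def open_maybe_gzip(path: PathLike, mode: str = "rt"):
    """Open a path, transparently decompressing ``.gz`` files."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Identifiers keep the full header line (so descriptions round-trip);
    bases are uppercased and U is normalized to T. An empty file yields
    an empty set with a warning; sequence data before the first header
    is a parse error naming the line.
    """
    with open_maybe_gzip(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}"
                )
            break
    else:
        warnings.warn(f"{path}: empty FASTA file")
        return SequenceSet([])
    records = []
    import io as _io

    for header, seq in SimpleFastaParser(_io.StringIO(text)):
        if seq != seq.upper():
            logger.info("read_fasta: uppercased bases in record %r", header)
        records.append((header, seq.upper().translate(_RNA_TABLE).upper()))
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path: PathLike, wrap: int = 80) -> None:
    """Write FASTA with deterministic line wrapping (default 80 columns)."""
    with open_maybe_gzip(path, "wt") as fh:
        for ident, seq in seqs:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def read_taxonomy_tsv(
    path: PathLike,
    schema: RankSchema,
    ambiguous_vocab: Sequence[str] = DEFAULT_AMBIGUOUS_VOCAB,
    lenient_header: bool = False,
) -> TaxonomyTable:
    """Read a two-column taxonomy TSV into a :class:`TaxonomyTable`.

    The expected header is ``Feature ID<TAB>Taxon``; with
    ``lenient_header=True`` a headerless file is accepted with a warning.
    Duplicate identifiers and rows without exactly two columns are errors.
    """
    entries: dict[str, Lineage] = {}
    with open_maybe_gzip(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines:
        raise TaxonomyError(f"{path}: empty taxonomy file")
    start = 1
    if lines[0].split("\t")[:2] != ["Feature ID", "Taxon"]:
        if not lenient_header:
            raise TaxonomyError(
                f"{path}: expected header 'Feature ID\\tTaxon', got {lines[0]!r}"
            )
        warnings.warn(f"{path}: headerless taxonomy file accepted leniently")
        start = 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise TaxonomyError(
                f"{path}: line {lineno}: expected 2 columns, got {len(cols)}"
            )
        ident, taxon = cols
        if ident in entries:
            raise TaxonomyError(f"{path}: duplicate Feature ID {ident!r}")
        entries[ident] = parse_lineage(taxon, schema, ambiguous_vocab)
    return TaxonomyTable(schema, entries)


def write_taxonomy_tsv(tax: TaxonomyTable, path: PathLike) -> None:
    """Write the taxonomy as a two-column TSV with '; '-joined lineages."""
    with open_maybe_gzip(path, "wt") as fh:
        fh.write("Feature ID\tTaxon\n")
        for ident, lin in tax.entries.items():
            fh.write(f"{ident}\t{lin.to_string(tax.schema)}\n")


def write_provenance(path: PathLike, action: str, params: Mapping) -> None:
    """Write a machine-readable record of an action's effective parameters."""
    payload = {"action": action, "parameters": dict(params)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
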