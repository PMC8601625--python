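"""Seeded synthetic reference-database generator.

Emulates every input the toolkit consumes without any download: a
hierarchical taxonomy of configurable shape, per-species sequence
families at controlled divergence (substitution-only mutations from a
family -> genus -> species ancestor chain, so planted identities are
exact under gap-free alignment), injected quality defects (homopolymer
runs, ambiguous bases, truncated records) and ambiguous species labels.
The generator returns the planted ground truth — true lineages, species
cluster membership, and which records violate which filter — so every
downstream property can be checked without re-deriving it from the
sequences. All randomness flows from a single seeded PRNG stream.

Background sequences are generated with homopolymer runs capped well
below the culling threshold, so the *only* records failing the default
quality filters are the planted ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .curate import SequenceSet
from .silva import SilvaTaxFiles
from .taxonomy import (
    SYNTH_SCHEMA,
    Lineage,
    RankSchema,
    TaxonomyError,
    TaxonomyTable,
)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "generate_reference_db",
    "emit_silva_files",
    "emit_taxdump_files",
    "fungal_silva_example",
    "FUNGAL_EXAMPLE_ACCESSIONS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: longest homopolymer run allowed in background (non-injected) sequence
_MAX_BACKGROUND_RUN = 6
_AMBIGUOUS_SPECIES_LABEL = "uncultured organism"


@dataclass
class FixtureSpec:
    """Shape and noise parameters of a synthetic reference database.

    Divergences are substitution fractions along ancestor branches:
    genus ancestors sit at ``between_genus_divergence / 2`` from their
    family ancestor (so genus pairs differ by about the stated
    fraction), species ancestors at ``between_species_divergence / 2``
    from the genus ancestor, and members at ``1 -
    within_species_identity`` from the species ancestor (their identity
    to the ancestor is exact by construction). Injection fields are
    (magnitude, fraction-of-records) pairs; injected records are chosen
    disjointly so each violates exactly one filter.
    """

    seed: int = 0
    n_phyla: int = 2
    n_classes_per_phylum: int = 1
    n_orders_per_class: int = 1
    n_families_per_order: int = 1
    n_genera_per_family: int = 2
    n_species_per_genus: int = 3
    seqs_per_species: int = 4
    seq_length: Union[int, tuple[int, int]] = 300
    within_species_identity: float = 0.99
    between_species_divergence: float = 0.10
    between_genus_divergence: float = 0.20
    domains: tuple[str, ...] = ("Bacteria",)
    ambiguous_label_fraction: float = 0.0
    homopolymer_injection: tuple[int, float] = (9, 0.0)  # (run length, fraction)
    ambiguous_base_injection: tuple[int, float] = (6, 0.0)  # (n bases, fraction)
    truncation_injection: tuple[int, float] = (0, 0.0)  # (target length, fraction)

    def validate(self) -> None:
        for name in ("within_species_identity",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("between_species_divergence", "between_genus_divergence"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        lo = self.seq_length if isinstance(self.seq_length, int) else self.seq_length[0]
        if lo < 20:
            raise ValueError("sequences shorter than 20 nt are not supported")
        if round(self.between_genus_divergence / 2 * lo) > lo:
            raise ValueError("divergence incompatible with sequence length")


@dataclass
class GroundTruth:
    """Planted truth: lineages, cluster membership, filter violations."""

    taxonomy: TaxonomyTable  # true lineages (pre ambiguous-label masking)
    true_species: dict[str, str]  # record id -> species key
    species_members: dict[str, list[str]]  # species key -> record ids
    violations: dict[str, list[str]] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)  # species key -> seq

    def clean_ids(self) -> list[str]:
        bad = {i for ids in self.violations.values() for i in ids}
        return [i for i in self.true_species if i not in bad]


def _cap_runs(codes: np.ndarray, rng: np.random.Generator,
              max_run: int = _MAX_BACKGROUND_RUN) -> None:
    """Break homopolymer runs longer than *max_run*, in place."""
    n = len(codes)
    run_start = 0
    i = 1
    while i <= n:
        if i == n or codes[i] != codes[run_start]:
            run_len = i - run_start
            if run_len > max_run:
                for pos in range(run_start + max_run, i, max_run + 1):
                    forbidden = {int(codes[pos])}
                    if pos + 1 < n:
                        forbidden.add(int(codes[pos + 1]))
                    if pos - 1 >= 0:
                        forbidden.add(int(codes[pos - 1]))
                    choices = [b for b in range(4) if b not in forbidden]
                    codes[pos] = rng.choice(choices)
            run_start = i
        i += 1


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=length, dtype=np.int64)
    _cap_runs(codes, rng)
    return codes


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute round(rate * L) distinct positions to a different base."""
    out = codes.copy()
    n_sub = int(round(rate * len(codes)))
    if n_sub == 0:
        return out
    pos = rng.choice(len(codes), size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub)
    out[pos] = (out[pos] + shift) % 4
    _cap_runs(out, rng)
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_reference_db(
    spec: FixtureSpec,
) -> tuple[SequenceSet, TaxonomyTable, GroundTruth]:
    """Generate sequences, taxonomy and planted ground truth from a spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    schema = SYNTH_SCHEMA
    records: list[tuple[str, np.ndarray]] = []
    entries: dict[str, Lineage] = {}
    true_entries: dict[str, Lineage] = {}
    true_species: dict[str, str] = {}
    species_members: dict[str, list[str]] = {}
    ancestors: dict[str, str] = {}
    counter = 0
    genus_no = 0
    fam_no = 0
    ord_no = 0
    cls_no = 0
    species_ambiguous: list[str] = []

    for p in range(spec.n_phyla):
        domain = spec.domains[p % len(spec.domains)]
        phylum = f"Phylum{p + 1:02d}"
        for c in range(spec.n_classes_per_phylum):
            cls_no += 1
            klass = f"Class{cls_no:02d}"
            for o in range(spec.n_orders_per_class):
                ord_no += 1
                order = f"Order{ord_no:02d}"
                for f in range(spec.n_families_per_order):
                    fam_no += 1
                    family = f"Family{fam_no:02d}"
                    if isinstance(spec.seq_length, int):
                        length = spec.seq_length
                    else:
                        length = int(rng.integers(spec.seq_length[0],
                                                  spec.seq_length[1] + 1))
                    family_anc = _random_seq(rng, length)
                    for g in range(spec.n_genera_per_family):
                        genus_no += 1
                        genus = f"Genus{genus_no:02d}"
                        genus_anc = _mutate(
                            family_anc, spec.between_genus_divergence / 2, rng
                        )
                        for s in range(spec.n_species_per_genus):
                            species = f"{genus} sp{s + 1}"
                            sp_anc = _mutate(
                                genus_anc,
                                spec.between_species_divergence / 2,
                                rng,
                            )
                            ancestors[species] = _to_str(sp_anc)
                            ambiguous = (
                                rng.random() < spec.ambiguous_label_fraction
                            )
                            labels = (domain, phylum, klass, order, family,
                                      genus, species)
                            emitted_labels = labels
                            mask = (True,) * 7
                            if ambiguous:
                                emitted_labels = labels[:6] + (
                                    _AMBIGUOUS_SPECIES_LABEL,
                                )
                                mask = (True,) * 6 + (False,)
                            species_members[species] = []
                            for m in range(spec.seqs_per_species):
                                counter += 1
                                ident = f"S{counter:05d}"
                                member = _mutate(
                                    sp_anc,
                                    1.0 - spec.within_species_identity,
                                    rng,
                                )
                                records.append((ident, member))
                                entries[ident] = Lineage(emitted_labels, mask)
                                true_entries[ident] = Lineage(labels, (True,) * 7)
                                true_species[ident] = species
                                species_members[species].append(ident)

    violations = _inject_defects(records, spec, rng)
    seqs = SequenceSet([(i, _to_str_with_n(c)) for i, c in records])
    tax = TaxonomyTable(schema, entries)
    truth = GroundTruth(
        taxonomy=TaxonomyTable(schema, true_entries),
        true_species=true_species,
        species_members=species_members,
        violations=violations,
        ancestors=ancestors,
    )
    return seqs, tax, truth


def _inject_defects(
    records: list[tuple[str, np.ndarray]],
    spec: FixtureSpec,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """Plant filter violations into disjoint subsets of records, in place."""
    n = len(records)
    order = rng.permutation(n)
    cursor = 0
    violations: dict[str, list[str]] = {}

    run_len, frac_h = spec.homopolymer_injection
    n_h = int(round(frac_h * n))
    n_count, frac_a = spec.ambiguous_base_injection
    n_a = int(round(frac_a * n))
    trunc_len, frac_t = spec.truncation_injection
    n_t = int(round(frac_t * n))
    if n_h + n_a + n_t > n:
        raise ValueError("injection fractions exceed the record count")

    for _ in range(n_h):
        idx = int(order[cursor]); cursor += 1
        ident, codes = records[idx]
        length = len(codes)
        pos = int(rng.integers(1, length - run_len - 1))
        base = int(rng.integers(0, 4))
        codes[pos : pos + run_len] = base
        flank = [b for b in range(4) if b != base]
        codes[pos - 1] = flank[int(rng.integers(0, 3))]
        codes[pos + run_len] = flank[int(rng.integers(0, 3))]
        violations.setdefault("homopolymer", []).append(ident)

    for _ in range(n_a):
        idx = int(order[cursor]); cursor += 1
        ident, codes = records[idx]
        pos = rng.choice(len(codes), size=n_count, replace=False)
        codes[pos] = -1  # sentinel, rendered as N below
        violations.setdefault("ambiguous_bases", []).append(ident)

    for _ in range(n_t):
        idx = int(order[cursor]); cursor += 1
        ident, codes = records[idx]
        records[idx] = (ident, codes[:trunc_len])
        violations.setdefault("length", []).append(ident)

    return violations


def _to_str_with_n(codes: np.ndarray) -> str:
    # ambiguous-base injections leave a -1 sentinel, rendered as N
    table = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return table[np.where(codes < 0, 4, codes)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# emitters: write a TaxonomyTable back out in the import dialects
# ---------------------------------------------------------------------------


def _lineage_chain(lin: Lineage, names: tuple[str, ...]) -> list[tuple[str, str]]:
    """(label, rank-name) chain up to the deepest non-empty label."""
    depth = 0
    for i, lab in enumerate(lin.labels):
        if lab:
            depth = i + 1
        elif any(lin.labels[i + 1 :]):
            raise TaxonomyError(
                "cannot emit a lineage with an internal empty rank"
            )
    return [(lin.labels[i], names[i]) for i in range(depth)]


def emit_silva_files(
    tax: TaxonomyTable,
    directory,
    insert_intermediate: Optional[str] = None,
) -> dict[str, Path]:
    """Write a SILVA-style triplet (taxrank, taxmap, Newick taxtree).

    If the schema's last rank is species, species labels become the
    taxmap "organism name" and the tree encodes only the ranks above —
    mirroring how SILVA stores species information. With
    *insert_intermediate* (a rank name, e.g. "subphylum"), an unmapped
    intermediate node is inserted below every phylum to exercise
    forward-fill on re-import.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = tax.schema
    has_species = schema.names[-1].lower() == "species"
    tree_rank_names = schema.names[:-1] if has_species else schema.names

    next_id = [2]  # root is taxid 1
    nodes: dict[tuple[str, ...], int] = {}
    children: dict[int, list[int]] = {1: []}
    node_info: dict[int, tuple[str, str, tuple[str, ...]]] = {}

    def get_node(prefix: tuple[str, ...], rank: str, parent: int) -> int:
        if prefix in nodes:
            return nodes[prefix]
        taxid = next_id[0]
        next_id[0] += 1
        nodes[prefix] = taxid
        children[parent].append(taxid)
        children[taxid] = []
        node_info[taxid] = (prefix[-1], rank, prefix)
        return taxid

    taxmap_rows = []
    for ident, lin in tax.entries.items():
        chain = _lineage_chain(lin, schema.names)
        if has_species:
            species_label = lin.labels[-1]
            chain = [cl for cl in chain if cl[1] != schema.names[-1]]
        else:
            species_label = ""
        parent = 1
        prefix: tuple[str, ...] = ()
        phylum_idx = (
            list(tree_rank_names).index("phylum")
            if "phylum" in tree_rank_names
            else None
        )
        for depth, (label, rank) in enumerate(chain):
            prefix = prefix + (label,)
            parent = get_node(prefix, rank, parent)
            if (
                insert_intermediate is not None
                and phylum_idx is not None
                and depth == phylum_idx
            ):
                sub = prefix + (f"{label}Sub",)
                parent = get_node(sub, insert_intermediate, parent)
                prefix = sub
        taxmap_rows.append((ident, species_label, parent))

    taxrank_path = directory / "taxrank.tsv"
    with open(taxrank_path, "w") as fh:
        fh.write("path\ttaxid\trank\n")
        fh.write("Root;\t1\tno rank\n")
        for taxid in sorted(node_info):
            name, rank, prefix = node_info[taxid]
            fh.write(f"{';'.join(prefix)};\t{taxid}\t{rank}\n")

    taxmap_path = directory / "taxmap.tsv"
    with open(taxmap_path, "w") as fh:
        fh.write("accession\torganism_name\ttaxid\n")
        for ident, organism, taxid in taxmap_rows:
            fh.write(f"{ident}\t{organism}\t{taxid}\n")

    def newick(taxid: int) -> str:
        kids = children.get(taxid, [])
        if not kids:
            return str(taxid)
        return "(" + ",".join(newick(c) for c in kids) + ")" + str(taxid)

    taxtree_path = directory / "taxtree.nwk"
    with open(taxtree_path, "w") as fh:
        fh.write(newick(1) + ";\n")
    return {
        "taxrank": taxrank_path,
        "taxmap": taxmap_path,
        "taxtree": taxtree_path,
    }


def emit_taxdump_files(
    tax: TaxonomyTable, directory, dialect: str = "taxdump"
) -> dict[str, Path]:
    """Write taxdump-style nodes/names/acc2taxid tables for a taxonomy.

    The top rank is written as "superkingdom" (NCBI's historical name for
    the domain/kingdom level) so re-import exercises the rank alias map.
    """
    if dialect not in ("taxdump", "tsv"):
        raise ValueError("dialect must be 'taxdump' or 'tsv'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = tax.schema
    rank_out = ["superkingdom"] + list(schema.names[1:])

    next_id = [2]
    nodes: dict[tuple[str, ...], int] = {}
    node_rows: list[tuple[int, int, str]] = [(1, 1, "no rank")]
    name_rows: list[tuple[int, str]] = [(1, "root")]
    acc_rows: list[tuple[str, int]] = []

    for ident, lin in tax.entries.items():
        chain = _lineage_chain(lin, schema.names)
        parent = 1
        prefix: tuple[str, ...] = ()
        for depth, (label, rank) in enumerate(chain):
            prefix = prefix + (label,)
            if prefix not in nodes:
                taxid = next_id[0]
                next_id[0] += 1
                nodes[prefix] = taxid
                node_rows.append((taxid, parent, rank_out[depth]))
                name_rows.append((taxid, label))
            parent = nodes[prefix]
        acc_rows.append((ident, parent))

    if dialect == "taxdump":
        sep, eol = "\t|\t", "\t|\n"
    else:
        sep, eol = "\t", "\n"
    nodes_path = directory / "nodes.dmp"
    with open(nodes_path, "w") as fh:
        for taxid, parent, rank in node_rows:
            fh.write(f"{taxid}{sep}{parent}{sep}{rank}{eol}")
    names_path = directory / "names.dmp"
    with open(names_path, "w") as fh:
        for taxid, name in name_rows:
            fh.write(f"{taxid}{sep}{name}{sep}{sep}scientific name{eol}")
    acc_path = directory / "acc2taxid.tsv"
    with open(acc_path, "w") as fh:
        fh.write("accession\ttaxid\n")
        for acc, taxid in acc_rows:
            fh.write(f"{acc}\t{taxid}\n")
    return {"nodes": nodes_path, "names": names_path, "acc2taxid": acc_path}


#: Accessions of the miniature fungal SILVA example (two Ascomycota
#: records whose sub-phylum annotation is unmapped in a six/seven-rank
#: schema, so forward fill propagates it into the empty lower ranks).
FUNGAL_EXAMPLE_ACCESSIONS = ("Z27393.1.1722", "AB671439.1.2071")


def fungal_silva_example() -> SilvaTaxFiles:
    """In-memory SILVA triplet for the classic sub-phylum forward-fill case.

    Two fungal records are annotated domain -> kingdom -> phylum plus an
    unmapped sub-phylum (Taphrinomycotina / Pezizomycotina); importing
    with rank propagation fills class through genus with the sub-phylum
    name, without propagation those ranks stay empty.
    """
    from .silva import parse_taxtree

    taxrank = {
        2: ("Eukaryota;", "domain"),
        3: ("Eukaryota;Fungi;", "kingdom"),
        4: ("Eukaryota;Fungi;Ascomycota;", "phylum"),
        5: ("Eukaryota;Fungi;Ascomycota;Taphrinomycotina;", "subphylum"),
        6: ("Eukaryota;Fungi;Ascomycota;Pezizomycotina;", "subphylum"),
    }
    taxmap = {
        FUNGAL_EXAMPLE_ACCESSIONS[0]: (5, "Saitoella complicata"),
        FUNGAL_EXAMPLE_ACCESSIONS[1]: (6, "Trichoderma aggressivum"),
    }
    taxtree = parse_taxtree("(((5,6)4)3)2;")
    return SilvaTaxFiles(taxrank=taxrank, taxmap=taxmap, taxtree=taxtree)
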