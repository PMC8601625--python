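"""Dereplication and greedy percent-identity clustering of sequences.

Dereplication collapses identical sequence strings, reconciling their
taxonomies either by keeping one record per distinct (sequence, lineage)
pair ("uniq") or by assigning a consensus lineage (LCA / majority /
super). Clustering is greedy and centroid-based: records are processed
in decreasing length order and join the first centroid whose pairwise
identity meets the threshold, emulating the classic OTU-picking
strategy. Pairwise identity is computed from a global alignment with
free terminal gaps (matches / alignment columns, terminal gap columns
excluded) — the cited clustering tool's default notion of identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio import Align

from .curate import SequenceSet
from .taxonomy import Lineage, TaxonomyError, TaxonomyTable, consensus_lineage

__all__ = [
    "ClusterResult",
    "pairwise_identity",
    "dereplicate",
    "cluster_greedy",
]

_DEREP_MODES = ("uniq", "lca", "majority", "super")


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Fraction of matching columns in a global alignment of *a* and *b*.

    Terminal gap columns are excluded from the denominator; if nothing
    aligns (fully staggered optimum), the identity is 0. Symmetric, in
    [0, 1], and exactly 1.0 for identical strings.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:
        return 1.0
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    start, end = 0, len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if s1[i] == s2[i])
    return matches / cols


@dataclass
class ClusterResult:
    """Greedy clustering output: ordered clusters plus consensus lineages."""

    clusters: list[tuple[str, list[str]]]  # (centroid id, member ids)
    perc_identity: float
    consensus: dict[str, Lineage] = field(default_factory=dict)
    identities: dict[str, float] = field(default_factory=dict)  # member -> identity to centroid
    _consensus_table: Optional[TaxonomyTable] = None

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        return {m: c for c, members in self.clusters for m in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"centroid": c, "member": m, "identity": self.identities.get(m, 1.0)}
            for c, members in self.clusters
            for m in members
        ]
        return pd.DataFrame(rows, columns=["centroid", "member", "identity"])

    def representatives(
        self, seqs: SequenceSet
    ) -> tuple[SequenceSet, TaxonomyTable]:
        """Centroid sequences with their consensus taxonomy."""
        reps = seqs.subset([c for c, _ in self.clusters])
        order = {c: i for i, (c, _) in enumerate(self.clusters)}
        reps = SequenceSet(sorted(reps.records, key=lambda r: order[r[0]]))
        return reps, self._consensus_table


def _require_taxonomy(seqs: SequenceSet, tax: TaxonomyTable) -> None:
    missing = [i for i in seqs.ids if i not in tax]
    if missing:
        raise TaxonomyError(
            f"records without taxonomy entries: {missing[:5]!r}"
            + ("" if len(missing) <= 5 else f" (+{len(missing) - 5} more)")
        )


def dereplicate(
    seqs: SequenceSet,
    tax: TaxonomyTable,
    mode: str = "uniq",
) -> tuple[SequenceSet, TaxonomyTable]:
    """Collapse identical sequence strings.

    ``uniq`` keeps one record per distinct (sequence, lineage) pair, so
    identical sequences with conflicting labels all survive; the
    consensus modes (``lca``/``majority``/``super``) keep one record per
    distinct sequence, labeled with the consensus of its members'
    lineages. The retained identifier is the first-seen member's.
    """
    if mode not in _DEREP_MODES:
        raise ValueError(f"unknown dereplication mode {mode!r}")
    _require_taxonomy(seqs, tax)
    groups: dict[str, list[str]] = {}
    for ident, seq in seqs:
        groups.setdefault(seq, []).append(ident)
    out_records: list[tuple[str, str]] = []
    out_tax: dict[str, Lineage] = {}
    for seq, members in groups.items():
        if mode == "uniq":
            seen: dict[tuple, str] = {}
            for m in members:
                key = tax[m].labels
                if key not in seen:
                    seen[key] = m
                    out_records.append((m, seq))
                    out_tax[m] = tax[m]
        else:
            keeper = members[0]
            out_records.append((keeper, seq))
            out_tax[keeper] = consensus_lineage([tax[m] for m in members], mode)
    return SequenceSet(out_records), TaxonomyTable(tax.schema, out_tax)


def _shared_kmers(a: str, b: str, k: int) -> bool:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in ka for i in range(len(b) - k + 1))


def cluster_greedy(
    seqs: SequenceSet,
    tax: TaxonomyTable,
    perc_identity: float,
    mode: str = "lca",
    prescreen_k: Optional[int] = None,
) -> ClusterResult:
    """Greedy centroid clustering at a percent-identity threshold.

    Records are processed in decreasing length order (ties broken by
    identifier); each joins the first existing centroid — in centroid
    creation order — with pairwise identity >= *perc_identity*, else
    founds a new centroid. Per-cluster consensus lineages are computed
    with :func:`consensus_lineage`. *prescreen_k* optionally skips
    alignments against centroids sharing no k-mer with the record (a
    speed device that does not change results at desk scale).
    """
    if not 0 < perc_identity <= 1:
        raise ValueError("perc_identity must be in (0, 1]")
    if mode not in ("lca", "majority", "super"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    _require_taxonomy(seqs, tax)
    order = sorted(seqs.records, key=lambda r: (-len(r[1]), r[0]))
    centroids: list[tuple[str, str]] = []
    members: list[list[str]] = []
    identities: dict[str, float] = {}
    for ident, seq in order:
        placed = False
        for ci, (cid, cseq) in enumerate(centroids):
            if prescreen_k is not None and not _shared_kmers(seq, cseq, prescreen_k):
                continue
            ident_frac = pairwise_identity(seq, cseq)
            if ident_frac >= perc_identity:
                members[ci].append(ident)
                identities[ident] = ident_frac
                placed = True
                break
        if not placed:
            centroids.append((ident, seq))
            members.append([ident])
            identities[ident] = 1.0
    clusters = [(cid, mem) for (cid, _), mem in zip(centroids, members)]
    consensus = {
        cid: consensus_lineage([tax[m] for m in mem], mode)
        for cid, mem in clusters
    }
    result = ClusterResult(clusters, perc_identity, consensus, identities)
    result._consensus_table = TaxonomyTable(tax.schema, dict(consensus))
    return result
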