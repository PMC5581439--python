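"""Marker-gene (rpS3) community abundance estimation.

Ribosomal protein S3 is a universal single-copy gene, so its per-sample
coverage is a proxy for the relative abundance of the organism carrying
it.  The pipeline stage implemented here mirrors common practice in
genome-resolved metagenomics:

1. cluster marker protein sequences at 99% identity (greedy,
   centroid-based, USEARCH-like);
2. take per-cluster read coverage (computed upstream) as abundance and
   normalise to percentages;
3. assign taxonomy per cluster from the best blastp hit against a
   labelled reference database, at an E-value cutoff of 1e-15.

Pairwise identity uses a global alignment with free terminal gaps
(match +2, mismatch -1, gap -2); identity is matches over aligned
columns, excluding terminal-gap columns by default (USEARCH-like), with
the full-column denominator available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .io_formats import BlastHit, SeqRecord

#: blastp E-value cutoff for taxonomy assignment.
DEFAULT_TAXONOMY_EVALUE = 1e-15

#: Identity threshold for marker-sequence clustering.
DEFAULT_CLUSTER_IDENTITY = 0.99

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ClusterSet:
    """A partition of sequences into centroid-labelled clusters."""

    clusters: tuple[tuple[str, frozenset[str]], ...]  # (centroid_id, members)
    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must lie in (0, 1]")
        seen: set[str] = set()
        for centroid, members in self.clusters:
            if centroid not in members:
                raise ValueError(f"centroid {centroid!r} not among its members")
            if seen & members:
                raise ValueError("clusters are not disjoint")
            seen |= members

    @property
    def centroid_ids(self) -> list[str]:
        return [c for c, _ in self.clusters]

    def membership(self) -> dict[str, str]:
        """sequence id -> centroid id."""
        out: dict[str, str] = {}
        for centroid, members in self.clusters:
            for m in members:
                out[m] = centroid
        return out

    def as_partition(self) -> set[frozenset[str]]:
        return {members for _, members in self.clusters}


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_internal_gap_score = -2
    aligner.extend_internal_gap_score = -2
    aligner.end_gap_score = 0  # free terminal gaps
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(
    a: SeqRecord, b: SeqRecord, *, include_terminal_gaps: bool = False
) -> float:
    """Fractional identity of two sequences under global alignment.

    The alignment is global with free terminal gaps.  Identity is the
    number of identical columns over the aligned columns, excluding
    terminal-gap columns from the denominator unless
    ``include_terminal_gaps`` is set.  Because free end gaps let the
    optimal alignment of two unrelated sequences collapse to a tiny
    overlap (which would then score as near-100% identical), the
    denominator is floored at the shorter sequence's length — a
    degenerate overlap therefore reports low, not high, identity.
    Symmetric by construction (the input pair is ordered canonically
    before aligning).
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    # canonical order makes identity(a, b) == identity(b, a) exactly
    first, second = sorted((a, b), key=lambda r: (-len(r.residues), r.id))
    aln = _ALIGNER.align(first.residues, second.residues)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    n_cols = len(s1)
    start, end = 0, n_cols
    if not include_terminal_gaps:
        while start < n_cols and (s1[start] == "-" or s2[start] == "-"):
            start += 1
        while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
            end -= 1
    if end <= start:
        return 0.0
    matches = sum(
        1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-"
    )
    shorter = min(len(a.residues), len(b.residues))
    denom = max(end - start, shorter) if not include_terminal_gaps else n_cols
    return matches / denom


def greedy_cluster(
    seqs: Sequence[SeqRecord],
    threshold: float = DEFAULT_CLUSTER_IDENTITY,
    *,
    include_terminal_gaps: bool = False,
) -> ClusterSet:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed by decreasing length (ties broken by id);
    each joins the first existing centroid, in founding order, whose
    identity to it is at least the threshold, otherwise it founds a new
    cluster.  Deterministic for a given input set.
    """
    if not seqs:
        raise ValueError("need at least one sequence to cluster")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("sequence ids must be unique")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    centroids: list[SeqRecord] = []
    members: list[set[str]] = []
    for seq in ordered:
        for i, centroid in enumerate(centroids):
            ident = pairwise_identity(
                seq, centroid, include_terminal_gaps=include_terminal_gaps
            )
            if ident >= threshold:
                members[i].add(seq.id)
                break
        else:
            centroids.append(seq)
            members.append({seq.id})
    clusters = tuple(
        (c.id, frozenset(m)) for c, m in zip(centroids, members)
    )
    return ClusterSet(clusters=clusters, threshold=threshold)


def assign_taxonomy(
    hits: Iterable[BlastHit],
    subject_taxa: Mapping[str, str],
    evalue_cutoff: float = DEFAULT_TAXONOMY_EVALUE,
) -> dict[str, str]:
    """Best-hit taxonomy per query from blastp results.

    For each query, the taxon of the qualifying hit (E-value <= cutoff)
    with the lowest E-value; ties broken by higher bit score, then
    lexicographic subject id.  Queries with no qualifying hit map to
    ``"unassigned"``.  Every qualifying subject must appear in the
    subject -> taxon map.
    """
    all_hits = list(hits)
    best: dict[str, BlastHit] = {}
    for hit in all_hits:
        if hit.evalue > evalue_cutoff:
            continue
        if hit.subject_id not in subject_taxa:
            raise KeyError(
                f"subject {hit.subject_id!r} missing from the taxon map"
            )
        cur = best.setdefault(hit.query_id, hit)
        if (hit.evalue, -hit.bitscore, hit.subject_id) < (
            cur.evalue,
            -cur.bitscore,
            cur.subject_id,
        ):
            best[hit.query_id] = hit
    return {
        q: (subject_taxa[best[q].subject_id] if q in best else UNASSIGNED)
        for q in {h.query_id for h in all_hits}
    }


def relative_abundance(
    coverages: Mapping[str, float],
    taxa: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage-weighted relative abundance per cluster and per taxon.

    Returns ``(per_cluster, per_taxon)``.  ``per_cluster`` is indexed by
    cluster id with columns ``coverage``, ``taxon``, ``rel_abundance``
    (percent, summing to 100); ``per_taxon`` sums member clusters.
    Clusters without a taxon assignment fall under ``"unassigned"``.
    """
    if not coverages:
        raise ValueError("no coverage values provided")
    for cid, cov in coverages.items():
        if cov < 0:
            raise ValueError(f"negative coverage for cluster {cid!r}")
    total = float(sum(coverages.values()))
    if total == 0:
        raise ValueError("total coverage is zero; abundances undefined")
    taxa = taxa or {}
    ids = sorted(coverages)
    per_cluster = pd.DataFrame(
        {
            "coverage": [float(coverages[c]) for c in ids],
            "taxon": [taxa.get(c, UNASSIGNED) for c in ids],
        },
        index=pd.Index(ids, name="cluster_id"),
    )
    per_cluster["rel_abundance"] = 100.0 * per_cluster["coverage"] / total
    per_taxon = (
        per_cluster.groupby("taxon")[["coverage", "rel_abundance"]]
        .sum()
        .sort_index()
    )
    return per_cluster, per_taxon
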