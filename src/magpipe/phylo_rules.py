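"""Alignment trimming/concatenation, monophyly testing and the
novel-phylum decision rule.

Candidate new phyla among metagenome-assembled genomes are screened with
two lines of evidence: (1) the 16S rRNA gene's maximum identity to any
previously described sequence, and (2) whether the candidate genomes
form a monophyletic clade in a concatenated ribosomal-protein tree.  A
new phylum is proposed when at least two genomes are monophyletic and
the 16S identity falls below 75%; for a very obvious, well-supported
clade (a user-asserted flag, since no quantitative criterion exists),
identities up to roughly 80% are tolerated.

Supporting operations: trimming alignment columns that are unaligned
ends or >95% gaps, concatenating per-gene alignments (the 16-protein
ribosomal set) with all-gap filling for missing genes, and a bipartition
monophyly test on unrooted trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PhyloTree, SeqRecord
from .marker_abundance import pairwise_identity

#: Interior columns with a gap fraction strictly above this are removed.
DEFAULT_INTERIOR_GAP = 0.95
#: End columns are peeled while their gap fraction exceeds this.
DEFAULT_END_GAP = 0.5
#: A genome must be present in at least this fraction of gene alignments.
DEFAULT_MIN_GENE_FRACTION = 0.5
#: 16S identity below this always qualifies toward a new phylum.
STRICT_IDENTITY_CUTOFF = 0.75
#: Identity tolerated when the clade is asserted to be very obvious.
RELAXED_IDENTITY_CUTOFF = 0.80


@dataclass(frozen=True)
class Msa:
    """A rectangular gapped alignment of uniquely-named sequences."""

    records: tuple[SeqRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one sequence")
        widths = {len(r.residues) for r in self.records}
        if len(widths) != 1:
            raise ValueError(f"alignment is not rectangular (widths {sorted(widths)})")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("alignment sequence ids must be unique")

    @property
    def width(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def to_array(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])


@dataclass(frozen=True)
class PhylumProposal:
    """Outcome of the novel-phylum decision rule for one candidate."""

    candidate_tips: frozenset[str]
    max_identity: float
    n_genomes: int
    monophyletic: bool
    strong_clade: bool
    decision: str  # propose | reject
    reason: str


def column_gap_fraction(msa: Msa) -> np.ndarray:
    """Fraction of gap characters ('-') per alignment column."""
    return (msa.to_array() == "-").mean(axis=0)


def trim_alignment(
    msa: Msa,
    interior_gap_threshold: float = DEFAULT_INTERIOR_GAP,
    end_gap_threshold: float = DEFAULT_END_GAP,
) -> Msa:
    """Remove unaligned ends and gap-dominated interior columns.

    First, columns are peeled from each end while their gap fraction
    exceeds ``end_gap_threshold`` (operationalising "unaligned ends");
    then any remaining column whose gap fraction exceeds
    ``interior_gap_threshold`` is dropped.  Row order is preserved.
    Idempotent.  Raises if no column survives.
    """
    gaps = column_gap_fraction(msa)
    n = len(gaps)
    start, end = 0, n
    while start < end and gaps[start] > end_gap_threshold:
        start += 1
    while end > start and gaps[end - 1] > end_gap_threshold:
        end -= 1
    keep = [
        i for i in range(start, end) if gaps[i] <= interior_gap_threshold
    ]
    if not keep:
        raise ValueError("trimming removed every alignment column")
    arr = msa.to_array()[:, keep]
    records = tuple(
        SeqRecord(id=r.id, residues="".join(row), description=r.description)
        for r, row in zip(msa.records, arr)
    )
    return Msa(records)


def concat_alignments(
    per_gene: Mapping[str, Msa],
    min_gene_fraction: float = DEFAULT_MIN_GENE_FRACTION,
) -> Msa:
    """Concatenate per-gene alignments into one supermatrix.

    Record ids are genome ids.  Genomes present in at least
    ``min_gene_fraction`` of the genes are retained; a genome's missing
    genes are filled with all-gap blocks of that gene's width.  Gene
    blocks appear in the mapping's order; total width is the sum of
    gene widths.
    """
    if not per_gene:
        raise ValueError("no gene alignments given")
    genes = list(per_gene)
    n_genes = len(genes)
    presence: dict[str, int] = {}
    for msa in per_gene.values():
        for gid in msa.ids:
            presence[gid] = presence.get(gid, 0) + 1
    kept = [g for g, k in sorted(presence.items()) if k / n_genes >= min_gene_fraction]
    if not kept:
        raise ValueError(
            f"no genome is present in >= {min_gene_fraction:.0%} of genes"
        )
    rows = {g: [] for g in kept}
    for gene in genes:
        msa = per_gene[gene]
        by_id = {r.id: r.residues for r in msa.records}
        blank = "-" * msa.width
        for g in kept:
            rows[g].append(by_id.get(g, blank))
    records = tuple(
        SeqRecord(id=g, residues="".join(rows[g])) for g in kept
    )
    return Msa(records)


def max_identity_to_reference(
    query: SeqRecord, refs: Sequence[SeqRecord]
) -> tuple[float, str]:
    """Highest pairwise identity of a query against a reference set.

    Returns ``(max_identity, best_ref_id)``; ties resolved to the
    lexicographically smallest reference id.
    """
    if not refs:
        raise ValueError("reference set is empty")
    best_id: str | None = None
    best = -1.0
    for ref in sorted(refs, key=lambda r: r.id):
        ident = pairwise_identity(query, ref)
        if ident > best:
            best, best_id = ident, ref.id
    return best, best_id


def is_monophyletic(
    tree: PhyloTree, tipset: Iterable[str], rooted: bool | None = None
) -> bool:
    """Whether a set of tips forms a clade.

    On unrooted trees the test is bipartition-based: true iff removing
    some edge splits the tips into exactly (tipset, complement).  On
    rooted trees, true iff some node's descendant tips equal the set.
    When ``rooted`` is None, a basal bifurcation is treated as a root.
    Singleton sets and the full tip set are trivially monophyletic.
    """
    target = frozenset(tipset)
    if not target:
        raise ValueError("tipset must be non-empty")
    all_tips = frozenset(t.name for t in tree.tips())
    unknown = target - all_tips
    if unknown:
        raise KeyError(
            f"tips not in tree: {', '.join(sorted(unknown))}"
        )
    if rooted is None:
        rooted = len(tree.children) == 2
    if len(target) == 1 or target == all_tips:
        return True
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            clade = frozenset([node.name])
        else:
            clade = frozenset(t.name for t in node.tips())
        if clade == target:
            return True
        if not rooted and clade == all_tips - target:
            return True
    return False


def propose_phylum(
    max_identity: float,
    n_genomes: int,
    monophyletic: bool,
    strong_clade: bool = False,
    strict_cutoff: float = STRICT_IDENTITY_CUTOFF,
    relaxed_cutoff: float = RELAXED_IDENTITY_CUTOFF,
    candidate_tips: Iterable[str] = (),
) -> PhylumProposal:
    """Apply the novel-phylum decision rule.

    Propose iff the candidates are monophyletic, number at least two,
    and the best 16S identity to described sequences is below the
    strict cutoff — or at most the relaxed cutoff when the clade is
    asserted to be very obvious (``strong_clade``).
    """
    if not (0.0 <= max_identity <= 1.0):
        raise ValueError("max_identity must lie in [0, 1]")
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    reasons: list[str] = []
    if not monophyletic:
        reasons.append("candidates are not monophyletic")
    if n_genomes < 2:
        reasons.append("fewer than two genomes")
    identity_ok = False
    if max_identity < strict_cutoff:
        identity_ok = True
        identity_reason = (
            f"max identity {max_identity:.3f} < {strict_cutoff:.2f}"
        )
    elif strong_clade and max_identity <= relaxed_cutoff:
        identity_ok = True
        identity_reason = (
            f"max identity {max_identity:.3f} <= {relaxed_cutoff:.2f} "
            "tolerated for a very obvious clade"
        )
    else:
        reasons.append(
            f"max identity {max_identity:.3f} exceeds the "
            f"{strict_cutoff:.2f} cutoff"
            + ("" if strong_clade else " (no strong-clade assertion)")
        )
    if not reasons and identity_ok:
        decision, reason = "propose", identity_reason
    else:
        decision, reason = "reject", "; ".join(reasons)
    return PhylumProposal(
        candidate_tips=frozenset(candidate_tips),
        max_identity=max_identity,
        n_genomes=n_genomes,
        monophyletic=monophyletic,
        strong_clade=strong_clade,
        decision=decision,
        reason=reason,
    )
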