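"""Genome-bin quality scoring from single-copy marker genes.

Completeness of a metagenome-assembled genome (MAG) is estimated as the
fraction of a conserved single-copy bacterial marker set found in the
bin; contamination ("misbin") as the fraction of those markers present
in more than one copy, since a correctly binned genome should carry each
exactly once.  Bins are assigned quality tiers:

* ``rejected``       — completeness <= 50% or misbin >= 10%;
* ``incomplete``     — completeness in [50%, 90%);
* ``near_complete``  — completeness >= 90% (and misbin < 10%).

The default marker set is the 31-gene conserved bacterial set popularised
by AMPHORA2; the HMM models themselves are not bundled — hit tables
(HMMER3 tblout) are inputs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import HmmHit

#: The 31 conserved single-copy bacterial marker genes (AMPHORA2 set).
AMPHORA2_BACTERIAL_MARKERS = (
    "dnaG", "frr", "infC", "nusA", "pgk", "pyrG",
    "rplA", "rplB", "rplC", "rplD", "rplE", "rplF",
    "rplK", "rplL", "rplM", "rplN", "rplP", "rplS", "rplT",
    "rpmA", "rpoB",
    "rpsB", "rpsC", "rpsE", "rpsI", "rpsJ", "rpsK", "rpsM", "rpsS",
    "smpB", "tsf",
)

#: hmmsearch reporting threshold used for marker hits (-E 0.00001).
DEFAULT_MARKER_EVALUE = 1e-5

COMPLETENESS_MIN = 0.50   # bins at or below are rejected
MISBIN_MAX = 0.10         # bins at or above are rejected
NEAR_COMPLETE_MIN = 0.90  # completeness at or above -> near_complete


@dataclass(frozen=True)
class MarkerSet:
    """A named set of single-copy marker gene identifiers."""

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker set must contain at least one marker")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker ids must be unique")

    def __len__(self) -> int:
        return len(self.markers)


DEFAULT_MARKER_SET = MarkerSet("amphora2_bacteria", AMPHORA2_BACTERIAL_MARKERS)


@dataclass
class MarkerHitTable:
    """Per-bin copy counts over a marker set."""

    bin_id: str
    copy_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, count in self.copy_counts.items():
            if count < 0:
                raise ValueError(f"{self.bin_id}: negative count for {marker}")


@dataclass(frozen=True)
class BinQcResult:
    bin_id: str
    completeness: float
    misbin: float
    tier: str  # rejected | incomplete | near_complete


def tabulate_markers(
    hits: Iterable[HmmHit],
    marker_set: MarkerSet = DEFAULT_MARKER_SET,
    evalue_cutoff: float = DEFAULT_MARKER_EVALUE,
    bin_id: str = "bin",
) -> MarkerHitTable:
    """Count marker copies in a bin from HMM hits.

    Hits to models outside the marker set are ignored, as are hits above
    the E-value cutoff.  Each ORF contributes to exactly one marker: the
    model of its best retained hit (lowest E-value, ties broken by
    higher bit score then lexicographic model name).
    """
    marker_names = set(marker_set.markers)
    best: dict[str, HmmHit] = {}
    for hit in hits:
        if hit.model_name not in marker_names or hit.full_evalue > evalue_cutoff:
            continue
        cur = best.get(hit.target_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.target_id] = hit
    counts: dict[str, int] = {m: 0 for m in marker_set.markers}
    for hit in best.values():
        counts[hit.model_name] += 1
    return MarkerHitTable(bin_id=bin_id, copy_counts=counts)


def _hit_rank(hit: HmmHit) -> tuple:
    return (hit.full_evalue, -hit.full_bitscore, hit.model_name)


def score_bin(
    table: MarkerHitTable, marker_set: MarkerSet = DEFAULT_MARKER_SET
) -> BinQcResult:
    """Score completeness and misbin for a bin and assign its tier.

    completeness = fraction of markers with >= 1 copy;
    misbin = fraction of markers with >= 2 copies.
    """
    unknown = set(table.copy_counts) - set(marker_set.markers)
    if unknown:
        raise ValueError(
            f"{table.bin_id}: counts for markers outside the set: "
            f"{', '.join(sorted(unknown))}"
        )
    n = len(marker_set)
    present = sum(1 for m in marker_set.markers if table.copy_counts.get(m, 0) >= 1)
    multi = sum(1 for m in marker_set.markers if table.copy_counts.get(m, 0) >= 2)
    completeness = present / n
    misbin = multi / n
    return BinQcResult(
        bin_id=table.bin_id,
        completeness=completeness,
        misbin=misbin,
        tier=classify_bin(completeness, misbin),
    )


def classify_bin(completeness: float, misbin: float) -> str:
    """Assign the QC tier for a (completeness, misbin) pair.

    Boundary convention: completeness exactly 0.50 is rejected, misbin
    exactly 0.10 is rejected, completeness exactly 0.90 is near-complete
    (tiers are the half-open intervals [0.50, 0.90) and [0.90, 1]).
    """
    if not (0.0 <= completeness <= 1.0 and 0.0 <= misbin <= 1.0):
        raise ValueError("completeness and misbin must lie in [0, 1]")
    if completeness <= COMPLETENESS_MIN or misbin >= MISBIN_MAX:
        return "rejected"
    if completeness >= NEAR_COMPLETE_MIN:
        return "near_complete"
    return "incomplete"
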