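"""Glycoside-hydrolase (GH) family profiling from dbCAN-style HMM hits.

Carbohydrate-active enzyme annotation (dbCAN) produces HMMER hits of
predicted ORFs against CAZy family models.  This module resolves each
ORF to a single family (lowest E-value wins, matching dbCAN practice),
builds a genome x GH-family count matrix over a fixed family universe
(default: GH1-GH135), and provides presence/absence and taxon-collapsed
views for community-level comparison.

Hits to non-GH CAZyme classes (GT, PL, CE, CBM, AA) are dropped with a
logged count; the GH family universe and the substrate-class annotation
used for reporting are shipped as editable text tables.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import HmmHit

logger = logging.getLogger("magpipe")

#: dbCAN hmmsearch reporting threshold (-E 0.00001).
DEFAULT_GH_EVALUE = 1e-5


def _load_data_lines(name: str) -> list[str]:
    text = resources.files("magpipe.data").joinpath(name).read_text("utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def default_family_universe() -> tuple[str, ...]:
    """The default GH family universe (135 families, GH1-GH135)."""
    return tuple(_load_data_lines("gh_families_default.txt"))


def load_substrate_classes() -> dict[str, str]:
    """GH family -> substrate class (cellulolytic/starch/chitin/other).

    A reporting aid only; edit the shipped table to change groupings.
    """
    out: dict[str, str] = {}
    for line in _load_data_lines("gh_substrate_classes.tsv"):
        fam, cls = line.split("\t")
        out[fam] = cls
    return out


def resolve_best_family(
    hits: Iterable[HmmHit], evalue_cutoff: float = DEFAULT_GH_EVALUE
) -> dict[str, str]:
    """Resolve each ORF to the family of its lowest-E-value hit.

    Ties are broken by higher bit score, then lexicographic family name.
    ORFs with no hit at or below the cutoff are omitted.
    """
    best: dict[str, HmmHit] = {}
    for hit in hits:
        if hit.full_evalue > evalue_cutoff:
            continue
        cur = best.get(hit.target_id)
        if cur is None or (
            hit.full_evalue, -hit.full_bitscore, hit.model_name
        ) < (cur.full_evalue, -cur.full_bitscore, cur.model_name):
            best[hit.target_id] = hit
    return {orf: h.model_name for orf, h in best.items()}


def build_profile(
    assignments: Mapping[str, Mapping[str, str]],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genome x GH-family count matrix from per-ORF family assignments.

    ``assignments`` maps genome id -> (ORF id -> family).  Families
    outside the universe (including non-GH CAZyme classes) are dropped;
    the number dropped is logged.  All universe columns are present and
    zero-filled.
    """
    fams = tuple(universe) if universe is not None else default_family_universe()
    if len(set(fams)) != len(fams):
        raise ValueError("family universe contains duplicates")
    genomes = sorted(assignments)
    profile = pd.DataFrame(
        0, index=pd.Index(genomes, name="genome"), columns=list(fams), dtype=int
    )
    fam_set = set(fams)
    dropped = 0
    for genome, orf_map in assignments.items():
        for family in orf_map.values():
            if family in fam_set:
                profile.loc[genome, family] += 1
            else:
                dropped += 1
    if dropped:
        logger.info(
            "build_profile: dropped %d ORF assignments outside the "
            "%d-family universe", dropped, len(fams)
        )
    return profile


def presence_absence(profile: pd.DataFrame) -> pd.DataFrame:
    """Binary view of a count profile (1 where count >= 1)."""
    if (profile.values < 0).any():
        raise ValueError("profile contains negative counts")
    return (profile >= 1).astype(int)


def collapse_by_taxon(
    profile: pd.DataFrame, genome_taxa: Mapping[str, str]
) -> pd.DataFrame:
    """Sum profile rows over genomes of the same taxon.

    Every genome in the profile must be mapped; total counts are
    conserved.
    """
    missing = [g for g in profile.index if g not in genome_taxa]
    if missing:
        raise KeyError(
            f"genomes missing from the taxon map: {', '.join(map(str, missing))}"
        )
    taxa = pd.Series({g: genome_taxa[g] for g in profile.index}, name="taxon")
    collapsed = profile.groupby(taxa).sum().sort_index()
    collapsed.index.name = "taxon"
    return collapsed
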