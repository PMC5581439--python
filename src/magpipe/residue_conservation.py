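"""Conserved functional-residue checking in protein alignments.

Putative function calls from metagenome bins (e.g. a copper nitrite
reductase, NirK) are strengthened by showing that the catalytic and
metal-ligand residues of well-characterised references are conserved in
the query sequences.  Given an alignment containing the reference, a
set of annotated reference positions (e.g. the type 1 Cu ligands
2x His/Cys/Met and the type 2 Cu ligands 3x His of NirK) is mapped
through the reference's gap pattern to alignment columns, and every
other sequence is scored ``match`` / ``mismatch`` / ``gap`` at each
site.

A shipped template (``data/nirk_cu_ligands_template.tsv``) lists the
canonical NirK ligand residues with placeholder coordinates; positions
must be set from the actual reference sequence before use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phylo_rules import Msa


@dataclass(frozen=True)
class Site:
    """One annotated reference position."""

    position: int  # 1-based, ungapped reference coordinate
    expected: frozenset[str]  # accepted amino-acid letters
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based; must be >= 1")
        if not self.expected:
            raise ValueError(f"site {self.label}: expected residue set is empty")


@dataclass(frozen=True)
class ResidueMap:
    """Annotated functional sites on a named reference sequence."""

    ref_id: str
    sites: tuple[Site, ...]

    def __post_init__(self) -> None:
        pos = [s.position for s in self.sites]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("site positions must be strictly increasing")


@dataclass
class ConservationReport:
    """Per-(sequence, site) conservation states plus per-sequence summary.

    ``cells`` has one row per non-reference sequence per site with
    columns ``seq_id, label, position, column, observed, state``;
    ``summary`` maps sequence id to the fraction of sites matched.
    """

    ref_id: str
    cells: pd.DataFrame
    summary: pd.Series


def load_residue_map(path, *, substitution_groups: Mapping[str, str] | None = None) -> ResidueMap:
    """Read a residue map from TSV (columns: ref_id, pos, expected, label).

    ``expected`` may list several accepted letters (e.g. ``HQ``).  With
    ``substitution_groups`` (letter -> group string), each expected
    letter is widened to its group (conservative-substitution mode).
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["ref_id", "pos", "expected", "label"], header=0)
    if df.empty:
        raise ValueError(f"{path}: residue map is empty")
    ref_ids = df["ref_id"].unique()
    if len(ref_ids) != 1:
        raise ValueError(f"{path}: residue map must name a single reference")
    sites = []
    for _, row in df.sort_values("pos").iterrows():
        letters = set(str(row["expected"]).upper())
        if substitution_groups:
            for letter in list(letters):
                letters |= set(substitution_groups.get(letter, ""))
        sites.append(Site(int(row["pos"]), frozenset(letters), str(row["label"])))
    return ResidueMap(ref_id=str(ref_ids[0]), sites=tuple(sites))


def nirk_template_path():
    """Path to the shipped NirK Cu-ligand template (placeholder positions)."""
    return resources.files("magpipe.data").joinpath("nirk_cu_ligands_template.tsv")


def map_reference_positions(
    msa: Msa, ref_id: str, positions: Sequence[int]
) -> dict[int, int]:
    """Map ungapped reference positions to 1-based alignment columns.

    Position ``k`` maps to the column holding the k-th non-gap character
    of the reference row.  Positions beyond the reference's ungapped
    length are an error.
    """
    try:
        ref_row = next(r for r in msa.records if r.id == ref_id)
    except StopIteration:
        raise KeyError(f"reference {ref_id!r} not in alignment") from None
    cols: list[int] = []  # cols[k-1] = alignment column of k-th residue
    for col, ch in enumerate(ref_row.residues, start=1):
        if ch != "-":
            cols.append(col)
    out: dict[int, int] = {}
    for pos in positions:
        if pos < 1 or pos > len(cols):
            raise IndexError(
                f"position {pos} beyond ungapped reference length {len(cols)}"
            )
        out[pos] = cols[pos - 1]
    return out


def check_conservation(msa: Msa, residue_map: ResidueMap) -> ConservationReport:
    """Score conservation of mapped sites in every non-reference sequence.

    State per (sequence, site): ``gap`` if the sequence has '-' in the
    mapped column, ``match`` if its residue is in the expected set, else
    ``mismatch``.  The summary is the fraction of sites matched per
    sequence.  Invariant to sequence order and to unmapped columns.
    """
    col_of = map_reference_positions(
        msa, residue_map.ref_id, [s.position for s in residue_map.sites]
    )
    rows = []
    for rec in msa.records:
        if rec.id == residue_map.ref_id:
            continue
        for site in residue_map.sites:
            col = col_of[site.position]
            observed = rec.residues[col - 1]
            if observed == "-":
                state = "gap"
            elif observed in site.expected:
                state = "match"
            else:
                state = "mismatch"
            rows.append(
                {
                    "seq_id": rec.id,
                    "label": site.label,
                    "position": site.position,
                    "column": col,
                    "observed": observed,
                    "state": state,
                }
            )
    cells = pd.DataFrame(
        rows, columns=["seq_id", "label", "position", "column", "observed", "state"]
    )
    if len(cells):
        summary = (
            cells.assign(hit=cells["state"] == "match")
            .groupby("seq_id")["hit"]
            .mean()
            .sort_index()
        )
    else:
        summary = pd.Series(dtype=float, name="hit")
    return ConservationReport(ref_id=residue_map.ref_id, cells=cells, summary=summary)
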