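"""Readers and writers for the external formats the pipeline touches.

Every other module consumes only the domain types produced here: FASTA
sequence records, HMMER3 ``--tblout`` hit rows, BLAST tabular (outfmt 6)
hit rows, Newick trees and labelled numeric matrices.  Formats are plain
text, UTF-8, tab-separated where columnar, ``.`` decimal.

Heavy parsing is delegated to the established libraries (Biopython for
FASTA, scikit-bio for Newick, pandas for TSV matrices); this module adds
the validation and normalisation contracts the pipeline relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import skbio
from Bio import SeqIO

logger = logging.getLogger("magpipe")

#: Column width used when wrapping sequence lines on FASTA output.
FASTA_WRAP = 80

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence (protein or nucleotide, optionally gapped)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass(frozen=True)
class HmmHit:
    """One target/model row of an HMMER3 per-target table (``--tblout``)."""

    target_id: str
    model_name: str
    full_evalue: float
    full_bitscore: float

    def __post_init__(self) -> None:
        if self.full_evalue <= 0:
            raise ValueError(
                f"hit {self.target_id}->{self.model_name}: E-value must be > 0"
            )


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: E-value must be > 0"
            )


# A phylogenetic tree is represented throughout by skbio.TreeNode; matrices
# (genome x GH-family counts, coverage tables, ordination coordinates) by
# pandas DataFrames with unique string row/column labels.
PhyloTree = skbio.TreeNode


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: PathLike) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Residues are uppercased and a trailing ``*`` (translated stop) is
    stripped.  Record order is preserved.  Duplicate ids are an error.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().rstrip("*")
        desc = rec.description[len(rec.id):].strip()
        records.append(SeqRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: PathLike) -> None:
    """Write records as FASTA, wrapping sequence lines at 80 columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), FASTA_WRAP):
                fh.write(rec.residues[i : i + FASTA_WRAP] + "\n")


# ---------------------------------------------------------------------------
# HMMER3 tblout
# ---------------------------------------------------------------------------


def read_tblout(path: PathLike) -> list[HmmHit]:
    """Parse an HMMER3 per-target table (``hmmsearch --tblout``).

    Only the fields the pipeline consumes are retained: target name
    (column 1), query/model name (column 3), full-sequence E-value
    (column 5) and full-sequence bit score (column 6).  Comment lines
    (``#``) and blank lines are skipped.
    """
    hits: list[HmmHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 whitespace-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                evalue = float(fields[4])
                score = float(fields[5])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric E-value/score field: {exc}"
                ) from None
            hits.append(
                HmmHit(
                    target_id=fields[0],
                    model_name=fields[2],
                    full_evalue=evalue,
                    full_bitscore=score,
                )
            )
    return hits


def write_tblout(hits: Iterable[HmmHit], path: PathLike) -> None:
    """Write hits in a minimal HMMER3-tblout-compatible layout.

    Emits the first six canonical columns (accessions as ``-``); enough
    for :func:`read_tblout` and any tblout consumer of those fields.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# target name  accession  query name  accession  "
                 "E-value  score\n")
        for h in hits:
            fh.write(
                f"{h.target_id} - {h.model_name} - "
                f"{h.full_evalue:.3g} {h.full_bitscore:.1f} -\n"
            )


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------

_BLAST6_NCOLS = 12


def read_blast6(path: PathLike) -> list[BlastHit]:
    """Parse 12-column tab-separated BLAST output (outfmt 6), in order."""
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST6_NCOLS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_BLAST6_NCOLS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric E-value/bitscore: {exc}"
                ) from None
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return hits


def write_blast6(hits: Iterable[BlastHit], path: PathLike) -> None:
    """Write hits as 12-column outfmt 6; unused columns are zero-filled."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            cols = [h.query_id, h.subject_id] + ["0"] * 8
            cols += [f"{h.evalue:.3g}", f"{h.bitscore:.1f}"]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: PathLike) -> PhyloTree:
    """Read a single Newick statement into a tree.

    Tip labels must be unique and the tree must have at least one tip.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: invalid newick: {exc}") from None
    tips = [t.name for t in tree.tips()]
    if not tips:
        raise FormatError(f"{path}: tree has no tips")
    if len(tips) != len(set(tips)):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise FormatError(f"{path}: duplicate tip labels: {', '.join(dupes)}")
    return tree


def write_newick(tree: PhyloTree, path: PathLike) -> None:
    """Write a tree as a Newick statement (branch lengths preserved)."""
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# TSV matrices
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: PathLike) -> pd.DataFrame:
    """Read a labelled numeric matrix from TSV.

    First row holds column ids, first column holds row ids, all cells
    numeric.  Ragged or non-numeric rows are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing or non-numeric cell in row {bad!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: non-numeric column {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: row/column ids must be unique")
    return df


def write_matrix_tsv(matrix: pd.DataFrame, path: PathLike) -> None:
    """Write a labelled numeric matrix as TSV.

    Floats are written with ``repr`` precision, so a write/read cycle
    reproduces values exactly.
    """
    matrix.to_csv(path, sep="\t", lineterminator="\n")
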