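"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline stage has a generator that plants a known truth and
emits data in the same formats the real pipeline consumes, so recovery
can be asserted exactly:

* marker hit tables with planted completeness/misbin (bin QC);
* protein sets with planted cluster structure and coverages (rpS3
  clustering and abundance);
* per-genome GH hit tables with taxon-specific family signatures
  (GH profiling and ordination);
* trees with a planted monophyletic clade (phylum rule);
* alignments with planted conserved sites, violations and gap-rich
  columns (trimming and residue conservation).

All randomness flows from one ``numpy.random.default_rng(seed)`` per
call; identical parameters and seed give identical output.  Generators
model only what the downstream operations consume — point mutations on
uniform random sequences, no realistic evolutionary process.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bin_qc import (
    DEFAULT_MARKER_SET,
    MarkerHitTable,
    MarkerSet,
    classify_bin,
)
from .gh_profiles import default_family_universe
from .io_formats import HmmHit, PhyloTree, SeqRecord
from .phylo_rules import Msa
from .residue_conservation import ResidueMap, Site

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = AMINO_ACIDS) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: Iterable[int],
            alphabet: str = AMINO_ACIDS) -> str:
    chars = list(seq)
    for pos in positions:
        choices = [c for c in alphabet if c != chars[pos]]
        chars[pos] = rng.choice(choices)
    return "".join(chars)


# ---------------------------------------------------------------------------
# Bin QC fixtures
# ---------------------------------------------------------------------------


def _grid_count(value: float, n: int, what: str) -> int:
    """Convert a planted fraction to a marker count, enforcing the 1/n grid."""
    k = value * n
    if abs(k - round(k)) > 1e-9:
        nearest = round(k) / n
        raise ValueError(
            f"{what}={value} is not a multiple of 1/{n}; "
            f"nearest grid point is {nearest:.6f}"
        )
    return int(round(k))


def gen_marker_tables(
    completeness_values: Sequence[float],
    misbin_values: Sequence[float],
    marker_set: MarkerSet = DEFAULT_MARKER_SET,
    seed: int = 0,
) -> tuple[list[MarkerHitTable], pd.DataFrame]:
    """Marker hit tables with planted completeness and misbin.

    Bin i has ``completeness_values[i] * n`` markers present, of which
    ``misbin_values[i] * n`` carry two copies (n = marker set size);
    both fractions must sit on the 1/n grid and the duplicated count
    cannot exceed the present count.  Returns the tables and a truth
    table with the planted values and implied QC tier.
    """
    if len(completeness_values) != len(misbin_values):
        raise ValueError("completeness and misbin lists must have equal length")
    rng = np.random.default_rng(seed)
    n = len(marker_set)
    tables: list[MarkerHitTable] = []
    truth_rows = []
    for i, (c, m) in enumerate(zip(completeness_values, misbin_values)):
        if not (0 <= c <= 1 and 0 <= m <= 1):
            raise ValueError("planted values must lie in [0, 1]")
        n_present = _grid_count(c, n, "completeness")
        n_multi = _grid_count(m, n, "misbin")
        if n_multi > n_present:
            raise ValueError(
                f"bin {i}: misbin {m} exceeds completeness {c}"
            )
        present = rng.choice(marker_set.markers, size=n_present, replace=False)
        multi = set(rng.choice(present, size=n_multi, replace=False)) if n_multi else set()
        counts = {mk: 0 for mk in marker_set.markers}
        for mk in present:
            counts[mk] = 2 if mk in multi else 1
        bin_id = f"bin{i:04d}"
        tables.append(MarkerHitTable(bin_id=bin_id, copy_counts=counts))
        truth_rows.append(
            {
                "bin_id": bin_id,
                "completeness": n_present / n,
                "misbin": n_multi / n,
                "tier": classify_bin(n_present / n, n_multi / n),
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("bin_id")
    return tables, truth


def marker_table_to_hits(
    table: MarkerHitTable, seed: int = 0
) -> list[HmmHit]:
    """Expand a marker copy-count table into synthetic HMM hits.

    Each copy becomes one ORF with a strong hit (E-value well below any
    sensible cutoff); useful for exercising the tblout path end-to-end.
    """
    rng = np.random.default_rng(seed)
    hits: list[HmmHit] = []
    orf = 0
    for marker in sorted(table.copy_counts):
        for _ in range(table.copy_counts[marker]):
            hits.append(
                HmmHit(
                    target_id=f"{table.bin_id}_orf{orf:05d}",
                    model_name=marker,
                    full_evalue=10.0 ** -rng.uniform(10, 40),
                    full_bitscore=float(rng.uniform(80, 400)),
                )
            )
            orf += 1
    return hits


# ---------------------------------------------------------------------------
# Clustering fixtures
# ---------------------------------------------------------------------------


def gen_cluster_fixture(
    n_clusters: int = 10,
    members_per_cluster: int = 5,
    intra_identity: float = 0.995,
    inter_identity: float = 0.90,
    seq_len: int = 200,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict[str, str], dict[str, float]]:
    """Protein sequences with planted cluster structure and coverages.

    Cluster centroids are independent random sequences (verified to be
    mutually no more than ``inter_identity`` identical); members differ
    from their centroid by ``round((1 - intra_identity) * seq_len)``
    point substitutions.  Returns ``(records, truth, coverages)`` where
    truth maps every sequence id to its planted centroid id and
    coverages gives one positive depth per centroid.
    """
    if not (0 < inter_identity < intra_identity <= 1):
        raise ValueError("need inter_identity < intra_identity within (0, 1]")
    from .marker_abundance import pairwise_identity  # local: avoids cycle at import

    rng = np.random.default_rng(seed)
    n_mut = int(round((1 - intra_identity) * seq_len))
    records: list[SeqRecord] = []
    truth: dict[str, str] = {}
    coverages: dict[str, float] = {}
    centroids: list[SeqRecord] = []
    for ci in range(n_clusters):
        for _attempt in range(20):
            cand = SeqRecord(
                id=f"c{ci:02d}_m00", residues=_random_seq(rng, seq_len)
            )
            if all(
                pairwise_identity(cand, other) <= inter_identity
                for other in centroids
            ):
                break
        else:
            raise RuntimeError(
                "could not draw centroids below the inter-cluster identity"
            )
        centroids.append(cand)
        records.append(cand)
        truth[cand.id] = cand.id
        coverages[cand.id] = float(rng.uniform(5.0, 150.0))
        for mi in range(1, members_per_cluster):
            positions = rng.choice(seq_len, size=n_mut, replace=False)
            member = SeqRecord(
                id=f"c{ci:02d}_m{mi:02d}",
                residues=_mutate(rng, cand.residues, positions),
            )
            records.append(member)
            truth[member.id] = cand.id
    return records, truth, coverages


# ---------------------------------------------------------------------------
# GH-profile fixtures
# ---------------------------------------------------------------------------


def gen_gh_fixture(
    taxa: Sequence[str],
    genomes_per_taxon: int = 3,
    signature_families: Mapping[str, Sequence[str]] | None = None,
    background_rate: float = 0.2,
    signature_mean: float = 8.0,
    universe: Sequence[str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, list[HmmHit]], pd.DataFrame, dict[str, str]]:
    """Per-genome GH hit tables with taxon-specific family signatures.

    Each taxon gets a signature family set (assigned disjointly from
    the universe unless given); signature families draw Poisson counts
    with mean ``signature_mean``, all others with mean
    ``background_rate``.  Each counted ORF emits one winning hit and,
    sometimes, a strictly worse decoy hit to another family, so that
    lowest-E-value resolution is actually exercised.  Returns
    ``(hits_per_genome, truth_profile, genome_taxa)``; the truth
    profile is exactly what profile construction must reproduce.
    """
    rng = np.random.default_rng(seed)
    fams = tuple(universe) if universe is not None else default_family_universe()
    if signature_families is None:
        n_sig = 4
        if len(taxa) * n_sig > len(fams):
            raise ValueError("universe too small for disjoint signatures")
        shuffled = list(fams)
        rng.shuffle(shuffled)
        signature_families = {
            t: shuffled[i * n_sig : (i + 1) * n_sig] for i, t in enumerate(taxa)
        }
    hits_per_genome: dict[str, list[HmmHit]] = {}
    genome_taxa: dict[str, str] = {}
    counts: dict[str, dict[str, int]] = {}
    for taxon in taxa:
        signature = set(signature_families[taxon])
        for gi in range(genomes_per_taxon):
            genome = f"{taxon}_g{gi:02d}"
            genome_taxa[genome] = taxon
            row: dict[str, int] = {}
            hits: list[HmmHit] = []
            orf = 0
            for fam in fams:
                mean = signature_mean if fam in signature else background_rate
                k = int(rng.poisson(mean))
                row[fam] = k
                for _ in range(k):
                    target = f"{genome}_orf{orf:05d}"
                    evalue = 10.0 ** -rng.uniform(8, 30)
                    hits.append(
                        HmmHit(target, fam, evalue, float(rng.uniform(50, 300)))
                    )
                    if rng.random() < 0.3:  # worse decoy to another family
                        decoy = rng.choice([f for f in fams[:20] if f != fam])
                        hits.append(
                            HmmHit(
                                target,
                                str(decoy),
                                evalue * 100.0,
                                float(rng.uniform(20, 50)),
                            )
                        )
                    orf += 1
            counts[genome] = row
            hits_per_genome[genome] = hits
    truth = pd.DataFrame(
        [[counts[g][f] for f in fams] for g in sorted(counts)],
        index=pd.Index(sorted(counts), name="genome"),
        columns=list(fams),
        dtype=int,
    )
    return hits_per_genome, truth, genome_taxa


# ---------------------------------------------------------------------------
# Tree fixtures
# ---------------------------------------------------------------------------


def _random_topology(labels: list[str], rng: np.random.Generator):
    """Random bifurcating topology as nested lists of labels."""
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    left, right = labels[:k], labels[k:]
    return [_random_topology(left, rng), _random_topology(right, rng)]


def _to_newick(node, rng: np.random.Generator) -> str:
    if isinstance(node, str):
        return f"{node}:{rng.uniform(0.01, 1.0):.4f}"
    inner = ",".join(_to_newick(ch, rng) for ch in node)
    return f"({inner}):{rng.uniform(0.01, 1.0):.4f}"


def gen_random_tree(n_tips: int, seed: int = 0, prefix: str = "t") -> PhyloTree:
    """Random unrooted-style tree (basal trifurcation) with unique tips."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i:03d}" for i in range(n_tips)]
    rng.shuffle(labels)
    k1 = 1 + int(rng.integers(0, n_tips - 2))
    k2 = k1 + 1 + int(rng.integers(0, n_tips - k1 - 1))
    parts = [labels[:k1], labels[k1:k2], labels[k2:]]
    newick = (
        "(" + ",".join(_to_newick(_random_topology(p, rng), rng) for p in parts) + ");"
    )
    return PhyloTree.read([newick])


def gen_tree_with_clade(
    n_background_tips: int = 10, clade_size: int = 3, seed: int = 0
) -> tuple[PhyloTree, frozenset[str]]:
    """Random tree with a planted monophyletic clade.

    The clade is built as its own subtree and grafted onto one edge of
    a random background topology, so it is monophyletic by
    construction.  Returns the tree and the planted tip set (labels
    ``clade000`` ...).
    """
    if n_background_tips < 2:
        raise ValueError("need at least 2 background tips")
    if clade_size < 1:
        raise ValueError("clade_size must be >= 1")
    rng = np.random.default_rng(seed)
    bg_labels = [f"bg{i:03d}" for i in range(n_background_tips)]
    rng.shuffle(bg_labels)
    clade_labels = [f"clade{i:03d}" for i in range(clade_size)]
    background = _random_topology(bg_labels, rng)
    clade = _random_topology(list(clade_labels), rng)

    # collect graftable positions: every proper subtree of the background
    positions: list[tuple[list, int]] = []

    def _walk(node) -> None:
        if isinstance(node, list):
            for i, child in enumerate(node):
                positions.append((node, i))
                _walk(child)

    root = [background]  # wrapper so the whole background is graftable
    _walk(root)
    parent, idx = positions[int(rng.integers(0, len(positions)))]
    parent[idx] = [parent[idx], clade]
    topology = root[0]
    if isinstance(topology, list) and len(topology) == 2:
        # present as unrooted: basal trifurcation where possible
        left, right = topology
        if isinstance(left, list):
            topology = [*left, right]
        elif isinstance(right, list):
            topology = [left, *right]
    newick = "(" + ",".join(_to_newick(ch, rng) for ch in topology) + ");"
    return PhyloTree.read([newick]), frozenset(clade_labels)


# ---------------------------------------------------------------------------
# MSA fixtures
# ---------------------------------------------------------------------------


def gen_msa_fixture(
    n_seqs: int = 25,
    length: int = 120,
    n_sites: int = 5,
    gap_col_fraction: float = 0.0,
    mutation_rate: float = 0.05,
    n_violations: int = 0,
    seed: int = 0,
) -> tuple[Msa, ResidueMap, dict]:
    """Alignment with planted conserved sites, violations and gap columns.

    The reference row (``ref``) is gapless; ``n_sites`` conserved sites
    keep the reference residue in every query except ``n_violations``
    planted (query, site) substitutions.  Off-site positions mutate at
    ``mutation_rate``.  ``gap_col_fraction`` of the columns (off-site)
    are gapped in every non-reference row, giving a gap fraction of
    (n_seqs - 1) / n_seqs — requesting gap columns therefore requires
    n_seqs >= 21 for the fraction to exceed the 0.95 trimming
    threshold.  Truth lists the violated cells and the gap columns.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    n_gap_cols = int(round(gap_col_fraction * length))
    if n_gap_cols and (n_seqs - 1) / n_seqs <= 0.95:
        raise ValueError(
            "planted gap columns need n_seqs >= 21 so that the gap "
            "fraction (n-1)/n exceeds 0.95 with a gapless reference"
        )
    rng = np.random.default_rng(seed)
    ref_seq = _random_seq(rng, length)
    columns = rng.permutation(length)
    site_cols = sorted(int(c) for c in columns[:n_sites])
    gap_cols = sorted(int(c) for c in columns[n_sites : n_sites + n_gap_cols])
    query_ids = [f"seq{i:03d}" for i in range(1, n_seqs)]
    if n_violations > len(query_ids) * n_sites:
        raise ValueError("more violations than (sequence, site) cells")
    cell_idx = rng.choice(len(query_ids) * n_sites, size=n_violations, replace=False)
    violations = {
        (query_ids[int(c) // n_sites], site_cols[int(c) % n_sites])
        for c in cell_idx
    }
    records = [SeqRecord(id="ref", residues=ref_seq)]
    site_set, gap_set = set(site_cols), set(gap_cols)
    for qid in query_ids:
        chars = list(ref_seq)
        for pos in range(length):
            if pos in gap_set:
                chars[pos] = "-"
            elif pos in site_set:
                if (qid, pos) in violations:
                    chars[pos] = str(
                        rng.choice([c for c in AMINO_ACIDS if c != ref_seq[pos]])
                    )
            elif rng.random() < mutation_rate:
                chars[pos] = str(
                    rng.choice([c for c in AMINO_ACIDS if c != ref_seq[pos]])
                )
        records.append(SeqRecord(id=qid, residues="".join(chars)))
    msa = Msa(tuple(records))
    sites = tuple(
        Site(
            position=c + 1,  # ref is gapless: column == ungapped position
            expected=frozenset(ref_seq[c]),
            label=f"site{i + 1}",
        )
        for i, c in enumerate(site_cols)
    )
    residue_map = ResidueMap(ref_id="ref", sites=sites)
    truth = {
        "violations": {(q, c + 1) for q, c in violations},  # 1-based positions
        "gap_columns": [c + 1 for c in gap_cols],
        "site_columns": [c + 1 for c in site_cols],
    }
    return msa, residue_map, truth
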