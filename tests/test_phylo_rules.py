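import numpy as np
import pytest

from magpipe.io_formats import PhyloTree, SeqRecord
from magpipe.phylo_rules import (
    Msa,
    column_gap_fraction,
    concat_alignments,
    is_monophyletic,
    max_identity_to_reference,
    propose_phylum,
    trim_alignment,
)
from magpipe.synthetic_data import gen_random_tree, gen_tree_with_clade


def msa(*rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return Msa(tuple(SeqRecord(i, r) for i, r in zip(ids, rows)))


class TestGapFractionAndTrim:
    def test_gap_fraction(self):
        m = msa("AC-T", "AC-T", "ACGT", "AC--")
        np.testing.assert_allclose(column_gap_fraction(m), [0, 0, 0.75, 0.25])

    def test_gapless_unchanged(self):
        m = msa("ACGT", "ACGA")
        trimmed = trim_alignment(m)
        assert [r.residues for r in trimmed.records] == ["ACGT", "ACGA"]

    def test_interior_all_gap_column_removed(self):
        m = msa("AC-T", "AG-T", "AT-T")
        trimmed = trim_alignment(m)
        assert trimmed.width == 3
        assert trimmed.records[0].residues == "ACT"

    def test_unaligned_ends_peeled(self):
        # first column gapped in 2/3 rows (> 0.5) -> peeled from the end
        m = msa("-ACGT", "-ACGA", "MACGG")
        trimmed = trim_alignment(m)
        assert trimmed.width == 4
        assert trimmed.records[2].residues == "ACGG"

    def test_idempotent(self):
        m = msa("-AC-T-", "GAC-TT", "-ACGTT", "--C-T-")
        once = trim_alignment(m)
        twice = trim_alignment(once)
        assert [r.residues for r in once.records] == [
            r.residues for r in twice.records
        ]

    def test_trim_preserves_rows_and_never_raises_gap_fraction(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            rows = [
                "".join(rng.choice(list("ACDE-"), size=30)) for _ in range(6)
            ]
            rows = [r if r.strip("-") else "A" + r[1:] for r in rows]
            m = msa(*rows)
            try:
                trimmed = trim_alignment(m)
            except ValueError:
                continue
            assert len(trimmed) == len(m)
            assert max(column_gap_fraction(trimmed)) <= max(
                max(column_gap_fraction(m)), 0.95
            )

    def test_all_columns_removed_errors(self):
        m = msa("--", "--", "A-")
        with pytest.raises(ValueError):
            trim_alignment(m)


class TestConcatAlignments:
    def test_single_gene_identity(self):
        g = msa("ACGT", "ACGA", ids=["g1", "g2"])
        out = concat_alignments({"gene1": g})
        assert sorted(out.ids) == ["g1", "g2"]
        assert out.width == 4

    def test_missing_gene_filled_with_gaps(self):
        g1 = msa("ACDEFGHIKL", "ACDEFGHIKV", ids=["a", "b"])
        g2 = msa("WYWYWYWYWY", ids=["a"])
        out = concat_alignments({"g1": g1, "g2": g2}, min_gene_fraction=0.5)
        assert sorted(out.ids) == ["a", "b"]
        row_b = next(r for r in out.records if r.id == "b")
        assert row_b.residues == "ACDEFGHIKV" + "-" * 10

    def test_genome_below_fraction_dropped(self):
        genes = {
            f"g{i}": msa("ACGT", ids=["core"]) for i in range(3)
        }
        genes["g3"] = msa("ACGT", "ACGA", ids=["core", "rare"])
        out = concat_alignments(genes, min_gene_fraction=0.5)
        assert out.ids == ["core"]

    def test_block_order_and_total_width(self):
        g1 = msa("AAAA", ids=["x"])
        g2 = msa("CCC", ids=["x"])
        out = concat_alignments({"first": g1, "second": g2})
        assert out.records[0].residues == "AAAACCC"

    def test_no_genome_retained_errors(self):
        genes = {f"g{i}": msa("ACGT", ids=[f"only{i}"]) for i in range(4)}
        with pytest.raises(ValueError):
            concat_alignments(genes, min_gene_fraction=0.9)


class TestMaxIdentity:
    def test_query_in_refs(self):
        q = SeqRecord("q", "MKLYWQ")
        refs = [SeqRecord("r1", "MKLYWQ"), SeqRecord("r2", "WWWWWW")]
        ident, best = max_identity_to_reference(q, refs)
        assert ident == 1.0 and best == "r1"

    def test_three_quarters(self):
        ident, _ = max_identity_to_reference(
            SeqRecord("q", "ACGT"), [SeqRecord("r", "ACGA")]
        )
        assert ident == pytest.approx(0.75)

    def test_empty_refs_errors(self):
        with pytest.raises(ValueError):
            max_identity_to_reference(SeqRecord("q", "ACGT"), [])


class TestMonophyly:
    def test_sister_pair_true(self):
        tree = PhyloTree.read(["((A,B),(C,D));"])
        assert is_monophyletic(tree, {"A", "B"})

    def test_split_pair_false(self):
        tree = PhyloTree.read(["((A,B),(C,D));"])
        assert not is_monophyletic(tree, {"A", "C"})

    def test_singleton_and_full_set_true(self):
        tree = PhyloTree.read(["((A,B),(C,D));"])
        assert is_monophyletic(tree, {"A"})
        assert is_monophyletic(tree, {"A", "B", "C", "D"})

    def test_unrooted_complement_side(self):
        # on an unrooted tree either side of an edge is a clade
        tree = PhyloTree.read(["(A,B,(C,(D,E)));"])
        assert is_monophyletic(tree, {"C", "D", "E"}, rooted=False)
        assert is_monophyletic(tree, {"A", "B"}, rooted=False)

    def test_unknown_tip_named_in_error(self):
        tree = PhyloTree.read(["((A,B),(C,D));"])
        with pytest.raises(KeyError, match="Z"):
            is_monophyletic(tree, {"A", "Z"})

    def test_agrees_with_dendropy_oracle_on_random_trees(self, mono_oracle):
        rng = np.random.default_rng(1)
        for i in range(120):
            tree = gen_random_tree(int(rng.integers(4, 13)), seed=i)
            tips = [t.name for t in tree.tips()]
            k = int(rng.integers(1, len(tips)))
            sub = list(rng.choice(tips, size=k, replace=False))
            assert is_monophyletic(tree, sub, rooted=False) == mono_oracle(
                tree, sub
            ), f"disagreement on seed {i}"

    def test_planted_clades_always_detected(self, mono_oracle):
        for seed in range(30):
            tree, tipset = gen_tree_with_clade(
                n_background_tips=8, clade_size=3, seed=seed
            )
            assert is_monophyletic(tree, tipset)
            assert mono_oracle(tree, tipset)


class TestProposePhylum:
    @pytest.mark.parametrize(
        "identity, n, mono, strong, decision",
        [
            (0.74, 4, True, False, "propose"),
            (0.78, 5, True, True, "propose"),
            (0.74, 1, True, False, "reject"),
            (0.85, 6, True, True, "reject"),
            (0.74, 4, False, False, "reject"),
            (0.78, 5, True, False, "reject"),  # needs the strong-clade flag
            (0.80, 5, True, True, "propose"),  # relaxed cutoff is inclusive
        ],
    )
    def test_decision_table(self, identity, n, mono, strong, decision):
        proposal = propose_phylum(identity, n, mono, strong_clade=strong)
        assert proposal.decision == decision
        assert proposal.reason

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            propose_phylum(1.5, 2, True)
        with pytest.raises(ValueError):
            propose_phylum(0.5, 0, True)
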