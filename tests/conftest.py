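import io

import dendropy
import pytest


def skbio_to_dendropy(tree):
    buf = io.StringIO()
    tree.write(buf)
    return dendropy.Tree.get(data=buf.getvalue(), schema="newick")


def dendropy_is_monophyletic(tree_skbio, labels) -> bool:
    """Independent unrooted monophyly oracle via dendropy bipartitions.

    A tip set is monophyletic on an unrooted tree iff its taxon bitmask
    (or the complement) appears among the tree's bipartition leafsets;
    singletons and the full set are trivially monophyletic.
    """
    t = skbio_to_dendropy(tree_skbio)
    t.encode_bipartitions()
    tns = t.taxon_namespace
    target = tns.taxa_bitmask(labels=list(labels))
    full = tns.all_taxa_bitmask()
    if bin(target).count("1") in (1, bin(full).count("1")):
        return True
    leafsets = {b.leafset_bitmask for b in t.bipartition_encoding}
    return target in leafsets or (full ^ target) in leafsets


@pytest.fixture
def mono_oracle():
    return dendropy_is_monophyletic
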