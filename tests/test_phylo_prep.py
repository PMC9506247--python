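"""Supermatrix construction, partitions and neighbor joining."""

import itertools

import dendropy
import numpy as np
import pytest

import mitocomp as mc
from mitocomp import GeneAlignment
from mitocomp.phylo_prep import PCG123_ORDER


def _aln(gene, n_codons, taxa=("t1", "t2"), seed=0):
    rng = np.random.default_rng(seed)
    rows = ["".join(rng.choice(list("ACGT"), 3 * n_codons)) for _ in taxa]
    return GeneAlignment(gene, list(taxa), rows, codon_aligned=True)


def random_additive_matrix(n, rng):
    """Random binary tree with positive branch lengths -> leaf path-distance
    matrix (additive by construction) plus the generating tree."""
    taxa = [f"t{i}" for i in range(n)]
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=__import__("random").Random(int(rng.integers(1 << 30))))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = taxa[i]
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
    return d, taxa, tree


def rf_distance(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns, rooting="force-unrooted")
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns, rooting="force-unrooted")
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestConcatenate:
    def test_two_gene_lengths_and_partitions(self):
        sm = mc.concatenate([_aln("cox1", 100), _aln("nad2", 50)])
        assert sm.length == 450
        genes = sm.gene_partitions()
        assert [(p.label, p.start, p.end) for p in genes] == \
            [("nad2", 1, 150), ("cox1", 151, 450)]

    def test_single_gene_supermatrix(self):
        a = _aln("cox1", 20)
        sm = mc.concatenate([a])
        assert sm.rows == a.rows and len(sm.gene_partitions()) == 1

    def test_pcg123_order_independent_of_input_order(self):
        sm = mc.concatenate([_aln("cytb", 10), _aln("nad2", 10), _aln("cox1", 10)])
        assert [p.label for p in sm.gene_partitions()] == ["nad2", "cox1", "cytb"]

    def test_column_content_preserved_per_block(self):
        a, b = _aln("nad2", 30, seed=1), _aln("cox1", 40, seed=2)
        sm = mc.concatenate([a, b])
        p = {q.label: q for q in sm.gene_partitions()}
        for t in sm.taxa:
            assert sm.row(t)[p["nad2"].start - 1:p["nad2"].end] == a.row(t)
            assert sm.row(t)[p["cox1"].start - 1:p["cox1"].end] == b.row(t)

    def test_missing_taxon_errors_unless_gap_filled(self):
        a = _aln("nad2", 10, taxa=("t1", "t2"))
        b = _aln("cox1", 10, taxa=("t1", "t3"))
        with pytest.raises(ValueError, match="gap_fill"):
            mc.concatenate([a, b])
        sm = mc.concatenate([a, b], gap_fill=True)
        assert sm.taxa == ["t1", "t2", "t3"]
        assert sm.row("t3")[:30] == "-" * 30

    def test_codon_position_partitions_have_period_three(self):
        sm = mc.concatenate([_aln("nad2", 100)])
        pos = [p for p in sm.partitions if p.kind == "codon-position"]
        assert [(p.start, p.stride) for p in pos] == [(1, 3), (2, 3), (3, 3)]

    def test_full_13_gene_partition_counts(self):
        sm = mc.concatenate([_aln(g, 10) for g in PCG123_ORDER])
        assert len(sm.gene_partitions()) == 13
        assert sum(p.kind == "codon-position" for p in sm.partitions) == 39
        # gene partitions tile [1, length] without overlap
        genes = sorted(sm.gene_partitions(), key=lambda p: p.start)
        assert genes[0].start == 1 and genes[-1].end == sm.length
        assert all(p.end + 1 == q.start for p, q in zip(genes, genes[1:]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = mc.nj_tree(d, ["a", "b", "c"])
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_recovery(self):
        # hand-drawn tree: (a,b) cherry, (c,d) cherry, internal edge 2
        # a=1, b=3, c=4, d=5
        d = np.array([
            [0, 4, 7, 8],
            [4, 0, 9, 10],
            [7, 9, 0, 9],
            [8, 10, 9, 0]], float)
        tree = mc.nj_tree(d, list("abcd"))
        newick = tree.as_string(schema="newick")
        # a-b must form a cherry; check via bipartition
        pdm = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        for (i, x), (j, y) in itertools.combinations(enumerate("abcd"), 2):
            assert pdm.patristic_distance(tx[x], tx[y]) == pytest.approx(d[i, j])

    def test_random_additive_matrices_recovered(self, rng):
        for n in (5, 6, 8):
            for _ in range(3):
                d, taxa, src = random_additive_matrix(n, rng)
                tree = mc.nj_tree(d, taxa)
                assert rf_distance(tree, src) == 0
                pdm = tree.phylogenetic_distance_matrix()
                tx = {t.label: t for t in tree.taxon_namespace}
                for i, j in itertools.combinations(range(n), 2):
                    assert pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]]) == \
                        pytest.approx(d[i, j], abs=1e-8)

    def test_negative_branch_clamped_with_warning(self):
        # strongly non-additive matrix known to drive one estimate negative
        d = np.array([
            [0.00, 1.95, 0.88, 0.22],
            [1.95, 0.00, 0.15, 2.46],
            [0.88, 0.15, 0.00, 2.75],
            [0.22, 2.46, 2.75, 0.00]], float)
        with pytest.warns(UserWarning, match="clamped"):
            tree = mc.nj_tree(d, list("abcd"))
        assert all((e.length or 0) >= 0 for e in tree.edges())

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            mc.nj_tree(np.array([[0, 1], [1, 0]], float), ["a", "b"])
        bad = np.array([[0, 1, 2], [1, 0, np.nan], [2, np.nan, 0]])
        with pytest.raises(ValueError):
            mc.nj_tree(bad, list("abc"))


class TestWriters:
    def test_fasta_supermatrix_roundtrip(self, tmp_path):
        sm = mc.concatenate([_aln("cox1", 30), _aln("nad2", 20)])
        mc.write_supermatrix(sm, tmp_path / "sm.fasta")
        back = mc.read_supermatrix(tmp_path / "sm.fasta")
        assert back.taxa == sm.taxa and back.rows == sm.rows

    def test_phylip_relaxed_written(self, tmp_path):
        sm = mc.concatenate([_aln("cox1", 10)])
        mc.write_supermatrix(sm, tmp_path / "sm.phy", format="phylip-relaxed")
        header = (tmp_path / "sm.phy").read_text().splitlines()[0].split()
        assert header == ["2", "30"]

    def test_unsafe_taxon_names_relaxed_with_mapping(self, tmp_path):
        a = GeneAlignment("cox1", ["Nilaparvata lugens (biotype 4)", "t2"],
                          ["ACGACG", "ACGACT"], codon_aligned=True)
        mapping = mc.write_supermatrix(mc.concatenate([a]), tmp_path / "sm.fasta")
        assert " " not in mapping["Nilaparvata lugens (biotype 4)"]
        assert (tmp_path / "sm.fasta.names.tsv").exists()

    def test_partition_file_format(self, tmp_path):
        sm = mc.concatenate([_aln(g, 10) for g in PCG123_ORDER])
        mc.write_partitions(sm, tmp_path / "parts.txt")
        lines = (tmp_path / "parts.txt").read_text().splitlines()
        assert len(lines) == 13 + 39
        assert lines[0] == "DNA, nad2 = 1-30"
        assert lines[1] == "DNA, nad2_pos1 = 1-30\\3"

    def test_newick_roundtrip(self, tmp_path):
        tree = mc.nj_tree(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                          ["a", "b", "c"])
        mc.write_newick(tree, tmp_path / "t.nwk")
        back = dendropy.Tree.get(path=str(tmp_path / "t.nwk"), schema="newick")
        assert rf_distance(tree, back) == 0

    def test_outgroup_roots_written_tree_only(self, tmp_path):
        d, taxa, _ = random_additive_matrix(5, np.random.default_rng(2))
        tree = mc.nj_tree(d, taxa)
        mc.write_newick(tree, tmp_path / "rooted.nwk", outgroup=taxa[0])
        text = (tmp_path / "rooted.nwk").read_text()
        assert text.strip().endswith(";")
        # original tree object untouched (still trifurcating root)
        assert len(tree.seed_node.child_nodes()) == 3
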