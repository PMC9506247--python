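"""Gene order, breakpoints, spacers/overlaps, repeats and poly-T."""

import numpy as np
import pytest

import mitocomp as mc
from mitocomp.architecture import GeneOrder, matches_iupac

from conftest import toy_genome


def _order(names, strands=None, taxon="q"):
    strands = strands or ["+"] * len(names)
    return GeneOrder(taxon, [(n, s, 1) for n, s in zip(names, strands)], names[0])


def oracle_breakpoints(q_names, r_names):
    """Brute-force circular adjacency-set diff for all-'+' permutations."""
    def adjs(names):
        n = len(names)
        out = set()
        for i in range(n):
            a, b = names[i], names[(i + 1) % n]
            out.add(min((a, b, "f"), (b, a, "r")))
        return out
    return len(adjs(q_names) - adjs(r_names))


class TestGeneOrder:
    def test_ancestral_genome_starts_at_trnI(self, planted_ancestral):
        genome, _ = planted_ancestral
        order = mc.gene_order(genome)
        assert [g[0] for g in order.order[:4]] == ["trnI", "trnQ", "trnM", "nad2"]

    def test_duplicated_trnc_copies_listed(self, planted):
        genome, _ = planted
        order = mc.gene_order(genome)
        copies = [(n, c) for n, s, c in order.order if n == "trnC"]
        assert copies == [("trnC", 1), ("trnC", 2)]

    def test_missing_anchor_falls_back_with_warning(self):
        g = toy_genome("A" * 300, [("cox1", "PCG", 0, 90, "+"),
                                   ("cox2", "PCG", 100, 190, "+")])
        with pytest.warns(UserWarning, match="anchor"):
            order = mc.gene_order(g)
        assert order.order[0][0] == "cox1"


class TestCompareOrders:
    def test_identical_orders(self):
        o = _order(list("abcdefghij"))
        rep = mc.compare_orders(o, _order(list("abcdefghij"), taxon="r"))
        assert rep.breakpoints == 0 and rep.moved_genes == set()

    def test_adjacent_transposition_gives_three_breakpoints(self):
        ref = list("abcdefghij")
        query = list("acbdefghij")
        rep = mc.compare_orders(_order(query), _order(ref, taxon="r"))
        assert rep.breakpoints == 3
        assert rep.moved_genes == {"a", "b", "c", "d"}
        assert rep.breakpoints == oracle_breakpoints(query, ref)

    def test_breakpoints_match_bruteforce_on_random_permutations(self):
        rng = np.random.default_rng(3)
        ref = [f"g{i}" for i in range(12)]
        for _ in range(25):
            q = list(ref)
            rng.shuffle(q)
            got = mc.compare_orders(_order(q), _order(ref, taxon="r")).breakpoints
            assert got == oracle_breakpoints(q, ref)

    def test_symmetry_for_permutation_only_differences(self):
        rng = np.random.default_rng(4)
        ref = [f"g{i}" for i in range(10)]
        for _ in range(10):
            q = list(ref)
            rng.shuffle(q)
            ab = mc.compare_orders(_order(q), _order(ref, taxon="r")).breakpoints
            ba = mc.compare_orders(_order(ref, taxon="r"), _order(q)).breakpoints
            assert ab == ba

    def test_strand_flip_breaks_adjacency(self):
        ref = _order(list("abcd"))
        q = GeneOrder("q", [("a", "+", 1), ("b", "-", 1), ("c", "+", 1),
                            ("d", "+", 1)], "a")
        rep = mc.compare_orders(q, ref)
        assert rep.breakpoints == 2 and rep.moved_genes == {"a", "b", "c"}

    def test_extra_gene_copy_reported_duplicated(self):
        ref = _order(list("abcde"))
        q = GeneOrder("q", [("a", "+", 1), ("b", "+", 1), ("c", "+", 1),
                            ("c", "+", 2), ("d", "+", 1), ("e", "+", 1)], "a")
        rep = mc.compare_orders(q, ref)
        assert rep.duplicated == [("c", 2)]
        assert rep.breakpoints == 1  # only the novel c-c junction is new

    def test_canonical_gene_content_bookkeeping(self, planted):
        genome, _ = planted
        rep = mc.compare_orders(mc.gene_order(genome), mc.reference_order())
        assert rep.missing_genes == set()
        assert rep.extra_genes == set()
        assert rep.duplicated == [("trnC", 2)]


class TestSpacersOverlaps:
    def test_abutting_spacer_overlap_arithmetic(self):
        g = toy_genome("A" * 300, [("cox1", "PCG", 0, 100, "+"),
                                   ("cox2", "PCG", 100, 200, "+")])
        rep = mc.spacers_overlaps(g)
        inner = [b for b in rep.boundaries if (b.left, b.right) == ("cox1", "cox2")]
        assert inner[0].gap == 0

        g2 = toy_genome("A" * 300, [("cox1", "PCG", 0, 100, "+"),
                                    ("cox2", "PCG", 104, 200, "+")])
        assert mc.spacers_overlaps(g2).boundaries[0].gap == 4

        g3 = toy_genome("A" * 300, [("cox1", "PCG", 0, 100, "+"),
                                    ("cox2", "PCG", 95, 200, "+")])
        rep3 = mc.spacers_overlaps(g3)
        assert rep3.boundaries[0].gap == -5
        assert rep3.overlap_count == 1 and rep3.overlap_bp == 5

    def test_wrap_boundary_closes_circle(self):
        g = toy_genome("A" * 300, [("cox1", "PCG", 10, 100, "+"),
                                   ("cox2", "PCG", 150, 290, "+")])
        rep = mc.spacers_overlaps(g)
        wrap = rep.boundaries[-1]
        assert (wrap.left, wrap.right) == ("cox2", "cox1")
        assert wrap.gap == 10 + 300 - 290

    def test_nested_feature_excluded_and_listed(self):
        g = toy_genome("A" * 300, [("rrnL", "rRNA", 0, 200, "+"),
                                   ("trnV", "tRNA", 50, 110, "+"),
                                   ("cox1", "PCG", 210, 290, "+")])
        rep = mc.spacers_overlaps(g)
        assert rep.contained == [("trnV", "rrnL")]
        assert all("trnV" not in (b.left, b.right) for b in rep.boundaries)

    def test_tiling_identity_on_planted_genome(self, planted):
        genome, truth = planted
        rep = mc.spacers_overlaps(genome, include_cr=True)
        total = sum(f.length for f in genome.features)
        assert total + rep.spacer_bp - rep.overlap_bp == genome.length
        gaps = {(l, r): gap for l, r, gap in truth.boundary_gaps}
        assert rep.overlap_bp == sum(-g for g in gaps.values() if g < 0)

    def test_cr_reported_separately_by_default(self, planted):
        genome, truth = planted
        rep = mc.spacers_overlaps(genome)
        assert rep.cr_length == truth.cr_span[1] - truth.cr_span[0]


class TestRepeats:
    def test_simple_triplet_array(self):
        reps = mc.find_tandem_repeats("ACGACGACG", (3, 3), 3)
        assert len(reps) == 1
        assert reps[0].unit == "ACG" and reps[0].copies == 3
        assert reps[0].span == (0, 9)

    def test_no_repeat_returns_empty(self):
        assert mc.find_tandem_repeats("ACGTACGGGTTACGTAAACC", (5, 8), 3) == []

    def test_degenerate_first_base_consensus(self):
        unit_core = "ATCGGATCGG"
        region = "CCCC"
        for i in range(4):
            region += ("G" if i % 2 == 0 else "A") + unit_core
        region += "CCCC"
        reps = mc.find_tandem_repeats(region, (5, 20), 3)
        best = max(reps, key=lambda r: r.copies)
        assert best.copies == 4
        assert best.unit == "R" + unit_core
        assert best.variable_positions == (0,)

    def test_planted_cr_array_recovered(self, planted):
        genome, truth = planted
        cr = next(f for f in genome.features if f.ftype == "control_region")
        region = mc.extract_gene(genome, cr)
        reps = mc.find_tandem_repeats(region)
        best = max(reps, key=lambda r: r.copies)
        assert best.copies == truth.repeat_copies == 15
        assert len(best.unit) == truth.repeat_unit_len == 20
        assert best.span == (truth.repeat_span[0] - cr.start,
                             truth.repeat_span[1] - cr.start)
        assert best.unit[0] == "R"

    def test_reported_arrays_verify_copy_by_copy(self, planted):
        genome, truth = planted
        cr = next(f for f in genome.features if f.ftype == "control_region")
        region = mc.extract_gene(genome, cr)
        reps = mc.find_tandem_repeats(region)
        spans = sorted(r.span for r in reps)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2  # non-overlapping
        for r in reps:
            k = len(r.unit)
            for c in range(r.copies):
                block = region[r.span[0] + c * k: r.span[0] + (c + 1) * k]
                assert all(matches_iupac(b, u) for b, u in zip(block, r.unit))


class TestPolyT:
    def test_simple_run(self):
        assert mc.longest_polyT("AAATTTTG") == (4, 3)

    def test_leftmost_on_tie(self):
        assert mc.longest_polyT("TTATT") == (2, 0)

    def test_no_t_at_all(self):
        assert mc.longest_polyT("AAAA") == (0, None)

    def test_planted_24bp_run(self, planted):
        genome, truth = planted
        cr = next(f for f in genome.features if f.ftype == "control_region")
        region = mc.extract_gene(genome, cr)
        length, start = mc.longest_polyT(region)
        assert length == truth.polyt_len == 24
        assert start == truth.polyt_start - cr.start
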