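import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import synthetic_data as sd
from mitocomp.gene_order import (
    AnnotationError,
    GeneOrder,
    NoMajorityError,
    breakpoint_distance,
    canonicalize_circular,
    classify_rearranged,
    extract_order,
    majority_ancestor,
    orders_identical,
    rearranged_genes,
)
from mitocomp.mito_io import GeneFeature, MitoGenome

from .oracles import brute_breakpoints

PERM14 = [0, 8, 5, 11, 12, 13, 14, 15, 6, 3, 4, 1, 7, 2, 9, 10, 16]


def _order(pairs, gid="x"):
    return GeneOrder(genome_id=gid, order=list(pairs))


def _reflect(pairs):
    return [(g, "-" if s == "+" else "+") for g, s in reversed(pairs)]


@st.composite
def random_orders(draw, n=8):
    genes = [f"g{i}" for i in range(n)] + ["cox1"]
    perm = draw(st.permutations(genes))
    strands = draw(st.lists(st.sampled_from("+-"), min_size=n + 1, max_size=n + 1))
    return _order(list(zip(perm, strands)))


class TestExtractOrder:
    def test_matches_manifest(self, small_genome):
        genome, manifest = small_genome
        o = extract_order(genome)
        expected = [tuple(t) for t in manifest["gene_order"] if t[0] in o.panel]
        assert o.order == expected
        assert o.missing == frozenset()

    def test_missing_gene_recorded(self, small_genome):
        genome, _ = small_genome
        pruned = MitoGenome(
            id="pruned",
            sequence=genome.sequence,
            features=[f for f in genome.features if f.name != "rps3"],
            introns=genome.introns,
        )
        o = extract_order(pruned)
        assert o.missing == frozenset({"rps3"})
        assert len(o.order) == 16

    def test_duplicate_panel_gene_raises(self, small_genome):
        genome, _ = small_genome
        doubled = MitoGenome(
            id="dup",
            sequence=genome.sequence,
            features=genome.features
            + [GeneFeature("cox1", "PCG", "+", [(1, 9)])],
        )
        with pytest.raises(AnnotationError, match="cox1"):
            extract_order(doubled)


class TestCanonicalize:
    BASE = [("cox1", "+"), ("nad2", "+"), ("rnl", "+")]

    def test_rotations_converge(self):
        for k in range(3):
            rot = self.BASE[k:] + self.BASE[:k]
            assert canonicalize_circular(_order(rot)).order == self.BASE

    def test_reflection_converges(self):
        assert canonicalize_circular(_order(_reflect(self.BASE))).order == self.BASE

    @settings(max_examples=50, deadline=None)
    @given(random_orders())
    def test_idempotent(self, o):
        once = canonicalize_circular(o)
        twice = canonicalize_circular(once)
        assert once.order == twice.order

    @settings(max_examples=50, deadline=None)
    @given(random_orders(), st.integers(0, 8))
    def test_rotation_and_reflection_invariant(self, o, k):
        rot = _order(o.order[k % len(o.order):] + o.order[: k % len(o.order)])
        refl = _order(_reflect(o.order))
        canon = canonicalize_circular(o).order
        assert canonicalize_circular(rot).order == canon
        assert canonicalize_circular(refl).order == canon


class TestOrdersIdentical:
    def test_rotated_copy_identical(self, small_genome):
        genome, _ = small_genome
        o = extract_order(genome)
        rot = _order(o.order[7:] + o.order[:7], "rot")
        assert orders_identical(o, rot)

    def test_adjacent_swap_differs(self, small_genome):
        genome, _ = small_genome
        o = extract_order(genome)
        sw = list(o.order)
        sw[2], sw[3] = sw[3], sw[2]
        assert not orders_identical(o, _order(sw, "sw"))

    def test_disjoint_sets_raise(self):
        a = _order([("cox1", "+"), ("nad2", "+")])
        b = _order([("rps3", "+"), ("atp6", "+")])
        with pytest.raises(ValueError):
            orders_identical(a, b)

    def test_identity_iff_zero_breakpoints(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i}" for i in range(7)] + ["cox1"]
        for _ in range(50):
            a = _order(
                [(g, rng.choice(["+", "-"])) for g in rng.permutation(genes)], "a"
            )
            b = _order(
                [(g, rng.choice(["+", "-"])) for g in rng.permutation(genes)], "b"
            )
            assert orders_identical(a, b) == (breakpoint_distance(a, b) == 0)


class TestBreakpointDistance:
    def test_identical_zero(self, small_genome):
        genome, _ = small_genome
        o = extract_order(genome)
        assert breakpoint_distance(o, o) == 0

    def test_two_gene_reversal_distance_two(self):
        base = [(f"g{i}", "+") for i in range(4)] + [("cox1", "+")]
        inv = list(base)
        inv[1:3] = [(g, "-") for g, _ in reversed(base[1:3])]
        assert breakpoint_distance(_order(base), _order(inv, "inv")) == 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(16)] + ["cox1"]
        for _ in range(100):
            a = canonicalize_circular(
                _order([(g, rng.choice(["+", "-"])) for g in rng.permutation(genes)], "a")
            )
            b = canonicalize_circular(
                _order([(g, rng.choice(["+", "-"])) for g in rng.permutation(genes)], "b")
            )
            assert breakpoint_distance(a, b) == brute_breakpoints(a.order, b.order)

    def test_metric_properties(self):
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(9)] + ["cox1"]

        def rand():
            return _order(
                [(g, rng.choice(["+", "-"])) for g in rng.permutation(genes)]
            )

        for _ in range(30):
            a, b, c = rand(), rand(), rand()
            assert breakpoint_distance(a, a) == 0
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)
            assert breakpoint_distance(a, c) <= (
                breakpoint_distance(a, b) + breakpoint_distance(b, c)
            )


class TestRearrangedGenes:
    def test_identical_genome_none_rearranged(self, small_genome):
        genome, _ = small_genome
        o = extract_order(genome)
        assert rearranged_genes(o, o) == []

    def test_moved_gene_flags_it_and_neighbors(self):
        base = [(f"g{i}", "+") for i in range(6)] + [("cox1", "+")]
        moved = list(base)
        gene = moved.pop(2)  # g2 leaves g1/g3, lands between g4 and g5
        moved.insert(4, gene)
        flagged = rearranged_genes(_order(moved, "mv"), _order(base))
        assert set(flagged) == {"g1", "g2", "g3", "g4", "g5"}

    def test_planted_4_14_5_pattern(self):
        spec = sd.GenomeSpec(id="bol", length=24000)
        edits = {4: [("swap", 2)], 5: [("permute", PERM14)], 6: [("move", 2, 9)]}
        genomes, manifest = sd.generate_cohort(
            8, spec, None, seed=11, order_edits=edits
        )
        orders = [extract_order(g) for g in genomes]
        anc = majority_ancestor(orders)
        counts = {
            gid: len(genes)
            for gid, genes in classify_rearranged(orders, anc).items()
        }
        assert counts["bol_d5"] == 4
        assert counts["bol_d6"] == 14
        assert counts["bol_d7"] == 5
        assert all(counts[g] == 0 for g in ("bol", "bol_d1", "bol_d2", "bol_d3", "bol_d4"))


class TestMajorityAncestor:
    def _cohort(self):
        spec = sd.GenomeSpec(id="bol", length=24000)
        edits = {4: [("swap", 2)], 5: [("permute", PERM14)], 6: [("move", 2, 9)]}
        genomes, manifest = sd.generate_cohort(8, spec, None, seed=11, order_edits=edits)
        return genomes, manifest

    def test_five_way_plurality_recovered(self):
        genomes, manifest = self._cohort()
        orders = [extract_order(g) for g in genomes]
        anc = majority_ancestor(orders)
        planted = [
            tuple(t) for t in manifest["ancestor"]["gene_order"] if t[0] in anc.panel
        ]
        assert orders_identical(anc, _order(planted, "planted"))

    def test_tie_raises(self):
        a = _order([("cox1", "+"), ("nad2", "+"), ("rnl", "+")], "a")
        b = _order([("cox1", "+"), ("rnl", "+"), ("nad2", "+")], "b")
        with pytest.raises(NoMajorityError, match="tied"):
            majority_ancestor([a, a, b, b])

    def test_all_unique_raises(self):
        a = _order([("cox1", "+"), ("nad2", "+"), ("rnl", "+")], "a")
        b = _order([("cox1", "+"), ("rnl", "+"), ("nad2", "+")], "b")
        c = _order([("cox1", "+"), ("nad2", "-"), ("rnl", "+")], "c")
        with pytest.raises(NoMajorityError):
            majority_ancestor([a, b, c])

    def test_single_repeated_order(self):
        a = _order([("cox1", "+"), ("nad2", "+"), ("rnl", "+")], "a")
        anc = majority_ancestor([a, a, a])
        assert orders_identical(anc, a)
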