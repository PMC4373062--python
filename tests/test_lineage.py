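"""Neighbor joining, threshold lineage delimitation, block trimming and
hit-table curation."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from hypothesis import given
from hypothesis import strategies as st

from ervkit import (
    DistanceMatrix,
    HitRecord,
    NucSequence,
    TrimParams,
    cut_lineages,
    hit_filter,
    make_ancestral_ltr,
    mutate_k2p,
    neighbor_joining,
    trim_blocks,
)
from ervkit.lineage import HitFilterConfig
from tests.conftest import random_additive_tree


def branch_lengths_by_split(tree: dendropy.Tree) -> dict[frozenset, float]:
    """Map each non-trivial bipartition (as a frozenset of leaf labels on the
    smaller side) plus each leaf to its branch length."""
    taxa = {t.label for t in tree.taxon_namespace}
    out: dict[frozenset, float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in edge.head_node.leaf_iter()
        )
        key = min(below, taxa - below, key=lambda s: (len(s), sorted(s)))
        out[frozenset(key)] = out.get(frozenset(key), 0.0) + edge.length
    return out


class TestNeighborJoining:
    def test_four_taxon_additive_case(self):
        dm = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = neighbor_joining(dm)
        dt = tree.as_dendropy()
        lengths = branch_lengths_by_split(dt)
        assert lengths[frozenset({"A"})] == pytest.approx(1.0)
        assert lengths[frozenset({"B"})] == pytest.approx(2.0)
        assert lengths[frozenset({"C"})] == pytest.approx(3.0)
        assert lengths[frozenset({"D"})] == pytest.approx(4.0)
        assert lengths[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        )
        lengths = branch_lengths_by_split(neighbor_joining(dm).as_dendropy())
        assert lengths[frozenset({"a"})] == pytest.approx(0.0)
        assert lengths[frozenset({"b"})] == pytest.approx(2.0)
        assert lengths[frozenset({"c"})] == pytest.approx(3.0)

    def test_recovers_random_additive_trees_exactly(self):
        """NJ is exact on additive matrices: topology and branch lengths of
        random trees with up to 8 taxa are recovered."""
        rng = np.random.default_rng(2)
        for rep in range(30):
            n = int(rng.integers(4, 9))
            true_newick, labels, m = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, m))
            tns = dendropy.TaxonNamespace()
            t_est = tree.as_dendropy(tns)
            t_true = dendropy.Tree.get(data=true_newick, schema="newick", taxon_namespace=tns)
            t_est.encode_bipartitions()
            t_true.encode_bipartitions()
            assert treecompare.symmetric_difference(t_est, t_true) == 0
            est_len = branch_lengths_by_split(t_est)
            true_len = branch_lengths_by_split(t_true)
            for split, ln in true_len.items():
                assert est_len[split] == pytest.approx(ln, abs=1e-8)

    def test_agrees_with_independent_implementation(self):
        """Topology matches scikit-bio's NJ on a noisy (non-additive) matrix."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(5)
        n = 7
        _, labels, m = random_additive_tree(rng, n)
        noise = rng.uniform(0, 0.05, size=(n, n))
        np.fill_diagonal(noise, 0)
        m_noisy = m + noise
        m_noisy = (m_noisy + m_noisy.T) / 2  # exactly symmetric
        ours = neighbor_joining(DistanceMatrix(labels, m_noisy))
        theirs = sk_nj(SkDM(m_noisy, ids=labels))
        tns = dendropy.TaxonNamespace()
        t1 = ours.as_dendropy(tns)
        t2 = dendropy.Tree.get(data=str(theirs), schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0

    def test_unrooted_binary_shape(self):
        rng = np.random.default_rng(3)
        _, labels, m = random_additive_tree(rng, 6)
        dt = neighbor_joining(DistanceMatrix(labels, m)).as_dendropy()
        internal = [n for n in dt if not n.is_leaf()]
        assert len(internal) == 6 - 2  # n-2 internal nodes, unrooted binary

    def test_negative_estimates_clamped_and_flagged(self):
        found = False
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = rng.uniform(0.1, 1.0, size=(5, 5))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(5)], m))
            for node in tree.as_dendropy():
                if node.edge.length is not None:
                    assert node.edge.length >= 0
            found = found or bool(tree.clamped_edges)
        assert found, "expected at least one clamped branch across random matrices"

    def test_requires_three_taxa_and_finite_entries(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(ValueError, match="finite"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], m))


def block_matrix(sizes: list[int], intra: float, inter: float) -> DistanceMatrix:
    n = sum(sizes)
    m = np.full((n, n), inter)
    at = 0
    for s in sizes:
        m[at : at + s, at : at + s] = intra
        at += s
    np.fill_diagonal(m, 0)
    return DistanceMatrix([f"s{i}" for i in range(n)], m)


class TestCutLineages:
    def test_two_well_separated_blocks(self):
        part = cut_lineages(block_matrix([3, 3], 0.05, 0.4), threshold=0.15)
        assert part.n_lineages == 2
        assert part.min_inter_lineage == pytest.approx(0.4)
        assert part.max_intra_lineage == pytest.approx(0.05)

    def test_all_identical_single_lineage(self):
        part = cut_lineages(block_matrix([4], 0.0, 0.0), threshold=0.15)
        assert part.n_lineages == 1

    def test_chain_connects_through_intermediate(self):
        """Single-linkage semantics: a-b and b-c at 0.10 join a and c even
        when d(a, c) is large."""
        m = np.array(
            [[0.0, 0.10, 0.40], [0.10, 0.0, 0.10], [0.40, 0.10, 0.0]]
        )
        part = cut_lineages(DistanceMatrix(["a", "b", "c"], m), threshold=0.15)
        assert part.n_lineages == 1

    def test_partition_invariant_to_input_order(self):
        dm = block_matrix([2, 3, 2], 0.04, 0.5)
        perm = [3, 0, 6, 2, 5, 1, 4]
        labels_p = [dm.labels[i] for i in perm]
        values_p = dm.values[np.ix_(perm, perm)]
        p1 = cut_lineages(dm)
        p2 = cut_lineages(DistanceMatrix(labels_p, values_p))
        group1 = {frozenset(v) for v in p1.lineages().values()}
        group2 = {frozenset(v) for v in p2.lineages().values()}
        assert group1 == group2

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            cut_lineages(block_matrix([2], 0, 0), threshold=1.5)

    def test_recovers_k_groups_from_simulated_sequences(self):
        """Sequences evolved from 4 unrelated ancestors (intra < 0.10,
        inter > 0.25) give exactly 4 lineages at the 0.15 threshold."""
        from ervkit import distance_matrix

        seqs = []
        for g in range(4):
            anc = make_ancestral_ltr(300, 0.45, seed=900 + g)
            for member in range(3):
                out = mutate_k2p(anc, 0.03, 2.0, seed=77 + 10 * g + member)
                seqs.append((f"g{g}m{member}", out.residues))
        dm = distance_matrix(seqs, model="p")
        part = cut_lineages(dm, threshold=0.15)
        assert part.n_lineages == 4
        assert part.max_intra_lineage < 0.10
        assert part.min_inter_lineage > 0.25
        groups = part.lineages()
        for members in groups.values():
            assert len({m[:2] for m in members}) == 1  # same ancestor


CONS = "ACGTACGTAC" * 5  # 50 perfectly conserved columns


class TestTrimBlocks:
    def test_fully_conserved_kept_as_one_block(self):
        t = trim_blocks([CONS] * 4)
        assert t.kept_intervals == ((0, 50),)

    def test_long_nonconserved_core_removed(self):
        # every core column holds four distinct residues: unambiguously
        # nonconserved, and the 12-column run exceeds the limit of 10
        rows = [CONS[:20] + "ACGT"[r] * 12 + CONS[20:] for r in range(4)]
        t = trim_blocks(rows, TrimParams(max_contig_nonconserved=10))
        assert t.kept_intervals == ((0, 20), (32, 62))

    def test_short_nonconserved_run_retained_within_block(self):
        rows = [CONS[:20] + x + CONS[20:] for x in ("AAA", "CCC", "GGG", "TTT")]
        t = trim_blocks(rows, TrimParams(max_contig_nonconserved=8))
        assert t.kept_intervals == ((0, 53),)

    def test_isolated_short_block_dropped(self):
        # a 4-column conserved island marooned between long nonconserved
        # stretches (each noise column holds four distinct residues)
        def noise(r: int, n: int) -> str:
            return "".join("ACGT"[(r + j) % 4] for j in range(n))

        rows = [noise(r, 12) + "ACGT" + noise(r + 1, 12) + CONS for r in range(4)]
        t = trim_blocks(rows, TrimParams(min_block=5, max_contig_nonconserved=8))
        assert t.kept_intervals == ((28, 78),)

    def test_majority_gap_columns_always_removed(self):
        rows = [CONS[:10] + "-" * 3 + CONS[10:] for _ in range(2)]
        rows[0] = CONS[:10] + "AAA" + CONS[10:]
        # gap in 1/2 sequences -> >= 50% -> excluded with its run
        t = trim_blocks(rows, TrimParams())
        cols = set(t.kept_columns)
        assert not cols & {10, 11, 12}

    def test_retrim_is_noop_and_subset(self):
        rng = np.random.default_rng(4)
        noise = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        rows = [CONS + noise(15) + CONS + noise(3) + CONS for _ in range(5)]
        t = trim_blocks(rows)
        assert set(t.kept_columns) <= set(range(len(rows[0])))
        again = trim_blocks(t.trimmed_rows(), t.params)
        assert again.trimmed_rows() == t.trimmed_rows()

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            trim_blocks(["ACGT", "ACG"])


class TestHitFilter:
    def make_six_rows(self):
        H = HitRecord
        return [
            H("q", "s1", 25, 90, 1e-10, "cat"),    # fails identity
            H("q", "s2", 28, 95, 1e-12, "cat"),    # fails identity
            H("q", "s3", 80, 90, 0.01, "cat"),     # fails e-value
            H("q", "s4", 97, 95, 1e-20, "tiger"),  # duplicate pair member
            H("q", "s5", 97, 96, 1e-30, "tiger"),  # kept: lowest e-value
            H("q", "s6", 85, 90, 1e-9, "dog"),     # passes
        ]

    def test_worked_example_two_rows_survive(self):
        out = hit_filter(self.make_six_rows())
        assert [h.subject_id for h in out] == ["s5", "s6"]

    def test_empty_input(self):
        assert hit_filter([]) == []

    def test_idempotent(self):
        out = hit_filter(self.make_six_rows())
        assert hit_filter(out) == out

    def test_coverage_floor(self):
        rows = [HitRecord("q", "s", 80, 60, 1e-9, "cat")]
        assert hit_filter(rows) == []
        assert hit_filter(rows, HitFilterConfig(min_coverage=50)) == rows

    @given(st.lists(
        st.tuples(
            st.floats(min_value=0, max_value=100),
            st.floats(min_value=0, max_value=100),
            st.floats(min_value=1e-30, max_value=1.0),
            st.sampled_from(["cat", "dog"]),
        ),
        max_size=12,
    ))
    def test_idempotence_property(self, raw):
        rows = [
            HitRecord(f"q", f"s{i}", ident, cov, ev, sp)
            for i, (ident, cov, ev, sp) in enumerate(raw)
        ]
        once = hit_filter(rows)
        assert hit_filter(once) == once
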