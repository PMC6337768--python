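"""Superfamily/lineage classification and the RT phylogeny."""

import numpy as np
import pytest

from repeatscape.annotate import DomainHit
from repeatscape.classify import (
    LineageLabel,
    assign_lineage,
    classify_superfamily,
    homology_classify,
)
from repeatscape.phylo import build_nj_tree, dedup_representatives, rt_distance_matrix
from repeatscape.references import default_library, mutate_peptide
from repeatscape.simulate import generate_background


def _hit(domain, start, end, score=80.0):
    return DomainHit(domain, 1, (start, end), score, ("unknown", "unknown"), 0.9)


class TestSuperfamilyOrder:
    def test_int_before_rt_is_copia(self):
        hits = [_hit("INT", 2000, 3000), _hit("RT", 3500, 4700)]
        assert classify_superfamily(hits) == "Copia"

    def test_rt_before_int_is_gypsy(self):
        hits = [_hit("RT", 2000, 3200), _hit("INT", 4000, 5000)]
        assert classify_superfamily(hits) == "Gypsy"

    def test_rt_only_is_unknown(self):
        assert classify_superfamily([_hit("RT", 2000, 3200)]) == "unknown"

    def test_best_scoring_hits_decide(self):
        hits = [_hit("INT", 2000, 3000, score=60), _hit("RT", 3500, 4700, score=90),
                _hit("INT", 5000, 5600, score=90)]
        # the higher-scoring INT lies after RT -> Gypsy
        assert classify_superfamily(hits) == "Gypsy"


class TestHomologyFallback:
    def test_long_shared_stretch_classified(self, rng):
        shared = generate_background(500, 0.4, rng)
        element = generate_background(1000, 0.4, rng) + shared + generate_background(1000, 0.4, rng)
        library = [("Gypsy", "Ogre/Tat", "nt", shared)]
        label = homology_classify(element, library)
        assert (label.superfamily, label.lineage, label.evidence) == \
            ("Gypsy", "Ogre/Tat", "homology")

    def test_random_sequence_stays_unknown(self, rng):
        element = generate_background(2000, 0.4, rng)
        library = [("Copia", "Angela", "nt", generate_background(2000, 0.4, rng))]
        label = homology_classify(element, library)
        assert label.superfamily == "unknown"
        assert label.evidence == "none"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            homology_classify("ACGT" * 100, [])

    def test_label_consistency_enforced(self):
        with pytest.raises(ValueError):
            LineageLabel("Copia", "Ogre/Tat", "homology")


class TestAssignLineage:
    def test_recovery_after_one_my_of_divergence(self, refs):
        rng = np.random.default_rng(3)
        for superfamily, lineage in [("Copia", "Angela"), ("Gypsy", "Reina")]:
            pep = mutate_peptide(refs.rt_for(superfamily, lineage), 0.03, rng)
            assert assign_lineage(pep, refs) == (superfamily, lineage)

    def test_low_identity_is_unknown(self, refs):
        rng = np.random.default_rng(4)
        pep = mutate_peptide(refs.rt_for("Copia", "Angela"), 0.70, rng)
        assert assign_lineage(pep, refs) == ("unknown", "unknown")

    def test_ambiguous_margin_is_unknown(self):
        # references at exactly equal identity to the query (margin 0)
        from repeatscape.references import ReferenceLibrary

        query = "MKWQERTYIPASDFGHKLCV" * 10
        ref_a = "AAAAAAAAAA" + query[10:]
        ref_b = query[:190] + "AAAAAAAAAA"
        refs = ReferenceLibrary(domain_consensus={}, rt_lineage={
            ("Copia", "SIRE"): ref_a, ("Copia", "Ivana"): ref_b})
        assert assign_lineage(query, refs)[1] == "unknown"
        # with a clear margin the call is made
        assert assign_lineage(ref_a, refs) == ("Copia", "SIRE")


class TestDedup:
    def test_identical_peptides_collapse(self):
        peps = [("a", "MKLVWFYHQ" * 10), ("b", "MKLVWFYHQ" * 10)]
        assert len(dedup_representatives(peps)) == 1

    def test_all_distinct_retained(self, rng):
        amino = list("ACDEFGHIKLMNPQRSTVWY")
        peps = [(f"p{i}", "".join(rng.choice(amino, size=80))) for i in range(5)]
        assert len(dedup_representatives(peps)) == 5

    def test_greedy_founding_order(self):
        base = "MKWQERTYIPASDFGHKLCV" * 5
        rng = np.random.default_rng(7)
        divergent = mutate_peptide(base, 0.5, rng)
        peps = [(f"a{i}", base) for i in range(10)] + [("b", divergent)]
        reps = dedup_representatives(peps)
        assert [name for name, _ in reps] == ["a0", "b"]


class TestDistanceMatrix:
    def test_identical_pair_distance_zero(self):
        peps = [("a", "MKLVWF" * 20), ("b", "MKLVWF" * 20), ("c", "WWWWYF" * 20)]
        d = rt_distance_matrix(peps)
        assert d[0, 1] == 0.0

    def test_hand_counted_p_distance(self):
        # 10 aligned residues, 2 mismatches -> 0.2
        peps = [("a", "MKLVWFYHQC"), ("b", "MKLVWFYHAA"), ("c", "MKLVWFYHQC")]
        d = rt_distance_matrix(peps)
        assert d[0, 1] == pytest.approx(0.2)

    def test_symmetry_and_zero_diagonal(self, rng):
        amino = list("ACDEFGHIKLMNPQRSTVWY")
        peps = [(f"p{i}", "".join(rng.choice(amino, size=60))) for i in range(5)]
        d = rt_distance_matrix(peps)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            rt_distance_matrix([("a", "MKL"), ("b", "MKL")])


class TestNeighborJoining:
    def test_additive_four_leaf_tree_recovered_exactly(self):
        # additive distances from branch lengths A:2 B:3 C:4 D:4, internal 3
        D = np.array([[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float)
        tree = build_nj_tree(D, list("ABCD"))
        assert tree.is_monophyletic({"A", "B"})
        assert tree.is_monophyletic({"C", "D"})
        lengths = {}

        def walk(node):
            for child, bl in node.children:
                if child.name:
                    lengths[child.name] = bl
                walk(child)

        walk(tree.root)
        assert lengths["A"] == pytest.approx(2.0)
        assert lengths["B"] == pytest.approx(3.0)
        assert lengths["C"] == pytest.approx(4.0)
        assert lengths["D"] == pytest.approx(4.0)

    def test_three_leaves_three_point_formula(self):
        D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]], float)
        tree = build_nj_tree(D, list("XYZ"))
        bls = {child.name: bl for child, bl in tree.root.children}
        assert bls["X"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert bls["Y"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert bls["Z"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_topology_matches_scikit_bio(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        n = 7
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = rng.uniform(0.1, 1.0)
        labels = [f"L{i}" for i in range(n)]
        mine = build_nj_tree(m, labels)
        other = skbio_nj(DistanceMatrix(m, labels))
        universe = frozenset(labels)

        def canon(split, total):
            comp = total - split
            return min(split, comp, key=lambda s: (len(s), sorted(s)))

        mine_splits = {canon(s, universe) for s in mine.splits()
                       if 1 < len(s) < n - 1}
        other_splits = set()
        for node in other.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                other_splits.add(canon(tips, universe))
        assert mine_splits == other_splits

    def test_non_finite_distances_rejected(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            build_nj_tree(D, list("ABC"))

    def test_lineage_monophyly_on_synthetic_rt_sets(self, refs):
        # 4 lineages x 5 mutated copies: within-lineage distance is far
        # below between-lineage distance, so each lineage forms a clade
        rng = np.random.default_rng(11)
        chosen = [("Copia", "Angela"), ("Copia", "Tork"),
                  ("Gypsy", "Ogre/Tat"), ("Gypsy", "CRM")]
        peps, groups = [], {}
        for superfamily, lineage in chosen:
            for i in range(5):
                name = f"{lineage.replace('/', '_')}_{i}"
                peps.append((name, mutate_peptide(refs.rt_for(superfamily, lineage), 0.03, rng)))
                groups.setdefault(lineage, set()).add(name)
        tree = build_nj_tree(rt_distance_matrix(peps), [n for n, _ in peps])
        for members in groups.values():
            assert tree.is_monophyletic(members)

    def test_chromovirus_and_nonchromovirus_form_disjoint_clades(self, refs):
        rng = np.random.default_rng(13)
        chromo = ["Tekay/Del", "Galadriel", "Reina", "CRM"]
        nonchromo = ["Ogre/Tat", "Athila"]
        peps, chromo_names = [], set()
        for lineage in chromo + nonchromo:
            for i in range(3):
                name = f"{lineage.replace('/', '_')}_{i}"
                peps.append((name, mutate_peptide(refs.rt_for("Gypsy", lineage), 0.03, rng)))
                if lineage in chromo:
                    chromo_names.add(name)
        tree = build_nj_tree(rt_distance_matrix(peps), [n for n, _ in peps])
        assert tree.is_monophyletic(chromo_names)
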