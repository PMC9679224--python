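import math

import numpy as np
import pytest

from oracles import nw_oracle, sw_oracle

from coldadapt import phylo, synthetic


class TestAlignment:
    def test_identical_no_gaps(self):
        aln = phylo.global_align("MA", "MA")
        assert aln.identity_percent == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_example_matches_oracle(self):
        score = phylo.global_align(
            "ACGT", "AGT", substitution=None, gap_open=-2, gap_extend=-2
        ).score
        assert score == nw_oracle("ACGT", "AGT")

    def test_score_symmetry(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 12))
            b = "".join(rng.choice(list("ACGT"), 9))
            kw = dict(substitution=None, gap_open=-2, gap_extend=-2)
            assert phylo.global_align(a, b, **kw).score == phylo.global_align(
                b, a, **kw
            ).score

    def test_global_and_local_match_dp_oracle_on_8mers(self, rng):
        kw = dict(substitution=None, gap_open=-2, gap_extend=-2)
        for _ in range(500):
            a = "".join(rng.choice(list("ACGT"), 8))
            b = "".join(rng.choice(list("ACGT"), 8))
            assert phylo.global_align(a, b, **kw).score == nw_oracle(a, b)
            assert phylo.local_align(a, b, **kw).score == sw_oracle(a, b)

    def test_local_coverage_of_embedded_query(self):
        aln = phylo.local_align("MKVLID", "AAAAAMKVLIDAAAAAA")
        assert aln.coverage_percent == 100.0
        assert aln.identity_percent == 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            phylo.global_align("", "MA")


class TestDistances:
    @pytest.mark.parametrize("rows,expected", [
        (("ACGT", "ACGA"), 0.25),
        (("ACGT", "ACGT"), 0.0),
        (("A-CT", "AGCT"), 0.0),   # gap column excluded: 0 of 3 differ
        (("AACT", "AGCT"), 0.25),
    ])
    def test_p_distance(self, rows, expected):
        assert phylo.p_distance(rows) == pytest.approx(expected)

    def test_p_distance_no_columns_nan(self):
        assert math.isnan(phylo.p_distance(("A---", "-CGT")))

    def test_jc_closed_forms(self):
        assert phylo.jukes_cantor(0.0, 4) == 0.0
        assert phylo.jukes_cantor(0.3, 4) == pytest.approx(-0.75 * math.log(0.6))
        assert phylo.jukes_cantor(0.3, 4) == pytest.approx(0.3831, abs=1e-4)
        assert phylo.jukes_cantor(0.05, 20) == pytest.approx(
            -0.95 * math.log(1 - 0.05 * 20 / 19)
        )
        assert phylo.jukes_cantor(0.05, 20) == pytest.approx(0.05137, abs=1e-4)

    def test_jc_saturation_and_monotonicity(self):
        assert math.isinf(phylo.jukes_cantor(0.75, 4))
        ps = np.linspace(0.001, 0.7, 50)
        ds = [phylo.jukes_cantor(p, 4) for p in ps]
        assert all(x < y for x, y in zip(ds, ds[1:]))
        # first order: d ~ p for small p
        assert phylo.jukes_cantor(1e-6, 20) / 1e-6 == pytest.approx(1.0, rel=1e-4)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = phylo.DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = phylo.neighbor_joining(dm)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_matrices_recovered_exactly(self):
        for seed in range(25):
            n = 5 + seed % 4
            tree, _ = synthetic.evolve_proteins(
                synthetic.TreeSpec(n_taxa=n), "M" * 60, seed=seed
            )
            dm = phylo.patristic_matrix(tree)
            recovered = phylo.neighbor_joining(dm)
            assert phylo.tree_bipartitions(recovered) == phylo.tree_bipartitions(tree)
            back = phylo.patristic_matrix(recovered)
            np.testing.assert_allclose(back.values, dm.values, atol=1e-9)

    def test_label_permutation_gives_isomorphic_tree(self, rng):
        tree, _ = synthetic.evolve_proteins(
            synthetic.TreeSpec(n_taxa=6), "M" * 60, seed=42
        )
        dm = phylo.patristic_matrix(tree)
        perm = list(rng.permutation(len(dm.labels)))
        dm2 = phylo.DistanceMatrix(
            [dm.labels[i] for i in perm], dm.values[np.ix_(perm, perm)]
        )
        t1 = phylo.neighbor_joining(dm)
        t2 = phylo.neighbor_joining(dm2)
        assert phylo.tree_bipartitions(t1) == phylo.tree_bipartitions(t2)

    def test_against_scikit_bio(self):
        """Independent NJ implementation recovers the same topology."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj

        tree, _ = synthetic.evolve_proteins(
            synthetic.TreeSpec(n_taxa=7), "M" * 60, seed=13
        )
        dm = phylo.patristic_matrix(tree)
        ours = phylo.neighbor_joining(dm)
        theirs = nj(SkbioDM(dm.values, ids=dm.labels))
        their_parts = set()
        labels = frozenset(dm.labels)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            canon = min(side, labels - side,
                        key=lambda s: (len(s), tuple(sorted(s))))
            if len(canon) >= 2:
                their_parts.add(canon)
        assert phylo.tree_bipartitions(ours) == their_parts

    def test_too_few_labels_rejected(self):
        dm = phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError):
            phylo.neighbor_joining(dm)


class TestPatristic:
    def test_star_tree(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        pm = phylo.patristic_matrix(tree)
        off_diag = pm.values[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off_diag, 2.0)

    def test_missing_lengths_rejected(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B,C:1);", schema="newick")
        with pytest.raises(ValueError):
            phylo.patristic_matrix(tree)


class TestBootstrap:
    def make_msa(self, seed=5, n=6, length=300, rate=0.5):
        _, leaves = synthetic.evolve_proteins(
            synthetic.TreeSpec(n_taxa=n, rate=rate), "ACDEFGHIKLMNPQRSTVWY" * (length // 20),
            seed=seed,
        )
        return sorted(leaves.items())

    def test_deterministic_given_seed(self):
        msa = self.make_msa()
        t1 = phylo.bootstrap_tree(msa, n_reps=100, seed=3)
        t2 = phylo.bootstrap_tree(msa, n_reps=100, seed=3)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_single_replicate_supports_boundary(self):
        msa = self.make_msa()
        tree = phylo.bootstrap_tree(msa, n_reps=1, seed=0)
        supports = [
            int(node.label)
            for node in tree.preorder_node_iter()
            if node.label is not None and not node.is_leaf()
        ]
        assert supports and set(supports) <= {0, 100}

    def test_strong_split_high_support(self):
        """Two 3-leaf clades separated by many exclusive conserved columns."""
        left = "A" * 150 + "C" * 150
        right = "A" * 150 + "G" * 150
        msa = [
            ("L1", left), ("L2", left[:-3] + "CCA"), ("L3", left[:-6] + "CCAAGC"),
            ("R1", right), ("R2", right[:-3] + "GGA"), ("R3", right[:-6] + "GGAAGC"),
        ]
        tree = phylo.bootstrap_tree(msa, n_reps=200, seed=1, alphabet_size=20)
        parts = {}
        labels = frozenset(x for x, _ in msa)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node or node.label is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            canon = min(side, labels - side, key=lambda s: (len(s), tuple(sorted(s))))
            parts[canon] = int(node.label)
        split = frozenset({"L1", "L2", "L3"})
        key = min(split, labels - split, key=lambda s: (len(s), tuple(sorted(s))))
        assert parts[key] >= 95


class TestOrthologSelection:
    def tables(self):
        def row(sp, label, i, pep):
            return (f"{sp}_{i}", label, pep)

        tables = {}
        for k in range(10):
            sp = f"sp{k}"
            rows = [row(sp, "common", 1, "MKVLID" + "A" * k)]
            if k < 8:
                rows.append(row(sp, "partial", 2, "MWWWW"))
            if k != 0:
                rows.append(row(sp, "not_in_sp0", 3, "MCCCC"))
            tables[sp] = rows
        return tables

    def test_min_species_threshold(self):
        groups = phylo.select_common_proteins(self.tables(), min_species=8)
        labels = {g.label for g in groups}
        assert labels == {"common", "partial", "not_in_sp0"}
        groups10 = phylo.select_common_proteins(self.tables(), min_species=10)
        assert {g.label for g in groups10} == {"common"}

    def test_required_species_filter(self):
        groups = phylo.select_common_proteins(
            self.tables(), min_species=8, required_species=["sp0"]
        )
        assert {g.label for g in groups} == {"common", "partial"}

    def test_longest_peptide_representative(self):
        tables = {"a": [("a_1", "x", "MKV"), ("a_2", "x", "MKVLL")],
                  "b": [("b_1", "x", "MKV")]}
        (group,) = phylo.select_common_proteins(tables, min_species=2)
        assert group.members["a"] == ("a_2", "MKVLL")


class TestMsaOperations:
    def test_star_align_rectangular_and_identity(self):
        msa = phylo.star_align([("a", "MKVLAG"), ("b", "MKVAG"), ("c", "MKVLAG")])
        widths = {len(s) for _, s in msa}
        assert len(widths) == 1
        assert dict(msa)["a"].replace("-", "") == "MKVLAG"

    def test_concatenate_widths_additive(self):
        groups = {
            "g1": {"a": "MKVLAGMKVL", "b": "MKVLAGMKVM"},
            "g2": {"a": "WWWWWCCCCCWWWWW", "b": "WWWWWCCCCCWWWWC"},
        }
        msa = phylo.concatenate_alignments(groups)
        assert all(len(s) == 25 for _, s in msa)

    def test_concatenate_single_group_identity(self):
        groups = {"g1": {"a": "MKV", "b": "MKA"}}
        assert dict(phylo.concatenate_alignments(groups)) == groups["g1"]

    def test_concatenate_species_mismatch_names_offender(self):
        groups = {"g1": {"a": "MKV", "b": "MKA"}, "g2": {"a": "MKV", "c": "MKA"}}
        with pytest.raises(ValueError, match="g2"):
            phylo.concatenate_alignments(groups)

    def test_concatenation_order_does_not_change_nj_topology(self):
        rng = np.random.default_rng(2)
        tree, leaves = synthetic.evolve_proteins(
            synthetic.TreeSpec(n_taxa=6, rate=0.5), "ACDEFGHIKLMNPQRSTVWY" * 10,
            seed=2,
        )
        seqs = dict(sorted(leaves.items()))
        half = len(next(iter(seqs.values()))) // 2
        g1 = {k: v[:half] for k, v in seqs.items()}
        g2 = {k: v[half:] for k, v in seqs.items()}
        t_a = phylo.neighbor_joining(phylo.msa_distance_matrix(
            phylo.concatenate_alignments({"x": g1, "y": g2}), 20))
        t_b = phylo.neighbor_joining(phylo.msa_distance_matrix(
            phylo.concatenate_alignments({"y": g2, "x": g1}), 20))
        assert phylo.tree_bipartitions(t_a) == phylo.tree_bipartitions(t_b)
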