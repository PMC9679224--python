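import numpy as np
import pandas as pd
import pytest

from coldadapt import compare
from coldadapt.sequence_io import CdsRecord


class TestAnovaTukey:
    def test_degenerate_constant_groups_untested(self):
        p, pairs = compare.anova_tukey({"a": [1, 1, 1], "b": [1, 1, 1]})
        assert np.isnan(p) and pairs == {}

    def test_small_groups_excluded(self):
        p, pairs = compare.anova_tukey({"a": [1.0], "b": [1, 2, 3], "c": [2, 3, 4]})
        assert set(pairs) == {("b", "c")}

    def test_two_groups_tukey_equals_t_test(self, rng):
        from scipy import stats

        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        _, pairs = compare.anova_tukey({"a": a, "b": b})
        p_tukey = pairs[("a", "b")]
        p_t = stats.ttest_ind(a, b).pvalue
        assert p_tukey < 0.05
        assert p_tukey == pytest.approx(p_t, rel=1e-6, abs=1e-12)

    def test_matches_statsmodels_tukey(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {g: rng.normal(mu, 1, n) for g, mu, n in
                  [("a", 0, 12), ("b", 0.8, 9), ("c", 0.1, 15)]}
        _, pairs = compare.anova_tukey(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        sm = pairwise_tukeyhsd(values, labels)
        sm_p = {
            tuple(sorted((row[0], row[1]))): row[3]
            for row in sm.summary().data[1:]
        }
        for pair, p in pairs.items():
            assert p == pytest.approx(float(sm_p[pair]), abs=1e-3)


class TestSignificanceHeatmap:
    def outcomes(self):
        return [
            compare.TukeyOutcome("glycolysis", "M1+2", "A", "B", 0.01),
            compare.TukeyOutcome("glycolysis", "Vf", "A", "B", 0.20),
            compare.TukeyOutcome("ribosome", "M1+2", "A", "C", 0.03),
        ]

    def test_counts_and_symmetry(self):
        mats = compare.significance_heatmap(self.outcomes(), ["A", "B", "C"])
        m = mats["M1+2"].to_dataframe()
        assert m.loc["A", "B"] == 1 and m.loc["B", "A"] == 1
        assert m.loc["A", "C"] == 1
        assert mats["combined"].to_dataframe().loc["A", "B"] == 1
        assert "Vf" not in mats  # no significant Vf cell

    def test_no_significance_zero_matrix(self):
        mats = compare.significance_heatmap(
            [compare.TukeyOutcome("p", "Vf", "A", "B", 0.5)], ["A", "B"]
        )
        assert not mats["combined"].counts.any()

    def test_monotone_in_alpha(self):
        oc = self.outcomes()
        tight = compare.significance_heatmap(oc, ["A", "B", "C"], alpha=0.02)
        loose = compare.significance_heatmap(oc, ["A", "B", "C"], alpha=0.05)
        assert np.all(tight["combined"].counts <= loose["combined"].counts)


class TestClusterEntities:
    def matrix(self):
        counts = np.array(
            [
                [0, 1, 9, 9],
                [1, 0, 9, 9],
                [9, 9, 0, 1],
                [9, 9, 1, 0],
            ]
        )
        return compare.PairwiseSignificanceMatrix(["A", "B", "C", "D"], counts, 0.05)

    def test_tied_blocks_merge_first(self):
        from coldadapt import phylo

        tree = compare.cluster_entities(self.matrix())
        parts = phylo.tree_bipartitions(tree)
        assert frozenset({"A", "B"}) in parts or frozenset({"C", "D"}) in parts

    def test_invariant_under_entity_permutation(self):
        from coldadapt import phylo

        m = self.matrix()
        perm = [2, 0, 3, 1]
        counts = m.counts[np.ix_(perm, perm)]
        m2 = compare.PairwiseSignificanceMatrix(
            [m.entities[i] for i in perm], counts, 0.05
        )
        t1 = compare.cluster_entities(m)
        t2 = compare.cluster_entities(m2)
        assert phylo.tree_bipartitions(t1) == phylo.tree_bipartitions(t2)


class TestDeltaRegression:
    def setup_inputs(self, slopes):
        entities = ["A", "B", "C", "D"]
        growth = {e: {"OTG": 5.0 * i, "Gr": 0.05 * i} for i, e in enumerate(entities)}
        rows = []
        for e in entities:
            rows.append(
                {"entity": e, "pathway": "p", "metric": "Vf",
                 "mean": slopes * growth[e]["OTG"] + 30.0}
            )
        means = pd.DataFrame(rows)
        sig = [("p", "Vf", (a, b)) for a in entities for b in entities if a < b]
        return means, growth, sig

    def test_collinear_points_r2_one_sign_recovered(self):
        means, growth, sig = self.setup_inputs(slopes=0.8)
        results = compare.delta_regression(means, growth, sig)
        otg = next(r for r in results if r.growth_param == "OTG")
        assert otg.r2 == pytest.approx(1.0)
        assert otg.slope == pytest.approx(0.8)
        assert otg.direction == "positive"
        assert not otg.two_point

    def test_two_point_flag(self):
        means, growth, _ = self.setup_inputs(slopes=-0.5)
        results = compare.delta_regression(
            means, growth, [("p", "Vf", ("A", "B")), ("p", "Vf", ("A", "D"))]
        )
        otg = next(r for r in results if r.growth_param == "OTG")
        assert otg.two_point and otg.r2 == 1.0
        assert otg.direction == "negative"

    def test_single_pair_skipped(self):
        means, growth, _ = self.setup_inputs(slopes=1.0)
        assert compare.delta_regression(
            means, growth, [("p", "Vf", ("A", "B"))]
        ) == []


class TestRedundancy:
    def records(self, labels, species="s"):
        return [
            CdsRecord(f"{species}_{i}", "c", 1 + 9 * i, 9 + 9 * i, "+", "MA",
                      annotation_label=lab)
            for i, lab in enumerate(labels)
        ]

    def test_counting_and_ranking(self):
        table, unann = compare.redundancy_table(
            {"s": self.records(["h", "h", "h", "t", ""])}
        )
        assert table.iloc[0]["annotation_label"] == "h"
        assert table.iloc[0]["s"] == 3
        assert unann == {"s": 1}
        assert table["total"].sum() == 4  # equals number of annotated CDSs

    def test_planted_family_counts_exact(self, default_spec):
        from coldadapt import synthetic

        _, _, truth = synthetic.generate_genome(default_spec, "G_martinii")
        recs = self.records(list(truth["cds"].annotation_label), "G_martinii")
        table, _ = compare.redundancy_table({"G_martinii": recs})
        counts = dict(zip(table.annotation_label, table["G_martinii"]))
        for row in truth["families"].itertuples():
            assert counts[row.annotation_label] == row.copies

    def test_redundancy_ratio(self):
        recs = self.records(["h", "h", "t", ""])
        assert compare.redundancy_ratio(recs) == pytest.approx(3 / 2)


def test_compare_flexibility_pipeline_with_planted_shift():
    """Planted Vf shifts in half the pathways show up as heatmap counts."""
    rng = np.random.default_rng(7)
    rows = []
    pathways = [f"pw{i}" for i in range(10)]
    for sp, shift in (("A", 0.0), ("B", 8.0)):
        for pw in pathways:
            shifted = shift if pw in pathways[:5] else 0.0
            for k in range(40):
                rows.append(
                    {"species": sp, "pathway": pw, "metric": "Vf",
                     "protein_id": f"{sp}{pw}{k}",
                     "value": rng.normal(30 + shifted, 4)}
                )
    table = pd.DataFrame(rows)
    outcomes = compare.compare_flexibility(table)
    mats = compare.significance_heatmap(outcomes, ["A", "B"])
    count = mats["combined"].to_dataframe().loc["A", "B"]
    assert 3 <= count <= 7  # 5 shifted pathways, binomial wiggle
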