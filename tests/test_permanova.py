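import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio.stats.distance import DistanceMatrix as SkDistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from phytocolon.containers import DistanceMatrix
from phytocolon.permanova import (
    ModelTerm,
    expand_nested_terms,
    gower_center,
    pairwise_tissue_permanova,
    permanova,
)


def euclid_dm(x, ids=None):
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] == 1:
        x = x.T
    d = squareform(pdist(x))
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(ids, d, "euclidean")


@pytest.fixture
def cluster_toy():
    """Two clusters of two: within-cluster d=0, between-cluster d=1."""
    d = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
    )
    dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d, "toy")
    meta = pd.DataFrame({"g": ["A", "A", "B", "B"]}, index=dm.sample_ids)
    return dm, meta


class TestFormula:
    def test_simple_nesting(self):
        terms = expand_nested_terms("A/B")
        assert [t.name for t in terms] == ["A", "A:B"]
        assert terms[1].factors == ("A", "B")

    def test_survey_model_has_six_terms_in_order(self):
        terms = expand_nested_terms("Year/Stage/Tissue + Run/Plate + Site")
        assert [t.name for t in terms] == [
            "Year", "Year:Stage", "Year:Stage:Tissue", "Run", "Run:Plate", "Site",
        ]

    def test_plus_concatenates(self):
        assert [t.name for t in expand_nested_terms("A + B")] == ["A", "B"]

    @pytest.mark.parametrize("formula", ["A +", "A//B", "/A", " + "])
    def test_malformed_rejected_with_position(self, formula):
        with pytest.raises(ValueError, match="position"):
            expand_nested_terms(formula)


class TestGowerCenter:
    def test_cluster_toy_trace(self, cluster_toy):
        dm, _ = cluster_toy
        g = gower_center(dm)
        assert np.trace(g) == pytest.approx(1.0, abs=1e-12)

    def test_zero_matrix(self):
        g = gower_center(np.zeros((4, 4)))
        assert np.allclose(g, 0.0)

    def test_rows_centered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2))
        g = gower_center(euclid_dm(x))
        assert np.allclose(g.sum(axis=1), 0.0, atol=1e-10)

    def test_trace_is_total_ss(self):
        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.normal(size=(9, 3))))
        g = gower_center(d)
        expect = (squareform(d) ** 2).sum() / 9
        assert np.trace(g) == pytest.approx(expect, rel=1e-12)


class TestPermanova:
    def test_cluster_toy_exact(self, cluster_toy):
        dm, meta = cluster_toy
        tab = permanova(dm, meta, [ModelTerm("g", ("g",))], permutations="exhaustive")
        assert tab.loc["g", "R2"] == pytest.approx(1.0, abs=1e-9)
        assert tab.loc["g", "p"] == pytest.approx(8 / 24, abs=1e-12)

    def test_sampled_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 2))
        dm = euclid_dm(x)
        meta = pd.DataFrame({"g": ["A", "A", "A", "B", "B", "B"]}, index=dm.sample_ids)
        terms = [ModelTerm("g", ("g",))]
        exact = permanova(dm, meta, terms, permutations="exhaustive").loc["g", "p"]
        sampled = permanova(dm, meta, terms, n_perm=4999, seed=1).loc["g", "p"]
        mc_sd = np.sqrt(exact * (1 - exact) / 4999)
        assert abs(sampled - exact) < 4 * mc_sd + 1 / 5000

    def test_one_way_pseudo_f_equals_anova_f(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 0.5, 1.5)]
        y = np.concatenate(groups)
        dm = euclid_dm(y)
        meta = pd.DataFrame(
            {"g": np.repeat(list("abc"), 8)}, index=dm.sample_ids
        )
        tab = permanova(dm, meta, [ModelTerm("g", ("g",))], n_perm=9, seed=0)
        assert tab.loc["g", "F"] == pytest.approx(f_oneway(*groups).statistic, rel=1e-9)

    def test_matches_reference_pseudo_f(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(16, 4))
        ids = [f"s{i}" for i in range(16)]
        d = squareform(pdist(x))
        meta = pd.DataFrame({"g": rng.permutation(list("aabb") * 4)}, index=ids)
        mine = permanova(
            DistanceMatrix(ids, d, "euclid"), meta, [ModelTerm("g", ("g",))],
            n_perm=9, seed=0,
        )
        ref = skbio_permanova(SkDistanceMatrix(d, ids), meta, column="g",
                              permutations=9)
        assert mine.loc["g", "F"] == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(11)
        dm = euclid_dm(rng.normal(size=(20, 3)))
        meta = pd.DataFrame(
            {
                "a": rng.choice(list("xy"), 20),
                "b": rng.choice(list("pqr"), 20),
            },
            index=dm.sample_ids,
        )
        tab = permanova(dm, meta, "a/b", n_perm=9, seed=0)
        assert tab["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)

    def test_sequential_ss_order_dependent_but_sum_invariant(self):
        rng = np.random.default_rng(13)
        dm = euclid_dm(rng.normal(size=(18, 2)))
        meta = pd.DataFrame(
            {
                "a": rng.choice(list("xy"), 18),
                "b": (rng.random(18) < 0.5 + 0.3 * (rng.random(18) < 0.5)).astype(str),
            },
            index=dm.sample_ids,
        )
        ab = permanova(dm, meta, "a + b", n_perm=9, seed=0)
        ba = permanova(dm, meta, "b + a", n_perm=9, seed=0)
        assert ab.loc["a", "SumOfSqs"] + ab.loc["b", "SumOfSqs"] == pytest.approx(
            ba.loc["a", "SumOfSqs"] + ba.loc["b", "SumOfSqs"], rel=1e-9
        )

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(15)
        n_rep, alpha, rejections = 120, 0.05, 0
        for _ in range(n_rep):
            dm = euclid_dm(rng.normal(size=(16, 3)))
            meta = pd.DataFrame(
                {"g": rng.permutation(["a"] * 8 + ["b"] * 8)}, index=dm.sample_ids
            )
            tab = permanova(dm, meta, [ModelTerm("g", ("g",))], n_perm=99,
                            seed=int(rng.integers(2**31)))
            rejections += tab.loc["g", "p"] <= alpha
        sd = np.sqrt(n_rep * alpha * (1 - alpha))
        assert abs(rejections - n_rep * alpha) < 2.9 * sd + 1

    def test_redundant_term_dropped_with_warning(self):
        rng = np.random.default_rng(17)
        dm = euclid_dm(rng.normal(size=(8, 2)))
        meta = pd.DataFrame({"g": list("aabbaabb")}, index=dm.sample_ids)
        meta["g2"] = meta["g"]
        with pytest.warns(UserWarning, match="no rank"):
            tab = permanova(dm, meta, "g + g2", n_perm=9, seed=0)
        assert "g2" not in tab.index

    def test_nested_df_is_rank_increment(self):
        # 2 years x 3 stages fully crossed: Year df 1, Year:Stage df 4
        rng = np.random.default_rng(19)
        years = np.repeat(["y1", "y2"], 9)
        stages = np.tile(np.repeat(["s1", "s2", "s3"], 3), 2)
        dm = euclid_dm(rng.normal(size=(18, 2)))
        meta = pd.DataFrame({"year": years, "stage": stages}, index=dm.sample_ids)
        tab = permanova(dm, meta, "year/stage", n_perm=9, seed=0)
        assert tab.loc["year", "df"] == 1
        assert tab.loc["year:stage", "df"] == 4
        assert tab.loc["Residual", "df"] == 12


class TestPairwiseTissue:
    def _meta(self, tissues, stages):
        ids = [f"s{i}" for i in range(len(tissues))]
        return ids, pd.DataFrame({"tissue": tissues, "stage": stages}, index=ids)

    def test_separated_groups_r2_near_one(self):
        ids, meta = self._meta(["Roots"] * 4 + ["Rosettes"] * 4, ["Flowering"] * 8)
        x = np.array([0.0, 0.01, -0.01, 0.02, 5.0, 5.01, 4.99, 5.02])
        dm = euclid_dm(x, ids)
        out = pairwise_tissue_permanova(
            dm, meta, [("Roots", "Rosettes")], ["Flowering"], n_perm=99, seed=0
        )
        assert out.loc[0, "R2"] > 0.99
        assert out.loc[0, "p"] <= 0.05

    def test_null_groups_not_significant(self):
        rng = np.random.default_rng(21)
        ids, meta = self._meta(
            list(rng.permutation(["Roots"] * 10 + ["Stems"] * 10)), ["Senescent"] * 20
        )
        dm = euclid_dm(rng.normal(size=(20, 3)), ids)
        out = pairwise_tissue_permanova(
            dm, meta, [("Roots", "Stems")], ["Senescent"], n_perm=199, seed=3
        )
        assert out.loc[0, "R2"] < 0.3

    def test_single_tissue_subset_rejected(self):
        ids, meta = self._meta(["Roots"] * 4, ["Flowering"] * 4)
        dm = euclid_dm(np.arange(4.0), ids)
        with pytest.raises(ValueError, match="fewer than 2 tissues"):
            pairwise_tissue_permanova(
                dm, meta, [("Roots", "Rosettes")], ["Flowering"]
            )
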