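import itertools

import numpy as np
import pytest
from scipy.spatial.distance import jaccard as jaccard_distance
from skbio.diversity import beta_diversity
from skbio.stats.distance import DistanceMatrix as SkDistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from phytocolon import dissim
from phytocolon.containers import DistanceMatrix
from phytocolon.synth import generate_tree

from conftest import make_star_tree, make_table


def raup_crick_enumeration(n_pool: int, a: int, b: int, j: int) -> float:
    """Exhaustive oracle: fraction of all b-subsets sharing >= j members
    with a fixed a-subset of an n_pool-member pool."""
    a_set = set(range(a))
    hits = total = 0
    for b_set in itertools.combinations(range(n_pool), b):
        total += 1
        if len(a_set.intersection(b_set)) >= j:
            hits += 1
    return hits / total


class TestPresenceAbsence:
    def test_binarises(self):
        table = make_table([[0, 3], [2, 0]])
        np.testing.assert_array_equal(
            dissim.presence_absence(table).counts, [[0, 1], [1, 0]]
        )

    def test_zero_column_stays_zero_and_idempotent(self):
        table = make_table([[0, 5], [0, 2]])
        pa = dissim.presence_absence(table)
        assert pa.data["s1"].sum() == 0
        assert dissim.presence_absence(pa) == pa


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = dissim.bray_curtis(make_table([[2, 2], [5, 5]]))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = dissim.bray_curtis(make_table([[3, 0], [0, 4]]))
        assert dm.values[0, 1] == 1.0

    def test_hand_example_one_third(self):
        dm = dissim.bray_curtis(make_table([[1, 3], [2, 2], [3, 1]]))
        assert dm.values[0, 1] == pytest.approx(4 / 12, abs=1e-9)

    def test_zero_total_sample_named(self):
        with pytest.raises(ValueError, match="s2"):
            dissim.bray_curtis(make_table([[1, 0], [2, 0]]))


class TestRaupCrick:
    def test_no_shared_members_gives_one(self):
        table = make_table([[1, 0], [0, 1], [0, 0], [0, 0]])
        dm = dissim.raup_crick(table)
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_pool4_hand_examples(self):
        # pool of 4 ASVs, both samples with richness 2
        full_overlap = make_table([[1, 1], [1, 1], [0, 0], [0, 0]])
        dm = dissim.raup_crick(full_overlap)
        assert dm.values[0, 1] == pytest.approx(1 / 6, abs=1e-9)  # j = 2
        one_shared = make_table([[1, 1], [1, 0], [0, 1], [0, 0]])
        dm = dissim.raup_crick(one_shared)
        assert dm.values[0, 1] == pytest.approx(5 / 6, abs=1e-9)  # j = 1

    def test_diagonal_is_self_null_probability(self):
        table = make_table([[1, 1], [1, 0], [0, 1], [0, 0]])
        dm = dissim.raup_crick(table)
        # P(two random 2-subsets of a 4-pool share both members) = 1/6
        assert dm.values[0, 0] == pytest.approx(1 / 6, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_analytic_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_pool = 10 if seed == 0 else 12
        pa = (rng.random((n_pool, 5)) < 0.5).astype(int)
        pa[:, 0] = 0
        pa[0, 0] = 1  # include a richness-1 sample
        dm = dissim.raup_crick(make_table(pa))
        richness = pa.sum(axis=0)
        shared = pa.T @ pa
        for i, k in itertools.combinations(range(5), 2):
            expect = raup_crick_enumeration(
                n_pool, int(richness[i]), int(richness[k]), int(shared[i, k])
            )
            assert dm.values[i, k] == pytest.approx(expect, abs=1e-12)

    def test_null_simulation_converges_to_analytic(self):
        pa = np.zeros((8, 2), dtype=int)
        pa[:3, 0] = 1
        pa[2:6, 1] = 1  # a=3, b=4, j=1 on a pool of 8
        table = make_table(pa)
        analytic = dissim.raup_crick(table).values[0, 1]
        sim = dissim.raup_crick(table, mode="null_sim", n_null=4000, seed=0)
        mc_sd = np.sqrt(analytic * (1 - analytic) / 4000)
        assert abs(sim.values[0, 1] - analytic) < 4 * mc_sd

    def test_weighted_null_simulation_seeded(self):
        pa = (np.random.default_rng(3).random((10, 3)) < 0.5).astype(int)
        pa[0, :] = 1
        table = make_table(pa)
        a = dissim.raup_crick(table, mode="null_sim", n_null=99, weighted=True, seed=5)
        b = dissim.raup_crick(table, mode="null_sim", n_null=99, weighted=True, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        assert ((a.values >= 0) & (a.values <= 1)).all()


class TestUnweightedUnifrac:
    def test_identical_tip_sets_zero(self):
        tree = make_star_tree(["t1", "t2", "t3"])
        table = make_table([[1, 2], [1, 3], [0, 0]], asv_ids=["t1", "t2", "t3"])
        dm = dissim.unweighted_unifrac(table.presence_absence(), tree)
        assert dm.values[0, 1] == 0.0

    def test_disjoint_star_one(self):
        tree = make_star_tree(["t1", "t2", "t3", "t4"])
        table = make_table(
            [[1, 0], [1, 0], [0, 1], [0, 1]], asv_ids=["t1", "t2", "t3", "t4"]
        )
        dm = dissim.unweighted_unifrac(table.presence_absence(), tree)
        assert dm.values[0, 1] == 1.0

    def test_star_hand_example_two_thirds(self):
        tree = make_star_tree(["t1", "t2", "t3"])
        table = make_table([[1, 0], [1, 1], [0, 1]], asv_ids=["t1", "t2", "t3"])
        dm = dissim.unweighted_unifrac(table.presence_absence(), tree)
        assert dm.values[0, 1] == pytest.approx(2 / 3, abs=1e-9)

    def test_star_tree_equals_jaccard_complement(self):
        rng = np.random.default_rng(7)
        tips = [f"t{i}" for i in range(15)]
        tree = make_star_tree(tips)
        pa = (rng.random((15, 6)) < 0.5).astype(int)
        pa[0, :] = 1  # no empty samples
        dm = dissim.unweighted_unifrac(make_table(pa, asv_ids=tips), tree)
        for i, k in itertools.combinations(range(6), 2):
            expect = jaccard_distance(pa[:, i], pa[:, k])
            assert dm.values[i, k] == pytest.approx(expect, abs=1e-12)

    def test_matches_reference_implementation_on_random_tree(self):
        rng = np.random.default_rng(11)
        tree = generate_tree(20, seed=4)
        tips = sorted(t.name for t in tree.tips())
        pa = (rng.random((20, 8)) < 0.4).astype(int)
        pa[0, :] = 1
        table = make_table(pa, asv_ids=tips)
        mine = dissim.unweighted_unifrac(table, tree)
        ref = beta_diversity(
            "unweighted_unifrac", pa.T, ids=table.sample_ids, tree=tree, taxa=tips
        )
        np.testing.assert_allclose(mine.values, ref.data, atol=1e-10)

    def test_missing_tip_listed(self):
        tree = make_star_tree(["t1", "t2"])
        table = make_table([[1, 0], [0, 1]], asv_ids=["t1", "tX"])
        with pytest.raises(ValueError, match="tX"):
            dissim.unweighted_unifrac(table, tree)


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self):
        tree = make_star_tree(["t1", "t2"])
        table = make_table([[10, 20], [30, 60]], asv_ids=["t1", "t2"])
        dm = dissim.weighted_unifrac(table, tree)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_star_tree_reduces_to_weighted_l1(self):
        tips = ["t1", "t2", "t3"]
        tree = make_star_tree(tips)
        counts = np.array([[5, 1], [3, 1], [2, 8]])
        table = make_table(counts, asv_ids=tips)
        rel = counts / counts.sum(axis=0)
        expect = np.abs(rel[:, 0] - rel[:, 1]).sum()
        dm = dissim.weighted_unifrac(table, tree, normalized=False)
        assert dm.values[0, 1] == pytest.approx(expect, abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(13)
        tree = generate_tree(15, seed=6)
        tips = sorted(t.name for t in tree.tips())
        counts = rng.poisson(4, size=(15, 5)) + (rng.random((15, 5)) < 0.2)
        counts[0, :] += 1
        table = make_table(counts, asv_ids=tips)
        for normalized in (False, True):
            mine = dissim.weighted_unifrac(table, tree, normalized=normalized)
            ref = beta_diversity(
                "weighted_unifrac", counts.T, ids=table.sample_ids, tree=tree,
                taxa=tips, normalized=normalized,
            )
            np.testing.assert_allclose(mine.values, ref.data, atol=1e-10)


class TestPcoa:
    def test_collinear_points_reconstructed(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], d, "euclid")
        res = dissim.pcoa(dm)
        coords = res.coordinates.to_numpy()
        for i, k in itertools.combinations(range(3), 2):
            assert np.linalg.norm(coords[i] - coords[k]) == pytest.approx(
                d[i, k], abs=1e-9
            )

    def test_zero_matrix_all_zero_eigenvalues(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "null")
        res = dissim.pcoa(dm)
        assert np.allclose(res.eigenvalues, 0.0)
        assert res.coordinates.shape[1] == 0

    def test_proportions_sorted_and_bounded(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(8, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(8)], d, "euclid")
        res = dissim.pcoa(dm)
        assert (np.diff(res.proportion_explained) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_matches_reference_eigenvalues(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(7, 4))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(7)]
        mine = dissim.pcoa(DistanceMatrix(ids, d, "euclid"))
        ref = skbio_pcoa(SkDistanceMatrix(d, ids))
        np.testing.assert_allclose(
            mine.eigenvalues[:4], ref.eigvals.to_numpy()[:4], atol=1e-8
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "bad")


class TestWithinBetween:
    @pytest.fixture
    def dm(self):
        n = 5
        vals = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) / 10.0
        return DistanceMatrix([f"s{i}" for i in range(n)], vals, "toy")

    def test_pair_counts(self, dm):
        import pandas as pd

        meta = pd.DataFrame(index=dm.sample_ids)
        within, between = dissim.within_between_distributions(
            dm, meta, ["s0", "s1", "s2"], ["s3", "s4"]
        )
        assert len(within) == 3  # C(3,2)
        assert len(between) == 6  # 3 x 2

    def test_no_double_counting_with_overlap(self, dm):
        import pandas as pd

        meta = pd.DataFrame(index=dm.sample_ids)
        within, between = dissim.within_between_distributions(
            dm, meta, dm.sample_ids, dm.sample_ids
        )
        assert len(within) + 0 <= 10  # C(5,2)
        assert len(between) <= 10
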