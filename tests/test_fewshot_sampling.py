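"""t-SNE reduction and Kennard-Stone maximin selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

import metarf as mf
from metarf.fewshot_sampling import EmbeddingConfig, kennard_stone, tsne_reduce


def brute_force_check(z, order):
    """Verify each greedy step: the selection must be maximin at every step.

    Step 0/1: the emitted pair must achieve the maximal pairwise distance.
    Step k: the chosen point's min-distance to the selected set must equal
    the maximum over all remaining candidates.
    """
    z = np.asarray(z, float)
    d = np.linalg.norm(z[:, None] - z[None, :], axis=-1)
    best_pair = max(
        (d[i, j] for i, j in itertools.combinations(range(len(z)), 2)),
        default=0.0,
    )
    if not np.isclose(d[order[0], order[1]], best_pair):
        return False
    for k in range(2, len(order)):
        chosen = order[:k]
        remaining = [i for i in range(len(z)) if i not in chosen]
        dists = {i: min(d[i, j] for j in chosen) for i in remaining}
        if not np.isclose(dists[order[k]], max(dists.values())):
            return False
    return True


class TestKennardStone:
    def test_one_dimensional_hand_example(self):
        """Points 0, 10, 1: farthest pair (0, 10) first, lower index first."""
        order = kennard_stone(np.array([[0.0], [10.0], [1.0]]), 3)
        assert order.tolist() == [0, 1, 2]

    def test_selecting_all_points_is_a_permutation(self, rng):
        z = rng.normal(size=(9, 3))
        order = kennard_stone(z, 9)
        assert sorted(order.tolist()) == list(range(9))

    def test_n_two_is_the_farthest_pair(self, rng):
        z = rng.normal(size=(12, 2))
        d = np.linalg.norm(z[:, None] - z[None, :], axis=-1)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert set(kennard_stone(z, 2).tolist()) == {i, j}

    def test_matches_exhaustive_maximin_on_random_sets(self, rng):
        for _ in range(30):
            n_pts = int(rng.integers(4, 9))
            z = rng.normal(size=(n_pts, int(rng.integers(1, 4))))
            for n in range(2, min(4, n_pts) + 1):
                order = kennard_stone(z, n)
                assert brute_force_check(z, order.tolist())

    def test_duplicate_points_break_ties_deterministically(self):
        z = np.array([[0.0], [0.0], [5.0], [5.0]])
        a = kennard_stone(z, 4)
        b = kennard_stone(z, 4)
        np.testing.assert_array_equal(a, b)
        assert a[0] == 0 and a[1] == 2  # lowest-index pair at max distance

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_invariances_of_the_selected_set(self, seed):
        """Translation/rotation invariance, scale equivariance."""
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(8, 2))
        base = kennard_stone(z, 4).tolist()
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        assert kennard_stone(z @ rot.T + rng.normal(size=2), 4).tolist() == base
        assert kennard_stone(3.7 * z, 4).tolist() == base

    @pytest.mark.parametrize("n", [1, 9])
    def test_out_of_range_n_raises(self, n, rng):
        with pytest.raises(ValueError):
            kennard_stone(rng.normal(size=(8, 2)), n)


class TestTsneReduce:
    def test_default_output_is_two_dimensional(self, rng):
        out = tsne_reduce(rng.normal(size=(25, 10)))
        assert out.shape == (25, 2)
        assert np.all(np.isfinite(out))

    def test_well_separated_clusters_stay_separated(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(30, 50))
        b = rng.normal(size=(30, 50)) + 10.0
        emb = tsne_reduce(np.vstack([a, b]), EmbeddingConfig(seed=0))
        labels = np.repeat([0, 1], 30)
        assert silhouette_score(emb, labels) > 0

    def test_same_seed_identical_coordinates(self, rng):
        x = rng.normal(size=(20, 8))
        a = tsne_reduce(x, EmbeddingConfig(seed=3))
        b = tsne_reduce(x, EmbeddingConfig(seed=3))
        np.testing.assert_array_equal(a, b)

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError, match="skip"):
            tsne_reduce(rng.normal(size=(3, 5)))

    def test_perplexity_must_be_below_n(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_reduce(rng.normal(size=(6, 5)), EmbeddingConfig(perplexity=6))


class TestSelectFewshot:
    def test_group_with_exactly_n_candidates_selects_all(self, small_dataset):
        dataset, _ = small_dataset
        group = dataset.group_values()[0]
        n = dataset.indices_of_group(group).size
        plan = mf.select_fewshot(dataset, group, n)
        assert sorted(plan.order.tolist()) == \
            sorted(dataset.indices_of_group(group).tolist())

    def test_low_dimensional_features_skip_reduction(self):
        cfg = mf.SynthConfig(
            roles=(mf.RoleSpec("a", 5, 1), mf.RoleSpec("b", 8, 1)),
            group_role="b", seed=1,
        )
        dataset, _ = mf.gen_dataset(cfg)
        plan = mf.select_fewshot(dataset, dataset.group_values()[0], 3)
        np.testing.assert_array_equal(
            plan.coords, dataset.features[plan.candidate_indices]
        )

    def test_selection_never_reads_yields(self, small_dataset):
        from dataclasses import replace

        dataset, _ = small_dataset
        group = dataset.group_values()[1]
        plan = mf.select_fewshot(dataset, group, 4, mf.EmbeddingConfig(seed=0))
        flipped = mf.ReactionDataset(
            records=[replace(r, yield_=100.0 - r.yield_) for r in dataset.records],
            roles=dataset.roles, group_role=dataset.group_role,
            role_dims=dict(dataset.role_dims),
        )
        plan2 = mf.select_fewshot(flipped, group, 4, mf.EmbeddingConfig(seed=0))
        np.testing.assert_array_equal(plan.order, plan2.order)

    def test_too_few_candidates_names_the_group(self, small_dataset):
        dataset, _ = small_dataset
        group = dataset.group_values()[0]
        too_many = dataset.indices_of_group(group).size + 1
        with pytest.raises(ValueError, match=group):
            mf.select_fewshot(dataset, group, too_many)

    def test_plan_frame_lists_rank_and_coordinates(self, small_dataset):
        dataset, _ = small_dataset
        group = dataset.group_values()[0]
        frame = mf.select_fewshot(dataset, group, 3).to_frame()
        assert list(frame["rank"]) == [0, 1, 2]
        assert {"group", "dataset_index", "coord_0"} <= set(frame.columns)

    def test_planted_clusters_are_covered(self):
        """With 4 well-separated planted clusters and n=4, every cluster
        contributes at least one selected reaction in >= 90% of seeds."""
        cfg = mf.SynthConfig(cluster_k=4, seed=0)
        dataset, truth = mf.gen_dataset(cfg)
        group = dataset.group_values()[0]
        cand = dataset.indices_of_group(group)
        labels = np.array([truth.reaction_cluster(dataset.records[i])
                           for i in cand])
        pos = {int(c): j for j, c in enumerate(cand)}
        covered = 0
        for seed in range(10):
            plan = mf.select_fewshot(dataset, group, 4,
                                     mf.EmbeddingConfig(seed=seed))
            chosen = {labels[pos[int(i)]] for i in plan.order}
            covered += len(chosen) == 4
        assert covered >= 9
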