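"""Synthetic task generators, nulls, balancing, splitting and planning."""

import numpy as np
import pytest

from seqprobe import (
    SequenceDataset,
    TokenTaskConfig,
    TrajectoryTaskConfig,
    generate_token_task,
    generate_trajectory_task,
    load_dataset,
    pairwise_binary,
    plan_experiment,
    reshuffle_null,
    save_dataset,
    split_dataset,
    upsample_minority,
)


class TestTokenTask:
    def test_sentence_geometry(self):
        ds = generate_token_task(TokenTaskConfig(n_per_class=50, C=2))
        assert ds.x.shape == (100, 66, 300)
        assert sorted(np.unique(ds.y)) == [0, 1]

    def test_neutral_first_token_makes_t0_identical(self):
        cfg = TokenTaskConfig(n_per_class=20, C=2, T=10, d=6, vocab_size=30,
                              neutral_first_token=True, position_profile="late", seed=3)
        ds = generate_token_task(cfg)
        assert np.all(ds.x[:, 0] == ds.x[0, 0])

    def test_seeded_determinism(self):
        cfg = TokenTaskConfig(n_per_class=15, C=3, T=9, d=5, vocab_size=40, seed=11)
        a, b = generate_token_task(cfg), generate_token_task(cfg)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_vocab_too_small_rejected(self):
        with pytest.raises(ValueError, match="vocab"):
            TokenTaskConfig(n_per_class=5, C=4, vocab_size=10,
                            n_discriminative_tokens=5)

    def test_user_token_vectors_hook(self, rng):
        cfg = TokenTaskConfig(n_per_class=5, C=2, T=6, d=4, vocab_size=30, seed=1)
        table = rng.standard_normal((30, 4))
        ds = generate_token_task(cfg, token_vectors=table)
        # every timestep vector must be a row of the supplied table
        flat = ds.x.reshape(-1, 4)
        assert all(any(np.array_equal(v, row) for row in table) for v in flat[:10])

    @pytest.mark.parametrize("profile,region", [("early", "first"), ("late", "last")])
    def test_position_profile_confines_informative_tokens(self, profile, region):
        cfg = TokenTaskConfig(n_per_class=400, C=2, T=12, d=4, vocab_size=40,
                              n_discriminative_tokens=3, position_profile=profile, seed=5)
        ds = generate_token_task(cfg)
        # per-slice class-conditional mean gap should concentrate in the region
        diff = np.linalg.norm(
            ds.x[ds.y == 0].mean(axis=0) - ds.x[ds.y == 1].mean(axis=0), axis=1
        )
        third = cfg.T // 3
        inside = diff[:third] if region == "first" else diff[-third:]
        outside = diff[third:] if region == "first" else diff[:-third]
        assert inside.mean() > 3 * outside.mean()


class TestTrajectoryTask:
    def test_gesture_geometry(self):
        ds = generate_trajectory_task(TrajectoryTaskConfig(n_per_class=3, C=2))
        assert ds.x.shape == (6, 150, 274)

    def test_no_signal_when_scales_zero(self):
        """With both class scales at zero a probe on the raw frames is at chance."""
        from seqprobe import ProbeConfig, knn_accuracy

        cfg = TrajectoryTaskConfig(n_per_class=150, C=2, T=10, d=6,
                                   class_offset_scale=0, class_dynamics_scale=0, seed=2)
        ds = generate_trajectory_task(cfg)
        acc = knn_accuracy(ds.x[:, 0, :], ds.y,
                           ProbeConfig(k=5, eval_protocol="stratified_cv", seed=2))
        # binomial 99% interval of chance at n=300
        assert abs(acc - 0.5) <= 2.576 * np.sqrt(0.25 / 300) + 0.02

    def test_degenerate_ar_gives_constant_frames(self):
        cfg = TrajectoryTaskConfig(n_per_class=4, C=2, T=8, d=5, ar_coefficient=0.0,
                                   noise_sd=0.0, class_dynamics_scale=0.0,
                                   class_offset_scale=1.0, seed=3)
        ds = generate_trajectory_task(cfg)
        for i in range(ds.n_items):
            assert np.allclose(ds.x[i], ds.x[i, 0])

    def test_offset_separates_class_means_at_t0(self):
        cfg = TrajectoryTaskConfig(n_per_class=200, C=2, T=6, d=8,
                                   class_offset_scale=2.0, class_dynamics_scale=0.0,
                                   noise_sd=0.1, seed=4)
        ds = generate_trajectory_task(cfg)
        m0 = ds.x[ds.y == 0, 0].mean(axis=0)
        m1 = ds.x[ds.y == 1, 0].mean(axis=0)
        assert np.linalg.norm(m0 - m1) > 1.0

    def test_variable_lengths_padded_and_masked(self):
        cfg = TrajectoryTaskConfig(
            n_per_class=10, C=2, T=12, d=4, seed=5,
            real_length_distribution=lambda rng, n: rng.integers(3, 13, size=n),
        )
        ds = generate_trajectory_task(cfg)
        lengths = ds.mask.sum(axis=1)
        assert lengths.min() >= 3
        for i in range(ds.n_items):
            assert np.all(ds.x[i, lengths[i]:] == 0)

    def test_lengths_exceeding_T_rejected(self):
        cfg = TrajectoryTaskConfig(
            n_per_class=4, C=2, T=5, d=3, seed=6,
            real_length_distribution=lambda rng, n: np.full(n, 9),
        )
        with pytest.raises(ValueError, match="exceed"):
            generate_trajectory_task(cfg)


class TestReshuffleNull:
    @pytest.fixture
    def ds(self):
        return generate_trajectory_task(
            TrajectoryTaskConfig(n_per_class=25, C=2, T=8, d=4, seed=9)
        )

    def test_label_permutation_preserves_label_multiset(self, ds):
        out = reshuffle_null(ds, "label_permutation", 1)
        assert np.array_equal(np.sort(out.y), np.sort(ds.y))
        assert np.array_equal(out.x, ds.x)

    def test_timestep_shuffle_preserves_frame_multiset(self, ds):
        out = reshuffle_null(ds, "within_item_timestep_shuffle", 1)
        assert np.array_equal(out.y, ds.y)
        for i in range(ds.n_items):
            orig = np.sort(ds.x[i].ravel())
            assert np.allclose(np.sort(out.x[i].ravel()), orig)

    def test_timestep_shuffle_of_identical_frames_is_identity(self):
        x = np.ones((3, 5, 2))
        ds = SequenceDataset(x=x, y=np.array([0, 1, 0]),
                             mask=np.ones((3, 5), bool), class_names=["a", "b"])
        out = reshuffle_null(ds, "within_item_timestep_shuffle", 0)
        assert np.array_equal(out.x, ds.x)

    def test_superimposition_draws_frames_from_same_timestep(self, ds):
        out = reshuffle_null(ds, "across_item_superimposition", 1)
        for t in range(ds.T):
            pool = {tuple(f) for f in ds.x[:, t]}
            assert all(tuple(f) in pool for f in out.x[:, t])

    def test_seeded_determinism(self, ds):
        a = reshuffle_null(ds, "across_item_superimposition", 42)
        b = reshuffle_null(ds, "across_item_superimposition", 42)
        assert np.array_equal(a.x, b.x)

    def test_unknown_strategy(self, ds):
        with pytest.raises(ValueError, match="unknown null strategy"):
            reshuffle_null(ds, "bogus", 0)


class TestUpsampleSplitPairs:
    def _unbalanced(self, n0, n1):
        x = np.arange((n0 + n1) * 2 * 3, dtype=float).reshape(n0 + n1, 2, 3)
        y = np.array([0] * n0 + [1] * n1)
        return SequenceDataset(x=x, y=y, mask=np.ones((n0 + n1, 2), bool),
                               class_names=["a", "b"])

    def test_upsample_matches_majority(self):
        out = upsample_minority(self._unbalanced(30, 70), seed=0)
        assert np.bincount(out.y).tolist() == [70, 70]

    def test_upsample_balanced_is_item_preserving(self):
        ds = self._unbalanced(20, 20)
        out = upsample_minority(ds, seed=0)
        assert np.allclose(np.sort(out.x.ravel()), np.sort(ds.x.ravel()))

    def test_upsample_single_source_item(self):
        out = upsample_minority(self._unbalanced(1, 99), seed=0)
        counts = np.bincount(out.y)
        assert counts.tolist() == [99, 99]
        src = self._unbalanced(1, 99).x[0]
        assert all(np.array_equal(out.x[i], src) for i in np.flatnonzero(out.y == 0))

    def test_upsample_empty_class_rejected(self):
        ds = self._unbalanced(5, 5)
        ds.class_names = ["a", "b", "c"]  # class 2 has zero items
        with pytest.raises(ValueError, match="zero items"):
            upsample_minority(ds, seed=0)

    @pytest.mark.parametrize("n,expected", [(1000, (640, 160, 200)), (10, (6, 2, 2))])
    def test_split_fractions(self, n, expected):
        ds = self._unbalanced(n // 2, n - n // 2)
        train, val, test = split_dataset(ds, seed=0)
        assert (train.n_items, val.n_items, test.n_items) == expected

    def test_split_is_a_partition(self):
        ds = self._unbalanced(23, 27)
        train, val, test = split_dataset(ds, seed=1)
        combined = np.concatenate([p.x.reshape(p.n_items, -1) for p in (train, val, test)])
        assert len(combined) == 50
        orig = {tuple(r) for r in ds.x.reshape(50, -1)}
        assert {tuple(r) for r in combined} == orig

    def test_split_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._unbalanced(2, 2), seed=0)

    @pytest.mark.parametrize("C,expected", [(2, 1), (4, 6), (6, 15)])
    def test_pairwise_counts(self, C, expected):
        n = 4 * C
        x = np.zeros((n, 2, 3))
        y = np.repeat(np.arange(C), 4)
        ds = SequenceDataset(x=x, y=y, mask=np.ones((n, 2), bool),
                             class_names=[f"c{i}" for i in range(C)])
        pairs = pairwise_binary(ds)
        assert len(pairs) == expected
        for p in pairs:
            assert sorted(np.unique(p.y)) == [0, 1]
            assert p.n_items == 8

    def test_pairwise_single_pair_keeps_membership(self):
        ds = self._unbalanced(6, 6)
        (pair,) = pairwise_binary(ds)
        assert np.allclose(np.sort(pair.x.ravel()), np.sort(ds.x.ravel()))


class TestPlanExperiment:
    def test_published_design_size(self):
        plan = plan_experiment(reps=25, dataset_ids=["sentence", "gesture"], C=6)
        assert len(plan) == 750

    def test_minimal_design(self):
        assert len(plan_experiment(1, ["d"], C=2)) == 1

    def test_conditions_double_the_count(self):
        a = plan_experiment(3, ["d"], C=4)
        b = plan_experiment(3, ["d"], C=4, conditions=("ordered", "reshuffled"))
        assert len(b) == 2 * len(a)

    def test_run_seeds_distinct_and_reproducible(self):
        a = plan_experiment(2, ["x", "y"], C=3, base_seed=5)
        b = plan_experiment(2, ["x", "y"], C=3, base_seed=5)
        seeds = [r.seed for r in a]
        assert seeds == [r.seed for r in b]
        assert len(set(seeds)) == len(seeds)
        assert all(0 <= s < 2**31 for s in seeds)


class TestPersistence:
    def test_roundtrip(self, tmp_path, small_token_dataset):
        save_dataset(small_token_dataset, tmp_path / "ds")
        back = load_dataset(tmp_path / "ds")
        assert np.array_equal(back.x, small_token_dataset.x)
        assert np.array_equal(back.y, small_token_dataset.y)
        assert back.class_names == small_token_dataset.class_names


class TestDatasetInvariants:
    def test_padding_must_be_zero(self):
        x = np.ones((2, 3, 2))
        mask = np.array([[True, True, False], [True, True, True]])
        with pytest.raises(ValueError, match="padding"):
            SequenceDataset(x=x, y=np.array([0, 1]), mask=mask, class_names=["a", "b"])

    def test_mask_must_be_prefix_true(self):
        x = np.zeros((1, 3, 2))
        mask = np.array([[True, False, True]])
        with pytest.raises(ValueError, match="prefix"):
            SequenceDataset(x=x, y=np.array([0]), mask=mask, class_names=["a", "b"])
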