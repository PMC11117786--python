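import math

import numpy as np
import pytest

from mrifusion.fusion_net import ModelConfig, build_model, reduced_extractor_config
from mrifusion.nn import Tensor, bce_with_logits
from mrifusion.training import (LossBreakdown, ScheduleConfig, SliceDataset,
                                TrainConfig, branch_loss, class_weights,
                                lr_multiplier, sample_indices, split_cohort,
                                total_loss, train, predict_cohort)
from mrifusion.synthetic_data import PhantomConfig, generate_cohort
from conftest import make_labelled_manifest


class TestClassWeights:
    def test_reciprocal_counts(self):
        w = class_weights([0, 0, 0, 1]).weight_per_class
        assert w == {0: pytest.approx(1 / 3), 1: 1.0}

    def test_balanced(self):
        assert class_weights([0, 1]).weight_per_class == {0: 1.0, 1: 1.0}

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="class"):
            class_weights([1, 1, 1])

    @pytest.mark.parametrize("n0,n1", [(150, 50), (90, 10)])
    def test_weighted_draws_balance_classes(self, n0, n1, rng):
        labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
        idx = sample_indices(labels, 10_000, rng)
        frac1 = labels[idx].mean()
        assert abs(frac1 - 0.5) < 0.02


class TestBranchLoss:
    def test_zero_logit_positive_label(self):
        assert branch_loss([0.0], [1]) == pytest.approx(math.log(2), abs=1e-9)

    def test_saturated_logit(self):
        assert branch_loss([20.0], [1]) < 1e-8

    def test_hand_computed_batch(self):
        # -log sigma(1.0) = 0.313262, -log(1 - sigma(-0.5)) = 0.474077
        assert branch_loss([1.0, -0.5], [1, 0]) == pytest.approx(0.3936689, abs=1e-6)

    def test_agrees_with_naive_form(self, rng):
        s = rng.normal(0, 3, 200)
        y = rng.integers(0, 2, 200)
        p = 1 / (1 + np.exp(-s))
        naive = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert abs(branch_loss(s, y) - naive) < 1e-6

    def test_agrees_with_tensor_loss(self, rng):
        s = rng.normal(0, 2, 64).astype(np.float32)
        y = rng.integers(0, 2, 64).astype(np.float32)
        t = bce_with_logits(Tensor(s, requires_grad=True), y)
        assert abs(float(t.data) - branch_loss(s, y)) < 1e-6

    def test_empty_batch(self):
        with pytest.raises(ValueError, match="empty"):
            branch_loss([], [])

    def test_nonfinite_logit(self):
        with pytest.raises(ValueError, match="finite"):
            branch_loss([np.inf], [1])


class TestTotalLoss:
    def test_sum_identity(self):
        lb = total_loss(0.1, 0.2, 0.3)
        assert lb.total == pytest.approx(0.6, abs=1e-12)

    def test_zero(self):
        assert total_loss(0.0, 0.0, 0.0).total == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)

    def test_random_batches_identity(self, rng):
        for _ in range(50):
            parts = rng.uniform(0, 5, 3)
            lb = total_loss(*parts)
            assert abs(lb.total - (lb.l_all + lb.l_t1 + lb.l_t2)) < 1e-9

    def test_shared_gradient_is_sum_of_branch_gradients(self, rng):
        """d(L_a + L_b)/dw == dL_a/dw + dL_b/dw through a shared parameter."""
        w = Tensor(rng.normal(size=(4, 1)).astype(np.float32), requires_grad=True)
        x = Tensor(rng.normal(size=(8, 4)).astype(np.float32))
        y = rng.integers(0, 2, 8).astype(np.float32)

        def losses():
            logit = (x @ w).reshape(-1)
            return bce_with_logits(logit, y), bce_with_logits(logit * 2.0, 1 - y)

        la, lb = losses()
        (la + lb).backward()
        g_joint = w.grad.copy()
        w.grad = None
        la, lb = losses()
        la.backward()
        g_a = w.grad.copy()
        w.grad = None
        la, lb = losses()
        lb.backward()
        g_b = w.grad.copy()
        np.testing.assert_allclose(g_joint, g_a + g_b, atol=1e-5)


class TestLrSchedule:
    def test_boundary_values(self):
        sch = ScheduleConfig()
        assert lr_multiplier(25, sch) == 1.0
        assert lr_multiplier(100, sch) == pytest.approx(0.0, abs=1e-12)
        assert lr_multiplier(10, sch) == pytest.approx(0.4)

    def test_matches_closed_form_everywhere(self):
        sch = ScheduleConfig(warmup_epoch=25, num_epoch=100)
        for e in range(1, 101):
            if e <= 25:
                expect = e / 25
            else:
                expect = 0.5 * (math.cos(math.pi * (e - 25) / 75) + 1)
            assert lr_multiplier(e, sch) == pytest.approx(expect, abs=1e-12)

    def test_monotone_up_then_down(self):
        sch = ScheduleConfig(warmup_epoch=25, num_epoch=100)
        vals = [lr_multiplier(e, sch) for e in range(1, 101)]
        assert all(a < b for a, b in zip(vals[:24], vals[1:25]))
        assert all(a > b for a, b in zip(vals[24:-1], vals[25:]))

    def test_midpoint_crossing(self):
        sch = ScheduleConfig(warmup_epoch=25, num_epoch=100)
        assert lr_multiplier(62, sch) > 0.5 > lr_multiplier(63, sch)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lr_multiplier(0, ScheduleConfig())
        with pytest.raises(ValueError):
            lr_multiplier(101, ScheduleConfig())

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ScheduleConfig(warmup_epoch=100, num_epoch=100)


class TestSplitCohort:
    def test_reference_sizes_at_311(self):
        m = make_labelled_manifest(311, 212)
        plan = split_cohort(m, k=5, seed=0)
        assert len(plan.train_ids) == 198
        assert len(plan.val_ids) == 50
        assert len(plan.test_ids) == 63

    def test_deterministic(self):
        m = make_labelled_manifest(100, 60)
        a = split_cohort(m, k=5, seed=3)
        b = split_cohort(m, k=5, seed=3)
        assert a.train_ids == b.train_ids
        assert a.folds == b.folds

    def test_partitions_disjoint_and_total(self):
        m = make_labelled_manifest(120, 80)
        plan = split_cohort(m, k=5, seed=1)
        all_ids = plan.train_ids + plan.val_ids + plan.test_ids
        assert len(set(all_ids)) == 120

    def test_folds_fix_test_set(self):
        m = make_labelled_manifest(120, 80)
        plan = split_cohort(m, k=5, seed=1)
        trval = set(plan.train_ids) | set(plan.val_ids)
        for tr, va in plan.folds:
            assert set(tr) | set(va) == trval
            assert not (set(tr) | set(va)) & set(plan.test_ids)

    def test_stratification_within_5_points(self):
        m = make_labelled_manifest(311, 212)
        frac = 212 / 311
        for seed in range(20):
            plan = split_cohort(m, k=0, seed=seed)
            for part in (plan.train_ids, plan.val_ids, plan.test_ids):
                labels = [int(i[1:]) < 212 for i in part]
                assert abs(np.mean(labels) - frac) < 0.05


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        config = PhantomConfig(volume_shape=(32, 32, 12), spacing=(1, 1, 3),
                               lesion_radius_range=(6, 9),
                               lesion_z_radius_range=(2, 4),
                               effect_t1=4.0, effect_t2=4.0,
                               t2_misalignment=(0, 0), seed=5)
        manifest, _ = generate_cohort(16, 0.5, config)
        dataset = SliceDataset(manifest, resolution=(32, 32),
                               slice_policy="central")
        split = split_cohort(manifest, proportions=(8, 4, 4), k=0, seed=0)
        return manifest, dataset, split

    def _run(self, dataset, split, seed=0, epochs=2):
        model = build_model(ModelConfig(
            extractor=reduced_extractor_config((32, 32)), seed=seed))
        schedule = ScheduleConfig(warmup_epoch=1, num_epoch=epochs)
        return train(model, dataset, split,
                     TrainConfig(batch_size=8, seed=seed), schedule)

    def test_same_seed_identical_history(self, tiny_setup):
        _, dataset, split = tiny_setup
        _, h1 = self._run(dataset, split)
        _, h2 = self._run(dataset, split)
        assert h1["L"].tolist() == h2["L"].tolist()
        assert h1["val_auc"].tolist() == h2["val_auc"].tolist()

    def test_loss_identity_per_epoch(self, tiny_setup):
        _, dataset, split = tiny_setup
        _, h = self._run(dataset, split)
        np.testing.assert_allclose(h["L"], h["L_ALL"] + h["L_T1"] + h["L_T2"],
                                   atol=1e-9)

    def test_descent_on_separable_data(self, tiny_setup):
        _, dataset, split = tiny_setup
        _, h = self._run(dataset, split, epochs=6)
        assert h["L"].iloc[-1] < h["L"].iloc[0]

    def test_predict_cohort_pure(self, tiny_setup):
        _, dataset, split = tiny_setup
        model, _ = self._run(dataset, split)
        before = [p.data.copy() for p in model.parameters()]
        predict_cohort(model, dataset, split.test_ids)
        after = [p.data for p in model.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))
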