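"""Schedules, dequantization, EMA, gradient accumulation, and the joint objective."""

import numpy as np
import pytest

from mvflow._autodiff import Adamax, EMA, Tensor
from mvflow.alignment import AlignmentConfig, build_projectors
from mvflow.flow_tabular import build_tabular_flow
from mvflow.trainer import (
    AugmentationSchedule,
    MultiviewBatch,
    ScheduleEntry,
    TrainerState,
    TrainingConfig,
    accumulate_and_step,
    dequantize,
    ema_update,
    parse_schedule_entry,
    schedule_value,
    total_loss,
    train_tabular,
)


class TestSchedules:
    @pytest.mark.parametrize("kind", ["linear", "cos", "exp"])
    def test_endpoints(self, kind):
        s = AugmentationSchedule({"a": ScheduleEntry(kind, 0.5, 0.1)})
        assert schedule_value(s, "a", 0.0) == pytest.approx(0.5)
        assert schedule_value(s, "a", 1.0) == pytest.approx(0.1)
        # held constant after the horizon
        assert schedule_value(s, "a", 3.0) == pytest.approx(0.1)

    def test_cosine_midpoint_is_average(self):
        s = AugmentationSchedule({"a": ScheduleEntry("cos", 0.05, 0.02)})
        assert schedule_value(s, "a", 0.5) == pytest.approx(0.035)

    def test_grammar_parses_paper_style_entry(self):
        name, e = parse_schedule_entry("noise_std: cos:0.05->0.02")
        assert name == "noise_std" and e.kind == "cos"
        assert (e.v0, e.v1) == (0.05, 0.02)

    def test_exponential_with_nonpositive_endpoint_rejected(self):
        with pytest.raises(ValueError):
            ScheduleEntry("exp", 0.0, 0.1)

    def test_value_bounded_between_endpoints(self):
        s = AugmentationSchedule({"a": ScheduleEntry("exp", 6.0, 0.2)})
        for t in np.linspace(0, 1, 21):
            v = schedule_value(s, "a", float(t))
            assert 0.2 <= v <= 6.0

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            schedule_value(AugmentationSchedule(), "missing", 0.5)


class TestDequantize:
    def test_zero_amplitude_is_identity_bit_exact(self, rng):
        x = rng.standard_normal((10, 4))
        assert np.array_equal(dequantize(x, 0.0, seed=1), x)

    def test_seed_reproducibility(self, rng):
        x = rng.standard_normal((10, 4))
        assert np.array_equal(dequantize(x, 0.1, seed=7), dequantize(x, 0.1, seed=7))

    def test_gaussian_noise_sd_matches_amplitude(self, rng):
        x = np.zeros((100_000, 1))
        noise = dequantize(x, 0.3, seed=0) - x
        assert noise.std() == pytest.approx(0.3, rel=0.05)

    def test_uniform_noise_bounded(self, rng):
        x = np.zeros((1000, 4))
        noise = dequantize(x, 0.2, seed=0, kind="uniform")
        assert np.all((noise >= 0) & (noise < 0.2))


class TestEMA:
    def test_zero_decay_tracks_current_params(self):
        out = ema_update([np.ones(3)], [np.full(3, 7.0)], decay=0.0)
        assert np.allclose(out[0], 7.0)

    def test_closed_form_after_k_steps(self):
        decay, k = 0.9, 15
        ema0, p = np.array([2.0]), np.array([5.0])
        ema = ema0
        for _ in range(k):
            ema = ema_update([ema], [p], decay)[0]
        expected = decay**k * ema0 + (1 - decay**k) * p
        assert np.allclose(ema, expected, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ema_update([np.ones(3)], [np.ones(4)], 0.5)


def _two_view_state(rng, weight=0.0, clip=1e9):
    data = {"v0": rng.standard_normal((32, 4)), "v1": rng.standard_normal((32, 4))}
    flows = {v: build_tabular_flow(4, 2, 16, seed=i) for i, v in enumerate(sorted(data))}
    pert = np.random.default_rng(99)
    for f in flows.values():
        for p in f.parameters():
            p.data += 0.05 * pert.standard_normal(p.data.shape)
    cfg = AlignmentConfig(method="vicreg", weight=weight)
    projectors = None
    params = [p for f in flows.values() for p in f.parameters()]
    if weight > 0:
        projectors = build_projectors({v: 4 for v in data}, hidden=8, output_dim=4)
        params += [p for pj in projectors.values() for p in pj.parameters()]
    state = TrainerState(flows=flows, projectors=projectors, align_cfg=cfg,
                         optimizer=Adamax(params, lr=1e-3),
                         ema=EMA(params, 0.99), clip_norm=clip)
    return state, data


class TestAccumulation:
    def test_accumulated_gradient_matches_full_batch_at_lambda_zero(self, rng):
        s1, data = _two_view_state(rng)
        mbs = [MultiviewBatch({v: data[v][i * 8:(i + 1) * 8] for v in data})
               for i in range(4)]
        accumulate_and_step(s1, mbs)
        g1 = np.concatenate([p.grad.ravel() for p in s1.optimizer.params])
        s2, _ = _two_view_state(rng)
        accumulate_and_step(s2, [MultiviewBatch(data)])
        g2 = np.concatenate([p.grad.ravel() for p in s2.optimizer.params])
        assert np.max(np.abs(g1 - g2)) <= 1e-5 * max(np.max(np.abs(g2)), 1.0)

    def test_alignment_statistics_are_per_microbatch(self, rng):
        # with lambda > 0 the microbatched objective differs from full-batch
        # because covariance/negative statistics are local to each microbatch
        s1, data = _two_view_state(rng, weight=1.0)
        mbs = [MultiviewBatch({v: data[v][i * 8:(i + 1) * 8] for v in data})
               for i in range(4)]
        r_micro = accumulate_and_step(s1, mbs)
        s2, _ = _two_view_state(rng, weight=1.0)
        r_full = accumulate_and_step(s2, [MultiviewBatch(data)])
        assert r_micro["align"] != pytest.approx(r_full["align"])

    def test_clip_norm_bounds_post_clip_gradient(self, rng):
        state, data = _two_view_state(rng, clip=0.1)
        accumulate_and_step(state, [MultiviewBatch(data)])
        post = np.sqrt(sum(float((p.grad**2).sum())
                           for p in state.optimizer.params if p.grad is not None))
        assert post <= 0.1 + 1e-6

    def test_empty_microbatch_rejected(self, rng):
        state, data = _two_view_state(rng)
        empty = MultiviewBatch({v: data[v][:0] for v in data})
        with pytest.raises(ValueError):
            accumulate_and_step(state, [empty])


class TestTotalLoss:
    def test_lambda_zero_reduces_to_pure_likelihood(self, rng):
        state, data = _two_view_state(rng)
        batch = MultiviewBatch(data)
        loss, bd = total_loss(state.flows, None, AlignmentConfig(weight=0.0), batch)
        manual = sum(
            float(-(f.log_prob(Tensor(data[v])).data.mean()))
            for v, f in state.flows.items()
        )
        assert loss.item() == manual  # bit-for-bit
        assert bd["align"] == 0.0

    def test_doubling_lambda_scales_only_the_alignment_term(self, rng):
        state, data = _two_view_state(rng, weight=1.0)
        batch = MultiviewBatch(data)
        l1, b1 = total_loss(state.flows, state.projectors,
                            AlignmentConfig(method="vicreg", weight=1.0), batch)
        l2, b2 = total_loss(state.flows, state.projectors,
                            AlignmentConfig(method="vicreg", weight=2.0), batch)
        assert b1["nll"] == pytest.approx(b2["nll"])
        assert l2.item() - l1.item() == pytest.approx(b1["align"], rel=1e-9)

    def test_single_view_pure_likelihood(self, rng):
        flow = build_tabular_flow(4, 2, 8, seed=0)
        x = rng.standard_normal((16, 4))
        loss, _ = total_loss({"v": flow}, None, AlignmentConfig(weight=0.0),
                             MultiviewBatch({"v": x}))
        assert loss.item() == pytest.approx(
            float(-(flow.log_prob(Tensor(x)).data.mean()))
        )

    def test_view_mismatch_rejected(self, rng):
        state, data = _two_view_state(rng)
        with pytest.raises(ValueError):
            total_loss(state.flows, None, AlignmentConfig(weight=0.0),
                       MultiviewBatch({"v0": data["v0"]}))

    def test_mismatched_batch_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            MultiviewBatch({"a": rng.standard_normal((4, 2)),
                            "b": rng.standard_normal((5, 2))})


class TestTrainTabular:
    def test_deterministic_loss_trajectory_under_fixed_seed(self, rng):
        x = rng.standard_normal((100, 3))
        cfg = TrainingConfig(iterations=20, microbatch_size=16, seed=11,
                             coupling_depth=2, hidden_channels=8, val_interval=10)
        h1 = train_tabular({"v": x}, cfg).history
        h2 = train_tabular({"v": x}, cfg).history
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_validation_nll_improves_from_initialization(self, rng):
        x = rng.standard_normal((300, 3)) @ np.diag([3.0, 1.0, 0.3])
        cfg = TrainingConfig(iterations=300, microbatch_size=64,
                             learning_rate=3e-3, warmup_steps=30, seed=0,
                             coupling_depth=3, hidden_channels=16, val_interval=50)
        res = train_tabular({"v": x}, cfg)
        vals = [h["val_nll"] for h in res.history if "val_nll" in h]
        assert vals[-1] < vals[0]

    def test_alignment_raises_shared_coordinate_correlation(self):
        # end-to-end smoke: lambda > 0 beats lambda = 0 on projected shared
        # coordinates, majority over 3 seeds
        from mvflow.synthetic import SharedFactorSpec, make_multiview_tabular

        wins = 0
        for seed in range(3):
            tv = make_multiview_tabular(
                SharedFactorSpec(n_subjects=300, shared_dim=2, private_dim=2,
                                 view_dims=(6, 6), noise_sd=0.1, seed=seed)
            )
            common = dict(iterations=250, microbatch_size=64, learning_rate=3e-3,
                          warmup_steps=30, coupling_depth=2, hidden_channels=16,
                          seed=seed, val_interval=100, projector_hidden=32,
                          projector_dim=8)
            res0 = train_tabular(tv.views, TrainingConfig(
                **common, alignment=AlignmentConfig(method="vicreg", weight=0.0)))
            res1 = train_tabular(tv.views, TrainingConfig(
                **common, alignment=AlignmentConfig(method="vicreg", weight=0.01)))

            def corr(res):
                projs = res.projectors or build_projectors(
                    {v: 6 for v in tv.views}, hidden=32, output_dim=8, seed=seed)
                es = []
                for v in sorted(tv.views):
                    z = res.flows[v].encode(tv.views[v][res.val_idx])
                    es.append(projs[v](Tensor(z)).data)
                a, b = es
                a = (a - a.mean(0)) / (a.std(0) + 1e-9)
                b = (b - b.mean(0)) / (b.std(0) + 1e-9)
                return float(np.mean(np.abs((a * b).mean(0))))

            wins += corr(res1) > corr(res0)
        assert wins >= 2
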