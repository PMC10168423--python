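"""Losses, gradient penalty, the three-step epoch, scheduling, checkpoints."""

import dataclasses

import numpy as np
import pytest

import surf2vol.autodiff as ad
from surf2vol import (
    PhantomParams,
    TrainConfig,
    adversarial_generator_loss,
    apply_normalization,
    critic_loss_gp,
    cycle_losses,
    fit,
    fit_normalization,
    generate_patient_series,
    gradient_penalty,
    identity_loss,
    infer,
    refinement_loss,
)
from surf2vol.training import Checkpoint, TrainState, train_epoch

identity_net = lambda t: t
zero_net = lambda t: ad.mul(t, ad.constant(0.0))


def const_field(value, shape=(1, 1, 4, 4, 4)):
    return ad.constant(np.full(shape, value, dtype=np.float32))


class TestCycleAndIdentityLosses:
    def test_identity_fixed_point(self):
        x = const_field(0.3)
        l_surf, l_vol = cycle_losses(identity_net, identity_net, x, x)
        assert l_surf.item() == pytest.approx(0.0)
        assert l_vol.item() == pytest.approx(0.0)

    def test_constant_verifier_hand_value(self):
        # GV == c everywhere, X == x constant: both Lsurf terms equal |c - x|
        c, xval = 0.8, 0.25
        gv = lambda t: const_field(c, t.shape)
        x = const_field(xval)
        y = const_field(0.5)
        l_surf, _ = cycle_losses(identity_net, gv, x, y)
        assert l_surf.item() == pytest.approx(abs(c - xval), abs=1e-6)

    def test_nonnegative_on_random_fields(self):
        rng = np.random.default_rng(0)
        x = ad.constant(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        y = ad.constant(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        l_surf, l_vol = cycle_losses(identity_net, identity_net, x, y)
        assert np.isfinite(l_surf.item()) and l_surf.item() >= 0
        assert np.isfinite(l_vol.item()) and l_vol.item() >= 0

    def test_identity_loss_zero_for_identity_nets(self):
        x = const_field(0.2)
        y = const_field(0.7)
        assert identity_loss(identity_net, identity_net, x, y).item() == pytest.approx(0.0)

    def test_identity_loss_zero_map_hand_value(self):
        # GR == 0 on y == 0.5 contributes 0.5*|0.5| = 0.25
        x = const_field(0.1)
        y = const_field(0.5)
        gv_cost = 0.5 * 0.1  # GV == 0 on x
        val = identity_loss(zero_net, zero_net, x, y).item()
        assert val == pytest.approx(0.25 + gv_cost, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cycle_losses(identity_net, identity_net, const_field(0), const_field(0, (1, 1, 2, 4, 4)))


class TestAdversarialLoss:
    def test_zero_critics(self):
        loss = adversarial_generator_loss(zero_net, zero_net, const_field(0.3), const_field(0.3))
        assert loss.item() == pytest.approx(0.0)

    def test_mean_critic_hand_value(self):
        mean_critic = lambda t: ad.mean(t, axis=(1, 2, 3, 4))
        loss = adversarial_generator_loss(mean_critic, zero_net, const_field(0.2), const_field(0.9))
        assert loss.item() == pytest.approx(-0.2, abs=1e-6)

    def test_decreasing_in_critic_score(self):
        mean_critic = lambda t: ad.mean(t, axis=(1, 2, 3, 4))
        low = adversarial_generator_loss(mean_critic, zero_net, const_field(0.1), const_field(0))
        high = adversarial_generator_loss(mean_critic, zero_net, const_field(0.9), const_field(0))
        assert high.item() < low.item()


class LinearCritic:
    """D(x) = w . flatten(x), a 1-Lipschitz-violating test critic."""

    def __init__(self, w):
        self.w = ad.constant(w.reshape(1, -1).T.astype(np.float32))

    def __call__(self, t):
        flat = ad.reshape(t, (t.shape[0], -1))
        return ad.matmul(flat, self.w)


class TestGradientPenalty:
    def test_linear_critic_closed_form(self):
        """For linear D with ||w|| = 3 and lambda = 10 the penalty is
        10*(3-1)^2 = 40 regardless of the mixing epsilon."""
        rng = np.random.default_rng(0)
        shape = (2, 1, 4, 4, 4)
        w = rng.normal(size=np.prod(shape[1:]))
        w *= 3.0 / np.linalg.norm(w)
        critic = LinearCritic(w)
        real = ad.constant(rng.normal(size=shape).astype(np.float32))
        fake = ad.constant(rng.normal(size=shape).astype(np.float32))
        for seed in (0, 1, 2):
            pen, eps = gradient_penalty(critic, real, fake, 10.0, 0.2, np.random.default_rng(seed))
            assert pen.item() == pytest.approx(40.0, abs=1e-3)
            assert np.all((eps >= 0) & (eps <= 1))

    def test_zero_lambda_constant_critic(self):
        critic = lambda t: ad.mul(ad.mean(t, axis=(1, 2, 3, 4)), ad.constant(0.0))
        loss = critic_loss_gp(
            critic, const_field(0.5, (1, 1, 4, 4, 4)), const_field(0.1, (1, 1, 4, 4, 4)),
            lambda_gp=0.0, rng=np.random.default_rng(0),
        )
        assert loss.item() == pytest.approx(0.0, abs=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            gradient_penalty(
                zero_net, const_field(0), const_field(0), -1.0, 0.2, np.random.default_rng(0)
            )

    def test_beta_draws_bimodal(self):
        rng = np.random.default_rng(0)
        draws = rng.beta(0.2, 0.2, size=4000)
        assert np.all((draws >= 0) & (draws <= 1))
        # Beta(0.2, 0.2) concentrates near the endpoints
        assert np.mean((draws < 0.1) | (draws > 0.9)) > 0.5


class TestRefinementLoss:
    def test_exact_refiner(self):
        y = const_field(0.3)
        assert refinement_loss(identity_net, y, y).item() == pytest.approx(0.0)

    def test_zero_refiner_constant_target(self):
        y = const_field(0.3)
        assert refinement_loss(zero_net, y, y).item() == pytest.approx(0.3, abs=1e-6)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            refinement_loss(identity_net, const_field(0), const_field(0, (1, 1, 2, 4, 4)))


def tiny_dataset(tiny_params, n_phases=4, seed=5):
    series = generate_patient_series(tiny_params, n_phases, seed=seed)
    grids = [g for _, v, s in series.phases for g in (v, s)]
    rec = fit_normalization(grids)
    pairs = [
        (apply_normalization(s, rec), apply_normalization(v, rec))
        for _, v, s in series.phases
    ]
    return pairs, rec


class TestTrainEpochAndFit:
    def test_epoch_smoke_and_decomposition(self, tiny_params):
        pairs, rec = tiny_dataset(tiny_params)
        cfg = TrainConfig(
            epochs=1, shape=(16, 32, 16), width_scale=1 / 8, seed=1,
            augment_probability=0.0, batch_coarse=2,
        )
        state = TrainState.create(cfg)
        state, report = train_epoch(state, pairs[:2], cfg)
        vals = report.as_dict()
        assert all(np.isfinite(v) for v in vals.values())
        assert report.gp_vol >= 0 and report.gp_surf >= 0 and report.l_refine >= 0
        # with a single batch per epoch the report is the per-step record
        assert report.l_total == pytest.approx(
            report.l_surf + report.l_vol + report.l_adv + report.l_identity, rel=1e-5
        )

    def test_epoch_determinism(self, tiny_params):
        pairs, _ = tiny_dataset(tiny_params)
        cfg = TrainConfig(epochs=1, shape=(16, 32, 16), width_scale=1 / 8, seed=3)
        reports = []
        for _ in range(2):
            state = TrainState.create(cfg)
            _, rep = train_epoch(state, pairs[:2], cfg)
            reports.append(rep.as_dict())
        assert reports[0] == reports[1]

    def test_empty_dataset(self, tiny_params):
        cfg = TrainConfig(epochs=1, shape=(16, 32, 16), width_scale=1 / 8)
        with pytest.raises(ValueError):
            train_epoch(TrainState.create(cfg), [], cfg)

    def test_lr_schedule_closed_form(self):
        cfg = TrainConfig(lr=1e-4, lr_decay=0.93, lr_decay_every=50)
        assert cfg.lr_at(49) == pytest.approx(1e-4)
        assert cfg.lr_at(50) == pytest.approx(0.93e-4)
        assert cfg.lr_at(100) == pytest.approx(0.8649e-4)

    def test_fit_needs_validation(self, tiny_params):
        pairs, rec = tiny_dataset(tiny_params)
        cfg = TrainConfig(epochs=1, shape=(16, 32, 16), width_scale=1 / 8)
        with pytest.raises(ValueError):
            fit(pairs[:2], None, cfg, rec)

    def test_loss_descent_on_toy_task(self, tiny_params):
        """A learnable degenerate task: the refinement loss decreases."""
        pairs, rec = tiny_dataset(tiny_params)
        cfg = TrainConfig(
            epochs=50, shape=(16, 32, 16), width_scale=1 / 8, seed=2,
            validate_every=25, augment_probability=0.0,
        )
        ck = fit(pairs[:3], pairs[3], cfg, rec)
        first = float(ck.history[0]["l_refine"])
        last = float(ck.history[-1]["l_refine"])
        assert last < first

    def test_checkpoint_argmin_and_bit_exact_reload(self, tiny_params, tmp_path):
        pairs, rec = tiny_dataset(tiny_params)
        cfg = TrainConfig(
            epochs=6, shape=(16, 32, 16), width_scale=1 / 8, seed=4, validate_every=2,
        )
        ck = fit(pairs[:3], pairs[3], cfg, rec)
        recorded = [float(r["val_refine"]) for r in ck.history if "val_refine" in r]
        assert ck.validation_loss == pytest.approx(min(recorded))
        series = generate_patient_series(tiny_params, 4, seed=5)
        surf = series.phases[3][2]
        out1 = infer(surf, ck)
        ck.save(tmp_path / "ckpt")
        out2 = infer(surf, Checkpoint.load(tmp_path / "ckpt"))
        assert np.array_equal(out1.intensities, out2.intensities)

    def test_infer_shape_mismatch(self, tiny_params):
        pairs, rec = tiny_dataset(tiny_params)
        cfg = TrainConfig(epochs=1, shape=(16, 32, 16), width_scale=1 / 8, validate_every=1)
        ck = fit(pairs[:2], pairs[2], cfg, rec)
        series = generate_patient_series(
            dataclasses.replace(tiny_params, shape=(20, 32, 16), spacing=(6.0, 5.0, 6.0)),
            2, seed=1,
        )
        with pytest.raises(ValueError):
            infer(series.phases[0][2], ck)


def test_critic_loss_decreases_with_frozen_generators():
    """With generators frozen, repeated critic updates reduce the critic's
    Wasserstein-GP loss on a fixed real/fake pair.

    Real samples are spatially smooth, fake ones are white noise: instance
    normalization inside the critic discards per-sample mean/scale, so the
    two classes must differ in structure for the property to be observable.
    """
    from scipy import ndimage as ndi

    import surf2vol.autodiff as a
    from surf2vol.networks import NetworkSpec, build_critic
    from surf2vol.training import Adam, gradient_penalty

    rng = np.random.default_rng(0)
    real = np.stack(
        [ndi.gaussian_filter(rng.normal(size=(16, 32, 16)), 2.5) for _ in range(2)]
    )[:, None]
    real = (real / real.std()).astype(np.float32) * 0.2 + 0.4
    fake = rng.normal(0.4, 0.2, size=(2, 1, 16, 32, 16)).astype(np.float32)
    critic = build_critic(
        NetworkSpec("critic", input_shape=(16, 32, 16), width_scale=1 / 8), seed=3
    )
    opt = Adam(critic.parameters, lr=1e-3, betas=(0.5, 0.999))
    losses = []
    for step in range(30):
        pen, _ = gradient_penalty(
            critic, real, fake, 10.0, 0.2, np.random.default_rng(step)
        )
        loss = a.add(
            a.sub(a.mean(critic(a.constant(fake))), a.mean(critic(a.constant(real)))),
            pen,
        )
        losses.append(loss.item())
        opt.step(a.grad(loss, opt.params))
    assert np.mean(losses[-5:]) < np.mean(losses[:5])
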