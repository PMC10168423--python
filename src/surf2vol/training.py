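"""Losses, the three-step training schedule, model selection and inference.

Each epoch runs three steps over the (augmented) training set:

1. update the reconstruction/verification generators GR, GV on
   ``L = Lsurf + Lvol + Ladv + Lidentity`` at half resolution, batch 2, where
   Lsurf/Lvol are the cycle-consistency MAE terms, Ladv is the standard
   Wasserstein generator objective ``-DR(GR(x)) - DV(GV(y))`` and Lidentity
   keeps each generator close to the identity on its own output domain;
2. update the critics DR, DV on the Wasserstein loss with gradient penalty
   ``D(fake) - D(real) + lambda * (||grad_mix D(mix)||_2 - 1)^2`` with the
   mixing weight drawn per sample from Beta(0.2, 0.2);
3. update the full-resolution refiner on MAE against the ground-truth
   volume, consuming trilinearly up-sampled coarse reconstructions from the
   current (frozen) coarse stage, batch 1, reshuffled.

Training runs with Adam (lr 1e-4, betas (0.5, 0.999)); the learning rate
decays to 0.93 of its value every 50 epochs; the refinement loss on a
held-out validation phase is evaluated every 10 epochs and the parameters
with the smallest validation refinement loss are kept as the final model.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .grids import SurfaceMatrix, VolumeGrid
from .networks import NetworkSpec, build_critic, build_generator, build_refiner
from .preprocess import (
    AugmentationPolicy,
    NormalizationRecord,
    augment_pair,
    downsample_half,
    invert_normalization,
    upsample_to,
)

__all__ = [
    "TrainConfig",
    "LossReport",
    "Checkpoint",
    "TrainState",
    "Adam",
    "mae_loss",
    "cycle_losses",
    "identity_loss",
    "adversarial_generator_loss",
    "gradient_penalty",
    "critic_loss_gp",
    "refinement_loss",
    "train_epoch",
    "fit",
    "infer",
]


@dataclasses.dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the full-scale protocol."""

    epochs: int = 2000
    batch_coarse: int = 2
    batch_refine: int = 1
    lr: float = 1e-4
    lr_decay: float = 0.93
    lr_decay_every: int = 50
    lambda_gp: float = 10.0
    beta_shape: float = 0.2
    adversarial_weight: float = 1.0
    identity_variant: str = "standard"  # or "as_printed"
    adam_betas: tuple = (0.5, 0.999)
    validate_every: int = 10
    seed: int = 0
    shape: tuple = (160, 256, 160)
    width_scale: float = 1.0
    use_skips: bool = True
    augment_probability: float = 0.5
    augment_shear: float = 0.1
    augment_rotation_deg: float = 10.0
    augment_scale: float = 0.1

    def __post_init__(self):
        if min(self.epochs, self.batch_coarse, self.batch_refine) < 1:
            raise ValueError("epochs and batch sizes must be positive")
        if self.lr <= 0 or not (0.0 < self.lr_decay <= 1.0):
            raise ValueError("lr must be positive and lr_decay in (0, 1]")
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be non-negative")
        if self.identity_variant not in ("standard", "as_printed"):
            raise ValueError("identity_variant must be 'standard' or 'as_printed'")

    def lr_at(self, epoch: int) -> float:
        """Stepwise decayed learning rate at a given (0-based) epoch."""
        return self.lr * self.lr_decay ** (epoch // self.lr_decay_every)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["adam_betas"] = tuple(d.get("adam_betas", (0.5, 0.999)))
        d["shape"] = tuple(d.get("shape", (160, 256, 160)))
        return cls(**d)


@dataclasses.dataclass
class LossReport:
    """Per-epoch mean losses; ``l_total`` is the exact sum of the four
    generator components at every step (averaged the same way)."""

    l_surf: float = 0.0
    l_vol: float = 0.0
    l_adv: float = 0.0
    l_identity: float = 0.0
    l_total: float = 0.0
    l_critic_vol: float = 0.0
    l_critic_surf: float = 0.0
    gp_vol: float = 0.0
    gp_surf: float = 0.0
    l_refine: float = 0.0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def mae_loss(pred: ad.Tensor, target: ad.Tensor) -> ad.Tensor:
    """Voxel-mean absolute difference over the full grid."""
    return ad.mean(ad.absolute(ad.sub(pred, target)))


def _half(t: ad.Tensor) -> ad.Tensor:
    return ad.mul(ad.constant(0.5), t)


def cycle_losses(GR, GV, x_down, y_down):
    """Cycle-consistency losses (surface and volume directions).

    ``l_surf = 0.5*MAE(GV(y), x) + 0.5*MAE(GV(GR(x)), x)`` and symmetrically
    for ``l_vol``. ``GR``/``GV`` may be any callables Tensor -> Tensor.
    """
    x = ad.as_tensor(x_down)
    y = ad.as_tensor(y_down)
    if x.shape != y.shape:
        raise ValueError("surface/volume grids must share shape")
    y_fake = GR(x)
    x_fake = GV(y)
    l_surf = ad.add(_half(mae_loss(x_fake, x)), _half(mae_loss(GV(y_fake), x)))
    l_vol = ad.add(_half(mae_loss(y_fake, y)), _half(mae_loss(GR(x_fake), y)))
    return l_surf, l_vol


def identity_loss(GR, GV, x_down, y_down, variant: str = "standard") -> ad.Tensor:
    """Identity regularizer: each generator should leave its own output
    domain unchanged. The conventional form is
    ``0.5*MAE(GR(y), y) + 0.5*MAE(GV(x), x)``; ``variant="as_printed"``
    instead feeds GR its own reconstruction GR(x)."""
    x = ad.as_tensor(x_down)
    y = ad.as_tensor(y_down)
    if x.shape != y.shape:
        raise ValueError("surface/volume grids must share shape")
    if variant == "as_printed":
        first = _half(mae_loss(GR(GR(x)), y))
    else:
        first = _half(mae_loss(GR(y), y))
    return ad.add(first, _half(mae_loss(GV(x), x)))


def adversarial_generator_loss(DR, DV, y_pred_down, x_pred_down) -> ad.Tensor:
    """Standard Wasserstein generator objective: raise the critics' scores
    of generated samples, ``-DR(y_pred) - DV(x_pred)``."""
    return ad.sub(
        ad.neg(ad.mean(DR(ad.as_tensor(y_pred_down)))),
        ad.mean(DV(ad.as_tensor(x_pred_down))),
    )


def gradient_penalty(D, real, fake, lambda_gp, beta_shape, rng):
    """lambda * mean_i (||grad_mix D(mix_i)||_2 - 1)^2 with per-sample
    Beta(beta_shape, beta_shape) mixing weights.

    Returns (penalty Tensor, epsilon draws). The gradient is taken with
    respect to the mixed sample, so the critic must be built from
    twice-differentiable primitives.
    """
    real = ad.as_tensor(real)
    fake = ad.as_tensor(fake)
    if real.shape != fake.shape:
        raise ValueError("real/fake shapes must match")
    if lambda_gp < 0:
        raise ValueError("lambda_gp must be non-negative")
    n = real.shape[0]
    eps = rng.beta(beta_shape, beta_shape, size=(n, 1, 1, 1, 1)).astype(np.float32)
    mix = ad.parameter(eps * fake.data + (1.0 - eps) * real.data)
    (gmix,) = ad.grad(ad.sum_(D(mix)), [mix])
    # the epsilon keeps sqrt differentiable when the critic's input gradient
    # underflows to zero (fresh critics with small init)
    sq = ad.add(ad.sum_(ad.mul(gmix, gmix), axis=(1, 2, 3, 4)), ad.constant(1e-12))
    norms = ad.power(sq, 0.5)
    d = ad.sub(norms, ad.constant(1.0))
    return ad.mul(ad.constant(float(lambda_gp)), ad.mean(ad.mul(d, d))), eps


def critic_loss_gp(D, real, fake, lambda_gp=10.0, beta_shape=0.2, rng=None) -> ad.Tensor:
    """Wasserstein critic loss with gradient penalty:
    ``D(fake) - D(real) + lambda*(||grad D(mix)|| - 1)^2``."""
    if rng is None:
        rng = np.random.default_rng(0)
    real = ad.as_tensor(real)
    fake = ad.as_tensor(fake)
    pen, _ = gradient_penalty(D, real, fake, lambda_gp, beta_shape, rng)
    return ad.add(ad.sub(ad.mean(D(fake)), ad.mean(D(real))), pen)


def refinement_loss(refiner, y_coarse, y_true) -> ad.Tensor:
    """MAE between the refined volume and the ground truth."""
    y_coarse = ad.as_tensor(y_coarse)
    y_true = ad.as_tensor(y_true)
    if y_coarse.shape != y_true.shape:
        raise ValueError("coarse/true shapes must match")
    return mae_loss(refiner(y_coarse), y_true)


# ---------------------------------------------------------------------------
# optimizer & state
# ---------------------------------------------------------------------------


class Adam:
    """Standard Adam on a list of parameter Tensors."""

    def __init__(self, params, lr=1e-4, betas=(0.5, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, ad.Tensor) else g
            m *= self.b1
            m += (1.0 - self.b1) * gd
            v *= self.b2
            v += (1.0 - self.b2) * gd * gd
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclasses.dataclass
class TrainState:
    GR: object
    GV: object
    DR: object
    DV: object
    refiner: object
    opt_gen: Adam
    opt_dr: Adam
    opt_dv: Adam
    opt_ref: Adam
    epoch: int = 0

    @classmethod
    def create(cls, config: TrainConfig, output_bias: float | None = None) -> "TrainState":
        h, w, l = config.shape
        coarse_shape = (h // 2, w // 2, l // 2)
        gen_spec = NetworkSpec(
            "generator", input_shape=coarse_shape, width_scale=config.width_scale
        )
        critic_spec = NetworkSpec(
            "critic", input_shape=coarse_shape, width_scale=config.width_scale
        )
        ref_spec = NetworkSpec(
            "refiner",
            input_shape=config.shape,
            width_scale=config.width_scale,
            use_skips=config.use_skips,
        )
        GR = build_generator(gen_spec, seed=config.seed * 4 + 0, output_bias=output_bias)
        GV = build_generator(gen_spec, seed=config.seed * 4 + 1, output_bias=output_bias)
        DR = build_critic(critic_spec, seed=config.seed * 4 + 2)
        DV = build_critic(critic_spec, seed=config.seed * 4 + 3)
        refiner = build_refiner(ref_spec, seed=config.seed * 4 + 4)
        return cls(
            GR,
            GV,
            DR,
            DV,
            refiner,
            opt_gen=Adam(GR.parameters + GV.parameters, config.lr, config.adam_betas),
            opt_dr=Adam(DR.parameters, config.lr, config.adam_betas),
            opt_dv=Adam(DV.parameters, config.lr, config.adam_betas),
            opt_ref=Adam(refiner.parameters, config.lr, config.adam_betas),
        )

    def set_lr(self, lr: float) -> None:
        for opt in (self.opt_gen, self.opt_dr, self.opt_dv, self.opt_ref):
            opt.lr = lr

    def network_states(self) -> dict:
        return {
            name: getattr(self, name).state()
            for name in ("GR", "GV", "DR", "DV", "refiner")
        }

    def load_network_states(self, states: dict) -> None:
        for name, st in states.items():
            getattr(self, name).load_state(st)


# ---------------------------------------------------------------------------
# the three-step epoch
# ---------------------------------------------------------------------------


def _stack(grids) -> np.ndarray:
    return np.stack([g.intensities for g in grids])[:, None].astype(np.float32)


def _prepare_epoch(dataset, config: TrainConfig, rng, norm_fill: float):
    """Seeded per-epoch augmentation + down-sampling of the training pairs."""
    policy = AugmentationPolicy(
        probability=config.augment_probability,
        shear_max=config.augment_shear,
        rotation_max=config.augment_rotation_deg,
        scale_max=config.augment_scale,
    )
    surfs, vols = [], []
    for surf, vol in dataset:
        if policy.probability > 0:
            vol_a, surf_a = augment_pair(vol, surf, policy, rng, fill_value=norm_fill)
        else:
            vol_a, surf_a = vol, surf
        surfs.append(surf_a)
        vols.append(vol_a)
    x_full = _stack(surfs)
    y_full = _stack(vols)
    x_down = np.stack([downsample_half(s).intensities for s in surfs])[:, None]
    y_down = np.stack([downsample_half(v).intensities for v in vols])[:, None]
    return x_full, y_full, x_down.astype(np.float32), y_down.astype(np.float32)


def _coarse_to_refiner_input(state: TrainState, x_down: np.ndarray, full_shape) -> np.ndarray:
    """Up-sampled coarse reconstructions from the frozen coarse stage."""
    with ad.no_grad():
        y_pred_down = state.GR(ad.constant(x_down)).data
    out = np.empty((x_down.shape[0], 1) + tuple(full_shape), dtype=np.float32)
    for i in range(x_down.shape[0]):
        grid = VolumeGrid(y_pred_down[i, 0], (1.0, 1.0, 1.0))
        out[i, 0] = upsample_to(grid, full_shape).intensities
    return out


def train_epoch(state: TrainState, dataset, config: TrainConfig, norm_fill: float = 0.0):
    """Run one three-step epoch over ``dataset`` (normalized (surface, volume)
    pairs at full resolution); returns ``(state, LossReport)``.

    Deterministic given (config.seed, state.epoch).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng([int(config.seed), 1000 + int(state.epoch)])
    x_full, y_full, x_down, y_down = _prepare_epoch(dataset, config, rng, norm_fill)
    n = x_full.shape[0]
    report = LossReport()
    half = ad.constant(0.5)

    # ---- step 1: generators on the cycle + adversarial + identity losses
    order = rng.permutation(n)
    n_batches = 0
    for b0 in range(0, n, config.batch_coarse):
        idx = order[b0 : b0 + config.batch_coarse]
        xt = ad.constant(x_down[idx])
        yt = ad.constant(y_down[idx])
        y_fake = state.GR(xt)
        x_fake = state.GV(yt)
        l_surf = ad.add(
            ad.mul(half, mae_loss(x_fake, xt)),
            ad.mul(half, mae_loss(state.GV(y_fake), xt)),
        )
        l_vol = ad.add(
            ad.mul(half, mae_loss(y_fake, yt)),
            ad.mul(half, mae_loss(state.GR(x_fake), yt)),
        )
        if config.identity_variant == "as_printed":
            id_first = ad.mul(half, mae_loss(state.GR(y_fake), yt))
        else:
            id_first = ad.mul(half, mae_loss(state.GR(yt), yt))
        l_id = ad.add(id_first, ad.mul(half, mae_loss(state.GV(xt), xt)))
        # A ~1-Lipschitz critic has a unit-norm input gradient, i.e. per-voxel
        # influence ~N^(-1/2), while per-voxel MAE gradients scale as N^(-1);
        # dividing the Wasserstein term by sqrt(N) puts both objectives on the
        # same per-voxel scale so the adversarial signal cannot swamp the
        # supervised cycle losses.
        n_vox = float(np.prod(x_down.shape[2:]))
        l_adv = ad.mul(
            ad.constant(config.adversarial_weight / np.sqrt(n_vox)),
            adversarial_generator_loss(state.DR, state.DV, y_fake, x_fake),
        )
        total = ad.add(ad.add(l_surf, l_vol), ad.add(l_adv, l_id))
        grads = ad.grad(total, state.opt_gen.params)
        state.opt_gen.step(grads)
        report.l_surf += l_surf.item()
        report.l_vol += l_vol.item()
        report.l_adv += l_adv.item()
        report.l_identity += l_id.item()
        report.l_total += total.item()
        n_batches += 1
    for f in ("l_surf", "l_vol", "l_adv", "l_identity", "l_total"):
        setattr(report, f, getattr(report, f) / n_batches)

    # ---- step 2: critics on Wasserstein loss with gradient penalty
    for b0 in range(0, n, config.batch_coarse):
        idx = order[b0 : b0 + config.batch_coarse]
        with ad.no_grad():
            y_fake = state.GR(ad.constant(x_down[idx])).data
            x_fake = state.GV(ad.constant(y_down[idx])).data
        for critic, opt, real, fake, f_loss, f_gp in (
            (state.DR, state.opt_dr, y_down[idx], y_fake, "l_critic_vol", "gp_vol"),
            (state.DV, state.opt_dv, x_down[idx], x_fake, "l_critic_surf", "gp_surf"),
        ):
            pen, _ = gradient_penalty(
                critic, real, fake, config.lambda_gp, config.beta_shape, rng
            )
            loss = ad.add(
                ad.sub(
                    ad.mean(critic(ad.constant(fake))),
                    ad.mean(critic(ad.constant(real))),
                ),
                pen,
            )
            grads = ad.grad(loss, opt.params)
            opt.step(grads)
            setattr(report, f_loss, getattr(report, f_loss) + loss.item())
            setattr(report, f_gp, getattr(report, f_gp) + pen.item())
    for f in ("l_critic_vol", "l_critic_surf", "gp_vol", "gp_surf"):
        setattr(report, f, getattr(report, f) / n_batches)

    # ---- step 3: refiner on up-sampled coarse reconstructions, batch 1
    y_coarse = _coarse_to_refiner_input(state, x_down, y_full.shape[2:])
    order3 = rng.permutation(n)
    for b0 in range(0, n, config.batch_refine):
        idx = order3[b0 : b0 + config.batch_refine]
        loss = refinement_loss(
            state.refiner, ad.constant(y_coarse[idx]), ad.constant(y_full[idx])
        )
        grads = ad.grad(loss, state.opt_ref.params)
        state.opt_ref.step(grads)
        report.l_refine += loss.item() * len(idx)
    report.l_refine /= n

    state.epoch += 1
    return state, report


# ---------------------------------------------------------------------------
# fit / checkpoint / inference
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Checkpoint:
    """Everything needed to reproduce inference bit-exactly."""

    network_states: dict
    config: TrainConfig
    normalization: NormalizationRecord
    epoch: int
    validation_loss: float
    history: list = dataclasses.field(default_factory=list)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, arrs in self.network_states.items():
            for i, arr in enumerate(arrs):
                arrays[f"{name}__{i}"] = arr
        np.savez(directory / "parameters.npz", **arrays)
        (directory / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))
        (directory / "normalization.json").write_text(
            json.dumps(self.normalization.to_dict())
        )
        meta = {"epoch": self.epoch, "validation_loss": self.validation_loss}
        (directory / "meta.json").write_text(json.dumps(meta))
        if self.history:
            fields = ["epoch"] + [f.name for f in dataclasses.fields(LossReport)]
            fields += ["val_refine"]
            with open(directory / "history.csv", "w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=fields, restval="")
                writer.writeheader()
                writer.writerows(self.history)
        return directory

    @classmethod
    def load(cls, directory) -> "Checkpoint":
        directory = Path(directory)
        config = TrainConfig.from_dict(
            yaml.safe_load((directory / "config.yaml").read_text())
        )
        norm = NormalizationRecord.from_dict(
            json.loads((directory / "normalization.json").read_text())
        )
        meta = json.loads((directory / "meta.json").read_text())
        data = np.load(directory / "parameters.npz")
        states: dict = {}
        for key in data.files:
            name, i = key.split("__")
            states.setdefault(name, {})[int(i)] = data[key]
        network_states = {
            name: [d[i] for i in sorted(d)] for name, d in states.items()
        }
        history = []
        hist_path = directory / "history.csv"
        if hist_path.exists():
            with open(hist_path) as fh:
                history = list(csv.DictReader(fh))
        return cls(
            network_states,
            config,
            norm,
            meta["epoch"],
            meta["validation_loss"],
            history,
        )

    def build_state(self) -> TrainState:
        state = TrainState.create(self.config)
        state.load_network_states(self.network_states)
        return state


def _validation_refine_loss(state: TrainState, val_pair, config: TrainConfig) -> float:
    surf, vol = val_pair
    x_down = downsample_half(surf).intensities[None, None]
    y_coarse = _coarse_to_refiner_input(state, x_down, vol.shape)
    with ad.no_grad():
        pred = state.refiner(ad.constant(y_coarse)).data
    return float(np.mean(np.abs(pred[0, 0] - vol.intensities)))


def fit(
    train_pairs,
    val_pair,
    config: TrainConfig,
    normalization: NormalizationRecord,
    log=None,
) -> Checkpoint:
    """Train the full pipeline; returns the checkpoint minimizing the
    validation refinement loss.

    ``train_pairs``: list of normalized (SurfaceMatrix, VolumeGrid) pairs at
    the configured full shape; ``val_pair``: one held-out normalized pair.
    """
    if val_pair is None:
        raise ValueError("a validation pair is required for model selection")
    norm_fill = (AIR_HU_FILL - normalization.global_min) / (
        normalization.global_max - normalization.global_min
    )
    # start the generators at the background intensity: most voxels are air
    state = TrainState.create(config, output_bias=norm_fill)
    best_states = state.network_states()
    best_loss = np.inf
    best_epoch = -1
    history = []
    for epoch in range(config.epochs):
        state.set_lr(config.lr_at(epoch))
        state, report = train_epoch(state, train_pairs, config, norm_fill)
        row = {"epoch": epoch, **report.as_dict()}
        if (epoch + 1) % config.validate_every == 0 or epoch == config.epochs - 1:
            val_loss = _validation_refine_loss(state, val_pair, config)
            row["val_refine"] = val_loss
            if val_loss < best_loss:
                best_loss = val_loss
                best_states = state.network_states()
                best_epoch = epoch
        history.append(row)
        if log is not None:
            log(row)
    return Checkpoint(
        network_states=best_states,
        config=config,
        normalization=normalization,
        epoch=best_epoch,
        validation_loss=float(best_loss),
        history=history,
    )


AIR_HU_FILL = -1000.0


def infer(surface: SurfaceMatrix, checkpoint: Checkpoint, state: TrainState | None = None) -> VolumeGrid:
    """Two-stage inference on a geometrically preprocessed HU surface.

    normalize -> downsample -> GR -> trilinear upsample -> refiner ->
    invert normalization; output is a HU volume at the configured shape.
    """
    cfg = checkpoint.config
    if tuple(surface.shape) != tuple(cfg.shape):
        raise ValueError(
            f"surface shape {surface.shape} does not match checkpoint shape {cfg.shape}"
        )
    if state is None:
        state = checkpoint.build_state()
    norm = checkpoint.normalization
    span = norm.global_max - norm.global_min
    x = (surface.intensities - norm.global_min) / span
    x_grid = SurfaceMatrix(x, surface.spacing, background_value=0.0)
    x_down = downsample_half(x_grid).intensities[None, None].astype(np.float32)
    y_coarse = _coarse_to_refiner_input(state, x_down, surface.shape)
    with ad.no_grad():
        pred = state.refiner(ad.constant(y_coarse)).data[0, 0]
    out = VolumeGrid(pred, surface.spacing, surface.origin)
    return invert_normalization(out, norm)
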