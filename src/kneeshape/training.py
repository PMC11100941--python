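"""Autodecoder training: curriculum-weighted clamped L1, latent regularization
with warmup + cyclic annealing, and dual learning-rate schedules.

One latent code per training shape is optimized jointly with the decoder
weights (AdamW, decoupled weight decay on the network only).  Each epoch
visits the shapes in shuffled order; for each shape a sign-balanced batch is
drawn from the bone sample set and from the cartilage sample set, and every
batch supervises both output heads (each sample stores its signed distance to
both surfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .sampling import BatchSpec, SDFSampleSet


# -- schedules ---------------------------------------------------------------
@dataclass(frozen=True)
class CurriculumSchedule:
    """Hard-sample weight lambda, ramped exponentially from 0 to lambda_max.

    The ramp is the normalized convex exponential
    ``lambda(e) = lambda_max * (exp(k e/ramp) - 1) / (exp(k) - 1)``,
    which starts at exactly 0 and reaches exactly lambda_max at ramp_epochs.
    """

    lambda_max: float = 0.2
    ramp_epochs: int = 1800
    k: float = 5.0

    def __call__(self, epoch: int) -> float:
        e = min(epoch, self.ramp_epochs)
        return self.lambda_max * float(np.expm1(self.k * e / self.ramp_epochs) / np.expm1(self.k))


@dataclass(frozen=True)
class AnnealSchedule:
    """Cyclic annealing of the latent-regularization weight with linear warmup.

    beta(t) ramps linearly to 1 over the first half of each cycle and holds at
    1 for the second half; the warmup factor min(e/warmup, 1) multiplies it.
    """

    warmup_epochs: int = 100
    n_cycles: int = 5
    total_epochs: int = 2000

    @property
    def cycle_length(self) -> int:
        return self.total_epochs // self.n_cycles

    def beta(self, t: float) -> float:
        T = self.cycle_length
        t = t % T
        return 2.0 * t / T if t < T / 2 else 1.0

    def __call__(self, epoch: int) -> float:
        warm = min(epoch / self.warmup_epochs, 1.0) if self.warmup_epochs else 1.0
        return warm * self.beta(epoch)


@dataclass(frozen=True)
class LRSchedule:
    """lr(e) = lr0 * f**(e / i) with a continuous exponent."""

    lr0: float
    f: float
    i: float

    def __call__(self, epoch: float) -> float:
        return self.lr0 * self.f ** (epoch / self.i)

    @classmethod
    def network_preset(cls) -> "LRSchedule":
        return cls(lr0=5e-3, f=1.0 / 1.05, i=16.67)

    @classmethod
    def latent_preset(cls) -> "LRSchedule":
        return cls(lr0=1e-4, f=0.1, i=1000.0)


@dataclass(frozen=True)
class RegularizationConfig:
    sigma: float = 100.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class Schedules:
    curriculum: CurriculumSchedule = CurriculumSchedule()
    anneal: AnnealSchedule = AnnealSchedule()
    lr_net: LRSchedule = field(default_factory=LRSchedule.network_preset)
    lr_latent: LRSchedule = field(default_factory=LRSchedule.latent_preset)


def schedule_eval(schedules: Schedules, epoch: int) -> tuple[float, float, float, float]:
    """(lambda, regularization weight, network lr, latent lr) at `epoch`."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return (
        schedules.curriculum(epoch),
        schedules.anneal(epoch),
        schedules.lr_net(epoch),
        schedules.lr_latent(epoch),
    )


# -- losses ------------------------------------------------------------------
def recon_loss(s_pred, s_true, lam: float = 0.0, delta: float = 0.1):
    """Curriculum-weighted clamped L1.

    mean over points of ``w * |clamp(s_pred) - clamp(s_true)|`` with the
    hard-sample weight ``w = 1 + lam * sign(s_true) * sign(s_true - s_pred)``:
    wrong-sign (hard) predictions are up-weighted by (1 + lam), easy ones
    down-weighted by (1 - lam); lam = 0 recovers plain clamped L1.

    Accepts a ``nn.Tensor`` prediction (returns a Tensor for backprop) or a
    numpy array (returns a float).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    s_true = np.asarray(s_true, dtype=np.float64)
    pred_data = s_pred.data if isinstance(s_pred, Tensor) else np.asarray(s_pred)
    if pred_data.shape != s_true.shape:
        raise ValueError("prediction/target length mismatch")
    w = 1.0 + lam * np.sign(s_true) * np.sign(s_true - pred_data)
    t_clamped = np.clip(s_true, -delta, delta)
    if isinstance(s_pred, Tensor):
        diff = nn.clip(s_pred, -delta, delta) - Tensor(t_clamped)
        return (Tensor(w.astype(np.float32)) * nn.abs_(diff)).mean()
    return float(np.mean(w * np.abs(np.clip(pred_data, -delta, delta) - t_clamped)))


def latent_reg(z, sigma: float = 100.0):
    """Independent per-component Gaussian penalty: sum_i z_i^2 / sigma^2."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if isinstance(z, Tensor):
        return (z * z).sum() * (1.0 / sigma**2)
    z = np.asarray(z, dtype=np.float64)
    return float((z**2).sum() / sigma**2)


# -- training loop -----------------------------------------------------------
@dataclass
class ShapeSamples:
    shape_id: str
    bone: SDFSampleSet
    cartilage: SDFSampleSet


@dataclass
class TrainConfig:
    epochs: int = 2000
    batch: BatchSpec = field(default_factory=BatchSpec)
    schedules: Schedules = field(default_factory=Schedules)
    regularization: RegularizationConfig = field(default_factory=RegularizationConfig)
    weight_decay: float = 1e-4
    latent_init_std: float = 0.01
    seed: int = 0


@dataclass
class TrainResult:
    params: dict
    codebook: dict  # shape_id -> Tensor latent
    trace: pd.DataFrame


def train(dataset: list[ShapeSamples], decoder, cfg: TrainConfig) -> TrainResult:
    """Jointly optimize decoder weights and the per-shape latent codebook."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 shapes to train an autodecoder")
    rng = np.random.default_rng(cfg.seed)
    delta = decoder.cfg.delta
    latent_len = decoder.cfg.latent_len
    params = decoder.init_params(rng)
    codebook = {
        s.shape_id: Tensor(
            rng.normal(0.0, cfg.latent_init_std, latent_len).astype(np.float32), True
        )
        for s in dataset
    }
    opt = nn.AdamW(
        [
            {"params": list(params.values()), "lr": cfg.schedules.lr_net.lr0, "weight_decay": cfg.weight_decay},
            {"params": list(codebook.values()), "lr": cfg.schedules.lr_latent.lr0, "weight_decay": 0.0},
        ]
    )
    rows = []
    for epoch in range(cfg.epochs):
        lam, w_reg, lr_net, lr_lat = schedule_eval(cfg.schedules, epoch)
        order = rng.permutation(len(dataset))
        ep_recon, ep_reg = 0.0, 0.0
        for si in order:
            shape = dataset[si]
            z = codebook[shape.shape_id]
            b_bone = _draw(shape.bone, cfg.batch, rng)
            b_cart = _draw(shape.cartilage, cfg.batch, rng)
            coords = np.vstack([b_bone.coordinates, b_cart.coordinates])
            nb = len(b_bone)
            s_bone, s_cart = decoder.forward(params, z, coords)
            # each sample set supervises both heads: s is the set's own
            # surface, s_other the paired one
            loss_r = (
                recon_loss(s_bone[:nb], b_bone.s, lam, delta)
                + recon_loss(s_cart[:nb], b_bone.s_other, lam, delta)
                + recon_loss(s_cart[nb:], b_cart.s, lam, delta)
                + recon_loss(s_bone[nb:], b_cart.s_other, lam, delta)
            )
            loss_reg = latent_reg(z, cfg.regularization.sigma)
            loss = loss_r + loss_reg * w_reg
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, shape {shape.shape_id}, "
                    f"lambda={lam:.4g}, lr_net={lr_net:.4g}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr_overrides=[lr_net, lr_lat])
            ep_recon += float(loss_r.data)
            ep_reg += float(loss_reg.data)
        rows.append(
            {
                "epoch": epoch,
                "recon_loss": ep_recon / len(dataset),
                "latent_reg": ep_reg / len(dataset),
                "lambda": lam,
                "w_reg": w_reg,
                "lr_net": lr_net,
                "lr_latent": lr_lat,
            }
        )
    return TrainResult(params=params, codebook=codebook, trace=pd.DataFrame(rows))


def _draw(samples: SDFSampleSet, spec: BatchSpec, rng: np.random.Generator) -> SDFSampleSet:
    from .sampling import draw_batch

    return draw_batch(samples, spec, seed=int(rng.integers(2**31)))


def prepare_training_set(
    pairs: list,
    sampling_cfg,
    register: bool = True,
    reference_index: int = 0,
    seed: int = 0,
) -> tuple[list[ShapeSamples], dict]:
    """Normalize raw mesh pairs and generate their SDF sample sets.

    Every bone is similarity-registered to the reference shape's bone (the
    transform carries the cartilage along), then the pair is centered on the
    bone centroid and scaled into the unit sphere.  Returns the per-shape
    sample sets and the original-frame -> normalized-frame transforms.
    """
    from dataclasses import replace

    from .geometry import (
        apply_transform_pair,
        normalize_unit_sphere,
        register_similarity,
    )
    from .sampling import sample_training_points

    rng = np.random.default_rng(seed)
    reference = pairs[reference_index].bone
    dataset, transforms = [], {}
    for i, pair in enumerate(pairs):
        if register and i != reference_index:
            t_reg = register_similarity(pair.bone, reference, seed=int(rng.integers(2**31)))
            pair_reg = apply_transform_pair(pair, t_reg)
        else:
            from .geometry import SimilarityTransform

            t_reg = SimilarityTransform()
            pair_reg = pair
        normalized, t_norm = normalize_unit_sphere(pair_reg)
        normalized = type(normalized)(normalized.bone, normalized.cartilage, frame_id=pair.frame_id)
        cfg_i = replace(sampling_cfg, seed=int(rng.integers(2**31)))
        bone_set, cart_set = sample_training_points(normalized, cfg_i)
        dataset.append(ShapeSamples(shape_id=pair.frame_id, bone=bone_set, cartilage=cart_set))
        transforms[pair.frame_id] = t_norm.compose(t_reg)
    return dataset, transforms
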