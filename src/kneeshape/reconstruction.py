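"""Test-time reconstruction: fit a latent to a new shape with frozen weights.

The pipeline mirrors training-time normalization: the input bone is
similarity-registered to the decoder's mean bone (the z = 0 reconstruction),
the transform is applied to the cartilage, both tissues are rescaled into the
unit sphere, and a randomly initialized latent is optimized with a clamped L1
loss on surface points whose target signed distance is zero.  Surfaces are
extracted by marching cubes over [-1, 1]^3 and mapped back to the original
frame with the inverse transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from . import nn
from .nn import Tensor
from .geometry import (
    EmptySurfaceError,
    SDFGrid,
    SimilarityTransform,
    TriangleMesh,
    TriangleMeshPair,
    apply_transform_pair,
    extract_surface,
    grid_coordinates,
    normalize_unit_sphere,
    register_similarity,
)
from .training import recon_loss


@dataclass
class FitConfig:
    epochs: int = 2000
    n_surface_points: int = 20_000
    delta: float = 0.1  # clamp bound on predicted s during fitting
    lr0: float = 5e-3
    lr_decay: float = 0.9
    lr_decay_every: int = 20
    patience: int = 50
    latent_init_std: float = 0.01
    mean_grid_resolution: int = 64
    chunk: int = 16_384

    def __post_init__(self):
        if self.patience >= self.epochs:
            raise ValueError("patience must be smaller than epochs")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def decode_grid(decoder, params, z, resolution: int, extent=(-1.0, 1.0), chunk: int = 16_384) -> tuple[SDFGrid, SDFGrid]:
    """Evaluate both decoder heads on a regular grid (forward only)."""
    coords = grid_coordinates(resolution, extent)
    zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float32))
    out_b = np.empty(len(coords), dtype=np.float32)
    out_c = np.empty(len(coords), dtype=np.float32)
    planes = decoder.planes(params, zt) if hasattr(decoder, "planes") else None
    for lo in range(0, len(coords), chunk):
        sl = slice(lo, lo + chunk)
        if planes is not None:
            local = decoder.local_latent(planes, coords[sl])
            out = decoder.trunk(params, local, coords[sl])
            sb, sc = out[:, 0], out[:, 1]
        else:
            sb, sc = decoder.forward(params, zt, coords[sl])
        out_b[sl] = sb.data
        out_c[sl] = sc.data
    shape3 = (resolution,) * 3
    return (
        SDFGrid(out_b.reshape(shape3), extent),
        SDFGrid(out_c.reshape(shape3), extent),
    )


def mean_shape(decoder, params, resolution: int = 64) -> TriangleMesh:
    """The decoder's mean bone: the z = 0 reconstruction."""
    grid_b, _ = decode_grid(decoder, params, np.zeros(decoder.cfg.latent_len), resolution)
    return extract_surface(grid_b)


@dataclass
class FitResult:
    latent: np.ndarray
    transform: SimilarityTransform  # original frame -> normalized frame
    trace: pd.DataFrame
    best_loss: float


def fit_latent(
    decoder,
    params,
    pair: TriangleMeshPair,
    cfg: FitConfig = None,
    seed: int = 0,
    mean_bone: TriangleMesh | None = None,
    z_init: np.ndarray | None = None,
) -> FitResult:
    """Optimize a latent code for `pair` with frozen decoder weights.

    `z_init` warm-starts the optimization (e.g. from a codebook entry);
    by default the latent starts at N(0, latent_init_std^2).
    """
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(seed)

    if mean_bone is None:
        try:
            mean_bone = mean_shape(decoder, params, cfg.mean_grid_resolution)
        except EmptySurfaceError:
            mean_bone = None
    if mean_bone is not None:
        try:
            reg = register_similarity(pair.bone, mean_bone, seed=int(rng.integers(2**31)))
        except Exception:
            warnings.warn("registration failed; falling back to centroid/scale alignment")
            reg = SimilarityTransform()
    else:
        reg = SimilarityTransform()
    registered = apply_transform_pair(pair, reg)
    normalized, norm_t = normalize_unit_sphere(registered)
    transform = norm_t.compose(reg)

    pts = {}
    for name, mesh in (("bone", normalized.bone), ("cartilage", normalized.cartilage)):
        sampled, _ = trimesh.sample.sample_surface(
            mesh.to_trimesh(), cfg.n_surface_points, seed=int(rng.integers(2**31))
        )
        pts[name] = np.asarray(sampled)
    coords = np.vstack([pts["bone"], pts["cartilage"]])
    nb = len(pts["bone"])
    targets = np.zeros(len(coords))

    if z_init is None:
        z_init = rng.normal(0.0, cfg.latent_init_std, decoder.cfg.latent_len)
    z = Tensor(np.asarray(z_init, dtype=np.float32).copy(), True)
    opt = nn.AdamW([{"params": [z], "lr": cfg.lr0, "weight_decay": 0.0}], beta2=0.999)
    best_loss, best_z, best_epoch = np.inf, z.data.copy(), -1
    rows = []
    for epoch in range(cfg.epochs):
        lr = cfg.lr0 * cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        s_bone, s_cart = decoder.forward(params, z, coords)
        loss = recon_loss(s_bone[:nb], targets[:nb], 0.0, cfg.delta) + recon_loss(
            s_cart[nb:], targets[nb:], 0.0, cfg.delta
        )
        val = float(loss.data)
        rows.append({"epoch": epoch, "loss": val, "lr": lr})
        if val < best_loss:
            best_loss, best_z, best_epoch = val, z.data.copy(), epoch
        if epoch - best_epoch >= cfg.patience:
            break
        opt.zero_grad()
        loss.backward()
        opt.step(lr_overrides=[lr])
    return FitResult(
        latent=best_z,
        transform=transform,
        trace=pd.DataFrame(rows),
        best_loss=best_loss,
    )


def encode_population(
    decoder,
    params,
    pairs: list[TriangleMeshPair],
    cfg: FitConfig = None,
    seed: int = 0,
    mean_bone: TriangleMesh | None = None,
) -> tuple[np.ndarray, list[FitResult]]:
    """Fit one latent per mesh pair with frozen weights; returns (Z, results).

    The model-mean bone is computed once and reused across fits.
    """
    cfg = cfg or FitConfig()
    if mean_bone is None:
        mean_bone = mean_shape(decoder, params, cfg.mean_grid_resolution)
    rng = np.random.default_rng(seed)
    results = [
        fit_latent(decoder, params, pair, cfg, seed=int(rng.integers(2**31)), mean_bone=mean_bone)
        for pair in pairs
    ]
    return np.stack([r.latent for r in results]), results


def reconstruct(
    decoder,
    params,
    z: np.ndarray,
    transform: SimilarityTransform | None = None,
    resolution: int = 256,
    extent=(-1.0, 1.0),
) -> TriangleMeshPair:
    """Decode z on a grid, extract both surfaces, and undo the normalization.

    A head whose grid never changes sign yields ``None`` for that tissue (a
    legitimate outcome for degenerate latents) rather than raising.
    """
    grid_b, grid_c = decode_grid(decoder, params, z, resolution, extent)
    meshes = {}
    for name, grid in (("bone", grid_b), ("cartilage", grid_c)):
        try:
            meshes[name] = extract_surface(grid)
        except EmptySurfaceError:
            warnings.warn(f"{name} head produced a single-sign grid; no surface extracted")
            meshes[name] = None
    if transform is not None:
        inv = transform.invert()
        for name, mesh in meshes.items():
            if mesh is not None:
                meshes[name] = TriangleMesh(inv.apply(mesh.vertices), mesh.faces)
        frame = "native"
    else:
        frame = "normalized"
    return TriangleMeshPair(meshes["bone"], meshes["cartilage"], frame_id=frame)
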