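"""Generative shape decoders mapping (latent z, coordinate x) -> signed distances.

Three architectures share one calling convention and produce two outputs per
query point (bone and cartilage signed distance), each bounded by a tanh
scaled to the clamp bound delta of the model class:

* ``HybridDecoder`` — a CNN expands the global latent into three orthogonal
  2-D feature planes; a point's local latent is read by projecting onto the
  planes and bilinearly interpolating, then decoded by a small MLP.
* ``MLPDecoder`` — two independent 8-layer width-512 ReLU trunks (one per
  tissue) on [x; z] with a skip connection re-injecting the input at layer 4.
* ``MPADecoder`` — a sinusoidal "synthesizer" trunk on x whose layer outputs
  are gated elementwise by a ReLU "modulator" trunk on z.

Parameters are plain dicts of named ``nn.Tensor``s so the training loop and
latent fitting can hand any subset to the optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class HybridConfig:
    latent_len: int = 512
    n_deconv: int = 5
    conv_channels: int = 512
    plane_features: int = 128
    trunk_width: int = 512
    trunk_hidden: int = 3
    delta: float = 1.0
    kernel: int = 4  # stride-2, padding-1 transpose convs: exact doubling

    @property
    def plane_resolution(self) -> int:
        return 2 * 2**self.n_deconv

    @property
    def final_channels(self) -> int:
        return 3 * self.plane_features

    @property
    def dense_out(self) -> int:
        return 4 * self.conv_channels  # reshaped to (C, 2, 2)

    @classmethod
    def tiny(cls) -> "HybridConfig":
        """Desk-scale variant: 16x16 planes, narrow channels and trunk."""
        return cls(latent_len=32, n_deconv=3, conv_channels=48, plane_features=32, trunk_width=128)


@dataclass(frozen=True)
class MLPConfig:
    latent_len: int = 512
    width: int = 512
    depth: int = 8
    skip_layer: int = 4  # 1-based: input concatenated into this layer's input
    delta: float = 0.1

    @classmethod
    def tiny(cls) -> "MLPConfig":
        return cls(latent_len=32, width=128)


@dataclass(frozen=True)
class MPAConfig:
    latent_len: int = 512
    width: int = 512
    depth: int = 8
    omega0: float = 30.0  # frequency scale of the first sinusoidal layer
    delta: float = 0.1

    @classmethod
    def tiny(cls) -> "MPAConfig":
        return cls(latent_len=32, width=128)


# ---------------------------------------------------------------------------
class HybridDecoder:
    def __init__(self, cfg: HybridConfig):
        self.cfg = cfg

    def layer_shapes(self) -> list[tuple[int, ...]]:
        c = self.cfg
        shapes: list[tuple[int, ...]] = [(c.latent_len, c.dense_out), (c.dense_out,)]
        for i in range(c.n_deconv):
            cout = c.final_channels if i == c.n_deconv - 1 else c.conv_channels
            shapes += [(c.conv_channels, cout, c.kernel, c.kernel), (cout,)]
        dims = [c.plane_features + 3] + [c.trunk_width] * c.trunk_hidden
        for din, dout in zip(dims[:-1], dims[1:]):
            shapes += [(din, dout), (dout,)]
        shapes += [(c.trunk_width, 2), (2,)]
        return shapes

    def init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        c = self.cfg
        p: dict[str, Tensor] = {}
        p["dense_w"] = Tensor(nn.he_init(rng, c.latent_len, (c.latent_len, c.dense_out)), True)
        p["dense_b"] = Tensor(np.zeros(c.dense_out), True)
        for i in range(c.n_deconv):
            cout = c.final_channels if i == c.n_deconv - 1 else c.conv_channels
            fan_in = c.conv_channels * c.kernel * c.kernel
            p[f"conv{i}_w"] = Tensor(
                nn.he_init(rng, fan_in, (c.conv_channels, cout, c.kernel, c.kernel)), True
            )
            p[f"conv{i}_b"] = Tensor(np.zeros(cout), True)
        dims = [c.plane_features + 3] + [c.trunk_width] * c.trunk_hidden
        for j, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            p[f"trunk{j}_w"] = Tensor(nn.he_init(rng, din, (din, dout)), True)
            p[f"trunk{j}_b"] = Tensor(np.zeros(dout), True)
        p["head_w"] = Tensor(nn.glorot_init(rng, c.trunk_width, 2, (c.trunk_width, 2)), True)
        p["head_b"] = Tensor(np.zeros(2), True)
        return p

    def planes(self, params: dict[str, Tensor], z: Tensor) -> Tensor:
        """Expand a global latent into (3, F, R, R) feature planes."""
        c = self.cfg
        # the latent expansion is linear: a ReLU here can die for z near 0
        # (autodecoder latents start at ~0) and permanently sever the latent
        # pathway, collapsing the model onto its bias-encoded mean shape
        h = (z @ params["dense_w"] + params["dense_b"]).reshape(c.conv_channels, 2, 2)
        for i in range(c.n_deconv):
            h = nn.conv_transpose2d(h, params[f"conv{i}_w"], params[f"conv{i}_b"])
            if i < c.n_deconv - 1:
                h = nn.relu(h)
        return h.reshape(3, c.plane_features, c.plane_resolution, c.plane_resolution)

    def local_latent(self, planes: Tensor, x: np.ndarray) -> Tensor:
        """Project x onto the (xy, xz, yz) planes, read bilinearly, and sum."""
        x = np.asarray(x, dtype=np.float64)
        if np.any(np.abs(x) > 1.0 + 1e-9):
            import warnings

            warnings.warn("coordinates outside [-1,1]^3 clamped to the cube boundary")
            x = np.clip(x, -1.0, 1.0)
        coords = np.stack([x[:, [0, 1]], x[:, [0, 2]], x[:, [1, 2]]], axis=0)
        return nn.plane_bilinear(planes, coords)

    def trunk(self, params: dict[str, Tensor], local_z: Tensor, x: np.ndarray) -> Tensor:
        c = self.cfg
        h = nn.concat([local_z, Tensor(np.clip(x, -1.0, 1.0))], axis=1)
        for j in range(c.trunk_hidden):
            h = nn.relu(h @ params[f"trunk{j}_w"] + params[f"trunk{j}_b"])
        out = nn.tanh(h @ params["head_w"] + params["head_b"]) * c.delta
        return out

    def forward(self, params: dict[str, Tensor], z: Tensor, x: np.ndarray) -> tuple[Tensor, Tensor]:
        planes = self.planes(params, z)
        local_z = self.local_latent(planes, x)
        out = self.trunk(params, local_z, x)
        return out[:, 0], out[:, 1]


class MLPDecoder:
    def __init__(self, cfg: MLPConfig):
        self.cfg = cfg

    def layer_shapes(self) -> list[tuple[int, ...]]:
        c = self.cfg
        d_in = 3 + c.latent_len
        shapes: list[tuple[int, ...]] = []
        for _trunk in range(2):
            prev = d_in
            for layer in range(1, c.depth + 1):
                din = prev + d_in if layer == c.skip_layer else prev
                shapes += [(din, c.width), (c.width,)]
                prev = c.width
            shapes += [(c.width, 1), (1,)]
        return shapes

    def init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        c = self.cfg
        d_in = 3 + c.latent_len
        p: dict[str, Tensor] = {}
        for t, name in enumerate(("bone", "cartilage")):
            prev = d_in
            for layer in range(1, c.depth + 1):
                din = prev + d_in if layer == c.skip_layer else prev
                p[f"{name}_l{layer}_w"] = Tensor(nn.he_init(rng, din, (din, c.width)), True)
                p[f"{name}_l{layer}_b"] = Tensor(np.zeros(c.width), True)
                prev = c.width
            p[f"{name}_head_w"] = Tensor(nn.glorot_init(rng, c.width, 1, (c.width, 1)), True)
            p[f"{name}_head_b"] = Tensor(np.zeros(1), True)
        return p

    def _trunk(self, params, name: str, inp: Tensor) -> Tensor:
        c = self.cfg
        h = inp
        for layer in range(1, c.depth + 1):
            if layer == c.skip_layer:
                h = nn.concat([h, inp], axis=1)
            h = nn.relu(h @ params[f"{name}_l{layer}_w"] + params[f"{name}_l{layer}_b"])
        out = nn.tanh(h @ params[f"{name}_head_w"] + params[f"{name}_head_b"]) * c.delta
        return out[:, 0]

    def forward(self, params: dict[str, Tensor], z: Tensor, x: np.ndarray) -> tuple[Tensor, Tensor]:
        c = self.cfg
        if z.data.shape[-1] != c.latent_len:
            raise ValueError(f"latent length {z.data.shape[-1]} != {c.latent_len}")
        n = len(x)
        ztile = z.reshape(1, c.latent_len) if z.data.ndim == 1 else z
        ones = Tensor(np.ones((n, 1), dtype=np.float32))
        zrow = ones @ ztile  # broadcast latent across the batch, differentiably
        inp = nn.concat([Tensor(np.asarray(x)), zrow], axis=1)
        return self._trunk(params, "bone", inp), self._trunk(params, "cartilage", inp)


class MPADecoder:
    def __init__(self, cfg: MPAConfig):
        self.cfg = cfg

    def layer_shapes(self) -> list[tuple[int, ...]]:
        c = self.cfg
        shapes: list[tuple[int, ...]] = []
        prev = 3
        for _ in range(c.depth):  # synthesizer
            shapes += [(prev, c.width), (c.width,)]
            prev = c.width
        prev = c.latent_len
        for layer in range(c.depth):  # modulator; z re-enters every layer > 0
            din = prev if layer == 0 else prev + c.latent_len
            shapes += [(din, c.width), (c.width,)]
            prev = c.width
        shapes += [(c.width, 2), (2,)]
        return shapes

    def init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        c = self.cfg
        p: dict[str, Tensor] = {}
        prev = 3
        for layer in range(c.depth):
            p[f"syn{layer}_w"] = Tensor(
                nn.siren_init(rng, prev, (prev, c.width), first=(layer == 0)), True
            )
            p[f"syn{layer}_b"] = Tensor(np.zeros(c.width), True)
            prev = c.width
        prev = c.latent_len
        for layer in range(c.depth):
            din = prev if layer == 0 else prev + c.latent_len
            p[f"mod{layer}_w"] = Tensor(nn.he_init(rng, din, (din, c.width)), True)
            # bias 1 => identity-like modulation at init; keeps the sinusoidal
            # signal from collapsing multiplicatively across depth
            p[f"mod{layer}_b"] = Tensor(np.ones(c.width), True)
            prev = c.width
        p["head_w"] = Tensor(nn.glorot_init(rng, c.width, 2, (c.width, 2)), True)
        p["head_b"] = Tensor(np.zeros(2), True)
        return p

    def forward(self, params: dict[str, Tensor], z: Tensor, x: np.ndarray) -> tuple[Tensor, Tensor]:
        c = self.cfg
        n = len(x)
        ztile = z.reshape(1, c.latent_len) if z.data.ndim == 1 else z
        ones = Tensor(np.ones((n, 1), dtype=np.float32))
        zrow = ones @ ztile
        h = Tensor(np.asarray(x))
        m = zrow
        for layer in range(c.depth):
            m_in = m if layer == 0 else nn.concat([m, zrow], axis=1)
            m = nn.relu(m_in @ params[f"mod{layer}_w"] + params[f"mod{layer}_b"])
            omega = c.omega0 if layer == 0 else 1.0
            s = nn.sin((h @ params[f"syn{layer}_w"] + params[f"syn{layer}_b"]) * omega)
            h = s * m
        out = nn.tanh(h @ params["head_w"] + params["head_b"]) * c.delta
        return out[:, 0], out[:, 1]


DECODER_CLASSES = {"hybrid": HybridDecoder, "mlp": MLPDecoder, "mpa": MPADecoder}
CONFIG_CLASSES = {"hybrid": HybridConfig, "mlp": MLPConfig, "mpa": MPAConfig}


def param_count(config) -> int:
    """Exact number of trainable scalars (weights + biases; codebook excluded)."""
    decoder = make_decoder(config)
    return int(sum(np.prod(s) for s in decoder.layer_shapes()))


def make_decoder(config):
    if isinstance(config, HybridConfig):
        return HybridDecoder(config)
    if isinstance(config, MLPConfig):
        return MLPDecoder(config)
    if isinstance(config, MPAConfig):
        return MPADecoder(config)
    raise TypeError(f"unknown decoder config {type(config)!r}")


# -- checkpointing -----------------------------------------------------------
def save_checkpoint(path: str | Path, config, params: dict[str, Tensor], extra: dict | None = None) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in params.items()})
    kind = {HybridConfig: "hybrid", MLPConfig: "mlp", MPAConfig: "mpa"}[type(config)]
    manifest = {"kind": kind, "config": config.__dict__, **(extra or {})}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path):
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_cls = CONFIG_CLASSES[manifest["kind"]]
    cfg_fields = {k: v for k, v in manifest["config"].items()}
    config = cfg_cls(**cfg_fields)
    data = np.load(path.with_suffix(".npz"))
    params = {k: Tensor(data[k], requires_grad=True) for k in data.files}
    return config, params, manifest
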