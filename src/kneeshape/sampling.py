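"""Training-point generation for SDF supervision.

For each normalized bone/cartilage pair, points are sampled separately per
surface: 90% start as approximately blue-noise surface samples perturbed by
isotropic Gaussian noise (45% with sigma=0.016, 45% with sigma=0.05 in
normalized units) and the remaining 10% are drawn uniformly over the cube
enclosing the unit sphere.  Every point stores its signed distance to *both*
surfaces so a single batch can supervise both decoder heads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import TriangleMesh, TriangleMeshPair, signed_distance

PROVENANCE = {"perturbed-small": 0, "perturbed-large": 1, "uniform": 2}


@dataclass
class SamplingConfig:
    n_total: int = 500_000
    frac_sigma_small: float = 0.45
    frac_sigma_large: float = 0.45
    sigma_small: float = 0.016
    sigma_large: float = 0.05
    frac_uniform: float = 0.10
    cube_extent: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not np.isclose(self.frac_sigma_small + self.frac_sigma_large + self.frac_uniform, 1.0):
            raise ValueError("sampling fractions must sum to 1")
        if self.sigma_small <= 0 or self.sigma_large <= 0:
            raise ValueError("sigmas must be positive")

    def counts(self) -> tuple[int, int, int]:
        """(n_small, n_large, n_uniform); the uniform class absorbs rounding."""
        n_small = int(np.floor(self.frac_sigma_small * self.n_total))
        n_large = int(np.floor(self.frac_sigma_large * self.n_total))
        return n_small, n_large, self.n_total - n_small - n_large


@dataclass
class SDFSampleSet:
    """Sampled coordinates with signed distances for one surface of one shape."""

    shape_id: str
    surface_id: str  # "bone" | "cartilage"
    coordinates: np.ndarray  # (N, 3) float32
    s: np.ndarray  # (N,) signed distance to this set's own surface
    s_other: np.ndarray  # (N,) signed distance to the paired surface
    provenance: np.ndarray  # (N,) uint8, see PROVENANCE

    def __len__(self) -> int:
        return len(self.coordinates)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            coordinates=self.coordinates.astype(np.float32),
            s=self.s.astype(np.float32),
            s_other=self.s_other.astype(np.float32),
            provenance=self.provenance.astype(np.uint8),
        )
        path.with_suffix(".json").write_text(
            json.dumps({"shape_id": self.shape_id, "surface_id": self.surface_id})
        )

    @classmethod
    def load(cls, path: str | Path) -> "SDFSampleSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        return cls(
            shape_id=meta["shape_id"],
            surface_id=meta["surface_id"],
            coordinates=data["coordinates"],
            s=data["s"],
            s_other=data["s_other"],
            provenance=data["provenance"],
        )


@dataclass
class BatchSpec:
    points_per_step: int = 17_000
    inside_fraction: float = 0.5

    def __post_init__(self):
        if self.inside_fraction == 0.5 and self.points_per_step % 2:
            raise ValueError("points_per_step must be even for a 50/50 sign split")


# ---------------------------------------------------------------------------
def sample_surface_blue_noise(mesh: TriangleMesh, n: int, seed: int = 0) -> np.ndarray:
    """Approximately blue-noise (Poisson-disk) samples on a mesh surface.

    Batched dart throwing: area-weighted candidates are accepted if no
    previously accepted point lies within radius r = sqrt(area / (n*pi*0.7)).
    If dart throwing underfills, the set is topped up with plain area-weighted
    uniform samples, so exactly `n` points are always returned.
    """
    if n <= 0:
        return np.zeros((0, 3))
    tm = mesh.to_trimesh()
    r = np.sqrt(tm.area / (n * np.pi * 0.7))
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    tree: cKDTree | None = None
    n_candidates = 0
    while len(accepted) < n and n_candidates < 8 * n:
        batch = min(4 * n, 8 * n - n_candidates)
        cand, _ = trimesh.sample.sample_surface(tm, batch, seed=int(rng.integers(2**31)))
        n_candidates += batch
        if tree is not None:
            d, _ = tree.query(cand, k=1)
            cand = cand[d >= r]
        # greedy within-batch thinning via grid hashing on cells of size r
        keys = np.floor(cand / r).astype(np.int64)
        _, first = np.unique(keys, axis=0, return_index=True)
        cand = cand[np.sort(first)]
        accepted.extend(cand)
        if len(accepted) > 0:
            tree = cKDTree(np.asarray(accepted))
    pts = np.asarray(accepted[:n]) if accepted else np.zeros((0, 3))
    if len(pts) < n:
        extra, _ = trimesh.sample.sample_surface(tm, n - len(pts), seed=int(rng.integers(2**31)))
        pts = np.vstack([pts, extra]) if len(pts) else np.asarray(extra)
    return pts


def sample_training_points(
    pair: TriangleMeshPair, cfg: SamplingConfig
) -> tuple[SDFSampleSet, SDFSampleSet]:
    """Generate the per-surface SDF training samples for a normalized pair."""
    n_small, n_large, n_uniform = cfg.counts()
    rng = np.random.default_rng(cfg.seed)
    out = {}
    meshes = {"bone": pair.bone, "cartilage": pair.cartilage}
    for surface_id, mesh in meshes.items():
        surf = sample_surface_blue_noise(mesh, n_small + n_large, seed=int(rng.integers(2**31)))
        pts_small = surf[:n_small] + rng.normal(0.0, cfg.sigma_small, (n_small, 3))
        pts_large = surf[n_small:] + rng.normal(0.0, cfg.sigma_large, (n_large, 3))
        lo, hi = cfg.cube_extent
        pts_uniform = rng.uniform(lo, hi, (n_uniform, 3))
        coords = np.vstack([pts_small, pts_large, pts_uniform])
        np.clip(coords, lo, hi, out=coords)  # rare tail of the sigma=0.05 class
        provenance = np.concatenate(
            [
                np.full(n_small, PROVENANCE["perturbed-small"], dtype=np.uint8),
                np.full(n_large, PROVENANCE["perturbed-large"], dtype=np.uint8),
                np.full(n_uniform, PROVENANCE["uniform"], dtype=np.uint8),
            ]
        )
        out[surface_id] = (coords, provenance)

    other = {"bone": "cartilage", "cartilage": "bone"}
    sdf = {
        (sid, tid): signed_distance(meshes[tid], out[sid][0])
        for sid in meshes
        for tid in meshes
    }
    shape_id = pair.frame_id
    return tuple(
        SDFSampleSet(
            shape_id=shape_id,
            surface_id=sid,
            coordinates=out[sid][0].astype(np.float32),
            s=sdf[(sid, sid)].astype(np.float32),
            s_other=sdf[(sid, other[sid])].astype(np.float32),
            provenance=out[sid][1],
        )
        for sid in ("bone", "cartilage")
    )


def draw_batch(samples: SDFSampleSet, spec: BatchSpec, seed: int = 0) -> SDFSampleSet:
    """Draw a sign-balanced minibatch: half s < 0, half s >= 0.

    Sampling is without replacement within each sign class; if a class has
    too few points it is drawn with replacement and a warning is issued.
    """
    rng = np.random.default_rng(seed)
    n_half = spec.points_per_step // 2
    neg = np.flatnonzero(samples.s < 0)
    pos = np.flatnonzero(samples.s >= 0)
    idx = []
    for cls in (neg, pos):
        pool = cls if len(cls) else np.arange(len(samples))
        if len(pool) >= n_half and len(cls):
            idx.append(rng.choice(pool, n_half, replace=False))
        else:
            warnings.warn(
                f"only {len(cls)} points of one sign for a half-batch of {n_half}; "
                "drawing with replacement"
            )
            idx.append(rng.choice(pool, n_half, replace=True))
    idx = np.concatenate(idx)
    return SDFSampleSet(
        shape_id=samples.shape_id,
        surface_id=samples.surface_id,
        coordinates=samples.coordinates[idx],
        s=samples.s[idx],
        s_other=samples.s_other[idx],
        provenance=samples.provenance[idx],
    )
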