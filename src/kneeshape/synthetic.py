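"""Seeded generator of femur-like bone/cartilage mesh pairs with planted
disease features and self-consistent clinical-style labels.

The bone is a smoothly deformed ellipsoid (icosphere topology, so always
watertight) in a fixed canonical pose: +x medial, +y anterior, +z proximal.
Cartilage is a closed shell over an angular band wrapping from anterior over
distal to posterior, built from the bone surface (inner wall) and a radially
offset outer wall whose offset is the analytic thickness field.  Disease
features are planted per MOAKS-style region:

* osteophytes — graded radial bumps on the bone at the cartilage rim;
* thinning — a patch covering a grade-controlled fraction of the region
  where thickness is halved (binary label positive iff fraction > 10%);
* holes — near-zero thickness inside a patch footprint.

A composite KL-like grade is a fixed clipped function of total feature
burden; it exists to exercise the ordinal machinery, not to be biologically
faithful.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .biomarkers import RegionAtlas, ThicknessMap
from .clinical import MOAKS_REGIONS, ClinicalLabelRecord, bin_labels
from .geometry import TriangleMesh, TriangleMeshPair


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    population: int = 30
    # bone base shape: ellipsoid radii (mm) drawn around these means
    radii_mean: tuple = (30.0, 36.0, 33.0)
    radii_sd: float = 1.5
    deform_sd: float = 0.02  # coefficients of the low-order radial deformation
    # cartilage band (canonical-pose atlas angles, radians)
    atlas: RegionAtlas = field(default_factory=RegionAtlas)
    thickness_base: float = 2.2  # mm
    thickness_variation: float = 0.35  # amplitude of the smooth spatial variation
    # osteophyte rim-bump amplitude (mm) per raw grade 0..3
    osteophyte_amplitude: tuple = (0.0, 1.0, 2.0, 3.0)
    osteophyte_width: float = 0.25  # angular radius of the bump (rad)
    thinning_depth: float = 0.5  # fractional thickness loss inside a thinned patch
    hole_radius: float = 0.22  # angular radius of a hole footprint (rad)
    hole_floor: float = 0.02  # mm; minimal shell offset keeping the mesh manifold
    subdivisions: int = 3  # icosphere resolution (3 -> 642 vertices)
    disease: bool = True  # False -> every sample is fully healthy

    def __post_init__(self):
        if min(self.radii_mean) - 3 * self.radii_sd <= 0:
            raise ValueError("degenerate radii")
        amps = self.osteophyte_amplitude
        if not (amps[0] == 0.0 and all(b > a for a, b in zip(amps[1:], amps[2:]))):
            raise ValueError("osteophyte amplitudes must be 0 at grade 0 and strictly increasing")


@dataclass
class SynthSample:
    shape_id: str
    pair: TriangleMeshPair
    thickness_truth: ThicknessMap  # analytic field on bone vertices, 5-region labels
    regions5: np.ndarray
    regions6: np.ndarray
    labels: ClinicalLabelRecord
    severity: float
    thinned_mask: np.ndarray | None = None  # planted thinning footprint
    hole_mask: np.ndarray | None = None  # planted hole footprint


# -- low-level fields ---------------------------------------------------------
_DEFORM_BASIS = (
    lambda u: u[:, 0] * u[:, 1],
    lambda u: u[:, 1] * u[:, 2],
    lambda u: u[:, 0] * u[:, 2],
    lambda u: u[:, 0] ** 2 - u[:, 2] ** 2,
    lambda u: u[:, 1] ** 2 - u[:, 2] ** 2,
)


def ellipsoid_radius(u: np.ndarray, radii: tuple) -> np.ndarray:
    rx, ry, rz = radii
    return 1.0 / np.sqrt((u[:, 0] / rx) ** 2 + (u[:, 1] / ry) ** 2 + (u[:, 2] / rz) ** 2)


def bump_field(u: np.ndarray, centers: np.ndarray, amplitudes: np.ndarray, width: float) -> np.ndarray:
    """Sum of Gaussian radial bumps (mm) centred at unit directions `centers`."""
    out = np.zeros(len(u))
    for c, a in zip(centers, amplitudes):
        ang = np.arccos(np.clip(u @ c, -1.0, 1.0))
        out += a * np.exp(-((ang / width) ** 2))
    return out


def _boundary_loop(faces: np.ndarray) -> list[int]:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in boundary:
        adj[int(a)].append(int(b))
        adj[int(b)].append(int(a))
    start = int(boundary[0, 0])
    loop = [start]
    prev = -1
    while True:
        nxt = [v for v in adj[loop[-1]] if v != prev]
        if not nxt:
            raise ValueError("open boundary chain; cartilage patch is not a disk")
        if nxt[0] == start:
            break
        prev = loop[-1]
        loop.append(nxt[0])
    return loop


def build_shell(
    bone: TriangleMesh, cap_mask: np.ndarray, offsets: np.ndarray
) -> TriangleMesh:
    """Closed shell over the bone cap: inner wall on the bone, outer wall
    radially offset by `offsets` (mm per bone vertex), rim stitched."""
    faces = bone.faces
    cap_faces = faces[cap_mask[faces].all(axis=1)]
    used = np.unique(cap_faces)
    remap = -np.ones(len(bone.vertices), dtype=np.int64)
    remap[used] = np.arange(len(used))
    patch_faces = remap[cap_faces]
    inner = bone.vertices[used]
    udir = inner / np.linalg.norm(inner, axis=1, keepdims=True)
    outer = inner + udir * offsets[used][:, None]
    n = len(used)
    loop = _boundary_loop(patch_faces)
    rim = []
    for i, j in zip(loop, loop[1:] + [loop[0]]):
        rim.append([i, j, j + n])
        rim.append([i, j + n, i + n])
    verts = np.vstack([inner, outer])
    all_faces = np.vstack([patch_faces[:, ::-1], patch_faces + n, np.asarray(rim)])
    tm = trimesh.Trimesh(verts, all_faces, process=False)
    tm.fix_normals()
    if tm.volume < 0:
        tm.invert()
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# -- per-sample feature planting ----------------------------------------------
_GRADE_THRESHOLDS = (0.35, 0.60, 0.85)  # raw grade = #thresholds exceeded
_THIN_FRACTIONS = {0: (0.0, 0.0), 1: (0.03, 0.08), 2: (0.16, 0.30), 3: (0.35, 0.55)}


def _raw_grade(x: float) -> int:
    return int(sum(x > t for t in _GRADE_THRESHOLDS))


def _region_centers(atlas: RegionAtlas) -> dict[str, np.ndarray]:
    """Unit direction at the middle of each 6-scheme region."""
    psi_mids = {
        "anterior": 0.5 * (atlas.psi_min + atlas.psi_anterior),
        "central": 0.5 * (atlas.psi_anterior + atlas.psi_posterior),
        "posterior": 0.5 * (atlas.psi_posterior + atlas.psi_max),
    }
    lat_mid = 0.45 * atlas.band_halfwidth
    out = {}
    for region in MOAKS_REGIONS:
        side, arc = region.split("-")
        lat = lat_mid if side == "medial" else -lat_mid
        psi = psi_mids[arc]
        out[region] = np.array(
            [np.sin(lat), np.cos(lat) * np.cos(psi), -np.cos(lat) * np.sin(psi)]
        )
    return out


def _rim_site(atlas: RegionAtlas, region: str) -> np.ndarray:
    """A point on the cartilage rim within `region` (osteophytes grow there)."""
    side, arc = region.split("-")
    lat_edge = 0.92 * atlas.band_halfwidth
    if arc == "anterior":
        psi, lat = atlas.psi_min + 0.05, (lat_edge if side == "medial" else -lat_edge) * 0.5
    elif arc == "posterior":
        psi, lat = atlas.psi_max - 0.05, (lat_edge if side == "medial" else -lat_edge) * 0.5
    else:
        psi, lat = 0.5 * (atlas.psi_anterior + atlas.psi_posterior), lat_edge if side == "medial" else -lat_edge
    return np.array([np.sin(lat), np.cos(lat) * np.cos(psi), -np.cos(lat) * np.sin(psi)])


def _patch_radius_for_fraction(u: np.ndarray, region_mask: np.ndarray, center: np.ndarray, frac: float) -> float:
    """Angular radius whose patch covers ~`frac` of the region's vertices."""
    ang = np.arccos(np.clip(u[region_mask] @ center, -1.0, 1.0))
    if frac <= 0 or not len(ang):
        return 0.0
    return float(np.quantile(ang, min(frac, 1.0)))


def _kl_from_burden(burden: float) -> int:
    for grade, hi in enumerate((0, 4, 10, 18)):
        if burden <= hi:
            return grade
    return 4


# -- generator ----------------------------------------------------------------
def generate_sample(
    cfg: SynthConfig, rng: np.random.Generator, shape_id: str, severity: float | None = None
) -> SynthSample:
    atlas = cfg.atlas
    base = trimesh.creation.icosphere(subdivisions=cfg.subdivisions, radius=1.0)
    u = np.asarray(base.vertices)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    faces = np.asarray(base.faces)

    radii = tuple(rng.normal(cfg.radii_mean, cfg.radii_sd))
    coeffs = rng.normal(0.0, cfg.deform_sd, len(_DEFORM_BASIS))
    r = ellipsoid_radius(u, radii) * (1.0 + sum(c * f(u) for c, f in zip(coeffs, _DEFORM_BASIS)))

    if severity is None:
        severity = float(rng.uniform())
    if not cfg.disease:
        severity = 0.0
    regions6 = atlas.labels(u, center=np.zeros(3), scheme=6)
    regions5 = atlas.labels(u, center=np.zeros(3), scheme=5)
    in_band = atlas.in_band(u, center=np.zeros(3))

    osteo_raw, thin_raw, hole_raw = {}, {}, {}
    bump_centers, bump_amps = [], []
    thickness = cfg.thickness_base + cfg.thickness_variation * (
        np.sin(2.0 * np.arctan2(-u[:, 2], u[:, 1])) * 0.5 + u[:, 0] * 0.5
    )
    thinned_mask = np.zeros(len(u), dtype=bool)
    hole_mask = np.zeros(len(u), dtype=bool)
    for region in MOAKS_REGIONS:
        if not cfg.disease:
            osteo_raw[region] = thin_raw[region] = hole_raw[region] = 0
            continue
        x = severity + rng.normal(0.0, 0.15)
        osteo_raw[region] = _raw_grade(float(x + rng.normal(0.0, 0.1)))
        thin_raw[region] = _raw_grade(float(x + rng.normal(0.0, 0.1)))
        hole_raw[region] = max(_raw_grade(float(x - 0.35 + rng.normal(0.0, 0.1))), 0)
        if osteo_raw[region] > 0:
            bump_centers.append(_rim_site(atlas, region))
            bump_amps.append(cfg.osteophyte_amplitude[osteo_raw[region]])
        region_mask = regions6 == region
        if thin_raw[region] > 0 and region_mask.any():
            lo, hi = _THIN_FRACTIONS[thin_raw[region]]
            frac = float(rng.uniform(lo, hi))
            center = u[region_mask][int(rng.integers(region_mask.sum()))]
            rad = _patch_radius_for_fraction(u, region_mask, center, frac)
            ang = np.arccos(np.clip(u @ center, -1.0, 1.0))
            thinned_mask |= region_mask & (ang <= rad)
        if hole_raw[region] > 0 and region_mask.any():
            center = _region_centers(atlas)[region]
            ang = np.arccos(np.clip(u @ center, -1.0, 1.0))
            hole_mask |= region_mask & (ang <= cfg.hole_radius)

    thickness = np.where(thinned_mask, thickness * (1.0 - cfg.thinning_depth), thickness)
    thickness = np.where(hole_mask, 0.0, thickness)
    thickness = np.where(in_band, thickness, 0.0)

    if bump_centers:
        r = r + bump_field(u, np.asarray(bump_centers), np.asarray(bump_amps), cfg.osteophyte_width)
    bone = TriangleMesh(u * r[:, None], faces)
    offsets = np.maximum(thickness, cfg.hole_floor)
    cartilage = build_shell(bone, in_band, offsets)

    # measured thinned-area fraction per region drives the planted label, so
    # label and geometry agree at the 10% threshold by construction
    record = ClinicalLabelRecord(shape_id=shape_id, kl=0)
    record.osteophyte_raw = dict(osteo_raw)
    record.thinning_raw = dict(thin_raw)
    record.hole_raw = dict(hole_raw)
    record = bin_labels(record)
    burden = (
        sum(record.osteophyte_binned.values())
        + 2 * sum(record.thinning_binary.values())
        + 2 * sum(record.hole_binary.values())
    )
    record.kl = _kl_from_burden(burden)
    record = bin_labels(record)
    p_oa = 1.0 / (1.0 + np.exp(-6.0 * (severity - 0.55)))
    record.future_oa = int(rng.uniform() < 0.6 * p_oa) if record.oa == 0 else 0
    record.future_kr = int(rng.uniform() < (0.25 * p_oa + 0.25 * (record.kl == 4)))

    tmap = ThicknessMap(thickness=thickness.copy(), region=regions5.copy())
    return SynthSample(
        shape_id=shape_id,
        pair=TriangleMeshPair(bone, cartilage, frame_id=shape_id),
        thickness_truth=tmap,
        regions5=regions5,
        regions6=regions6,
        labels=record,
        severity=severity,
        thinned_mask=thinned_mask,
        hole_mask=hole_mask,
    )


def generate_population(cfg: SynthConfig) -> list[SynthSample]:
    """Deterministic population of watertight bone/cartilage pairs.

    Disease severities are stratified (evenly spaced, jittered, shuffled) so
    even modest populations span the full range of label classes.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population
    severities = np.linspace(0.02, 0.98, n) + rng.normal(0.0, 0.02, n)
    severities = rng.permutation(np.clip(severities, 0.0, 1.0))
    return [
        generate_sample(cfg, rng, f"synth-{cfg.seed:04d}-{i:03d}", severity=float(severities[i]))
        for i in range(n)
    ]


# -- canonical fixtures -------------------------------------------------------
def constant_shell_pair(
    radius: float = 20.0, thickness: float = 2.0, subdivisions: int = 3
) -> tuple[TriangleMeshPair, np.ndarray]:
    """Spherical bone with a concentric constant-thickness cap shell.

    Returns the pair and the analytic per-vertex thickness field (thickness
    under the cap, 0 elsewhere).
    """
    atlas = RegionAtlas()
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(base.vertices)
    bone = TriangleMesh(u * radius, np.asarray(base.faces))
    in_band = atlas.in_band(u, center=np.zeros(3))
    t = np.where(in_band, thickness, 0.0)
    shell = build_shell(bone, in_band, np.maximum(t, 1e-3))
    return TriangleMeshPair(bone, shell, frame_id="constant-shell"), t


def graded_shell_pair(
    radius: float = 20.0, t_min: float = 1.0, t_max: float = 3.0, subdivisions: int = 3
) -> tuple[TriangleMeshPair, np.ndarray]:
    """Cap shell whose thickness grades linearly with arc position psi."""
    atlas = RegionAtlas()
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(base.vertices)
    bone = TriangleMesh(u * radius, np.asarray(base.faces))
    in_band = atlas.in_band(u, center=np.zeros(3))
    psi, _ = atlas.psi_lat(u, center=np.zeros(3))
    frac = np.clip((psi - atlas.psi_min) / (atlas.psi_max - atlas.psi_min), 0.0, 1.0)
    t = np.where(in_band, t_min + (t_max - t_min) * frac, 0.0)
    shell = build_shell(bone, in_band, np.maximum(t, 1e-3))
    return TriangleMeshPair(bone, shell, frame_id="graded-shell"), t


def make_fixture_suite(seed: int = 0) -> dict:
    """The canonical cross-module test fixtures, regenerated from one seed."""
    sphere = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    ell = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    ell_v = np.asarray(ell.vertices) * np.array([1.0, 0.6, 0.4])
    train_cfg = SynthConfig(seed=seed, population=10)
    heldout_cfg = SynthConfig(seed=seed + 10_000, population=2)
    suite = {
        "sphere": TriangleMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces)),
        "ellipsoid": TriangleMesh(ell_v, np.asarray(ell.faces)),
        "constant_shell": constant_shell_pair(),
        "graded_shell": graded_shell_pair(),
        "train": generate_population(train_cfg),
        "heldout": generate_population(heldout_cfg),
    }
    return suite
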