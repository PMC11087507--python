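"""Synthetic label-volume and scene generation with analytic ground truth.

Every downstream metric in this package (shell sizes, band contacts, distance
profiles, morphometry, nucleus distances, zonation summaries) can be checked
against scenes whose geometry is known by construction:

* mitochondria as digital balls, ellipsoids, capsules or branched capsule
  unions (a voxel is included iff its **center** lies within the continuous
  surface — the standard digitization, which makes brute-force oracles
  unambiguous);
* ER structures placed at controlled discrete gaps from a mitochondrion:
  ``wrapped_shell`` (a shell of voxels at city-block distance exactly
  ``gap_voxels + 1`` from the object, covering a chosen solid-angle
  fraction), ``parallel_sheets`` (stacked planar slabs) and ``tubule``
  (a curved tube);
* lipid-droplet balls and one or two nuclear balls per cell;
* zonation line profiles with a programmed zone-dependent intensity.

The gap construction uses the same city-block metric as the iterative
face-connected dilation in the contact pipeline, so a structure built at
``gap_voxels = g`` is first reached at dilation step ``g + 1`` exactly.
Every generated object has one entry in the emitted manifest recording its
true voxel volume, analytic continuous volume/surface area where defined,
centroid and gap; generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from orgcontact.volume_io import LabelImage2D, LabelVolume
from orgcontact.zonation import LineProfile

__all__ = [
    "MitoSpec",
    "ERSpec",
    "BallSpec",
    "SceneSpec",
    "SyntheticManifest",
    "generate_scene",
    "generate_tem_scene",
    "generate_zonation_profiles",
    "random_contact_scene",
    "TEMSceneSpec",
]


# ---------------------------------------------------------------------------
# voxel stamping primitives (center-inclusion digitization)
# ---------------------------------------------------------------------------


def _grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def stamp_ball(shape, center, radius) -> np.ndarray:
    zz, yy, xx = _grid(shape)
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def stamp_ellipsoid(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = _grid(shape)
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def stamp_capsule(shape, p0, p1, radius) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (in voxel coordinates)."""
    zz, yy, xx = _grid(shape)
    pts = np.stack([zz, yy, xx], axis=-1)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        return stamp_ball(shape, p0, radius)
    t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
    nearest = p0 + t[..., None] * d
    dist2 = ((pts - nearest) ** 2).sum(axis=-1)
    return dist2 <= radius**2


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------


@dataclass
class MitoSpec:
    """One mitochondrion: ``ball`` (radius), ``ellipsoid`` (semi_axes),
    ``capsule`` (p0, p1, radius) or ``branched`` (segments: list of
    (p0, p1, radius) capsules). All geometry in voxel units."""

    shape: str
    center: tuple[float, float, float] | None = None
    radius: float | None = None
    semi_axes: tuple[float, float, float] | None = None
    p0: tuple[float, float, float] | None = None
    p1: tuple[float, float, float] | None = None
    segments: list | None = None


@dataclass
class ERSpec:
    """One ER structure.

    ``wrapped_shell`` wraps mitochondrion ``attached_to`` at city-block
    distance ``gap_voxels + 1`` (gap_voxels empty voxels in between) over a
    solid-angle ``coverage`` fraction, ``thickness_voxels`` thick.
    ``parallel_sheets`` is a free stack of ``n_sheets`` slabs normal to y.
    ``tubule`` is a sinusoidally curved tube.
    """

    mode: str
    attached_to: int | None = None  # 1-based mito id for wrapped_shell
    gap_voxels: int = 0
    thickness_voxels: int = 1
    coverage: float = 1.0
    # parallel_sheets / tubule placement
    origin: tuple[float, float, float] | None = None
    n_sheets: int = 3
    sheet_spacing: int = 4
    extent: tuple[int, int] = (16, 16)  # (z, x) half-extent for sheets
    length: float = 20.0  # tubule length
    radius: float = 1.5  # tubule radius
    axis_direction: tuple[float, float, float] | None = None  # coverage cap axis

    def __post_init__(self) -> None:
        if self.gap_voxels < 0:
            raise ValueError("gap_voxels must be >= 0")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must lie in (0, 1]")


@dataclass
class BallSpec:
    """A simple ball object (lipid droplets, nuclei)."""

    center: tuple[float, float, float]
    radius: float


@dataclass
class SceneSpec:
    """Full specification of a synthetic cell scene."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_nm: float | tuple[float, float, float] = 8.0
    mitochondria: list[MitoSpec] = field(default_factory=list)
    er_structures: list[ERSpec] = field(default_factory=list)
    lipid_droplets: list[BallSpec] = field(default_factory=list)
    nuclei: list[BallSpec] = field(default_factory=list)
    seed: int = 0
    allow_overlap: bool = False
    allow_boundary: bool = False

    def __post_init__(self) -> None:
        if len(self.nuclei) > 2:
            raise ValueError("a cell has 1 or 2 nuclei")

    @classmethod
    def from_yaml(cls, path) -> "SceneSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            shape=tuple(raw.get("shape", (64, 64, 64))),
            voxel_size_nm=raw.get("voxel_size_nm", 8.0),
            mitochondria=[MitoSpec(**m) for m in raw.get("mitochondria", [])],
            er_structures=[ERSpec(**e) for e in raw.get("er_structures", [])],
            lipid_droplets=[BallSpec(**d) for d in raw.get("lipid_droplets", [])],
            nuclei=[BallSpec(**n) for n in raw.get("nuclei", [])],
            seed=raw.get("seed", 0),
            allow_overlap=raw.get("allow_overlap", False),
            allow_boundary=raw.get("allow_boundary", False),
        )


@dataclass
class SyntheticManifest:
    """Ground-truth record emitted with every generated scene.

    One entry per labeled object (id, class, voxel volume, analytic
    continuous volume/surface area where the shape admits one, centroid,
    gap_voxels for ER structures) plus the generation seed.
    """

    entries: list[dict]
    seed: int
    voxel_size_nm: tuple[float, float, float]
    shape: tuple[int, int, int]

    def by_class(self, cls: str) -> list[dict]:
        return [e for e in self.entries if e["class"] == cls]

    def entry(self, cls: str, obj_id: int) -> dict:
        for e in self.entries:
            if e["class"] == cls and e["id"] == obj_id:
                return e
        raise KeyError(f"no manifest entry for {cls} id {obj_id}")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "voxel_size_nm": list(self.voxel_size_nm),
            "shape": list(self.shape),
            "entries": self.entries,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _stamp_mito(shape, spec: MitoSpec) -> tuple[np.ndarray, dict]:
    """Stamp one mitochondrion; return (mask, analytic truth)."""
    truth: dict = {"shape": spec.shape}
    if spec.shape == "ball":
        mask = stamp_ball(shape, spec.center, spec.radius)
        r = spec.radius
        truth["analytic_volume_vox3"] = 4.0 / 3.0 * np.pi * r**3
        truth["analytic_surface_vox2"] = 4.0 * np.pi * r**2
    elif spec.shape == "ellipsoid":
        mask = stamp_ellipsoid(shape, spec.center, spec.semi_axes)
        a, b, c = spec.semi_axes
        truth["analytic_volume_vox3"] = 4.0 / 3.0 * np.pi * a * b * c
        # Thomsen approximation (relative error < 1.1%)
        p = 1.6075
        truth["analytic_surface_vox2"] = (
            4.0
            * np.pi
            * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
        )
    elif spec.shape == "capsule":
        mask = stamp_capsule(shape, spec.p0, spec.p1, spec.radius)
        L = float(np.linalg.norm(np.subtract(spec.p1, spec.p0)))
        r = spec.radius
        truth["analytic_volume_vox3"] = np.pi * r**2 * L + 4.0 / 3.0 * np.pi * r**3
        truth["analytic_surface_vox2"] = 2.0 * np.pi * r * L + 4.0 * np.pi * r**2
    elif spec.shape == "branched":
        mask = np.zeros(shape, dtype=bool)
        for p0, p1, r in spec.segments:
            mask |= stamp_capsule(shape, p0, p1, r)
        # unions of capsules: continuous volume/SA not attempted
    else:
        raise ValueError(f"unknown mitochondrion shape {spec.shape!r}")
    return mask, truth


def _cap_mask(shape, mask_source: np.ndarray, centroid, coverage: float, axis) -> np.ndarray:
    """Solid-angle cap selector: keep directions within a spherical cap of
    area fraction ``coverage`` around ``axis`` (seen from the centroid)."""
    if coverage >= 1.0:
        return np.ones(shape, dtype=bool)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    zz, yy, xx = _grid(shape)
    vec = np.stack([zz - centroid[0], yy - centroid[1], xx - centroid[2]], axis=-1)
    norm = np.linalg.norm(vec, axis=-1)
    norm[norm == 0] = 1.0
    cosang = (vec @ axis) / norm
    # spherical-cap area fraction (1 - cos θ)/2 = coverage
    return cosang >= 1.0 - 2.0 * coverage


def generate_scene(spec: SceneSpec):
    """Generate a scene: (mito, er, ld, nuc) label volumes plus manifest.

    Objects are stamped in the order mitochondria, nuclei, lipid droplets,
    ER. Explicit-geometry objects may not overlap each other or leave the
    volume unless the corresponding spec flags allow it; ER structures are
    carved out of free space, so voxels already occupied by another class are
    simply excluded from them. Deterministic for a fixed seed.
    """
    shape = tuple(spec.shape)
    voxel = spec.voxel_size_nm
    rng = np.random.default_rng(spec.seed)
    vsize = LabelVolume(np.zeros((1, 1, 1), np.uint8), voxel).voxel_size_nm
    um_scale = np.asarray(vsize) * 1e-3
    vox_um3 = float(np.prod(um_scale))
    vox_um2 = float(um_scale[1] * um_scale[2])  # isotropic scenes: any face

    mito = np.zeros(shape, dtype=np.uint16)
    nuc = np.zeros(shape, dtype=np.uint16)
    ld = np.zeros(shape, dtype=np.uint16)
    er = np.zeros(shape, dtype=np.uint16)
    entries: list[dict] = []

    def occupied() -> np.ndarray:
        return (mito > 0) | (nuc > 0) | (ld > 0) | (er > 0)

    def place(target: np.ndarray, mask: np.ndarray, obj_id: int, cls: str):
        if not spec.allow_boundary and _touches_boundary(mask):
            raise ValueError(f"{cls} {obj_id} touches the volume boundary")
        clash = mask & occupied()
        if clash.any() and not spec.allow_overlap:
            raise ValueError(f"{cls} {obj_id} overlaps an existing object")
        target[mask & ~occupied() if spec.allow_overlap else mask] = obj_id

    def record(cls: str, obj_id: int, mask: np.ndarray, truth: dict):
        n = int(mask.sum())
        centroid = np.argwhere(mask).mean(axis=0) * um_scale if n else None
        entry = {
            "id": obj_id,
            "class": cls,
            "voxel_count": n,
            "centroid_um": None if centroid is None else [float(v) for v in centroid],
            "seed": spec.seed,
        }
        if "analytic_volume_vox3" in truth:
            entry["true_volume_um3"] = truth["analytic_volume_vox3"] * vox_um3
        if "analytic_surface_vox2" in truth:
            entry["true_surface_area_um2"] = truth["analytic_surface_vox2"] * vox_um2
        entry.update({k: v for k, v in truth.items() if k.startswith(("shape", "mode", "gap"))})
        entries.append(entry)

    for i, mspec in enumerate(spec.mitochondria, start=1):
        mask, truth = _stamp_mito(shape, mspec)
        place(mito, mask, i, "mito")
        record("mito", i, mask, truth)

    for i, nspec in enumerate(spec.nuclei, start=1):
        mask = stamp_ball(shape, nspec.center, nspec.radius)
        place(nuc, mask, i, "nucleus")
        record(
            "nucleus", i, mask,
            {"analytic_volume_vox3": 4 / 3 * np.pi * nspec.radius**3,
             "analytic_surface_vox2": 4 * np.pi * nspec.radius**2},
        )

    for i, dspec in enumerate(spec.lipid_droplets, start=1):
        mask = stamp_ball(shape, dspec.center, dspec.radius)
        place(ld, mask, i, "lipid_droplet")
        record(
            "lipid_droplet", i, mask,
            {"analytic_volume_vox3": 4 / 3 * np.pi * dspec.radius**3,
             "analytic_surface_vox2": 4 * np.pi * dspec.radius**2},
        )

    for i, espec in enumerate(spec.er_structures, start=1):
        mask = _stamp_er(shape, espec, mito, rng)
        mask &= ~occupied()
        er[mask] = i
        record(
            "er", i, mask,
            {"mode": espec.mode, "gap_voxels": espec.gap_voxels
             if espec.mode == "wrapped_shell" else None},
        )

    vols = tuple(
        LabelVolume(arr, voxel, name=name)
        for arr, name in ((mito, "mito"), (er, "er"), (ld, "ld"), (nuc, "nuc"))
    )
    manifest = SyntheticManifest(
        entries=entries, seed=spec.seed, voxel_size_nm=vsize, shape=shape
    )
    _check_manifest(vols, manifest)
    return (*vols, manifest)


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )


def _stamp_er(shape, espec: ERSpec, mito: np.ndarray, rng) -> np.ndarray:
    if espec.mode == "wrapped_shell":
        if espec.attached_to is None:
            raise ValueError("wrapped_shell requires attached_to (a mito id)")
        target = mito == espec.attached_to
        if not target.any():
            raise ValueError(f"mitochondrion {espec.attached_to} not found")
        # city-block distance from the object; dilation step k reaches dist == k
        dist = ndimage.distance_transform_cdt(~target, metric="taxicab")
        lo = espec.gap_voxels + 1
        mask = (dist >= lo) & (dist <= lo + espec.thickness_voxels - 1)
        if espec.coverage < 1.0:
            centroid = np.argwhere(target).mean(axis=0)
            axis = espec.axis_direction
            if axis is None:
                axis = rng.normal(size=3)
            mask &= _cap_mask(shape, target, centroid, espec.coverage, axis)
        return mask
    if espec.mode == "parallel_sheets":
        origin = espec.origin
        if origin is None:
            raise ValueError("parallel_sheets requires origin")
        oz, oy, ox = (int(round(v)) for v in origin)
        ez, ex = espec.extent
        mask = np.zeros(shape, dtype=bool)
        for s in range(espec.n_sheets):
            y0 = oy + s * (espec.thickness_voxels + espec.sheet_spacing)
            mask[
                max(oz - ez, 0): oz + ez,
                y0: y0 + espec.thickness_voxels,
                max(ox - ex, 0): ox + ex,
            ] = True
        return mask
    if espec.mode == "tubule":
        origin = np.asarray(
            espec.origin if espec.origin is not None else rng.uniform(8, np.min(shape) - 8, 3)
        )
        t = np.linspace(0, 1, max(8, int(espec.length * 3)))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        normal = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(normal) < 1e-6:
            normal = np.cross(direction, [0.0, 1.0, 0.0])
        normal /= np.linalg.norm(normal)
        amp = espec.length / 6.0
        pts = (
            origin
            + t[:, None] * direction * espec.length
            + np.sin(2 * np.pi * t)[:, None] * normal * amp
        )
        pts = np.clip(pts, 1, np.asarray(shape) - 2)
        mask = np.zeros(shape, dtype=bool)
        for p0, p1 in zip(pts[:-1], pts[1:]):
            mask |= stamp_capsule(shape, p0, p1, espec.radius)
        return mask
    raise ValueError(f"unknown ER mode {espec.mode!r}")


def _check_manifest(vols, manifest: SyntheticManifest) -> None:
    """Manifest completeness: label set of volumes == manifest id set."""
    cls_of = {"mito": "mito", "er": "er", "ld": "lipid_droplet", "nuc": "nucleus"}
    for vol in vols:
        want = {e["id"] for e in manifest.by_class(cls_of[vol.name]) if e["voxel_count"] > 0}
        have = set(int(v) for v in vol.labels())
        if want != have:
            raise RuntimeError(
                f"manifest mismatch for {vol.name}: manifest {sorted(want)} "
                f"vs volume {sorted(have)}"
            )


# ---------------------------------------------------------------------------
# randomized scenes for oracle sweeps
# ---------------------------------------------------------------------------


def random_contact_scene(seed: int, shape=(40, 40, 40)) -> tuple:
    """A randomized small scene for contact-oracle sweeps.

    One or two mitochondria of random shape and size, each with a random ER
    structure (wrapped shell at a random gap, partial coverage, or a tubule
    nearby). Draws that would collide are redrawn deterministically from the
    same stream. Returns the same tuple as :func:`generate_scene`.
    """
    rng = np.random.default_rng(seed)
    for _ in range(50):
        try:
            return _random_contact_scene_once(rng, seed, shape)
        except ValueError:
            continue
    raise RuntimeError(f"could not place a collision-free scene for seed {seed}")


def _random_contact_scene_once(rng, seed: int, shape) -> tuple:
    shape = tuple(shape)
    lo = min(shape)
    n_mito = int(rng.integers(1, 3))
    mitos, ers = [], []
    centers = np.linspace(0.3, 0.7, n_mito)
    for i in range(n_mito):
        c = tuple(float(v) for v in (centers[i] * lo + rng.uniform(-2, 2, 3)))
        kind = rng.choice(["ball", "ellipsoid", "capsule"])
        if kind == "ball":
            mitos.append(MitoSpec("ball", center=c, radius=float(rng.uniform(3, 6))))
        elif kind == "ellipsoid":
            mitos.append(
                MitoSpec("ellipsoid", center=c, semi_axes=tuple(rng.uniform(3, 7, 3)))
            )
        else:
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d) * rng.uniform(4, 8)
            mitos.append(
                MitoSpec(
                    "capsule",
                    p0=tuple(np.asarray(c) - d / 2),
                    p1=tuple(np.asarray(c) + d / 2),
                    radius=float(rng.uniform(2, 4)),
                )
            )
        mode = rng.choice(["wrapped_shell", "wrapped_shell", "tubule"])
        if mode == "wrapped_shell":
            ers.append(
                ERSpec(
                    "wrapped_shell",
                    attached_to=i + 1,
                    gap_voxels=int(rng.integers(0, 8)),
                    thickness_voxels=int(rng.integers(1, 3)),
                    coverage=float(rng.uniform(0.3, 1.0)),
                )
            )
        else:
            ers.append(
                ERSpec(
                    "tubule",
                    origin=tuple(rng.uniform(0.25 * lo, 0.75 * lo, 3)),
                    length=float(rng.uniform(8, 0.4 * lo)),
                    radius=float(rng.uniform(1.0, 2.0)),
                )
            )
    spec = SceneSpec(
        shape=shape,
        mitochondria=mitos,
        er_structures=ers,
        seed=seed,
        allow_boundary=True,
    )
    return generate_scene(spec)


# ---------------------------------------------------------------------------
# 2D TEM scenes
# ---------------------------------------------------------------------------


@dataclass
class TEMSceneSpec:
    """2D TEM scene: mitochondrion discs and ER arcs at controlled gaps.

    ``discs``: list of (center_yx, radius_px). ``arcs``: list of dicts with
    ``attached_to`` (1-based disc id), ``gap_px``, ``thickness_px`` and
    ``angle_deg`` = (start, stop) angular span measured from +x
    counter-clockwise.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 8.0
    discs: list = field(default_factory=list)
    arcs: list = field(default_factory=list)


def generate_tem_scene(spec2d: TEMSceneSpec, seed: int = 0):
    """Generate (mito image, er image, manifest) for a 2D TEM scene.

    Discs follow center-inclusion digitization; each arc occupies the pixels
    whose Euclidean distance to its disc lies in [gap, gap + thickness)
    pixels within the requested angular span, so the minimum membrane-to-
    membrane distance equals ``gap_px`` exactly (achieved along the axis
    directions).
    """
    shape = tuple(spec2d.shape)
    mito = np.zeros(shape, dtype=np.uint16)
    er = np.zeros(shape, dtype=np.uint16)
    entries: list[dict] = []
    yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")

    for i, (center, radius) in enumerate(spec2d.discs, start=1):
        cy, cx = center
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        if (mito[mask] > 0).any():
            raise ValueError(f"disc {i} overlaps an existing disc")
        mito[mask] = i
        entries.append(
            {
                "id": i,
                "class": "mito",
                "voxel_count": int(mask.sum()),
                "true_area_px2": np.pi * radius**2,
                "centroid_px": [float(cy), float(cx)],
                "seed": seed,
            }
        )

    for i, arc in enumerate(spec2d.arcs, start=1):
        target = mito == arc["attached_to"]
        if not target.any():
            raise ValueError(f"disc {arc['attached_to']} not found")
        dist = ndimage.distance_transform_edt(~target)
        gap = float(arc["gap_px"])
        thickness = float(arc.get("thickness_px", 2))
        mask = (dist >= gap) & (dist < gap + thickness) & ~target
        a0, a1 = arc.get("angle_deg", (0.0, 360.0))
        if (a1 - a0) % 360 != 0 or a1 - a0 < 360:
            cy, cx = np.argwhere(target).mean(axis=0)
            ang = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
            span = (ang - a0) % 360.0 <= (a1 - a0) % 360.0 if a1 != a0 else ang >= 0
            if a1 - a0 >= 360:
                span = np.ones(shape, dtype=bool)
            mask &= span
        mask &= mito == 0
        mask &= er == 0
        er[mask] = i
        entries.append(
            {
                "id": i,
                "class": "er",
                "voxel_count": int(mask.sum()),
                "gap_px": gap,
                "seed": seed,
            }
        )

    manifest = SyntheticManifest(
        entries=entries,
        seed=seed,
        voxel_size_nm=(spec2d.pixel_size_nm,) * 3,
        shape=(1, *shape),
    )
    return (
        LabelImage2D(mito, spec2d.pixel_size_nm, name="mito2d"),
        LabelImage2D(er, spec2d.pixel_size_nm, name="er2d"),
        manifest,
    )


# ---------------------------------------------------------------------------
# zonation profiles
# ---------------------------------------------------------------------------


def generate_zonation_profiles(
    n_profiles: int,
    zone_effect: Callable[[np.ndarray], np.ndarray] | float | str = "portal_ramp",
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = 200,
    length_um_range: tuple[float, float] = (150.0, 350.0),
    channel: str = "RRBP1",
):
    """Synthetic central-vein -> portal-vein intensity profiles.

    ``zone_effect`` maps percent position (0 = central vein, 100 = portal
    vein) to noiseless intensity. It can be a callable, a constant, or a
    preset: ``"portal_ramp"`` (linear 0 -> 100, periportal-enriched, the
    pattern of a rough-ER marker such as RRBP1) or ``"central_ramp"`` (the
    reverse). Gaussian noise with standard deviation ``noise_sd`` is added.
    Returns (profiles, truth) where ``truth`` is the noiseless function.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if callable(zone_effect):
        fn = zone_effect
    elif isinstance(zone_effect, str):
        presets = {
            "portal_ramp": lambda p: np.asarray(p, dtype=float),
            "central_ramp": lambda p: 100.0 - np.asarray(p, dtype=float),
        }
        if zone_effect not in presets:
            raise ValueError(f"unknown zone_effect preset {zone_effect!r}")
        fn = presets[zone_effect]
    else:
        const = float(zone_effect)
        fn = lambda p: np.full_like(np.asarray(p, dtype=float), const)

    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n_profiles):
        length = rng.uniform(*length_um_range)
        pos = np.linspace(0.0, length, n_samples)
        pct = 100.0 * pos / length
        intensity = np.asarray(fn(pct), dtype=float)
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd, size=n_samples)
        profiles.append(
            LineProfile(pos, intensity, channel=channel, profile_id=f"profile_{i}")
        )
    return profiles, fn
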