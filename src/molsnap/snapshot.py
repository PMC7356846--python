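"""Multi-angle snapshot rendering of 3D ball-and-stick models.

A molecule's 3D conformer is photographed from a grid of rotation poses.
Per axis, the user supplies an angle increment; the pose angles are all
multiples k*inc below 360 deg, and the pose grid is the Cartesian product
over the x, y and z axes. The default increment (176, 176, 176) yields
ceil(360/176)^3 = 27 poses per molecule.

Each pose is rasterized deterministically to a fixed-size RGB PNG:
orthographic projection after rotation (applied in the fixed order Rz Ry Rx),
atoms as filled CPK-colored circles scaled to a percentage of their van der
Waals radius, bonds as capsules colored half-and-half by their end atoms,
painter's-algorithm depth sorting, white background, no anti-aliasing. The
projection scale is computed once per molecule from its rotation-invariant
bounding sphere, so apparent size does not change between poses.

Bonds can be perceived from interatomic distances alone: i and j are bonded
iff  min_bond_distance <= d(i,j) <= r_cov(i) + r_cov(j) + bond_tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

from .chem_prep import Conformer3D
from .elements import element_info


@dataclass(frozen=True)
class SnapshotConfig:
    """All depiction parameters, with screen-capture defaults.

    bond_radius_mA is in milliangstroms and taken literally: the 14.5 mA
    default draws sub-pixel sticks at 256 px that rasterize one pixel wide.
    ``JMOL_STICK_PRESET`` (145 mA) gives conventional stick thickness.
    """

    angle_increments: tuple[float, float, float] = (176.0, 176.0, 176.0)
    pixel_size: tuple[int, int] = (256, 256)
    zoom_percent: float = 100.0
    atom_vdw_percent: float = 23.0
    bond_radius_mA: float = 14.5
    min_bond_distance_A: float = 0.4
    bond_tolerance_A: float = 0.8
    molecules_per_sdf: int = 100
    background: tuple[int, int, int] = (255, 255, 255)
    margin_fraction: float = 0.05  # frame fraction kept clear at zoom 100%

    def __post_init__(self) -> None:
        for inc in self.angle_increments:
            if not (0 < inc <= 360):
                raise ValueError("angle increments must be in (0, 360]")
        if self.pixel_size[0] <= 0 or self.pixel_size[1] <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.atom_vdw_percent <= 0:
            raise ValueError("atom_vdw_percent must be positive")

    @property
    def bond_radius_A(self) -> float:
        return self.bond_radius_mA / 1000.0


#: thicker-stick preset (the conventional on-screen stick radius)
JMOL_STICK_PRESET = SnapshotConfig(bond_radius_mA=145.0)


@dataclass(frozen=True)
class RotationPose:
    angles: tuple[float, float, float]  # degrees about x, y, z
    rotation: np.ndarray = field(compare=False, default=None)  # 3x3, det +1

    def __post_init__(self) -> None:
        if self.rotation is None:
            object.__setattr__(self, "rotation", rotation_matrix(*self.angles))


@dataclass
class RenderedImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    pose: RotationPose
    compound_id: str = ""

    @property
    def filename(self) -> str:
        tx, ty, tz = (_fmt_angle(a) for a in self.pose.angles)
        return f"{self.compound_id}_{tx}_{ty}_{tz}.png"

    def save(self, directory: str | Path) -> Path:
        path = Path(directory) / self.filename
        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG",
                                                      optimize=False)
        return path


def _fmt_angle(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else f"{a:g}"


def _axis_rotation(axis: int, degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    c, s = math.cos(t), math.sin(t)
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    if axis == 1:  # y-axis has opposite off-diagonal signs
        m[i, j] = s
        m[j, i] = -s
    else:
        m[i, j] = -s
        m[j, i] = s
    return m


def rotation_matrix(tx: float, ty: float, tz: float) -> np.ndarray:
    """Composed rotation Rz @ Ry @ Rx (x applied first) for angles in degrees."""
    return _axis_rotation(2, tz) @ _axis_rotation(1, ty) @ _axis_rotation(0, tx)


def axis_angles(increment: float) -> list[float]:
    """Pose angles for one axis: k * increment for k = 0, 1, ... below 360."""
    if not (0 < increment <= 360):
        raise ValueError("angle increment must be in (0, 360]")
    return [k * increment for k in range(math.ceil(360.0 / increment))]


def enumerate_rotations(
    increments: tuple[float, float, float]) -> list[RotationPose]:
    """Cartesian product of per-axis angle grids, x outermost to z innermost."""
    ax, ay, az = (axis_angles(i) for i in increments)
    return [RotationPose(angles=(tx, ty, tz))
            for tx in ax for ty in ay for tz in az]


def perceive_bonds(conformer: Conformer3D,
                   config: SnapshotConfig = SnapshotConfig()) -> list[tuple[int, int]]:
    """Distance-based bond perception with a covalent-radius ceiling."""
    if conformer.n_atoms < 1:
        raise ValueError("conformer has no atoms")
    r_cov = np.array([element_info(el).covalent_radius
                      for el in conformer.elements])
    d = np.linalg.norm(conformer.coords[:, None, :] - conformer.coords[None, :, :],
                       axis=-1)
    ceiling = r_cov[:, None] + r_cov[None, :] + config.bond_tolerance_A
    bonded = (d >= config.min_bond_distance_A) & (d <= ceiling)
    return [(i, j) for i in range(conformer.n_atoms)
            for j in range(i + 1, conformer.n_atoms) if bonded[i, j]]


# ---------------------------------------------------------------------------
# rasterization


def _drawn_atom_radii(conformer: Conformer3D, config: SnapshotConfig) -> np.ndarray:
    return np.array([element_info(el).vdw_radius for el in conformer.elements]) \
        * (config.atom_vdw_percent / 100.0)


def molecule_scale(conformer: Conformer3D, config: SnapshotConfig) -> float:
    """Pixels per angstrom: bounding sphere (incl. drawn radii) fills
    zoom_percent of the frame minus the fixed margin. Rotation-invariant,
    hence constant across the pose grid."""
    centered = conformer.coords - conformer.coords.mean(axis=0)
    radii = _drawn_atom_radii(conformer, config)
    rmax = float(np.max(np.linalg.norm(centered, axis=1) + radii))
    rmax = max(rmax, 1e-6)
    half_frame = min(config.pixel_size) / 2.0
    return half_frame * (1.0 - config.margin_fraction) \
        * (config.zoom_percent / 100.0) / rmax


def _paint_circle(img: np.ndarray, cx: float, cy: float, r: float,
                  color: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    x0 = max(int(math.floor(cx - r)), 0)
    x1 = min(int(math.ceil(cx + r)) + 1, w)
    y0 = max(int(math.floor(cy - r)), 0)
    y1 = min(int(math.ceil(cy + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r * r
    img[y0:y1, x0:x1][mask] = color


def _paint_capsule(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, r: float,
                   color: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    x0 = max(int(math.floor(min(p0[0], p1[0]) - r)), 0)
    x1 = min(int(math.ceil(max(p0[0], p1[0]) + r)) + 1, w)
    y0 = max(int(math.floor(min(p0[1], p1[1]) - r)), 0)
    y1 = min(int(math.ceil(max(p0[1], p1[1]) + r)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    px, py = np.meshgrid(xs, ys)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        t = np.zeros_like(px)
    else:
        t = np.clip(((px - p0[0]) * d[0] + (py - p0[1]) * d[1]) / len2, 0.0, 1.0)
    dist2 = (px - (p0[0] + t * d[0])) ** 2 + (py - (p0[1] + t * d[1])) ** 2
    img[y0:y1, x0:x1][dist2 <= r * r] = color


def render_pose(conformer: Conformer3D, pose: RotationPose,
                config: SnapshotConfig = SnapshotConfig(),
                bonds: Optional[Sequence[tuple[int, int]]] = None,
                scale: Optional[float] = None) -> RenderedImage:
    """Rasterize one pose to an RGB buffer.

    Primitives (atom spheres, bond half-capsules) are depth-sorted and
    painted back to front; +z after rotation faces the viewer. Pure
    function of its inputs.
    """
    if conformer.n_atoms == 0:
        raise ValueError("cannot render a zero-atom conformer")
    w, h = config.pixel_size
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = config.background

    if bonds is None:
        bonds = conformer.bonds if conformer.bonds else perceive_bonds(conformer, config)
    if scale is None:
        scale = molecule_scale(conformer, config)

    centered = conformer.coords - conformer.coords.mean(axis=0)
    rot = centered @ pose.rotation.T
    cx, cy = w / 2.0, h / 2.0
    px = cx + scale * rot[:, 0]
    py = cy - scale * rot[:, 1]  # screen y grows downward
    depth = rot[:, 2]

    radii_px = _drawn_atom_radii(conformer, config) * scale
    colors = [element_info(el).cpk_color for el in conformer.elements]
    bond_r_px = max(config.bond_radius_A * scale, 0.5)  # keep >= 1 px wide

    # primitive list: (depth, kind, payload); bonds split at the midpoint so
    # each half carries its atom's color, as conventional viewers draw them
    prims: list[tuple[float, int, tuple]] = []
    for i in range(conformer.n_atoms):
        prims.append((float(depth[i]), 1, ("atom", i)))
    for i, j in bonds:
        mid_px = np.array([(px[i] + px[j]) / 2.0, (py[i] + py[j]) / 2.0])
        mid_depth = (depth[i] + depth[j]) / 2.0
        for a in (i, j):
            prims.append(((float(depth[a]) + mid_depth) / 2.0, 0,
                          ("bond", a, mid_px)))
    # stable sort: far to near; bonds (kind 0) under atoms at equal depth
    prims.sort(key=lambda p: (p[0], p[1]))

    for _, _, payload in prims:
        if payload[0] == "atom":
            i = payload[1]
            _paint_circle(img, px[i], py[i], radii_px[i], colors[i])
        else:
            _, a, mid = payload
            _paint_capsule(img, np.array([px[a], py[a]]), mid, bond_r_px,
                           colors[a])
    return RenderedImage(pixels=img, pose=pose, compound_id=conformer.compound_id)


def snap_molecule(conformer: Conformer3D,
                  config: SnapshotConfig = SnapshotConfig(),
                  out_dir: Optional[str | Path] = None) -> list[RenderedImage]:
    """Render every pose of the rotation grid; optionally write PNGs.

    Filenames follow ``<compound_id>_<tx>_<ty>_<tz>.png``.
    """
    bonds = conformer.bonds if conformer.bonds else perceive_bonds(conformer, config)
    scale = molecule_scale(conformer, config)
    images = [render_pose(conformer, pose, config, bonds=bonds, scale=scale)
              for pose in enumerate_rotations(config.angle_increments)]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for im in images:
            im.save(out)
    return images


def split_sdf_batches(conformers: Sequence[Conformer3D],
                      config: SnapshotConfig = SnapshotConfig()) -> list[list[Conformer3D]]:
    """Chunk conformers into SDF-sized batches of molecules_per_sdf."""
    n = config.molecules_per_sdf
    if n < 1:
        raise ValueError("molecules_per_sdf must be >= 1")
    return [list(conformers[i:i + n]) for i in range(0, len(conformers), n)]
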