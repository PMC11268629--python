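"""Deterministic synthetic data: helical filaments, membranes, label stacks.

These generators emulate the inputs the annotation tools are designed for —
a tomogram containing a helical filament with known lattice parameters, a
membrane-like sheet or sphere annotated with per-slice point strips, and a
sparsely annotated label volume — each with exact ground truth attached so
recovery can be measured.  All randomness flows from an explicit seed; the
same spec always produces the identical output.

Real tomograms differ from these fixtures in ways that matter: they carry
missing-wedge anisotropy, contrast transfer, and crowding, none of which is
modelled here.  The fixtures validate the geometry pipelines, not detection
robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tomogeom.core_model import ImageVolume, LabeledVolume, PoseSet, poses_from_points

__all__ = [
    "HelixVolumeSpec",
    "MembraneSpec",
    "LabelStackSpec",
    "make_helix_volume",
    "make_membrane_fixture",
    "make_label_stack",
]


@dataclass(frozen=True)
class HelixVolumeSpec:
    """A straight helical filament of Gaussian blobs along +z.

    The helix has ``n_subunits`` blobs at positions
    ``(cx + radius·cos(j·twist), cy + radius·sin(j·twist), z0 + j·rise)``.
    """

    size: tuple[int, int, int] = (64, 64, 64)  # (z, y, x) voxels
    rise: float = 5.0
    twist: float = 30.0  # degrees per subunit
    radius: float = 8.0
    n_subunits: int = 10
    blob_sigma: float = 1.5
    noise_sigma: float = 0.0
    seed: int = 0


def make_helix_volume(spec: HelixVolumeSpec) -> tuple[ImageVolume, PoseSet]:
    """Synthesise a helix tomogram plus its ground-truth poses."""
    nz, ny, nx = spec.size
    z0 = (nz - 1 - (spec.n_subunits - 1) * spec.rise) / 2
    if z0 < 0:
        raise ValueError(
            f"helix of {spec.n_subunits} subunits at rise {spec.rise} "
            f"exceeds the volume ({nz} z-slices)"
        )
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    j = np.arange(spec.n_subunits)
    theta = np.deg2rad(spec.twist) * j
    truth = np.column_stack(
        [
            cx + spec.radius * np.cos(theta),
            cy + spec.radius * np.sin(theta),
            z0 + spec.rise * j,
        ]
    )
    if truth[:, :2].min() < 0 or truth[:, 0].max() > nx - 1 or truth[:, 1].max() > ny - 1:
        raise ValueError("helix radius exceeds the volume cross-section")

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    data = np.zeros(spec.size)
    for x, y, z in truth:
        d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
        data += np.exp(-d2 / (2 * spec.blob_sigma**2))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sigma, size=data.shape)
    volume = ImageVolume(data=data, pixel_spacing=1.0, experiment_id="synthetic_helix")
    poses = poses_from_points(truth, experiment_id="synthetic_helix", pixel_spacing=1.0)
    return volume, poses


@dataclass(frozen=True)
class MembraneSpec:
    """A membrane-like sheet annotated with per-slice point strips.

    ``kind="plane"`` builds the tilted plane x = z (the surface
    z - x = const through the volume centre); ``kind="sphere"`` builds a
    spherical shell; ``kind="sine"`` a gently corrugated sheet
    ``x = x0 + amplitude·sin(2πy/period)``.  Strips are sampled on the
    surface at ``n_slices`` z-levels with ``points_per_strip`` picks each,
    jittered by ``jitter`` voxels.
    """

    kind: str = "plane"
    size: tuple[int, int, int] = (64, 64, 64)
    n_slices: int = 5
    points_per_strip: int = 6
    sphere_radius: float = 40.0
    sine_amplitude: float = 4.0
    sine_period: float = 40.0
    shell_sigma: float = 1.5
    jitter: float = 0.0
    seed: int = 0


def _plane_strips(spec: MembraneSpec):
    nz, ny, nx = spec.size
    zs = np.linspace(nz * 0.2, nz * 0.8, spec.n_slices)
    ys = np.linspace(ny * 0.1, ny * 0.9, spec.points_per_strip)
    strips = [np.column_stack([np.full_like(ys, z), ys, np.full_like(ys, z)]) for z in zs]
    normal = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)

    def normal_at(point):
        return normal

    return strips, normal_at


def _sphere_strips(spec: MembraneSpec):
    nz, ny, nx = spec.size
    center = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    r = spec.sphere_radius
    zs = center[2] + np.linspace(-0.5, 0.5, spec.n_slices) * r
    strips = []
    for z in zs:
        ring_r = np.sqrt(r**2 - (z - center[2]) ** 2)
        phi = np.linspace(-np.pi / 3, np.pi / 3, spec.points_per_strip)
        strips.append(
            np.column_stack(
                [
                    center[0] + ring_r * np.cos(phi),
                    center[1] + ring_r * np.sin(phi),
                    np.full_like(phi, z),
                ]
            )
        )

    def normal_at(point):
        v = np.asarray(point, dtype=float) - center
        return v / np.linalg.norm(v)

    return strips, normal_at


def _sine_strips(spec: MembraneSpec):
    nz, ny, nx = spec.size
    x0 = (nx - 1) / 2
    zs = np.linspace(nz * 0.2, nz * 0.8, spec.n_slices)
    ys = np.linspace(ny * 0.1, ny * 0.9, spec.points_per_strip)
    strips = []
    for z in zs:
        xs = x0 + spec.sine_amplitude * np.sin(2 * np.pi * ys / spec.sine_period)
        strips.append(np.column_stack([xs, ys, np.full_like(ys, z)]))

    def normal_at(point):
        # surface F(x,y) = x - x0 - A sin(2πy/P) = 0; ∇F = (1, -A·2π/P·cos, 0)
        y = point[1]
        grad = np.array(
            [
                1.0,
                -spec.sine_amplitude
                * 2
                * np.pi
                / spec.sine_period
                * np.cos(2 * np.pi * y / spec.sine_period),
                0.0,
            ]
        )
        return grad / np.linalg.norm(grad)

    return strips, normal_at


def make_membrane_fixture(spec: MembraneSpec):
    """Synthesise a membrane volume, its per-slice picks, and analytic normals.

    Returns ``(volume, strips, normal_at)`` where ``strips`` is a list of
    ordered (x, y, z) point rows (one per annotated z-slice) and
    ``normal_at(point)`` evaluates the true surface normal.
    """
    builders = {"plane": _plane_strips, "sphere": _sphere_strips, "sine": _sine_strips}
    if spec.kind not in builders:
        raise ValueError(f"unknown membrane kind {spec.kind!r}")
    strips, normal_at = builders[spec.kind](spec)
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        strips = [s + rng.normal(0.0, spec.jitter, size=s.shape) for s in strips]

    nz, ny, nx = spec.size
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij", sparse=True
    )
    if spec.kind == "plane":
        dist = (xx - zz) / np.sqrt(2) + 0 * yy
    elif spec.kind == "sphere":
        center = ((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2)
        dist = (
            np.sqrt(
                (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
            )
            - spec.sphere_radius
        )
    else:
        x0 = (nx - 1) / 2
        dist = xx - x0 - spec.sine_amplitude * np.sin(2 * np.pi * yy / spec.sine_period) + 0 * zz
    data = np.exp(-(dist**2) / (2 * spec.shell_sigma**2))
    volume = ImageVolume(
        data=np.broadcast_to(data, (nz, ny, nx)).copy(),
        pixel_spacing=1.0,
        experiment_id=f"synthetic_{spec.kind}",
    )
    return volume, strips, normal_at


@dataclass(frozen=True)
class LabelStackSpec:
    """Sparse annotated slices with analytic shapes at known positions.

    Each entry of ``disks`` is ``(slice_index, label, cy, cx, radius)``;
    each entry of ``squares`` is ``(slice_index, label, cy, cx, half_size)``.
    All other slices are empty.
    """

    size: tuple[int, int, int] = (11, 64, 64)
    disks: tuple = ((0, 1, 32, 32, 4.0), (10, 1, 32, 32, 8.0))
    squares: tuple = ()
    seed: int = 0


def make_label_stack(spec: LabelStackSpec) -> LabeledVolume:
    data = np.zeros(spec.size, dtype=np.int32)
    yy, xx = np.meshgrid(
        np.arange(spec.size[1]), np.arange(spec.size[2]), indexing="ij", sparse=True
    )
    for z, label, cy, cx, radius in spec.disks:
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        data[z][mask] = label
    for z, label, cy, cx, half in spec.squares:
        mask = (np.abs(yy - cy) <= half) & (np.abs(xx - cx) <= half)
        data[z][mask] = label
    return LabeledVolume(data)
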