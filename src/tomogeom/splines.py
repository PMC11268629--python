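"""Parametric 3D splines with arc-length reparametrisation and moving frames.

The computational substrate of filament and surface picking.  A curve is fit
as a B-spline through (or near, when smoothing) the control points; a dense
arc-length table maps the spline parameter ``t ∈ [0, 1]`` to cumulative
Euclidean length, so samples can be placed equidistantly *in space* rather
than in parameter.  Orientations along the curve come from a
rotation-minimising frame (double-reflection parallel transport), which is
twist-free and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate

__all__ = ["Spline3D", "fit_spline", "sample_equidistant", "frames_along"]

#: minimum number of parameter samples in the arc-length table
MIN_ARC_SAMPLES = 1000


@dataclass
class Spline3D:
    """A smoothed parametric 3D curve with an arc-length map.

    Attributes
    ----------
    control_points
        The ``(M, 3)`` input points the spline was fit to.
    order
        Effective spline order ``k`` (requested order demoted to ``M - 1``
        when too few points are given).
    smoothing
        Smoothing factor ``s`` of the least-squares fit; ``0`` interpolates.
    tck
        The scipy ``splprep`` representation.
    arc_params, arc_lengths
        Dense monotone table mapping parameter to cumulative length;
        ``arc_lengths[-1]`` is the total curve length.
    control_params
        Chord-length parameter assigned to each control point by the fit.
    """

    control_points: np.ndarray
    order: int
    smoothing: float
    tck: tuple
    arc_params: np.ndarray
    arc_lengths: np.ndarray
    control_params: np.ndarray = None

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])

    def __call__(self, t, derivative: int = 0) -> np.ndarray:
        """Evaluate position (or a parameter-derivative) at parameter(s) t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack(interpolate.splev(t, self.tck, der=derivative), axis=-1)

    def arc_to_param(self, lengths) -> np.ndarray:
        """Invert the arc-length map by monotone linear interpolation."""
        return np.interp(np.asarray(lengths, dtype=float), self.arc_lengths, self.arc_params)

    def tangent(self, t) -> np.ndarray:
        """Unit tangent vector(s) at parameter(s) t."""
        d = self(t, derivative=1)
        norms = np.linalg.norm(d, axis=-1, keepdims=True)
        if np.any(norms < 1e-12):
            bad = np.nonzero(norms.ravel() < 1e-12)[0]
            raise ArithmeticError(f"zero tangent at parameter index {bad[0]}")
        return d / norms


def fit_spline(points: np.ndarray, order: int = 3, smoothing: float = 0.0) -> Spline3D:
    """Fit a parametric B-spline through 3D points.

    With ``smoothing=0`` the curve interpolates the points in order; larger
    values perform a least-squares smoothing fit.  The requested ``order`` is
    demoted to ``M - 1`` when only ``M <= order`` points are supplied.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    m = len(points)
    if m < 2:
        raise ValueError(f"need at least 2 points to fit a spline, got {m}")
    if not np.all(np.isfinite(points)):
        raise ValueError("control points contain non-finite coordinates")
    if np.allclose(points, points[0], atol=1e-12):
        raise ValueError("all control points coincide; the curve is degenerate")
    if not 1 <= order <= 5:
        raise ValueError(f"spline order must be in [1, 5], got {order}")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    k = min(order, m - 1)
    # chord-length parametrisation in [0, 1]; splprep does this via u=None
    tck, u = interpolate.splprep(points.T, k=k, s=smoothing, u=None)
    n_arc = max(MIN_ARC_SAMPLES, 10 * m * (k + 1))
    params = np.linspace(0.0, 1.0, n_arc)
    xyz = np.stack(interpolate.splev(params, tck), axis=-1)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    lengths = np.concatenate([[0.0], np.cumsum(seg)])
    if lengths[-1] <= 0:
        raise ValueError("spline has zero length")
    return Spline3D(
        control_points=points,
        order=k,
        smoothing=float(smoothing),
        tck=tck,
        arc_params=params,
        arc_lengths=lengths,
        control_params=np.asarray(u, dtype=float),
    )


def sample_equidistant(spline: Spline3D, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the curve at points equidistant in Euclidean arc length.

    ``K = max(2, round(L/spacing) + 1)`` samples are placed at arc lengths
    ``j · L/(K-1)``: exact equidistance is preferred over hitting the nominal
    spacing, and both endpoints are always included.

    Returns
    -------
    points : (K, 3) array
    params : (K,) parameter values of the samples
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    total = spline.length
    k = max(2, int(round(total / spacing)) + 1)
    arcs = np.linspace(0.0, total, k)
    params = spline.arc_to_param(arcs)
    params[0], params[-1] = 0.0, 1.0
    return spline(params), params


def _seed_normal(tangent: np.ndarray) -> np.ndarray:
    """Deterministic initial frame normal: project the coordinate axis with
    the smallest-magnitude tangent component into the normal plane."""
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(tangent)))] = 1.0
    normal = axis - np.dot(axis, tangent) * tangent
    return normal / np.linalg.norm(normal)


def _double_reflection(points: np.ndarray, tangents: np.ndarray, r0: np.ndarray) -> np.ndarray:
    """Rotation-minimising frame transport (double-reflection method).

    Given curve samples, unit tangents, and an initial normal, returns the
    parallel-transported normal at every sample.
    """
    normals = np.empty_like(tangents)
    normals[0] = r0
    for i in range(len(points) - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-300:
            normals[i + 1] = normals[i]
            continue
        r_l = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        t_l = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - t_l
        c2 = np.dot(v2, v2)
        if c2 < 1e-300:
            normals[i + 1] = r_l
        else:
            normals[i + 1] = r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
    return normals


def frames_along(spline: Spline3D, parameters: np.ndarray) -> np.ndarray:
    """Twist-free orthonormal frames at the given parameters.

    Each frame is a proper rotation whose **third column** (local Z) is the
    unit tangent; X and Y are carried along the curve by rotation-minimising
    (double-reflection) parallel transport seeded at ``t = 0``, so frames
    never flip along smooth curves.  On a straight line along +z the frame is
    the identity.
    """
    parameters = np.atleast_1d(np.asarray(parameters, dtype=float))
    if parameters.size and (parameters.min() < -1e-9 or parameters.max() > 1 + 1e-9):
        raise ValueError("parameters must lie in [0, 1]")
    # transport over a dense grid that contains the requested parameters so
    # accuracy does not depend on how coarse the request is
    dense = np.union1d(np.linspace(0.0, 1.0, 512), np.clip(parameters, 0.0, 1.0))
    pts = spline(dense)
    tans = spline.tangent(dense)
    normals = _double_reflection(pts, tans, _seed_normal(tans[0]))
    idx = np.searchsorted(dense, np.clip(parameters, 0.0, 1.0))
    frames = np.empty((parameters.size, 3, 3))
    for j, i in enumerate(idx):
        z = tans[i]
        x = normals[i] - np.dot(normals[i], z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        frames[j] = np.stack([x, y, z], axis=1)
    return frames
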