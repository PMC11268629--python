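"""Euler-angle conventions of the particle formats.

Orientation matrices throughout the package map reference-frame basis
vectors onto particle basis vectors.  Under that semantics:

* **relion_zyz** (rot, tilt, psi in degrees):
  ``R = Rz(-rot) · Ry(-tilt) · Rz(-psi)``.
* **dynamo_zxz** (tdrot, tilt, narot in degrees):
  ``R = Rz(-tdrot) · Rx(-tilt) · Rz(-narot)``.

``matrix_to_euler`` is the exact inverse away from gimbal lock; at lock
(tilt = 0 or 180) the in-plane rotation is assigned entirely to the first
angle and the third is set to 0, and the round trip through matrices is
still exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["EulerTriple", "euler_to_matrix", "matrix_to_euler", "CONVENTIONS"]

CONVENTIONS = ("relion_zyz", "dynamo_zxz")
_SEQ = {"relion_zyz": "ZYZ", "dynamo_zxz": "ZXZ"}


@dataclass(frozen=True)
class EulerTriple:
    """Three Euler angles in degrees under a named convention."""

    angles: tuple[float, float, float]
    convention: str = "relion_zyz"

    def __post_init__(self) -> None:
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; expected one of {CONVENTIONS}"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("Euler angles must be finite")


def euler_to_matrix(e: EulerTriple) -> np.ndarray:
    """Rotation matrix (reference→particle) for an Euler triple."""
    seq = _SEQ[e.convention]
    return Rotation.from_euler(seq, [-a for a in e.angles], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray, convention: str = "relion_zyz") -> EulerTriple:
    """Euler triple of a rotation matrix under the given convention."""
    if convention not in CONVENTIONS:
        raise ValueError(
            f"unknown convention {convention!r}; expected one of {CONVENTIONS}"
        )
    seq = _SEQ[convention]
    with warnings.catch_warnings():
        # at gimbal lock scipy warns and zeroes the third angle -- exactly
        # the documented behaviour here, so the warning is noise
        warnings.filterwarnings("ignore", message="Gimbal lock")
        angles = Rotation.from_matrix(np.asarray(matrix, dtype=float)).as_euler(
            seq, degrees=True
        )
    return EulerTriple(angles=tuple(-angles), convention=convention)


def eulers_to_matrices(angles: np.ndarray, convention: str) -> np.ndarray:
    """Vectorised euler→matrix for an (N, 3) angle array."""
    angles = np.asarray(angles, dtype=float).reshape(-1, 3)
    if len(angles) == 0:
        return np.empty((0, 3, 3))
    return Rotation.from_euler(_SEQ[convention], -angles, degrees=True).as_matrix()


def matrices_to_eulers(matrices: np.ndarray, convention: str) -> np.ndarray:
    """Vectorised matrix→euler for an (N, 3, 3) matrix array."""
    matrices = np.asarray(matrices, dtype=float).reshape(-1, 3, 3)
    if len(matrices) == 0:
        return np.empty((0, 3))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        return -Rotation.from_matrix(matrices).as_euler(_SEQ[convention], degrees=True)
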