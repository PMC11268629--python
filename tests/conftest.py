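import numpy as np
import pandas as pd
import pytest

from tomogeom.core_model import PoseSet


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Proper rotation matrices via QR decomposition with det fixed to +1."""
    out = np.empty((n, 3, 3))
    for i in range(n):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))  # make the factorisation unique
        if np.linalg.det(q) < 0:
            q[:, 2] = -q[:, 2]
        out[i] = q
    return out


def smooth_random_curve(rng: np.random.Generator, n_points: int = 12) -> np.ndarray:
    """A smooth, non-self-intersecting 3D polyline: a random-walk direction
    with small angular increments, so consecutive segments bend gently."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    points = [np.zeros(3)]
    for _ in range(n_points - 1):
        direction = direction + 0.25 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        points.append(points[-1] + direction * rng.uniform(8.0, 12.0))
    return np.asarray(points)


def random_poseset(rng: np.random.Generator, n: int = 10, exp_id: str = "tomo_1") -> PoseSet:
    return PoseSet(
        positions=rng.uniform(0, 200, size=(n, 3)),
        orientations=random_rotations(n, rng),
        features=pd.DataFrame({"score": rng.uniform(0, 1, n)}),
        experiment_id=exp_id,
        pixel_spacing=1.5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
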