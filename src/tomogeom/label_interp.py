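"""Dense segmentation from sparse slices by signed-distance-field averaging.

A label volume annotated on only a few slices along one dimension is filled
in between them: for each label, the (n-1)-dimensional signed distance field
(SDF) of every annotated slice is computed (positive inside the label,
negative outside), the SDFs of the two bounding annotated slices are
linearly averaged at each intermediate slice with weights proportional to
the distance from the *other* slice, and a voxel joins the interpolated
label wherever the averaged field is strictly positive.  Competing labels
are resolved by the largest field value.

Annotated slices pass through unchanged; slices outside the annotated range
stay empty (no extrapolation).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from tomogeom.core_model import LabeledVolume

__all__ = ["signed_distance_field", "interpolate_labels"]


def signed_distance_field(mask: np.ndarray, cap: float | None = None) -> np.ndarray:
    """Euclidean signed distance field of a binary mask.

    Positive inside the mask (distance to the nearest background voxel),
    negative outside (minus the distance to the nearest mask voxel), clipped
    to ``±cap``.  An empty mask gives a uniform ``-cap`` field ("label
    absent"), a full mask uniform ``+cap``.  The default cap — the sum of the
    slice dimensions, an unreachable distance — keeps averages finite.
    """
    mask = np.asarray(mask, dtype=bool)
    if cap is None:
        cap = float(sum(mask.shape))
    if not mask.any():
        return np.full(mask.shape, -cap)
    if mask.all():
        return np.full(mask.shape, cap)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return np.clip(inside - outside, -cap, cap)


def interpolate_labels(labels: LabeledVolume, dim: int = 0) -> LabeledVolume:
    """Fill empty slices between annotated slices along ``dim``.

    A slice is *annotated* when it contains any nonzero label.  For an empty
    slice at position ``x`` strictly between consecutive annotated slices
    ``a < b``, each label's field is
    ``((b - x)·SDF_a + (x - a)·SDF_b) / (b - a)``; the voxel is assigned the
    label with the largest field value, provided that value is > 0.

    Raises ``ValueError`` with fewer than 2 annotated slices or a bad dim.
    """
    data = np.asarray(labels.data)
    if not -data.ndim <= dim < data.ndim:
        raise ValueError(f"dim {dim} out of range for {data.ndim}D labels")
    moved = np.moveaxis(data, dim, 0)
    annotated = [i for i in range(moved.shape[0]) if moved[i].any()]
    if len(annotated) < 2:
        raise ValueError(
            f"need at least 2 annotated slices along dim {dim}, found {len(annotated)}"
        )
    label_ids = np.unique(moved)
    label_ids = label_ids[label_ids != 0]
    out = moved.copy()
    cap = float(sum(moved.shape[1:]))

    for a, b in zip(annotated[:-1], annotated[1:]):
        if b - a < 2:
            continue
        sdf_a = {lab: signed_distance_field(moved[a] == lab, cap) for lab in label_ids}
        sdf_b = {lab: signed_distance_field(moved[b] == lab, cap) for lab in label_ids}
        for x in range(a + 1, b):
            best_field = np.full(moved.shape[1:], -np.inf)
            best_label = np.zeros(moved.shape[1:], dtype=out.dtype)
            for lab in label_ids:
                # integer-weighted form: exact where the average crosses zero
                field = ((b - x) * sdf_a[lab] + (x - a) * sdf_b[lab]) / (b - a)
                better = field > best_field
                best_field = np.where(better, field, best_field)
                best_label = np.where(better, lab, best_label)
            out[x] = np.where(best_field > 0, best_label, 0)

    return LabeledVolume(np.moveaxis(out, 0, dim))
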