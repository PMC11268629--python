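"""Signed-distance-field computation and sparse-slice label interpolation."""

import numpy as np
import pytest

from tomogeom.core_model import LabeledVolume
from tomogeom.fixtures import LabelStackSpec, make_label_stack
from tomogeom.label_interp import interpolate_labels, signed_distance_field


def disk_mask(shape, cy, cx, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def brute_force_sdf(mask):
    """All-pairs distance oracle: for each pixel, the exact Euclidean
    distance to the nearest pixel of the opposite value, signed."""
    yy, xx = np.meshgrid(*map(np.arange, mask.shape), indexing="ij")
    inside = np.column_stack([yy[mask], xx[mask]])
    outside = np.column_stack([yy[~mask], xx[~mask]])
    out = np.empty(mask.shape)
    pix = np.stack([yy, xx], axis=-1).reshape(-1, 2)
    d_out = np.sqrt(((pix[:, None] - outside[None]) ** 2).sum(-1)).min(1)
    d_in = np.sqrt(((pix[:, None] - inside[None]) ** 2).sum(-1)).min(1)
    out.flat = np.where(mask.ravel(), d_out, -d_in)
    return out


class TestSignedDistanceField:
    def test_disk_center_value_matches_all_pairs_oracle(self):
        mask = disk_mask((32, 32), 16, 16, 8)
        sdf = signed_distance_field(mask)
        oracle = brute_force_sdf(mask)
        assert sdf[16, 16] == pytest.approx(oracle[16, 16], abs=1e-9)
        assert abs(sdf[16, 16] - 8) <= 1.0
        # full-field agreement with the oracle (same EDT definition)
        np.testing.assert_allclose(sdf, oracle, atol=1e-9)

    def test_empty_and_full_masks(self):
        empty = signed_distance_field(np.zeros((8, 8), bool), cap=16)
        np.testing.assert_array_equal(empty, -16)
        full = signed_distance_field(np.ones((8, 8), bool), cap=16)
        np.testing.assert_array_equal(full, 16)

    def test_complement_antisymmetry(self):
        mask = disk_mask((32, 32), 16, 16, 7)
        a = signed_distance_field(mask)
        b = signed_distance_field(~mask)
        # fields are negatives up to the one-voxel boundary band
        assert np.abs(a + b).max() <= 1.0 + 1e-9

    def test_cap_clips(self):
        sdf = signed_distance_field(disk_mask((64, 64), 32, 32, 2), cap=5)
        assert sdf.min() == -5 and sdf.max() <= 5


class TestInterpolateLabels:
    def test_identical_disks_fill_through(self):
        spec = LabelStackSpec(disks=((0, 1, 32, 32, 6.0), (10, 1, 32, 32, 6.0)))
        dense = interpolate_labels(make_label_stack(spec), dim=0)
        ref = dense.data[0]
        for z in range(1, 10):
            # same disk up to a 1-voxel boundary band
            diff = dense.data[z] != ref
            yy, xx = np.nonzero(diff)
            if len(yy):
                r = np.sqrt((yy - 32) ** 2 + (xx - 32) ** 2)
                assert np.all(np.abs(r - 6.0) <= 1.5)

    def test_concentric_disks_average_radius(self):
        dense = interpolate_labels(make_label_stack(LabelStackSpec()), dim=0)
        mid = dense.data[5]
        assert set(np.unique(mid)) <= {0, 1}
        radius = np.sqrt(mid.sum() / np.pi)
        assert abs(radius - 6.0) <= 1.0
        # every interpolated disk stays concentric and round
        yy, xx = np.nonzero(mid)
        assert abs(yy.mean() - 32) < 0.5 and abs(xx.mean() - 32) < 0.5

    def test_annotated_slices_copied_exactly(self):
        stack = make_label_stack(LabelStackSpec())
        dense = interpolate_labels(stack, dim=0)
        np.testing.assert_array_equal(dense.data[0], stack.data[0])
        np.testing.assert_array_equal(dense.data[10], stack.data[10])

    def test_outside_annotated_range_stays_empty(self):
        spec = LabelStackSpec(size=(15, 64, 64), disks=((2, 1, 32, 32, 5.0), (9, 1, 32, 32, 5.0)))
        dense = interpolate_labels(make_label_stack(spec), dim=0)
        assert not dense.data[:2].any() and not dense.data[10:].any()

    def test_two_disjoint_labels_stay_disjoint(self):
        spec = LabelStackSpec(
            disks=(),
            squares=(
                (0, 1, 16, 16, 6), (10, 1, 16, 16, 6),
                (0, 2, 48, 48, 6), (10, 2, 48, 48, 6),
            ),
        )
        dense = interpolate_labels(make_label_stack(spec), dim=0)
        for z in range(11):
            sl = dense.data[z]
            assert set(np.unique(sl)) <= {0, 1, 2}
            # each voxel has exactly one label by construction of the output
            assert (sl[:32, :32] != 2).all() and (sl[32:, 32:] != 1).all()

    def test_matches_per_label_brute_force_oracle(self, rng):
        for _ in range(20):
            shape = (7, 24, 24)
            data = np.zeros(shape, dtype=np.int32)
            for z in (0, 6):
                for lab in (1, 2):
                    cy, cx = rng.integers(5, 19, size=2)
                    r = rng.uniform(2, 5)
                    mask = disk_mask(shape[1:], cy, cx, r)
                    data[z][mask & (data[z] == 0)] = lab
            if not (data[0].any() and data[6].any()):
                continue
            dense = interpolate_labels(LabeledVolume(data), dim=0)
            cap = float(shape[1] + shape[2])
            for z in range(1, 6):
                fields = {}
                for lab in (1, 2):
                    fa = signed_distance_field(data[0] == lab, cap)
                    fb = signed_distance_field(data[6] == lab, cap)
                    fields[lab] = ((6 - z) * fa + z * fb) / 6
                best = np.maximum(fields[1], fields[2])
                expect = np.where(
                    best > 0, np.where(fields[1] >= fields[2], 1, 2), 0
                )
                np.testing.assert_array_equal(dense.data[z], expect)

    def test_reversal_symmetry(self):
        spec = LabelStackSpec(disks=((0, 1, 20, 40, 4.0), (10, 1, 44, 24, 8.0)))
        stack = make_label_stack(spec)
        fwd = interpolate_labels(stack, dim=0).data
        rev = interpolate_labels(LabeledVolume(stack.data[::-1].copy()), dim=0).data
        np.testing.assert_array_equal(fwd, rev[::-1])

    def test_monotone_inclusion(self):
        # label 2's square sits inside label 1's disk on both bounding slices
        data = np.zeros((9, 48, 48), dtype=np.int32)
        for z in (0, 8):
            data[z][disk_mask((48, 48), 24, 24, 14)] = 1
            data[z][20:28, 20:28] = 2
        dense = interpolate_labels(LabeledVolume(data), dim=0)
        for z in range(9):
            region1 = dense.data[z] >= 1
            region2 = dense.data[z] == 2
            # the inner label never escapes the outer one's footprint
            assert not (region2 & ~region1).any()

    def test_errors(self):
        one_slice = np.zeros((5, 8, 8), dtype=np.int32)
        one_slice[2, 4, 4] = 1
        with pytest.raises(ValueError, match="2 annotated"):
            interpolate_labels(LabeledVolume(one_slice), dim=0)
        with pytest.raises(ValueError, match="dim"):
            interpolate_labels(LabeledVolume(one_slice), dim=7)
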