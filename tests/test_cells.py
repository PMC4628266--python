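import numpy as np
import pytest
from scipy import ndimage

from parenchyma3d.cells import (
    cell_morphometrics,
    remove_border_labels,
    virtual_sieve,
    watershed_separate,
)
from conftest import two_ball_mask


def test_two_fused_balls_split_into_two_labels():
    mask, c1, c2 = two_ball_mask(d_um=150.0, gap_um=140.0, pitch_um=2.5)
    labels = watershed_separate(mask, 2.5, h_min_um=10.0)
    assert labels.max() == 2
    l1 = labels[int(c1[0]), int(c1[1]), int(c1[2])]
    l2 = labels[int(c2[0]), int(c2[1]), int(c2[2])]
    assert l1 != 0 and l2 != 0 and l1 != l2


def test_single_ball_single_label(ball200):
    labels = watershed_separate(ball200.voids, 2.0)
    assert labels.max() == 1
    assert (labels > 0).sum() == ball200.voids.sum()


def test_watershed_conserves_volume():
    mask, _, _ = two_ball_mask()
    labels = watershed_separate(mask, 2.5)
    assert (labels > 0).sum() == mask.sum()
    assert not (labels[~mask]).any()


def test_empty_mask_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        labels = watershed_separate(np.zeros((5, 5, 5), bool), 2.0)
    assert labels.max() == 0


def test_border_removal_interior_untouched(ball200):
    labels = ndimage.label(ball200.voids)[0]
    out, frac = remove_border_labels(labels)
    np.testing.assert_array_equal(out, labels)
    assert frac == 0.0


def test_border_removal_full_domain_label():
    labels = np.ones((5, 5, 5), np.int32)
    out, frac = remove_border_labels(labels)
    assert not out.any()
    assert frac == 1.0


def test_border_removal_fraction_matches_recount(phantom_1mm):
    _, masks, _ = phantom_1mm
    labels = watershed_separate(masks.cells, 8.0)
    out, frac = remove_border_labels(labels)
    recount = 1.0 - (out > 0).sum() / (labels > 0).sum()
    assert frac == pytest.approx(recount)
    # brute-force face scan agrees on which labels had to go
    faces = np.concatenate([
        labels[0].ravel(), labels[-1].ravel(),
        labels[:, 0].ravel(), labels[:, -1].ravel(),
        labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
    ])
    gone = set(np.unique(faces)) - {0}
    assert gone == set(np.unique(labels)) - set(np.unique(out)) - {0}


def test_ball_morphometrics(ball200):
    labels = ndimage.label(ball200.voids)[0]
    t = cell_morphometrics(labels, None, 2.0)
    row = t.iloc[0]
    assert row.esd_um == pytest.approx(200.0, abs=2.0)
    assert row.elongation <= 1.05
    assert row.sphericity >= 0.97
    assert row.max_length_um == pytest.approx(200.0, abs=6.0)
    assert not row.touches_border


def test_ellipsoid_elongation_two_to_one():
    zz, yy, xx = np.indices((130, 70, 70)).astype(float)
    ell = ((zz - 65) / 60) ** 2 + ((yy - 35) / 30) ** 2 + ((xx - 35) / 30) ** 2 <= 1
    t = cell_morphometrics(ell.astype(np.int32), None, 2.0)
    assert t.iloc[0].elongation == pytest.approx(2.0, abs=0.1)


def test_cell_surrounded_by_void_shell():
    labels = np.zeros((20, 20, 20), np.int32)
    labels[5:15, 5:15, 5:15] = 1
    voids = ~(labels > 0)
    t = cell_morphometrics(labels, voids, 2.0)
    assert t.iloc[0].cell_to_void_area_fraction == 1.0


def test_one_voxel_label_degenerate_but_defined():
    labels = np.zeros((5, 5, 5), np.int32)
    labels[2, 2, 2] = 1
    t = cell_morphometrics(labels, None, 2.0)
    row = t.iloc[0]
    assert row.degenerate
    assert row.elongation == pytest.approx(1.0)
    assert np.isfinite(row.sphericity)


def test_sieve_keeps_ball_rejects_plate_and_long(ball200):
    # assemble three objects in one map: a d=200 ball (kept), a fused
    # double-ball spanning ~450 um (length rule), a thin plate (sphericity)
    pitch = 2.5
    fused, _, _ = two_ball_mask(d_um=240.0, gap_um=210.0, pitch_um=pitch)
    f = fused.shape
    ball = ndimage.zoom(ball200.voids, 2.0 / pitch, order=0)
    s = ball.shape
    shape = (f[0] + 10, s[1] + f[1] + 20, max(s[2], f[2], 112) + 120)
    labels = np.zeros(shape, np.int32)
    labels[5:5 + s[0], 5:5 + s[1], 5:5 + s[2]][ball] = 1
    labels[5:5 + f[0], 10 + s[1]:10 + s[1] + f[1], 10:10 + f[2]][fused] = 2
    labels[100:108, 8:108, 120:220] = 3  # 20 x 250 x 250 um plate
    out, rejected = virtual_sieve(labels, pitch)
    kept = set(np.unique(out)) - {0}
    assert kept == {1}
    rules = dict(zip(rejected.label, rejected.rule))
    assert "length" in rules[2]
    assert "sphericity" in rules[3]


def test_sieve_monotone_in_thresholds():
    mask, _, _ = two_ball_mask()
    labels = watershed_separate(mask, 2.5)
    table = cell_morphometrics(labels, None, 2.5)
    loose, _ = virtual_sieve(labels, 2.5, max_length_um=500, min_sphericity=0.5, table=table)
    tight, _ = virtual_sieve(labels, 2.5, max_length_um=160, min_sphericity=0.9, table=table)
    kept_loose = set(np.unique(loose)) - {0}
    kept_tight = set(np.unique(tight)) - {0}
    assert kept_tight <= kept_loose
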