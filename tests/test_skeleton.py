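import numpy as np
import pytest
from scipy import ndimage

from parenchyma3d.phantom import generate_ball, generate_tissue, generate_tube
from parenchyma3d.skeleton import build_graph, network_summary, skeletonize

STRUCT26 = np.ones((3, 3, 3), bool)


def y_fixture(n=81, arm=35, r=3.5):
    """Three tubes meeting at one point (in the z-y plane)."""
    c = n // 2
    zz, yy, xx = np.indices((n, n, n)).astype(float)
    m = np.zeros((n, n, n), bool)
    for uz, uy in [(1.0, 0.0), (-0.5, 0.866), (-0.5, -0.866)]:
        t = np.clip((zz - c) * uz + (yy - c) * uy, 0, arm)
        d2 = (zz - c - t * uz) ** 2 + (yy - c - t * uy) ** 2 + (xx - c) ** 2
        m |= d2 <= r**2
    return m


def test_tube_skeleton_is_single_axis_chain(tube1000):
    sk = skeletonize(tube1000.voids)
    g = build_graph(sk, tube1000.voids, 4.0)
    assert len(g.branches) == 1
    assert g.n_junctions == 0
    assert g.total_length_um == pytest.approx(1000.0, rel=0.05)


def test_ball_skeleton_collapses_to_short_segment(ball200):
    sk = skeletonize(ball200.voids)
    coords = np.argwhere(sk)
    assert 1 <= len(coords) <= 60
    # residue stays well inside the ball: a point or short central segment
    assert (coords.max(axis=0) - coords.min(axis=0)).max() <= 0.55 * 100
    assert ndimage.label(sk, structure=STRUCT26)[1] == 1


def test_component_count_preserved(phantom_1mm):
    _, masks, _ = phantom_1mm
    n_mask = ndimage.label(masks.voids, structure=STRUCT26)[1]
    sk = skeletonize(masks.voids)
    assert ndimage.label(sk, structure=STRUCT26)[1] == n_mask


def test_y_junction_topology():
    m = y_fixture()
    sk = skeletonize(m)
    g = build_graph(sk, m, 4.0)
    assert len(g.branches) == 3
    assert g.n_junctions == 1
    assert g.n_components == 1


def test_local_thickness_matches_tube_radius():
    tube = generate_tube(1000.0, 60.0, axis=0, pitch_um=4.0)
    sk = skeletonize(tube.voids)
    g = build_graph(sk, tube.voids, 4.0)
    thick = np.concatenate([b.thickness_um for b in g.branches])
    assert thick.mean() == pytest.approx(30.0, abs=3.0)


def test_arc_length_at_least_euclidean(phantom_1mm):
    _, masks, _ = phantom_1mm
    sk = skeletonize(masks.voids)
    g = build_graph(sk, masks.voids, 8.0)
    for b in g.branches[:200]:
        chord = np.linalg.norm(b.points_um[-1] - b.points_um[0])
        assert b.length_um >= chord - 1e-6


def test_total_length_additive_over_disjoint_union():
    tube = generate_tube(400.0, 40.0, axis=0, pitch_um=4.0)
    s = tube.voids.shape
    union = np.zeros((s[0] + 10, 50, 50), bool)
    union[5:5 + s[0], 2:2 + s[1], 2:2 + s[2]] = tube.voids
    union[5:5 + s[0], 30:30 + s[1], 30:30 + s[2]] = tube.voids
    g_single = build_graph(skeletonize(tube.voids), tube.voids, 4.0)
    g_union = build_graph(skeletonize(union), union, 4.0)
    assert g_union.total_length_um == pytest.approx(2 * g_single.total_length_um, rel=0.01)
    assert g_union.n_components == 2


def test_network_summary_single_tube(tube1000):
    g = build_graph(skeletonize(tube1000.voids), tube1000.voids, 4.0)
    s = network_summary(g, 1.0)
    assert s["branch_count_per_mm3"] == 0
    assert s["total_path_length_mm_per_mm3"] == pytest.approx(
        g.total_length_um / 1000.0
    )
    assert s["mean_path_per_void_mm"] == s["total_path_length_mm_per_mm3"]


def test_path_length_grows_with_porosity_at_fixed_channel_radius():
    """More channels of the same radius mean more porosity and a longer
    centerline network."""
    lengths, porosities = [], []
    for frag in (0.6, 0.0):
        _, masks, truth = generate_tissue(
            shape_um=(800.0,) * 3, pitch_um=8.0, fragmentation=frag,
            channel_halfwidth_um=10.0, seed=6,
        )
        g = build_graph(skeletonize(masks.voids), masks.voids, 8.0)
        lengths.append(g.total_length_um)
        porosities.append(truth.porosity_realized)
    assert porosities[1] > porosities[0]
    assert lengths[1] > lengths[0]


def test_edge_table_schema(phantom_1mm):
    _, masks, _ = phantom_1mm
    g = build_graph(skeletonize(masks.voids), masks.voids, 8.0)
    t = g.to_edge_table()
    assert {"node_a", "node_b", "length_um", "mean_thickness_um"} <= set(t.columns)
    assert (t.length_um > 0).all()
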