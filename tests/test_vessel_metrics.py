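import math

import networkx as nx
import numpy as np
import pytest

import octaquant as oq
from octaquant.vessel_metrics import Branch, VesselGraph
from conftest import straight_branch, thick_curve


# ---------------------------------------------------------------------------
# thresholding and vessel density
# ---------------------------------------------------------------------------

def test_mean_threshold_constant_and_masked():
    img = np.full((10, 10), 0.4)
    assert oq.compute_mean_threshold(img) == pytest.approx(0.4)
    img[:, 5:] = 1.0
    img[:, :5] = 0.0
    assert oq.compute_mean_threshold(img) == pytest.approx(0.5)
    mask = np.zeros((10, 10), bool)
    mask[:, 5:] = True
    assert oq.compute_mean_threshold(img, mask) == pytest.approx(1.0)
    with pytest.raises(oq.ValidationError):
        oq.compute_mean_threshold(img, np.zeros((10, 10), bool))


def test_binarize_is_inclusive():
    img = np.full((6, 6), 0.4)
    assert oq.binarize(img, 0.4).pixels.all()
    checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
    out = oq.binarize(checker.astype(float), 0.5)
    assert np.array_equal(out.pixels, checker)
    assert not oq.binarize(img, 1.1).pixels.any()


def test_vessel_density_fractions():
    assert oq.vessel_density(oq.BinaryMap(np.ones((5, 5), bool))) == 1.0
    checker = np.indices((8, 8)).sum(axis=0) % 2 == 0
    assert oq.vessel_density(oq.BinaryMap(checker)) == 0.5
    three = np.zeros((3, 3), bool)
    three.flat[:3] = True
    assert oq.vessel_density(oq.BinaryMap(three)) == pytest.approx(1 / 3)


def test_vessel_density_invariant_under_rotation_and_mirroring():
    rng = np.random.default_rng(0)
    px = rng.random((32, 32)) > 0.6
    mask = rng.random((32, 32)) > 0.3
    base = oq.vessel_density(oq.BinaryMap(px), mask)
    for op in (np.rot90, np.fliplr, np.flipud):
        assert oq.vessel_density(oq.BinaryMap(op(px)), op(mask)) == pytest.approx(base)


# ---------------------------------------------------------------------------
# skeletonization
# ---------------------------------------------------------------------------

def _brute_force_thin_check(sk: np.ndarray) -> bool:
    """No 2x2 all-true block outside pixels with >= 3 neighbors."""
    from scipy import ndimage

    counts = ndimage.convolve(sk.astype(int), np.ones((3, 3), int), mode="constant") - sk
    for r in range(sk.shape[0] - 1):
        for c in range(sk.shape[1] - 1):
            block = sk[r : r + 2, c : c + 2]
            if block.all() and (counts[r : r + 2, c : c + 2] < 3).any():
                return False
    return True


def test_skeletonize_bar_is_thin_single_path():
    bar = np.zeros((30, 80), bool)
    bar[10:15, 10:70] = True
    sk = oq.skeletonize(oq.BinaryMap(bar))
    assert _brute_force_thin_check(sk.pixels)
    assert sk.pixels.sum() == pytest.approx(60, abs=3)
    assert (sk.pixels & ~bar).sum() == 0  # subset of input
    from scipy import ndimage

    assert ndimage.label(sk.pixels, np.ones((3, 3)))[1] == 1


def test_skeletonize_single_pixel_fixed_point():
    px = np.zeros((9, 9), bool)
    px[4, 4] = True
    assert np.array_equal(oq.skeletonize(oq.BinaryMap(px)).pixels, px)


def test_skeletonize_annulus_topology():
    yy, xx = np.mgrid[0:120, 0:120]
    d2 = (yy - 60) ** 2 + (xx - 60) ** 2
    ann = (d2 >= 30**2) & (d2 <= 40**2)
    sk = oq.skeletonize(oq.BinaryMap(ann))
    graph = oq.extract_graph(sk)
    assert len(graph.components) == 1
    assert len(graph.endpoints()) == 0
    assert len(graph.branches) == 1


def test_skeletonize_preserves_component_count():
    from scipy import ndimage

    rng = np.random.default_rng(3)
    canvas = np.zeros((120, 120), bool)
    for _ in range(6):  # scatter short thick strokes
        r, c = rng.integers(10, 100, 2)
        ang = rng.uniform(0, math.pi)
        t = np.linspace(0, 15, 60)
        pts = np.column_stack([r + t * math.sin(ang), c + t * math.cos(ang)])
        canvas |= thick_curve(pts, (120, 120), width=3)
    n_before = ndimage.label(canvas, np.ones((3, 3)))[1]
    sk = oq.skeletonize(oq.BinaryMap(canvas))
    n_after = ndimage.label(sk.pixels, np.ones((3, 3)))[1]
    assert n_before == n_after


def test_skeletonize_rejects_empty():
    with pytest.raises(oq.ValidationError):
        oq.skeletonize(oq.BinaryMap(np.zeros((5, 5), bool)))


# ---------------------------------------------------------------------------
# graph extraction
# ---------------------------------------------------------------------------

def test_extract_graph_straight_path():
    px = np.zeros((10, 40), bool)
    px[5, 5:35] = True  # 30 pixels
    g = oq.extract_graph(oq.BinaryMap(px, "skeleton"))
    assert sorted(kind for _, kind in g.nodes.values()) == ["endpoint", "endpoint"]
    assert len(g.branches) == 1
    assert g.branches[0].path_length_px == pytest.approx(29.0)


def test_extract_graph_y_junction():
    y = np.zeros((60, 60), bool)
    y[30, 10:31] = True
    for k in range(21):
        y[30 - k, 30 + k] = True
        y[30 + k, 30 + k] = True
    g = oq.extract_graph(oq.BinaryMap(y, "skeleton"))
    kinds = sorted(kind for _, kind in g.nodes.values())
    assert kinds == ["endpoint", "endpoint", "endpoint", "junction"]
    assert len(g.branches) == 3


def test_extract_graph_isolated_loop():
    rr, cc = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
    loop = np.abs(rr - 10) + np.abs(cc - 10) == 6  # diamond: all degree 2
    g = oq.extract_graph(oq.BinaryMap(loop, "skeleton"))
    assert len(g.branches) == 1
    assert g.branches[0].is_loop
    assert len(g.branches[0].path) == int(loop.sum()) + 1  # closed walk
    (coord, kind), = [v for v in g.nodes.values()]
    assert kind == "loop" and coord == (4, 10)  # topmost-leftmost


def test_extract_graph_rejects_thick_input():
    thick = np.zeros((20, 40), bool)
    thick[5:10, 5:35] = True
    with pytest.raises(oq.ValidationError, match="thin"):
        oq.extract_graph(oq.BinaryMap(thick, "skeleton"))


def test_every_skeleton_pixel_in_branch_or_node():
    truth, _, _ = oq.generate_network(oq.NetworkParams(image_size_px=200), seed=5)
    sk = oq.skeletonize(truth)
    g = oq.extract_graph(sk)
    covered = np.zeros_like(sk.pixels)
    for br in g.branches:
        covered[br.path[:, 0], br.path[:, 1]] = True
    from octaquant.vessel_metrics import _neighbor_counts

    counts = _neighbor_counts(sk.pixels)
    junction = sk.pixels & (counts >= 3)
    assert np.all(sk.pixels <= (covered | junction))


# ---------------------------------------------------------------------------
# roots and Strahler
# ---------------------------------------------------------------------------

def _manual_graph(paths):
    """Build a VesselGraph from explicit pixel paths (test scaffolding)."""
    nodes = {}
    coord_to_id = {}
    g = nx.MultiGraph()
    branches = []

    def nid(coord, kind):
        if coord not in coord_to_id:
            i = len(nodes)
            nodes[i] = (coord, kind)
            coord_to_id[coord] = i
            g.add_node(i)
        return coord_to_id[coord]

    # degree count to decide endpoint/junction kinds
    from collections import Counter

    ends = Counter()
    for p in paths:
        ends[tuple(p[0])] += 1
        ends[tuple(p[-1])] += 1
    for p in paths:
        a = nid(tuple(p[0]), "endpoint" if ends[tuple(p[0])] == 1 else "junction")
        b = nid(tuple(p[-1]), "endpoint" if ends[tuple(p[-1])] == 1 else "junction")
        br = Branch(path=np.array(p), id=len(branches))
        branches.append(br)
        g.add_edge(a, b, key=br.id, branch=br)
    return VesselGraph(nodes=nodes, branches=branches, graph=g)


def test_detect_roots_nearest_endpoint_and_ties():
    path = [(0, 10 + k) for k in range(41)]  # endpoints at col 10 and 50
    g = _manual_graph([path])
    roots = oq.detect_roots(g, disc_center=(0, 0))
    assert g.nodes[roots[0]][0] == (0, 10)
    # two components -> two roots
    g2 = _manual_graph([path, [(20, 0 + k) for k in range(10)]])
    assert len(oq.detect_roots(g2, (0, 0))) == 2
    # equidistant endpoints -> lexicographically smaller pixel
    sym = [(10, 0 + k) for k in range(21)]  # ends (10,0) and (10,20), center (0,10)
    g3 = _manual_graph([sym])
    assert g3.nodes[oq.detect_roots(g3, (0, 10))[0]][0] == (10, 0)


def test_strahler_single_path_and_confluence():
    g = _manual_graph([[(0, k) for k in range(10)]])
    oq.detect_roots(g, (0, 0))
    oq.strahler_orders(g)
    assert g.branches[0].strahler_order == 1

    paths = [
        [(0, 0), (1, 1), (2, 2)],
        [(4, 0), (3, 1), (2, 2)],
        [(2, 2), (2, 3), (2, 4), (2, 5)],
    ]
    g = _manual_graph(paths)
    oq.detect_roots(g, (2, 10))  # root at far end of the trunk
    oq.strahler_orders(g)
    orders = {br.id: br.strahler_order for br in g.branches}
    assert orders[0] == 1 and orders[1] == 1 and orders[2] == 2


def _oracle_strahler(g, root):
    """Independent recursive Strahler computation on a tree."""
    import sys

    sys.setrecursionlimit(100_000)
    orders = {}

    def edge_order(node, parent):
        child_orders = []
        for a, b, k in g.graph.edges(node, keys=True):
            other = b if a == node else a
            if other == parent:
                continue
            child_orders.append(edge_order(other, node))
        if not child_orders:
            o = 1
        else:
            m = max(child_orders)
            o = m + 1 if child_orders.count(m) >= 2 else m
        orders[(parent, node)] = o
        return o

    for a, b, k in g.graph.edges(root, keys=True):
        other = b if a == root else a
        edge_order(other, root)
    return orders


def _random_tree(rng, max_branches=50):
    n_branch = int(rng.integers(1, max_branches + 1))
    paths = []
    coords = [(0, 0)]
    while len(paths) < n_branch:
        start = coords[int(rng.integers(0, len(coords)))]
        end = (len(coords), int(rng.integers(0, 10_000)))
        length = int(rng.integers(1, 30))
        mid = [(start[0], start[1] + k + 1) for k in range(length)]
        paths.append([start] + mid + [end])
        coords.append(end)
    return _manual_graph(paths)


@pytest.mark.parametrize("block", range(4))
def test_strahler_matches_recursive_oracle_on_random_trees(block):
    for trial in range(25):
        g = _random_tree(np.random.default_rng(1000 + 25 * block + trial))
        roots = oq.detect_roots(g, (0, 0))
        oq.strahler_orders(g)
        oracle = _oracle_strahler(g, roots[0])
        for a, b, k in g.graph.edges(keys=True):
            br = g.graph.edges[a, b, k]["branch"]
            expected = oracle.get((a, b), oracle.get((b, a)))
            assert br.strahler_order == expected


def test_strahler_cycle_broken_at_shortest_branch():
    # triangle: two long sides, one short; short side should stay order 1
    paths = [
        [(0, 0)] + [(0, k) for k in range(1, 21)],      # (0,0)-(0,20) long
        [(0, 20), (1, 19), (2, 18), (3, 17), (4, 16)],   # (0,20)-(4,16) medium
        [(4, 16), (2, 8), (0, 0)],                        # short chord back
        [(0, 0), (-1, -1) if False else (1, 0)],          # stub to make a root arm
    ]
    paths[3] = [(0, 0), (1, 0), (2, 0), (3, 0)]
    g = _manual_graph(paths)
    oq.detect_roots(g, (3, 0))
    oq.strahler_orders(g)
    orders = {br.id: br.strahler_order for br in g.branches}
    assert orders[2] == 1  # shortest cycle branch removed -> order 1


# ---------------------------------------------------------------------------
# tortuosity
# ---------------------------------------------------------------------------

def test_straight_branch_tortuosity_exactly_one():
    assert oq.branch_tortuosity(straight_branch(30)) == pytest.approx(1.0, abs=1e-9)
    diag = oq.Branch(path=np.array([(k, k) for k in range(30)]))
    assert oq.branch_tortuosity(diag) == pytest.approx(1.0, abs=1e-9)


def test_semicircle_tortuosity_near_half_pi(semicircle_mask):
    sk = oq.skeletonize(oq.BinaryMap(semicircle_mask))
    g = oq.extract_graph(sk)
    br = max(g.branches, key=lambda b: b.path_length_px)
    assert oq.branch_tortuosity(br) == pytest.approx(math.pi / 2, rel=0.02)


def test_sine_tortuosity_matches_quadrature_oracle(sine_curve):
    mask, oracle = sine_curve
    sk = oq.skeletonize(oq.BinaryMap(mask))
    g = oq.extract_graph(sk)
    br = max(g.branches, key=lambda b: b.path_length_px)
    assert oq.branch_tortuosity(br) == pytest.approx(oracle, rel=0.03)


def test_loop_branch_tortuosity_degenerate():
    loop = oq.Branch(path=np.array([(0, 0), (0, 1), (1, 1), (1, 0), (0, 0)]))
    with pytest.raises(oq.DegenerateMetricError):
        oq.branch_tortuosity(loop)


def test_all_branch_tortuosities_at_least_one():
    truth, _, _ = oq.generate_network(oq.NetworkParams(image_size_px=200), seed=9)
    g = oq.extract_graph(oq.skeletonize(truth))
    for br in g.branches:
        if not br.is_loop:
            assert oq.branch_tortuosity(br) >= 1.0 - 1e-12


def test_vessel_tortuosity_aggregation_modes():
    a = straight_branch(20)  # tortuosity 1.0
    th = np.linspace(0, math.pi, 2000)
    arc = np.column_stack(np.round([30 - 9.5 * np.sin(th), 10 + 9.5 * np.cos(th)]))
    arc = arc[np.any(np.diff(arc, axis=0, prepend=np.nan) != 0, axis=1)].astype(int)
    b = oq.Branch(path=arc)
    g = nx.MultiGraph()
    g.add_edge(0, 1, key=0, branch=a)
    g.add_edge(2, 3, key=1, branch=b)
    vg = VesselGraph(
        nodes={0: ((5, 5), "endpoint"), 1: ((5, 24), "endpoint"),
               2: (tuple(arc[0]), "endpoint"), 3: (tuple(arc[-1]), "endpoint")},
        branches=[a, b], graph=g,
    )
    ta, tb = oq.branch_tortuosity(a), oq.branch_tortuosity(b)
    assert oq.vessel_tortuosity(vg) == pytest.approx((ta + tb) / 2)
    w = a.arc_length_px + b.arc_length_px
    expected = (ta * a.arc_length_px + tb * b.arc_length_px) / w
    assert oq.vessel_tortuosity(vg, length_weighted=True) == pytest.approx(expected)


def test_vessel_tortuosity_no_eligible_branch_signals():
    vg = _manual_graph([[(0, 0), (0, 1)]])  # chord 1 < min_chord 3
    with pytest.raises(oq.DegenerateMetricError):
        oq.vessel_tortuosity(vg)


def test_tortuosity_monotone_in_sine_amplitude():
    measured = []
    for amp in (0.0, 5.0, 10.0, 15.0):
        params = oq.NetworkParams(
            image_size_px=256, tortuosity_amplitude_px=amp, branching_depth=2
        )
        truth, branches, _ = oq.generate_network(params, seed=11)
        g = oq.extract_graph(oq.skeletonize(truth))
        measured.append(oq.vessel_tortuosity(g, min_chord_px=10))
    assert all(b > a for a, b in zip(measured, measured[1:]))


# ---------------------------------------------------------------------------
# per-image pipeline
# ---------------------------------------------------------------------------

def _synthetic_image(seed=0, **kw):
    truth, _, _ = oq.generate_network(oq.NetworkParams(image_size_px=200), seed)
    return oq.render_angio(truth, oq.NoiseParams(**kw), seed + 1)


def test_analyze_image_quadrant_restriction():
    px = np.full((100, 100), 0.1)
    px[5:20, 40:60] = 0.9  # vessels only well inside the S sector
    img = oq.AngioImage(
        pixels=px, scan_size_mm=3.0, plexus="RPC", laterality="OD",
        disc_center=(50, 50), quality_index=90, patient_id="t", group="CONTROL",
    )
    quads = oq.quadrant_masks(px.shape, (50, 50), "OD")
    out = oq.analyze_image(img, quads)
    assert out["vd_S"] > 0
    assert out["vd_I"] == out["vd_N"] == out["vd_T"] == 0.0


def test_analyze_image_deterministic():
    img = _synthetic_image(seed=21)
    quads = oq.quadrant_masks(img.pixels.shape, img.disc_center, img.laterality)
    a = oq.analyze_image(img, quads)
    b = oq.analyze_image(img, quads)
    assert a == b


def test_analyze_image_skips_quadrants_for_deep_plexus():
    img = _synthetic_image(seed=22)
    img.plexus = "DCP"
    quads = oq.quadrant_masks(img.pixels.shape, img.disc_center, img.laterality)
    out = oq.analyze_image(img, quads)
    assert "vd_S" not in out and "vt" in out
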