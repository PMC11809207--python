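import numpy as np
import pytest

from mitomorph import synth
from mitomorph.core import BinaryMask
from mitomorph.skeleton import SkeletonBranch, SkeletonGraph, SkeletonNode


@pytest.fixture
def straight_tube_truth():
    """One straight axis-aligned tube: L = 6 µm, r = 0.3 µm, 0.1 µm voxels."""
    L, r = 6.0, 0.3
    pts = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + L]])
    graph = synth.TruthGraph(pts, [synth.Branch(0, 1, pts, r)],
                             box=(2.0, 2.0, L + 2.0), seed=0)
    return synth.rasterize_network(graph, (0.1, 0.1, 0.1))


@pytest.fixture
def y_skeleton():
    """Hand-built voxel Y with one clean junction voxel.

    Arm directions +x, (+y, −x) and (−y, −x) keep the three first arm
    voxels mutually non-adjacent under 26-connectivity, so the centre is the
    only junction.  Arm lengths at 0.1 µm spacing: 40 axial steps = 4 µm,
    20 diagonal steps = 2√2 µm, 15 diagonal steps = 1.5√2 µm.
    """
    skel = np.zeros((5, 80, 80), dtype=bool)
    cz, cy, cx = 2, 40, 35
    skel[cz, cy, cx:cx + 41] = True                     # +x arm
    for k in range(1, 21):
        skel[cz, cy + k, cx - k] = True                 # (+y, -x) arm
    for k in range(1, 16):
        skel[cz, cy - k, cx - k] = True                 # (-y, -x) arm
    lengths = (4.0, 2.0 * np.sqrt(2), 1.5 * np.sqrt(2))
    return skel, 0.1, lengths


def make_abstract_graph(branch_defs):
    """SkeletonGraph from (node_a, node_b, length) tuples; geometry is dummy."""
    n_nodes = max(max(a, b) for a, b, _ in branch_defs) + 1
    nodes = [SkeletonNode(i, (0, 0, i), "junction") for i in range(n_nodes)]
    branches = [SkeletonBranch(a, b, np.zeros((2, 3), dtype=int), float(L), float(L))
                for a, b, L in branch_defs]
    return SkeletonGraph(nodes, branches, spacing=1.0)


def random_tree_graph(rng, max_branches=25):
    """Random abstract tree with uniform branch lengths."""
    n = int(rng.integers(1, max_branches + 1))
    defs = []
    for i in range(n):
        a = int(rng.integers(i + 1))  # attach to any existing node
        defs.append((a, i + 1, float(rng.uniform(0.5, 5.0))))
    return make_abstract_graph(defs)


def brute_force_graph_diameter(graph):
    """Independent oracle: Floyd–Warshall over the branch weight matrix."""
    n = len(graph.nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for br in graph.branches:
        w = br.path_length
        if w < d[br.node_a, br.node_b]:
            d[br.node_a, br.node_b] = d[br.node_b, br.node_a] = w
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    finite = d[np.isfinite(d)]
    return float(finite.max()) if finite.size else 0.0


@pytest.fixture
def ball_mask():
    """Digital ball, radius 1.5 µm at 0.1 µm voxels."""
    r_um, sp = 1.5, 0.1
    n = int(2 * r_um / sp) + 9
    c = (n - 1) / 2.0
    zz, yy, xx = np.ogrid[:n, :n, :n]
    mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * sp ** 2 <= r_um ** 2
    return BinaryMask(mask, (sp, sp, sp)), r_um
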