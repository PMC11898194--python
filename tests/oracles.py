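"""Independent oracles reused across test modules.

Each oracle recomputes a quantity from its definition by a route disjoint
from the implementation it checks (brute force, enumeration, or an
alternative decomposition).
"""

import dendropy
import numpy as np

def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I from the definition (dense weight matrix)."""
    z = values - values.mean()
    n = values.size
    w_sum = weights.sum()
    num = float(z @ (weights @ z))
    den = float(z @ z)
    return (n / w_sum) * num / den


def rook_weights(n_rows: int, n_cols: int) -> np.ndarray:
    """Lag-1 rook-adjacency weight matrix for a row-major grid."""
    n = n_rows * n_cols
    w = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    w[i, rr * n_cols + cc] = 1.0
    return w


def faith_pd_oracle(tree: dendropy.Tree, species: set) -> float:
    """Brute-force Faith's PD: mark every edge on a root-ward path."""
    marked = set()
    tips = {l.taxon.label: l for l in tree.leaf_node_iter()}
    for s in species:
        node = tips[s]
        while node.parent_node is not None:
            marked.add(id(node.edge))
            node = node.parent_node
    total = 0.0
    for e in tree.preorder_edge_iter():
        if id(e) in marked and e.length is not None:
            total += e.length
    return total


def delaunay_volume(points: np.ndarray) -> float:
    """Hull volume via Delaunay simplex decomposition (independent route)."""
    from math import factorial

    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    d = points.shape[1]
    vol = 0.0
    for simplex in tri.simplices:
        verts = points[simplex]
        vol += abs(np.linalg.det(verts[1:] - verts[0])) / factorial(d)
    return vol


def enumerate_fixed_margin(row_sums, col_sums):
    """All binary matrices with the given margins, as byte strings."""
    from itertools import combinations

    n_rows = len(row_sums)
    n_cols = len(col_sums)
    out = []

    def rec(i, remaining_cols, rows):
        if i == n_rows:
            if all(r == 0 for r in remaining_cols):
                out.append(np.array(rows, dtype=np.int8).tobytes())
            return
        rows_left = n_rows - i - 1
        for combo in combinations(range(n_cols), row_sums[i]):
            ok = True
            new_rem = list(remaining_cols)
            for c in combo:
                new_rem[c] -= 1
                if new_rem[c] < 0:
                    ok = False
                    break
            if ok and all(r <= rows_left for r in new_rem):
                row = [0] * n_cols
                for c in combo:
                    row[c] = 1
                rec(i + 1, new_rem, rows + [row])

    rec(0, list(col_sums), [])
    return set(out)
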