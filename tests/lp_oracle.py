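"""Independent brute-force LP oracle for small flux polytopes.

Enumerate the vertices of {v : N v = 0, lb <= v <= ub} directly: with
d = n - rank(N) degrees of freedom, every vertex is the solution of the
equality system plus d variables pinned at a bound, so scanning all
C(n, d) * 2^d pinnings and keeping the feasible solutions finds every
extreme point.  Linear objectives (FBA) and per-reaction ranges (FVA) are
then min/max over the vertex set.  Deliberately shares no code with the
package's linprog-based solver.
"""

from itertools import combinations, product

import numpy as np

TOL = 1e-7


def polytope_vertices(N: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    m, n = N.shape
    r = np.linalg.matrix_rank(N, tol=1e-9) if m else 0
    d = n - r
    found = []
    if d == 0:
        v, *_ = np.linalg.lstsq(N, np.zeros(m), rcond=None)
        if _feasible(N, lb, ub, v):
            found.append(v)
    for idx in combinations(range(n), d):
        for side in product((0, 1), repeat=d):
            rows = np.zeros((d, n))
            rhs = np.zeros(d)
            for k, (j, s) in enumerate(zip(idx, side)):
                rows[k, j] = 1.0
                rhs[k] = ub[j] if s else lb[j]
            A = np.vstack([N, rows]) if m else rows
            b = np.concatenate([np.zeros(m), rhs])
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) < TOL and _feasible(N, lb, ub, v):
                found.append(v)
    if not found:
        raise ValueError("no feasible vertex found (polytope empty?)")
    return np.array(found)


def _feasible(N, lb, ub, v) -> bool:
    if N.size and np.max(np.abs(N @ v)) > TOL:
        return False
    return bool(np.all(v >= lb - TOL) and np.all(v <= ub + TOL))


def oracle_fba(N, lb, ub, j_obj: int, direction: str) -> float:
    vals = polytope_vertices(N, lb, ub)[:, j_obj]
    return float(vals.max() if direction == "max" else vals.min())


def oracle_fva(N, lb, ub, j: int) -> tuple[float, float]:
    vals = polytope_vertices(N, lb, ub)[:, j]
    return float(vals.min()), float(vals.max())


def random_flux_network(rng: np.random.Generator, max_reactions: int = 8):
    """Random small stoichiometric network with 0 in the flux box.

    Returns (N, lb, ub); bounds are finite and bracket zero, so the polytope
    is non-empty and bounded and both solvers must agree exactly.
    """
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, n))
    N = np.zeros((m, n))
    while not N.any():
        mask = rng.random((m, n)) < 0.45
        N = np.where(mask, rng.integers(-3, 4, size=(m, n)), 0).astype(float)
    lb = np.where(rng.random(n) < 0.7, -rng.uniform(0.1, 10.0, n), 0.0)
    ub = np.where(rng.random(n) < 0.9, rng.uniform(0.1, 10.0, n), 0.0)
    return N, lb, ub
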