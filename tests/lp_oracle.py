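"""Brute-force oracle for small flux polytopes.

Enumerates every vertex of {v : S v = 0, lb <= v <= ub} by fixing
(n - rank(S)) coordinates at a bound and solving the remaining square
system.  Valid only for bounded polytopes with finite bounds and a handful
of reactions; used to cross-check FBA optima and FVA ranges independently
of any LP solver.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

TOL = 1e-7


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """All vertices of the flux polytope, as an array of shape (k, n)."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue
        for vals in product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.asarray(vals) if fixed else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            else:
                sol = np.zeros(0)
            v = np.zeros(n)
            v[list(fixed)] = vals
            v[free] = sol
            if np.max(np.abs(S @ v)) > TOL:
                continue
            if np.any(v < lb - TOL) or np.any(v > ub + TOL):
                continue
            if not any(np.allclose(v, w, atol=1e-6) for w in vertices):
                vertices.append(v)
    return np.array(vertices) if vertices else np.zeros((0, n))


def brute_force_fba(S, lb, ub, obj_idx: int, sense: str = "maximize") -> float:
    """Optimal objective value by vertex enumeration."""
    verts = enumerate_vertices(S, np.asarray(lb, float), np.asarray(ub, float))
    if verts.shape[0] == 0:
        raise ValueError("empty flux polytope")
    col = verts[:, obj_idx]
    return float(col.max() if sense == "maximize" else col.min())


def brute_force_fva(S, lb, ub, obj_idx: int, fraction: float = 1.0) -> list[tuple[float, float]]:
    """Per-reaction (min, max) over the near-optimal face, by enumeration.

    The optimal face of a polytope is itself a polytope whose vertices are
    vertices of the parent, so scanning parent vertices suffices at
    fraction 1; for fraction < 1 the near-optimal set is approximated the
    same way (adequate for the toy cases used in tests).
    """
    verts = enumerate_vertices(S, np.asarray(lb, float), np.asarray(ub, float))
    if verts.shape[0] == 0:
        raise ValueError("empty flux polytope")
    z = verts[:, obj_idx].max()
    threshold = fraction * z if z >= 0 else z / fraction
    face = verts[verts[:, obj_idx] >= threshold - TOL]
    return [(float(face[:, j].min()), float(face[:, j].max())) for j in range(verts.shape[1])]
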