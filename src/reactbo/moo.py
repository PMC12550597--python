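"""Multi-objective machinery: dominance, NSGA-II, hypervolume.

Everything here works in **minimization** convention; callers negate
maximized objectives.  NSGA-II is the standard real-coded variant
(fast non-dominated sorting, crowding distance, binary tournament,
simulated binary crossover, polynomial mutation) over the unit box, which
is all the Thompson-sampling loop needs to refine sampled GP paths.
Hypervolume is exact for up to three objectives by recursive slicing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["dominates", "non_dominated_mask", "non_dominated_sort",
           "crowding_distance", "nsga2", "hypervolume", "NSGA2Result"]


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """True if ``a`` Pareto-dominates ``b`` (minimization)."""
    a, b = np.asarray(a), np.asarray(b)
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_mask(F: np.ndarray) -> np.ndarray:
    """Boolean mask of the non-dominated rows of ``F`` (minimization)."""
    F = np.atleast_2d(F)
    n = len(F)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        if not mask[i]:
            continue
        le = np.all(F <= F[i], axis=1)
        lt = np.any(F < F[i], axis=1)
        if np.any(le & lt):
            mask[i] = False
    return mask


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """D[i, j] True iff row i dominates row j (vectorized pairwise check)."""
    le = np.all(F[:, None, :] <= F[None, :, :], axis=-1)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=-1)
    return le & lt


def non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    """Fast non-dominated sorting; returns index arrays per front (best first)."""
    F = np.atleast_2d(F)
    D = _domination_matrix(F)
    n_dom = D.sum(axis=0)
    fronts = []
    assigned = np.zeros(len(F), dtype=bool)
    while not assigned.all():
        current = np.flatnonzero((n_dom == 0) & ~assigned)
        fronts.append(current)
        assigned[current] = True
        n_dom = n_dom - D[current].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    """Crowding distance of each row within one front."""
    F = np.atleast_2d(F)
    n, m = F.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(F[:, k], kind="stable")
        span = F[order[-1], k] - F[order[0], k]
        d[order[0]] = d[order[-1]] = np.inf
        if span == 0:
            continue
        d[order[1:-1]] += (F[order[2:], k] - F[order[:-2], k]) / span


    return d


def _sbx_batch(rng, P1, P2, eta=15.0, cross_prob=0.9):
    """Simulated binary crossover on paired parent arrays (vectorized)."""
    u = rng.random(P1.shape)
    beta = np.where(u <= 0.5,
                    (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    do_pair = (rng.random(len(P1)) <= cross_prob)[:, None]
    do_gene = (rng.random(P1.shape) <= 0.5) & (P1 != P2) & do_pair
    lo, hi = np.minimum(P1, P2), np.maximum(P1, P2)
    c1 = np.where(do_gene, 0.5 * ((lo + hi) - beta * (hi - lo)), P1)
    c2 = np.where(do_gene, 0.5 * ((lo + hi) + beta * (hi - lo)), P2)
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _poly_mutation_batch(rng, X, eta=20.0, prob=None):
    """Polynomial mutation on a population array (vectorized)."""
    d = X.shape[1]
    prob = prob if prob is not None else 1.0 / d
    u = rng.random(X.shape)
    delta = np.where(u < 0.5,
                     (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    do = rng.random(X.shape) < prob
    return np.clip(np.where(do, X + delta, X), 0.0, 1.0)


@dataclass
class NSGA2Result:
    X: np.ndarray  # non-dominated decision vectors, (k, d)
    F: np.ndarray  # their objective values (minimization), (k, m)


def nsga2(objective_fns, dim: int, pop_size: int = 60, generations: int = 60,
          seed: int = 0, X0: np.ndarray | None = None) -> NSGA2Result:
    """Minimize a list of vectorized objective callables over [0, 1]^dim.

    Each callable maps (n, dim) -> (n,).  Returns the final population's
    non-dominated set.  Deterministic given ``seed``; ``X0`` rows seed the
    initial population.
    """
    rng = np.random.default_rng(seed)
    n_obj = len(objective_fns)
    if n_obj < 1:
        raise ValueError("need at least one objective")

    def evaluate(X):
        return np.column_stack([np.asarray(f(X), dtype=float).ravel() for f in objective_fns])

    X = rng.random((pop_size, dim))
    if X0 is not None and len(X0):
        k = min(len(X0), pop_size)
        X[:k] = np.clip(np.atleast_2d(X0)[:k], 0.0, 1.0)
    F = evaluate(X)

    def rank_and_crowd(Fm):
        fronts = non_dominated_sort(Fm)
        rank = np.empty(len(Fm), dtype=int)
        crowd = np.empty(len(Fm))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = crowding_distance(Fm[front])
        return rank, crowd

    rank, crowd = rank_and_crowd(F)
    n_pairs = (pop_size + 1) // 2
    for _ in range(generations):
        # binary tournament by (rank, -crowding), vectorized
        cand = rng.integers(0, pop_size, size=(2 * n_pairs, 2))
        better = (rank[cand[:, 0]] < rank[cand[:, 1]]) | (
            (rank[cand[:, 0]] == rank[cand[:, 1]])
            & (crowd[cand[:, 0]] > crowd[cand[:, 1]]))
        parents = np.where(better, cand[:, 0], cand[:, 1])
        c1, c2 = _sbx_batch(rng, X[parents[:n_pairs]], X[parents[n_pairs:]])
        Xc = _poly_mutation_batch(rng, np.vstack([c1, c2]))[:pop_size]
        Fc = evaluate(Xc)
        X_all = np.vstack([X, Xc])
        F_all = np.vstack([F, Fc])
        rank_all, crowd_all = rank_and_crowd(F_all)
        order = np.lexsort((-crowd_all, rank_all))[:pop_size]
        X, F = X_all[order], F_all[order]
        rank, crowd = rank_and_crowd(F)

    mask = non_dominated_mask(F)
    return NSGA2Result(X=X[mask], F=F[mask])


def hypervolume(front: np.ndarray, reference: np.ndarray) -> float:
    """Exact hypervolume of ``front`` w.r.t. ``reference`` (minimization,
    up to 3 objectives, recursive slicing).

    Every point must weakly dominate the reference in each coordinate.
    """
    F = np.atleast_2d(np.asarray(front, dtype=float))
    ref = np.asarray(reference, dtype=float)
    m = F.shape[1]
    if m > 3:
        raise ValueError("exact hypervolume implemented for <= 3 objectives")
    if np.any(F > ref[None, :]):
        raise ValueError("all front points must dominate the reference point")
    F = F[non_dominated_mask(F)]
    if m == 1:
        return float(ref[0] - F[:, 0].min())
    if m == 2:
        order = np.argsort(F[:, 0], kind="stable")
        hv = 0.0
        prev_y = ref[1]
        for i in order:
            x, y = F[i]
            if y < prev_y:
                hv += (ref[0] - x) * (prev_y - y)
                prev_y = y
        return float(hv)
    # m == 3: sweep the third coordinate, accumulating 2-D slices
    order = np.argsort(F[:, 2], kind="stable")
    zs = F[order, 2]
    hv = 0.0
    for i, idx in enumerate(order):
        z_lo = zs[i]
        z_hi = zs[i + 1] if i + 1 < len(order) else ref[2]
        if z_hi <= z_lo:
            continue
        active = F[order[: i + 1], :2]
        hv += hypervolume(active, ref[:2]) * (z_hi - z_lo)
    return float(hv)
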