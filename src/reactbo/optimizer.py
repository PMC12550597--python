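"""Acquisition strategies over the encoded unit cube.

Two loops are provided, matching common closed-loop reaction-optimization
practice:

* ``suggest_ei`` — single-objective Bayesian optimization: maximize the
  closed-form expected improvement of one GP by multi-start local search.
* ``suggest_tsemo`` — Thompson-sampling efficient multi-objective
  optimization: draw one spectral posterior sample per objective, refine
  the sampled front with NSGA-II, then pick the candidate with the largest
  hypervolume improvement over the observed front.

Both are deterministic given their seed; all internal randomness is spawned
from it.  Objectives here follow **minimization** convention (callers
negate maximized quantities such as yield).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .gp import GPModel, expected_improvement, thompson_sample
from .moo import hypervolume, non_dominated_mask, nsga2

__all__ = ["suggest_ei", "suggest_tsemo", "hypervolume_improvement"]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def suggest_ei(gp: GPModel, dim: int, best: float, seed: int = 0,
               n_candidates: int = 1024, n_refine: int = 10) -> np.ndarray:
    """Point in [0,1]^dim maximizing expected improvement (maximization of
    the modelled objective; ``best`` is the incumbent objective value)."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_candidates, dim))
    ei = expected_improvement(gp, X, best)
    top = np.argsort(-ei, kind="stable")[:n_refine]

    def neg_ei(x):
        return -float(expected_improvement(gp, x[None, :], best)[0])

    best_x, best_val = X[top[0]], -ei[top[0]]
    for i in top:
        res = minimize(neg_ei, X[i], method="L-BFGS-B",
                       bounds=[(0.0, 1.0)] * dim)
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, 0.0, 1.0)
    return best_x


def hypervolume_improvement(candidate_F: np.ndarray, observed_F: np.ndarray,
                            reference: np.ndarray) -> np.ndarray:
    """Hypervolume improvement of each candidate row over the observed front
    (minimization convention); candidates are clipped to the reference."""
    observed_F = np.atleast_2d(observed_F)
    base_front = observed_F[non_dominated_mask(observed_F)]
    base_front = np.minimum(base_front, reference[None, :])
    base = hypervolume(base_front, reference)
    out = np.empty(len(candidate_F))
    for i, c in enumerate(np.atleast_2d(candidate_F)):
        c = np.minimum(c, reference)
        out[i] = hypervolume(np.vstack([base_front, c[None, :]]), reference) - base
    return np.maximum(out, 0.0)


def suggest_tsemo(gps: list[GPModel], observed_F: np.ndarray, dim: int,
                  seed: int = 0, n_features: int = 500, pop_size: int = 60,
                  generations: int = 60) -> np.ndarray:
    """One TS-EMO acquisition step (minimization convention).

    With a single objective this degenerates to minimizing the one Thompson
    sample.  The observed points (``gps[0].X``) warm-start the NSGA-II
    population.
    """
    n_obj = len(gps)
    seeds = _child_seeds(seed, n_obj + 2)
    samples = [thompson_sample(gp, n_features=n_features, seed=s)
               for gp, s in zip(gps, seeds[:n_obj])]
    result = nsga2(samples, dim=dim, pop_size=pop_size, generations=generations,
                   seed=seeds[n_obj], X0=gps[0].X)
    if len(result.X) == 0:  # pragma: no cover - defensive fallback
        return np.random.default_rng(seeds[n_obj + 1]).random(dim)
    if n_obj == 1:
        return result.X[int(np.argmin(result.F[:, 0]))]
    observed_F = np.atleast_2d(observed_F)
    reference = np.max(np.vstack([observed_F, result.F]), axis=0) + \
        0.1 * (np.ptp(np.vstack([observed_F, result.F]), axis=0) + 1e-12)
    hvi = hypervolume_improvement(result.F, observed_F, reference)
    return result.X[int(np.argmax(hvi))]
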