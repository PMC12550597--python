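"""Synthetic catalyst tables and campaign configs.

Real Mayr nucleophilicities are available from the reactivity-parameter
databases but are deliberately not hardcoded here; fixture catalysts carry
``n_source='fixture'`` and a plausible N spread (roughly 12–27, the range
covered by amidine/guanidine organocatalysts) so the encoding and
optimization machinery can be exercised and tested without claiming real
descriptor values.  Users with database access substitute their own table
via :func:`reactbo.descriptors.load_catalyst_table`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .descriptors import Catalyst, CatalystSet, write_catalyst_table

__all__ = ["fixture_catalyst_set", "write_fixture_table", "write_fixture_config"]

#: fixture descriptor rows for the 6-catalyst benchmarks: name, N, s, M (g/mol),
#: cost (currency/g).  Cost increases with N, mimicking the price gap between
#: commodity amines and bicyclic guanidines.
_FIXTURE_ROWS = (
    ("cat01", 12.0, 1.00, 79.10, 0.5),
    ("cat02", 15.0, 0.95, 101.19, 1.2),
    ("cat03", 18.0, 0.90, 115.18, 3.5),
    ("cat04", 21.0, 0.85, 152.24, 8.0),
    ("cat05", 24.0, 0.80, 153.27, 15.0),
    ("cat06", 27.0, 0.75, 139.20, 40.0),
)


def fixture_catalyst_set(n: int = 6, seed: int | None = None) -> CatalystSet:
    """A synthetic catalyst set of size ``n``.

    For ``n <= 6`` and no seed, rows are drawn from a fixed table with N
    equally spread over 12–27 (subset keeps the extremes first).  With a
    seed, descriptors are sampled afresh: N uniform over [12, 27] (sorted),
    molar mass 79–160 g/mol, cost log-uniform 0.5–40 and increasing in N.
    """
    if seed is None:
        if n == 6:
            rows = _FIXTURE_ROWS
        elif 2 <= n < 6:
            # keep both extremes plus evenly spaced interior rows
            idx = np.round(np.linspace(0, 5, n)).astype(int)
            rows = tuple(_FIXTURE_ROWS[i] for i in idx)
        else:
            raise ValueError("fixed fixture table has 6 rows; pass a seed for other sizes")
        cats = tuple(
            Catalyst(name=r[0], nucleophilicity=r[1], sensitivity=r[2],
                     molar_mass=r[3], cost_per_g=r[4], n_source="fixture")
            for r in rows
        )
        return CatalystSet(cats, provenance="synthetic fixture table")
    rng = np.random.default_rng(seed)
    ns = np.sort(rng.uniform(12.0, 27.0, size=n))
    masses = rng.uniform(79.0, 160.0, size=n)
    costs = np.sort(np.exp(rng.uniform(np.log(0.5), np.log(40.0), size=n)))
    cats = tuple(
        Catalyst(name=f"cat{i + 1:02d}", nucleophilicity=float(ns[i]),
                 sensitivity=float(rng.uniform(0.7, 1.0)),
                 molar_mass=float(masses[i]), cost_per_g=float(costs[i]),
                 n_source="fixture")
        for i in range(n)
    )
    return CatalystSet(cats, provenance=f"synthetic fixture table (seed={seed})")


def write_fixture_table(path: str | Path, n: int = 6, seed: int | None = None) -> CatalystSet:
    """Emit a fixture catalyst CSV and return the set it encodes."""
    cs = fixture_catalyst_set(n=n, seed=seed)
    write_catalyst_table(cs, path)
    return cs


def write_fixture_config(path: str | Path, *, benchmark: str = "amidation_sim",
                         encoding: str = "chemistry", algorithm: str = "tsemo",
                         objectives: tuple[str, ...] = ("yield",),
                         budget: int = 50, seed: int = 0,
                         noise_sd_rel: float = 0.0) -> dict:
    """Emit a flat key-value campaign config file (YAML)."""
    cfg = {
        "benchmark": benchmark,
        "encoding": encoding,
        "algorithm": algorithm,
        "objectives": list(objectives),
        "n_initial": "auto",
        "budget": budget,
        "seed": seed,
        "noise_sd_rel": noise_sd_rel,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
    return cfg
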