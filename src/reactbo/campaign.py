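"""Closed-loop optimization campaigns.

A campaign is: a space-filling initial design (Latin hypercube over the
continuous dimensions, catalysts spread as evenly as possible — "twice the
number of variables, two per base" in the balanced case), followed by a
fixed budget of algorithm iterations, each of which fits the surrogate(s)
on the encoded history, asks the acquisition strategy for a point, snaps it
to valid conditions, runs the kinetic simulator and appends the outcome.

All randomness flows from the single campaign seed through spawned child
seeds recorded in the history, so any persisted campaign is exactly
replayable from its config.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .descriptors import CatalystSet
from .encoding import make_encoder
from .gp import fit_gp
from .kinetics import Benchmark, make_benchmark, simulate_reaction
from .moo import non_dominated_mask
from .objectives import ObjectiveCaps, ObjectiveVector, compute_objectives
from .optimizer import suggest_ei, suggest_tsemo
from .space import Conditions, ParameterSpace

__all__ = [
    "CampaignConfig", "HistoryRecord", "CampaignHistory", "ComparisonReport",
    "initial_design", "run_campaign", "best_so_far", "pareto_front",
    "compare_encodings", "benchmark_optimum", "save_history", "load_history",
]

#: +1 = maximized, -1 = minimized (internal minimization convention applies -sign)
OBJECTIVE_SIGNS = {"yield": +1.0, "base_cost": -1.0, "pmi": -1.0}

HISTORY_COLUMNS = (
    "iteration", "provenance", "temperature_C", "time_min", "conc_M",
    "amine_equiv", "cat_equiv", "catalyst", "yield_pct", "base_cost_per_g",
    "pmi", "capped_flags", "child_seed",
)


@dataclass(frozen=True)
class CampaignConfig:
    """Everything needed to reproduce one campaign."""

    benchmark: str = "amidation_sim"
    encoding: str = "chemistry"
    algorithm: str = "tsemo"  # or "sobo_ei"
    objectives: tuple[str, ...] = ("yield",)
    n_initial: int | str = "auto"
    budget: int = 50
    seed: int = 0
    noise_sd_rel: float = 0.0
    n_catalysts: int = 6
    #: label-permutation seed, independent of the campaign seed so the same
    #: randomized order is held fixed across replicate campaigns
    label_seed: int = 1234
    caps_pmi: float = 500.0
    caps_base_cost: float = 100.0
    gp_restarts: int = 5
    n_features: int = 500
    pop_size: int = 60
    generations: int = 60

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.algorithm not in ("tsemo", "sobo_ei"):
            raise ValueError("algorithm must be 'tsemo' or 'sobo_ei'")
        unknown = set(self.objectives) - set(OBJECTIVE_SIGNS)
        if unknown:
            raise ValueError(f"unknown objectives {sorted(unknown)}")
        if self.algorithm == "sobo_ei" and len(self.objectives) != 1:
            raise ValueError("sobo_ei is single-objective; pass exactly one objective")

    @property
    def caps(self) -> ObjectiveCaps:
        return ObjectiveCaps(pmi=self.caps_pmi, base_cost=self.caps_base_cost)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["objectives"] = list(self.objectives)
        return d

    @staticmethod
    def from_dict(d: dict) -> "CampaignConfig":
        d = dict(d)
        if "objectives" in d:
            d["objectives"] = tuple(d["objectives"])
        return CampaignConfig(**d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @staticmethod
    def from_file(path: str | Path) -> "CampaignConfig":
        return CampaignConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class HistoryRecord:
    iteration: int
    provenance: str  # "init" | "algorithm"
    conditions: Conditions
    objectives: ObjectiveVector
    child_seed: int
    failed: bool = False


@dataclass
class CampaignHistory:
    config: CampaignConfig
    encoder_state: dict
    records: list[HistoryRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            c, o = r.conditions, r.objectives
            flags = list(o.capped_flags) + (["failed"] if r.failed else [])
            rows.append({
                "iteration": r.iteration, "provenance": r.provenance,
                "temperature_C": c.temperature_C, "time_min": c.time_min,
                "conc_M": c.conc_M, "amine_equiv": c.amine_equiv,
                "cat_equiv": c.cat_equiv, "catalyst": c.catalyst.name,
                "yield_pct": o.yield_pct, "base_cost_per_g": o.base_cost_per_g,
                "pmi": o.pmi, "capped_flags": "|".join(flags),
                "child_seed": r.child_seed,
            })
        return pd.DataFrame(rows, columns=list(HISTORY_COLUMNS))

    def objective_matrix(self, objectives: Sequence[str] | None = None,
                         minimize: bool = True) -> np.ndarray:
        """Objective values per record; minimization convention when asked."""
        objectives = tuple(objectives or self.config.objectives)
        cols = {"yield": "yield_pct", "base_cost": "base_cost_per_g", "pmi": "pmi"}
        df = self.to_frame()
        F = np.column_stack([df[cols[o]].to_numpy(dtype=float) for o in objectives])
        if minimize:
            F = F * np.array([-OBJECTIVE_SIGNS[o] for o in objectives])[None, :]
        return F


def _resolve_n_initial(config: CampaignConfig, space: ParameterSpace) -> int:
    if config.n_initial == "auto":
        return 2 * (space.n_continuous + 1)
    return int(config.n_initial)


def initial_design(space: ParameterSpace, catalyst_set: CatalystSet,
                   rule: str = "twice_vars_two_per_cat", seed: int = 0,
                   n: int | None = None) -> list[Conditions]:
    """Space-filling initial experiments.

    Continuous settings come from a seeded Latin hypercube of size
    ``n`` (default twice the number of variables, the categorical counted
    as one).  Catalysts are assigned in a seeded random order so that each
    appears ``floor(n/n_cat)`` or ``ceil(n/n_cat)`` times — exactly twice
    per catalyst in the balanced "two per base" case.
    """
    if len(catalyst_set) == 0:
        raise ValueError("empty catalyst set")
    if rule != "twice_vars_two_per_cat":
        raise ValueError(f"unknown initial-design rule {rule!r}")
    n_vars = space.n_continuous + 1
    size = int(n) if n is not None else 2 * n_vars
    if size < len(catalyst_set):
        raise ValueError("initial design smaller than the catalyst set; "
                         "every catalyst must appear at least once")
    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=space.n_continuous, seed=rng)
    unit = sampler.random(size)
    X = space.lows[None, :] + unit * (space.highs - space.lows)[None, :]
    reps = int(np.ceil(size / len(catalyst_set)))
    cat_idx = np.tile(np.arange(len(catalyst_set)), reps)[:size]
    rng.shuffle(cat_idx)
    return [Conditions.from_values(X[i], space, catalyst_set[int(cat_idx[i])])
            for i in range(size)]


def _evaluate(benchmark: Benchmark, conditions: Conditions, caps: ObjectiveCaps,
              child_seed: int) -> tuple[ObjectiveVector, bool]:
    try:
        outcome = simulate_reaction(benchmark.model, conditions,
                                    rng=np.random.default_rng(child_seed))
        return compute_objectives(conditions, outcome, benchmark, caps), False
    except RuntimeError:
        zero = ObjectiveVector(yield_pct=0.0, base_cost_per_g=caps.base_cost,
                               pmi=caps.pmi, capped_flags=("base_cost", "pmi"))
        return zero, True


def run_campaign(config: CampaignConfig) -> CampaignHistory:
    """Run one closed-loop campaign; returns the complete history
    (``n_initial + budget`` records)."""
    benchmark = make_benchmark(config.benchmark, n_catalysts=config.n_catalysts,
                               noise_sd_rel=config.noise_sd_rel)
    space, cats = benchmark.space, benchmark.catalyst_set
    encoder = make_encoder(config.encoding, cats, seed=config.label_seed)
    caps = config.caps
    n_init = _resolve_n_initial(config, space)

    root = np.random.SeedSequence(int(config.seed))
    init_ss, *iter_ss = root.spawn(1 + config.budget)
    init_seed = int(init_ss.generate_state(1)[0] % (2**31))
    init_children = [int(s.generate_state(1)[0] % (2**31))
                     for s in init_ss.spawn(n_init)]

    history = CampaignHistory(config=config, encoder_state=encoder.state())
    for i, cond in enumerate(initial_design(space, cats, seed=init_seed, n=n_init)):
        obj, failed = _evaluate(benchmark, cond, caps, init_children[i])
        history.records.append(HistoryRecord(i, "init", cond, obj,
                                             init_children[i], failed))

    dim = encoder.dimensionality(space)
    signs = np.array([OBJECTIVE_SIGNS[o] for o in config.objectives])
    for it in range(config.budget):
        child = int(iter_ss[it].generate_state(1)[0] % (2**31))
        fit_seeds = [int(s.generate_state(1)[0] % (2**31))
                     for s in iter_ss[it].spawn(len(config.objectives) + 2)]
        X = np.array([encoder.encode(r.conditions, space).vector
                      for r in history.records])
        F_min = history.objective_matrix(minimize=True)  # (n, m), minimize
        if config.algorithm == "sobo_ei":
            # EI works in maximization convention on the single objective
            y_max = -F_min[:, 0]
            gp = fit_gp(X, y_max, seed=fit_seeds[0], n_restarts=config.gp_restarts)
            x_next = suggest_ei(gp, dim, best=float(np.max(y_max)),
                                seed=fit_seeds[-1])
        else:
            gps = [fit_gp(X, F_min[:, j], seed=fit_seeds[j],
                          n_restarts=config.gp_restarts)
                   for j in range(F_min.shape[1])]
            x_next = suggest_tsemo(gps, F_min, dim, seed=fit_seeds[-1],
                                   n_features=config.n_features,
                                   pop_size=config.pop_size,
                                   generations=config.generations)
        cond = encoder.decode_vector(x_next, space)
        obj, failed = _evaluate(benchmark, cond, caps, child)
        history.records.append(
            HistoryRecord(n_init + it, "algorithm", cond, obj, child, failed))
    return history


def best_so_far(history: CampaignHistory, objective: str = "yield") -> np.ndarray:
    """Cumulative-best trajectory of a maximized (yield) or minimized
    objective; length equals the number of records."""
    if len(history) == 0:
        raise ValueError("empty history")
    vals = history.objective_matrix((objective,), minimize=False).ravel()
    if OBJECTIVE_SIGNS[objective] > 0:
        return np.maximum.accumulate(vals)
    return np.minimum.accumulate(vals)


def pareto_front(history: CampaignHistory,
                 objectives: Sequence[str] | None = None) -> list[HistoryRecord]:
    """Non-dominated records under (max yield, min cost, min PMI) — or the
    subset of objectives the campaign tracked.  Order-independent: the
    returned records are in history order, duplicates collapsed."""
    if len(history) == 0:
        raise ValueError("empty history")
    F = history.objective_matrix(objectives, minimize=True)
    mask = non_dominated_mask(F)
    seen: set[tuple] = set()
    out = []
    for rec, m, row in zip(history.records, mask, F):
        key = tuple(np.round(row, 12))
        if m and key not in seen:
            seen.add(key)
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# persistence

_CONFIG_PREFIX = "#reactbo-config "


def save_history(history: CampaignHistory, path: str | Path) -> None:
    """Write a history CSV with its config embedded as a comment header."""
    buf = io.StringIO()
    buf.write(_CONFIG_PREFIX + json.dumps(history.config.to_dict(), sort_keys=True) + "\n")
    history.to_frame().to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def load_history(path: str | Path) -> tuple[CampaignConfig, pd.DataFrame]:
    """Read back a history CSV; returns (config, records frame)."""
    text = Path(path).read_text()
    first, _, rest = text.partition("\n")
    if not first.startswith(_CONFIG_PREFIX):
        raise ValueError(f"{path} is not a reactbo history file")
    config = CampaignConfig.from_dict(json.loads(first[len(_CONFIG_PREFIX):]))
    df = pd.read_csv(io.StringIO(rest), keep_default_na=False,
                     na_values=[], dtype={"capped_flags": str},
                     float_precision="round_trip")
    return config, df


def replay_campaign(path: str | Path) -> tuple[CampaignHistory, bool]:
    """Re-run a persisted campaign from its embedded config; returns the
    regenerated history and whether it matches the stored records exactly."""
    config, stored = load_history(path)
    rerun = run_campaign(config)
    regenerated = rerun.to_frame()
    stored_cmp = stored.astype(regenerated.dtypes.to_dict())
    return rerun, bool(regenerated.equals(stored_cmp))


# ---------------------------------------------------------------------------
# encoding comparison

def benchmark_optimum(benchmark: Benchmark, n_samples: int = 4000,
                      seed: int = 0) -> float:
    """Approximate best attainable yield (%) by dense random search on the
    noiseless simulator."""
    rng = np.random.default_rng(seed)
    space = benchmark.space
    model = replace(benchmark.model, noise_sd_rel=0.0)
    U = rng.random((n_samples, space.n_continuous))
    X = space.lows[None, :] + U * (space.highs - space.lows)[None, :]
    cat_idx = rng.integers(0, len(benchmark.catalyst_set), size=n_samples)
    best = 0.0
    for i in range(n_samples):
        cond = Conditions.from_values(X[i], space,
                                      benchmark.catalyst_set[int(cat_idx[i])])
        out = simulate_reaction(model, cond)
        best = max(best, 100.0 * out.yield_fraction)
    return best


@dataclass
class ComparisonReport:
    """Per-strategy convergence statistics of replicated campaigns."""

    benchmark: str
    algorithm: str
    strategies: tuple[str, ...]
    seeds: tuple[int, ...]
    threshold_pct: float
    #: strategy -> (n_replicates, n_records) best-so-far yield trajectories
    trajectories: dict[str, np.ndarray]
    histories: dict[str, list[CampaignHistory]] = field(default_factory=dict)

    def median_trajectory(self, strategy: str) -> np.ndarray:
        return np.median(self.trajectories[strategy], axis=0)

    def iqr_trajectory(self, strategy: str) -> tuple[np.ndarray, np.ndarray]:
        T = self.trajectories[strategy]
        return np.percentile(T, 25, axis=0), np.percentile(T, 75, axis=0)

    def final_best(self, strategy: str) -> np.ndarray:
        return self.trajectories[strategy][:, -1]

    def median_final_best(self, strategy: str) -> float:
        return float(np.median(self.final_best(strategy)))

    def first_to_threshold(self, strategy: str) -> np.ndarray:
        """1-based record index at which each replicate first reaches the
        threshold yield; never-reaching replicates count as one past the end."""
        T = self.trajectories[strategy]
        n = T.shape[1]
        out = np.empty(T.shape[0])
        for r in range(T.shape[0]):
            hit = np.flatnonzero(T[r] >= self.threshold_pct)
            out[r] = (hit[0] + 1) if len(hit) else n + 1
        return out

    def median_first_to_threshold(self, strategy: str) -> float:
        return float(np.median(self.first_to_threshold(strategy)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strategies:
            med = self.median_trajectory(s)
            q25, q75 = self.iqr_trajectory(s)
            for i in range(len(med)):
                rows.append({"strategy": s, "record": i + 1,
                             "median_best_yield_pct": med[i],
                             "q25": q25[i], "q75": q75[i]})
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        meta = {"benchmark": self.benchmark, "algorithm": self.algorithm,
                "strategies": list(self.strategies), "seeds": list(self.seeds),
                "threshold_pct": self.threshold_pct,
                "trajectories": {s: T.tolist() for s, T in self.trajectories.items()}}
        Path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "ComparisonReport":
        meta = json.loads(Path(path).read_text())
        return ComparisonReport(
            benchmark=meta["benchmark"], algorithm=meta["algorithm"],
            strategies=tuple(meta["strategies"]), seeds=tuple(meta["seeds"]),
            threshold_pct=meta["threshold_pct"],
            trajectories={s: np.array(T) for s, T in meta["trajectories"].items()},
        )


def compare_encodings(benchmark: str = "amidation_sim", algorithm: str = "tsemo",
                      strategies: Sequence[str] = ("one_hot", "label", "chemistry"),
                      n_replicates: int = 10, budget: int = 50, base_seed: int = 0,
                      n_catalysts: int = 6, threshold_pct: float | None = None,
                      keep_histories: bool = False,
                      **config_overrides) -> ComparisonReport:
    """Replicated seeded campaigns per encoding strategy, paired by seed.

    Each strategy sees the same replicate seeds so differences reflect the
    encoding, not the random stream.  The threshold statistic defaults to
    90% of the benchmark's dense-random-search optimum.
    """
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies to compare")
    if n_replicates < 3:
        raise ValueError("need at least 3 replicates")
    seeds = tuple(int(s % (2**31)) for s in
                  np.random.SeedSequence(int(base_seed)).generate_state(n_replicates))
    if threshold_pct is None:
        bm = make_benchmark(benchmark, n_catalysts=n_catalysts)
        threshold_pct = 0.9 * benchmark_optimum(bm, seed=base_seed)
    trajectories: dict[str, np.ndarray] = {}
    histories: dict[str, list[CampaignHistory]] = {}
    for strategy in strategies:
        runs = []
        for seed in seeds:
            cfg = CampaignConfig(benchmark=benchmark, encoding=strategy,
                                 algorithm=algorithm, budget=budget, seed=seed,
                                 n_catalysts=n_catalysts, **config_overrides)
            runs.append(run_campaign(cfg))
        trajectories[strategy] = np.vstack([best_so_far(h) for h in runs])
        if keep_histories:
            histories[strategy] = runs
    return ComparisonReport(benchmark=benchmark, algorithm=algorithm,
                            strategies=tuple(strategies), seeds=seeds,
                            threshold_pct=float(threshold_pct),
                            trajectories=trajectories, histories=histories)
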