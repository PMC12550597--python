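"""Process objectives computed from a simulated outcome.

Three objectives mirror a typical early process-development trade-off:

* **yield** (%) — maximize;
* **base cost per gram of product** (currency/g) — minimize; the catalyst
  (an organic base) is often the most expensive input;
* **process mass intensity** (PMI, g of all materials per g product) —
  minimize; the standard green-chemistry mass metric.

All masses are evaluated for exactly 1 mL of reaction mixture (PMI
"normalized to 1 mL"), with the solvent mass taken as density x 1 mL and
dissolved-species volumes ignored.  Because cost and PMI diverge as the
product mass goes to zero, both minimized objectives carry configurable
upper caps; values at or above a cap are clipped to it and flagged, which
keeps failed reactions finite for the surrogate model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .kinetics import Benchmark, Outcome
from .space import Conditions

__all__ = ["ObjectiveCaps", "ObjectiveVector", "compute_pmi", "compute_base_cost",
           "apply_caps", "compute_objectives", "OBJECTIVE_NAMES"]

OBJECTIVE_NAMES = ("yield", "base_cost", "pmi")


@dataclass(frozen=True)
class ObjectiveCaps:
    """Upper limits for the minimized objectives (yield is never capped)."""

    pmi: float = 500.0
    base_cost: float = 100.0

    def __post_init__(self) -> None:
        if self.pmi <= 0 or self.base_cost <= 0:
            raise ValueError("caps must be positive")


@dataclass(frozen=True)
class ObjectiveVector:
    yield_pct: float
    base_cost_per_g: float
    pmi: float
    capped_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not -1e-9 <= self.yield_pct <= 100 + 1e-9:
            raise ValueError("yield_pct outside [0, 100]")
        if self.base_cost_per_g < 0 or self.pmi < 0:
            raise ValueError("minimized objectives must be >= 0")


def _per_ml_masses(conditions: Conditions, benchmark: Benchmark) -> tuple[float, float]:
    """(total input mass, substrate moles) for 1 mL of reaction mixture."""
    mol_substrate = conditions.conc_M * 1e-3  # mol in 1 mL
    m_sub = mol_substrate * benchmark.substrate_molar_mass
    m_amine = conditions.amine_equiv * mol_substrate * benchmark.amine_molar_mass
    m_cat = conditions.cat_equiv * mol_substrate * conditions.catalyst.molar_mass
    m_solvent = benchmark.solvent_density * 1.0
    return m_sub + m_amine + m_cat + m_solvent, mol_substrate


def _product_mass(conditions: Conditions, outcome: Outcome, benchmark: Benchmark) -> float:
    mol_substrate = conditions.conc_M * 1e-3
    return outcome.yield_fraction * mol_substrate * benchmark.product_molar_mass


def compute_pmi(conditions: Conditions, outcome: Outcome, benchmark: Benchmark) -> float:
    """PMI = total input mass / product mass, per 1 mL; ``inf`` at zero yield."""
    total, _ = _per_ml_masses(conditions, benchmark)
    product = _product_mass(conditions, outcome, benchmark)
    if product <= 0.0:
        return math.inf
    return total / product


def compute_base_cost(conditions: Conditions, outcome: Outcome, benchmark: Benchmark) -> float:
    """Catalyst (base) cost per gram of product, per 1 mL; ``inf`` at zero yield."""
    mol_substrate = conditions.conc_M * 1e-3
    m_cat = conditions.cat_equiv * mol_substrate * conditions.catalyst.molar_mass
    product = _product_mass(conditions, outcome, benchmark)
    if product <= 0.0:
        return math.inf
    return m_cat * conditions.catalyst.cost_per_g / product


def apply_caps(vector: ObjectiveVector, caps: ObjectiveCaps) -> ObjectiveVector:
    """Clip minimized objectives to their caps; record which were clipped."""
    flags = list(vector.capped_flags)
    cost, pmi = vector.base_cost_per_g, vector.pmi
    if cost > caps.base_cost or math.isinf(cost):
        cost = caps.base_cost
        if "base_cost" not in flags:
            flags.append("base_cost")
    if pmi > caps.pmi or math.isinf(pmi):
        pmi = caps.pmi
        if "pmi" not in flags:
            flags.append("pmi")
    return replace(vector, base_cost_per_g=cost, pmi=pmi, capped_flags=tuple(flags))


def compute_objectives(conditions: Conditions, outcome: Outcome, benchmark: Benchmark,
                       caps: ObjectiveCaps | None = None) -> ObjectiveVector:
    """All three objectives for one (conditions, outcome) pair, caps applied."""
    caps = caps or ObjectiveCaps()
    vec = ObjectiveVector(
        yield_pct=100.0 * min(outcome.yield_fraction, 1.0),
        base_cost_per_g=compute_base_cost(conditions, outcome, benchmark),
        pmi=compute_pmi(conditions, outcome, benchmark),
    )
    return apply_caps(vec, caps)
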