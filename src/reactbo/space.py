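"""Parameter spaces and reaction conditions.

All benchmarks in this package share the same five continuous degrees of
freedom of a flow amidation slug — temperature, residence time, substrate
concentration, amine equivalents, catalyst equivalents — plus one
categorical dimension, the identity of the nucleophilic catalyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .descriptors import Catalyst, CatalystSet

__all__ = ["ContinuousDim", "ParameterSpace", "Conditions", "CONTINUOUS_NAMES"]

#: canonical order of the continuous dimensions (also the history CSV order)
CONTINUOUS_NAMES = ("temperature_C", "time_min", "conc_M", "amine_equiv", "cat_equiv")


@dataclass(frozen=True)
class ContinuousDim:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"dimension {self.name!r}: low must be < high")


@dataclass(frozen=True)
class ParameterSpace:
    """Continuous bounds plus one categorical (catalyst) dimension."""

    continuous: tuple[ContinuousDim, ...]
    catalyst_set: CatalystSet

    @property
    def n_continuous(self) -> int:
        return len(self.continuous)

    @property
    def n_catalysts(self) -> int:
        return len(self.catalyst_set)

    @property
    def lows(self) -> np.ndarray:
        return np.array([d.low for d in self.continuous], dtype=float)

    @property
    def highs(self) -> np.ndarray:
        return np.array([d.high for d in self.continuous], dtype=float)

    def contains(self, conditions: "Conditions", atol: float = 1e-9) -> bool:
        x = conditions.continuous_values(self)
        return bool(
            np.all(x >= self.lows - atol)
            and np.all(x <= self.highs + atol)
            and conditions.catalyst.name in self.catalyst_set.names
        )


@dataclass(frozen=True)
class Conditions:
    """One fully specified reaction.

    Units: temperature in deg C, time in minutes, substrate concentration in
    mol/L; amine and catalyst loadings as equivalents relative to substrate.
    """

    temperature_C: float
    time_min: float
    conc_M: float
    amine_equiv: float
    cat_equiv: float
    catalyst: Catalyst

    def __post_init__(self) -> None:
        if self.temperature_C <= -273.15:
            raise ValueError("temperature below absolute zero")
        if self.time_min < 0:
            raise ValueError("time must be >= 0")
        if self.conc_M <= 0:
            raise ValueError("substrate concentration must be > 0")
        if self.amine_equiv < 0 or self.cat_equiv < 0:
            raise ValueError("equivalents must be >= 0")

    def continuous_values(self, space: ParameterSpace) -> np.ndarray:
        """Continuous values in the order of ``space.continuous``."""
        as_dict = {
            "temperature_C": self.temperature_C,
            "time_min": self.time_min,
            "conc_M": self.conc_M,
            "amine_equiv": self.amine_equiv,
            "cat_equiv": self.cat_equiv,
        }
        return np.array([as_dict[d.name] for d in space.continuous], dtype=float)

    #: values used for dimensions a reduced space does not vary
    DEFAULTS = {"temperature_C": 25.0, "time_min": 1.0, "conc_M": 0.1,
                "amine_equiv": 1.0, "cat_equiv": 1.0}

    @staticmethod
    def from_values(values: Mapping[str, float] | np.ndarray, space: ParameterSpace,
                    catalyst: Catalyst) -> "Conditions":
        if not isinstance(values, Mapping):
            values = {d.name: float(v) for d, v in zip(space.continuous, values)}
        get = lambda k: float(values[k]) if k in values else Conditions.DEFAULTS[k]
        return Conditions(
            temperature_C=get("temperature_C"),
            time_min=get("time_min"),
            conc_M=get("conc_M"),
            amine_equiv=get("amine_equiv"),
            cat_equiv=get("cat_equiv"),
            catalyst=catalyst,
        )
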