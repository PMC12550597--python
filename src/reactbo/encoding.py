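"""Encoding of the categorical catalyst dimension for continuous optimizers.

Three strategies are provided:

``one_hot``
    Each catalyst becomes a distinct standard basis vector, adding one
    dimension per catalyst.
``label``
    Each catalyst receives a single numeric label; the labels are a seeded
    random permutation of equally spaced points in [0, 1], so the implied
    ordering carries no chemical information (by construction).
``chemistry``
    Labels are the min-max normalized Mayr nucleophilicities of the active
    catalyst set, so the order of and distance between levels reflects
    relative reactivity.
``chemistry_rank``
    Rank-only variant: labels equally spaced in [0, 1] but ordered by N.

Optimizer suggestions live in the continuous relaxation; decoding snaps the
categorical coordinate to the nearest label (Euclidean distance; argmax for
one-hot), ties broken toward the lowest catalyst index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import CatalystSet
from .space import Conditions, ParameterSpace

__all__ = ["Encoder", "EncodedPoint", "make_encoder", "STRATEGIES"]

STRATEGIES = ("one_hot", "label", "chemistry", "chemistry_rank")


@dataclass(frozen=True)
class EncodedPoint:
    """A point in normalized optimizer space ([0,1] continuous block +
    categorical block of length 1 or n_catalysts)."""

    continuous_part: np.ndarray
    categorical_part: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.continuous_part, self.categorical_part])


@dataclass(frozen=True)
class Encoder:
    strategy: str
    catalyst_set: CatalystSet
    #: per-catalyst coordinates in encoded space, shape (n_cat, n_cat_dims)
    label_values: np.ndarray
    shuffle_seed: int | None = None

    @property
    def n_categorical_dims(self) -> int:
        return self.label_values.shape[1]

    def dimensionality(self, space: ParameterSpace) -> int:
        """Total optimizer dimensionality for ``space`` under this encoder."""
        return space.n_continuous + self.n_categorical_dims

    # -- forward ---------------------------------------------------------
    def encode(self, conditions: Conditions, space: ParameterSpace) -> EncodedPoint:
        x = conditions.continuous_values(space)
        lo, hi = space.lows, space.highs
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError(f"conditions {x} outside space bounds [{lo}, {hi}]")
        cont = (x - lo) / (hi - lo) if len(x) else np.empty(0)
        idx = self.catalyst_set.index(conditions.catalyst.name)
        return EncodedPoint(np.clip(cont, 0.0, 1.0), self.label_values[idx].copy())

    # -- inverse with snapping ------------------------------------------
    def snap(self, categorical_part: np.ndarray) -> int:
        """Index of the catalyst nearest to a suggested categorical coordinate.

        Euclidean nearest label; for one-hot this is the argmax component.
        Ties resolve to the lowest catalyst index (np.argmin/argmax order).
        """
        cat = np.asarray(categorical_part, dtype=float)
        if not np.all(np.isfinite(cat)):
            raise ValueError("non-finite categorical coordinate")
        if self.strategy == "one_hot":
            return int(np.argmax(cat))
        d2 = np.sum((self.label_values - cat[None, :]) ** 2, axis=1)
        return int(np.argmin(d2))

    def decode(self, point: EncodedPoint, space: ParameterSpace) -> Conditions:
        cont = np.asarray(point.continuous_part, dtype=float)
        if len(cont) != space.n_continuous or len(point.categorical_part) != self.n_categorical_dims:
            raise ValueError("encoded point dimensionality does not match encoder/space")
        if not np.all(np.isfinite(cont)):
            raise ValueError("non-finite continuous coordinate")
        x = space.lows + np.clip(cont, 0.0, 1.0) * (space.highs - space.lows)
        catalyst = self.catalyst_set[self.snap(point.categorical_part)]
        return Conditions.from_values(x, space, catalyst)

    def decode_vector(self, v: np.ndarray, space: ParameterSpace) -> Conditions:
        v = np.asarray(v, dtype=float)
        nc = space.n_continuous
        return self.decode(EncodedPoint(v[:nc], v[nc:]), space)

    # -- serialization ---------------------------------------------------
    def state(self) -> dict:
        return {
            "strategy": self.strategy,
            "shuffle_seed": self.shuffle_seed,
            "catalysts": list(self.catalyst_set.names),
            "label_values": self.label_values.tolist(),
        }


def _label_coordinates(strategy: str, catalyst_set: CatalystSet,
                       seed: int | None) -> np.ndarray:
    n = len(catalyst_set)
    if strategy == "one_hot":
        return np.eye(n)
    if strategy == "label":
        if seed is None:
            raise ValueError("label encoding requires a shuffle seed")
        base = np.linspace(0.0, 1.0, n)
        perm = np.random.default_rng(seed).permutation(n)
        return base[perm][:, None]
    ns = catalyst_set.nucleophilicities
    if strategy == "chemistry":
        span = ns.max() - ns.min()
        if span == 0:
            raise ValueError("chemistry encoding needs >= 2 distinct nucleophilicities")
        return ((ns - ns.min()) / span)[:, None]
    if strategy == "chemistry_rank":
        order = np.argsort(np.argsort(ns, kind="stable"), kind="stable")
        return (order / (n - 1))[:, None]
    raise ValueError(f"unknown encoding strategy {strategy!r}; choose from {STRATEGIES}")


def make_encoder(strategy: str, catalyst_set: CatalystSet,
                 seed: int | None = None) -> Encoder:
    """Build an encoder for ``catalyst_set`` under ``strategy``.

    ``seed`` is required by (and only affects) the ``label`` strategy, where
    it fixes the random permutation of the equally spaced labels; the
    chemistry strategies are fully determined by the nucleophilicities.
    """
    if len(catalyst_set) < 2:
        raise ValueError("need at least 2 catalysts to encode a categorical choice")
    for c in catalyst_set:
        if strategy in ("chemistry", "chemistry_rank") and not np.isfinite(c.nucleophilicity):
            raise ValueError(f"catalyst {c.name!r} has no usable nucleophilicity")
    values = _label_coordinates(strategy, catalyst_set, seed)
    return Encoder(strategy=strategy, catalyst_set=catalyst_set,
                   label_values=values,
                   shuffle_seed=seed if strategy == "label" else None)
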