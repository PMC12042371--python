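"""Anagenetic and cladogenetic machinery of the DEC model family.

Along a branch, a range evolves by *anagenesis*: area gain (dispersal, rate
``d`` scaled by the stratum's multiplier matrix) and area loss (extirpation,
rate ``e`` per occupied area).  The null range is absorbing — a lineage that
loses its last area is dead and cannot resurrect.

At a speciation node, the ancestral range is partitioned between the two
daughters by a *cladogenetic* event.  The three base families differ in
which events they allow:

========== ================================================================
DEC        narrow sympatry, subset sympatry, vicariance with one
           single-area daughter
DIVALIKE   narrow sympatry, vicariance with any bipartition
BAYAREALIKE narrow sympatry and exact range copying only
========== ================================================================

Each family has an optional founder-event (+J) variant in which one
daughter may jump to a single area outside the ancestral range, with
weight ``j``.  Event probabilities are weights normalized per ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np
from scipy.linalg import expm

from .rangespace import GeoRange, StateSpace

__all__ = [
    "BiogeoParams",
    "ModelSpec",
    "CladoTable",
    "BASE_MODELS",
    "MODEL_NAMES",
    "build_rate_matrix",
    "cladogenesis_table",
    "transition_matrix",
    "J_MAX",
]

BASE_MODELS = ("DEC", "DIVALIKE", "BAYAREALIKE")
MODEL_NAMES = ("DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
               "BAYAREALIKE", "BAYAREALIKE+J")

#: Upper bound on the founder-event weight, with base event weights fixed
#: at 1; keeps the +J model nested over its base at j = 0.
J_MAX = 3.0


@dataclass(frozen=True)
class BiogeoParams:
    """Rates of the anagenetic process and the founder-event weight.

    ``d`` — dispersal (area gain) rate, events per lineage per my;
    ``e`` — extirpation (area loss) rate, same units;
    ``j`` — dimensionless founder-event weight, 0 disables jumps.
    """

    d: float
    e: float
    j: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0 or self.e < 0:
            raise ValueError("rates d and e must be nonnegative")
        if not 0 <= self.j <= J_MAX:
            raise ValueError(f"founder-event weight j must be in [0, {J_MAX}]")


@dataclass(frozen=True)
class ModelSpec:
    """A base cladogenesis family with or without founder-event jumps.

    The per-event weights are fixed by the family: ``y`` (sympatry /
    range copy), ``s`` (subset sympatry) and ``v`` (vicariance).
    """

    base: str
    with_j: bool = False

    def __post_init__(self) -> None:
        if self.base not in BASE_MODELS:
            raise ValueError(f"unknown base model {self.base!r}")

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        """Parse names like ``"DEC"`` or ``"DIVALIKE+J"``."""
        base, _, suffix = name.partition("+")
        if suffix not in ("", "J"):
            raise ValueError(f"unknown model name {name!r}")
        return cls(base=base, with_j=suffix == "J")

    @property
    def name(self) -> str:
        return self.base + ("+J" if self.with_j else "")

    @property
    def weights(self) -> tuple[float, float, float]:
        """(y, s, v) for this family."""
        if self.base == "DEC":
            return (1.0, 1.0, 1.0)
        if self.base == "DIVALIKE":
            return (1.0, 0.0, 1.0)
        return (1.0, 0.0, 0.0)  # BAYAREALIKE

    @property
    def n_free_params(self) -> int:
        return 3 if self.with_j else 2


def build_rate_matrix(
    space: StateSpace, params: BiogeoParams, multipliers: np.ndarray
) -> np.ndarray:
    """Anagenetic generator Q over the state space for one stratum.

    Gain of area ``k`` by range ``R`` proceeds at ``d * sum_{a in R} m[a,k]``
    (each occupied area is a potential dispersal source); loss of any
    occupied area proceeds at ``e``.  The null range is absorbing and the
    diagonal makes every row sum to zero.
    """
    n = space.n_areas
    multipliers = np.asarray(multipliers, dtype=float)
    if multipliers.shape != (n, n):
        raise ValueError(f"multiplier matrix must be {n}x{n}, got {multipliers.shape}")
    if np.any(multipliers < 0):
        raise ValueError("multipliers must be nonnegative")
    S = space.n_states
    Q = np.zeros((S, S))
    for i, r in enumerate(space.states):
        if r.is_null:
            continue  # absorbing
        occupied = r.indices()
        # dispersal: add one unoccupied area, if the grown range is legal
        if r.size < space.max_range_size:
            for k in range(n):
                if not r.contains(k):
                    grown = GeoRange(r.bits | (1 << k))
                    rate = params.d * sum(multipliers[a, k] for a in occupied)
                    Q[i, space.index_of(grown)] += rate
        # extirpation: drop one occupied area
        for a in occupied:
            shrunk = GeoRange(r.bits & ~(1 << a))
            Q[i, space.index_of(shrunk)] += params.e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """``expm(Q * dt)`` with tiny negative round-off clipped to zero."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return np.eye(Q.shape[0])
    P = expm(Q * dt)
    P[(P < 0) & (P > -1e-12)] = 0.0
    return P


@dataclass
class CladoTable:
    """Cladogenetic event distribution per ancestral range.

    For every non-null ancestral state the allowed ordered daughter pairs
    and their probabilities (weights normalized per ancestor).  Flat
    index arrays over all events support vectorized likelihood sums.
    """

    space: StateSpace
    spec: ModelSpec
    j: float
    anc_idx: np.ndarray = field(repr=False)
    left_idx: np.ndarray = field(repr=False)
    right_idx: np.ndarray = field(repr=False)
    prob: np.ndarray = field(repr=False)

    def events(self, ancestor: GeoRange) -> list[tuple[GeoRange, GeoRange, float]]:
        """(left daughter, right daughter, probability) for one ancestor."""
        ai = self.space.index_of(ancestor)
        sel = self.anc_idx == ai
        return [
            (self.space.states[l], self.space.states[r], float(p))
            for l, r, p in zip(
                self.left_idx[sel], self.right_idx[sel], self.prob[sel]
            )
        ]

    def row_sums(self) -> np.ndarray:
        """Total event probability per ancestral state (0 for null)."""
        out = np.zeros(self.space.n_states)
        np.add.at(out, self.anc_idx, self.prob)
        return out


def _iter_events(
    space: StateSpace, spec: ModelSpec, j: float
) -> Iterator[tuple[int, int, int, float]]:
    """Yield (ancestor, left, right, weight) over all allowed ordered events."""
    y, s, v = spec.weights
    n = space.n_areas
    for ai, r in enumerate(space.states):
        if r.is_null:
            continue
        occupied = r.indices()
        if r.size == 1:
            # narrow sympatry: both daughters inherit the single area
            if y > 0:
                yield ai, ai, ai, y
        else:
            if spec.base == "BAYAREALIKE" and y > 0:
                # range copy: both daughters inherit the full range
                yield ai, ai, ai, y
            if spec.base == "DEC" and s > 0:
                # subset sympatry: one daughter keeps R, the other one area of R
                for a in occupied:
                    si = space.index_of(GeoRange(1 << a))
                    yield ai, ai, si, s
                    yield ai, si, ai, s
            if v > 0:
                # vicariance: R split into two disjoint non-empty parts;
                # DEC requires one part to be a single area
                for k in range(1, r.size // 2 + 1):
                    for left in combinations(occupied, k):
                        lbits = 0
                        for a in left:
                            lbits |= 1 << a
                        rbits = r.bits & ~lbits
                        lsize, rsize = k, r.size - k
                        if spec.base == "DEC" and min(lsize, rsize) != 1:
                            continue
                        if 2 * k == r.size and lbits > rbits:
                            continue  # count each unordered bipartition once
                        li = space.index_of(GeoRange(lbits))
                        ri = space.index_of(GeoRange(rbits))
                        yield ai, li, ri, v
                        yield ai, ri, li, v
        if j > 0:
            # founder event: one daughter jumps to a single unoccupied area
            for k in range(n):
                if not r.contains(k):
                    ki = space.index_of(GeoRange(1 << k))
                    yield ai, ai, ki, j
                    yield ai, ki, ai, j


def cladogenesis_table(space: StateSpace, spec: ModelSpec, j: float = 0.0) -> CladoTable:
    """Build the normalized cladogenetic event table for one model.

    ``j`` must be 0 when the spec has no founder-event parameter; per
    ancestor, each allowed event gets probability weight / total weight.
    """
    if not spec.with_j and j != 0:
        raise ValueError(f"model {spec.name} has no founder-event parameter; j must be 0")
    if not 0 <= j <= J_MAX:
        raise ValueError(f"j must be in [0, {J_MAX}]")
    anc, left, right, w = [], [], [], []
    for ai, li, ri, weight in _iter_events(space, spec, j):
        anc.append(ai)
        left.append(li)
        right.append(ri)
        w.append(weight)
    anc_idx = np.array(anc, dtype=np.int64)
    left_idx = np.array(left, dtype=np.int64)
    right_idx = np.array(right, dtype=np.int64)
    weights = np.array(w, dtype=float)
    totals = np.zeros(space.n_states)
    np.add.at(totals, anc_idx, weights)
    prob = weights / totals[anc_idx]
    return CladoTable(space, spec, j, anc_idx, left_idx, right_idx, prob)
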