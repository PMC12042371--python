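"""Time-stratified dispersal-multiplier scenarios.

Dispersal multipliers scale the per-area dispersal rate ``d``
multiplicatively, encoding paleogeography: within each time stratum a
symmetric area x area matrix gives the relative ease of dispersal
between every pair of areas.  Four named scenarios are shipped:

``null``
    Every multiplier is 1 in every stratum — geography-free dispersal.
``panama``
    A land/water baseline (adjacent land 0.5, across water 0.25) in the
    youngest stratum; before the closure of the Panama isthmus (3 mya)
    the Mesoamerica <-> Pacific corridor is nearly shut (0.01).
``closing_americas``
    As ``panama`` after closure; between 3 and 20 mya the approaching
    continents allow over-water interchange (0.5); before 20 mya the
    corridor is nearly shut (0.01).
``gaarlandia``
    As ``closing_americas``, plus elevated dispersal on every route to
    and from the Caribbean in the 30-40 mya stratum, representing the
    hypothesized Greater Antilles-Aves Ridge land connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "TimeStratum",
    "ConnectivitySpec",
    "DispersalScenario",
    "build_scenario",
    "default_strata",
    "SCENARIO_NAMES",
    "ScenarioError",
    "ADJACENT_LAND",
    "ACROSS_WATER",
    "NON_ADJACENT",
]

SCENARIO_NAMES = ("null", "panama", "closing_americas", "gaarlandia")

ADJACENT_LAND = "adjacent-land"
ACROSS_WATER = "across-water"
NON_ADJACENT = "non-adjacent"

#: Baseline multipliers: staying costs 1, adjacent land half of that,
#: across water half of land.  Non-adjacent land pairs get the across-water
#: value — no third tier is defined.
MULTIPLIER_BY_RELATION = {
    ADJACENT_LAND: 0.5,
    ACROSS_WATER: 0.25,
    NON_ADJACENT: 0.25,
}

#: Corridor multiplier when Central and South America were separated.
CORRIDOR_SHUT = 0.01
#: Default elevated Caribbean multiplier for the GAARlandia stratum.
GAARLANDIA_CARIBBEAN = 0.5


class ScenarioError(ValueError):
    """Raised for invalid scenario configuration."""


@dataclass(frozen=True)
class TimeStratum:
    """A half-open interval of time, ``[younger_bound, older_bound)`` in mya."""

    index: int
    younger_bound: float
    older_bound: float

    def __post_init__(self) -> None:
        if not 0 <= self.younger_bound < self.older_bound:
            raise ScenarioError(
                f"stratum bounds must satisfy 0 <= younger < older, got "
                f"({self.younger_bound}, {self.older_bound})"
            )

    def contains(self, age: float) -> bool:
        # half-open in age: a boundary age belongs to the older-bound side,
        # i.e. age 3.0 falls in the 3-20 stratum, not 0-3
        return self.younger_bound <= age < self.older_bound


def default_strata(bounds: Sequence[float] = (0, 3, 20, 30, 40, 120)) -> tuple[TimeStratum, ...]:
    """The shipped five strata: 0-3, 3-20, 20-30, 30-40 and 40-120 mya."""
    return tuple(
        TimeStratum(i, lo, hi) for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
    )


@dataclass
class ConnectivitySpec:
    """Symmetric pairwise relations between areas (land / water / none)."""

    area_names: tuple[str, ...]
    relations: dict[frozenset, str] = field(default_factory=dict)

    def set(self, a: str, b: str, relation: str) -> None:
        if relation not in MULTIPLIER_BY_RELATION:
            raise ScenarioError(f"unknown relation {relation!r}")
        if a == b:
            raise ScenarioError("self-relation is fixed and cannot be set")
        for nm in (a, b):
            if nm not in self.area_names:
                raise ScenarioError(f"unknown area {nm!r}")
        self.relations[frozenset((a, b))] = relation

    def relation(self, a: str, b: str) -> str:
        if a == b:
            raise ScenarioError("self-relation is fixed")
        return self.relations.get(frozenset((a, b)), NON_ADJACENT)

    def baseline_matrix(self) -> np.ndarray:
        """Area x area multiplier matrix from the land/water classification."""
        n = len(self.area_names)
        m = np.ones((n, n))
        for i in range(n):
            for k in range(n):
                if i != k:
                    rel = self.relation(self.area_names[i], self.area_names[k])
                    m[i, k] = MULTIPLIER_BY_RELATION[rel]
        return m

    @classmethod
    def from_yaml(cls, path) -> "ConnectivitySpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        spec = cls(area_names=tuple(doc["areas"]))
        for rel_name, pairs in doc.get("relations", {}).items():
            for a, b in pairs:
                spec.set(a, b, rel_name)
        return spec

    def to_yaml(self, path) -> None:
        pairs: dict[str, list] = {}
        for key, rel in sorted(self.relations.items(), key=lambda kv: sorted(kv[0])):
            pairs.setdefault(rel, []).append(sorted(key))
        doc = {"areas": list(self.area_names), "relations": pairs}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class DispersalScenario:
    """Named time strata, each carrying an area x area multiplier matrix."""

    name: str
    area_names: tuple[str, ...]
    strata: tuple[TimeStratum, ...]
    multipliers: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.multipliers) != len(self.strata):
            raise ScenarioError("one multiplier matrix per stratum is required")
        n = len(self.area_names)
        for m in self.multipliers:
            if m.shape != (n, n):
                raise ScenarioError(f"multiplier matrix must be {n}x{n}")
            if not np.allclose(np.diag(m), 1.0):
                raise ScenarioError("diagonal multipliers must equal 1")
            if np.any(m <= 0) or np.any(m > 1):
                raise ScenarioError("multipliers must lie in (0, 1]")

    @property
    def oldest_bound(self) -> float:
        return self.strata[-1].older_bound

    @property
    def boundaries(self) -> tuple[float, ...]:
        """Internal boundary ages, for branch slicing."""
        return tuple(s.older_bound for s in self.strata[:-1])

    def stratum_at(self, age: float) -> TimeStratum:
        if age >= self.oldest_bound:
            raise ScenarioError(
                f"age {age} lies at or beyond the oldest stratum bound "
                f"{self.oldest_bound}"
            )
        for s in self.strata:
            if age < s.older_bound:
                return s
        raise AssertionError("unreachable")

    def multiplier(self, from_area: str, to_area: str, age: float) -> float:
        """Multiplier for dispersal from one area to another at a given age."""
        s = self.stratum_at(age)
        i = self.area_names.index(from_area)
        k = self.area_names.index(to_area)
        return float(self.multipliers[s.index][i, k])

    def matrix_for_stratum(self, stratum_index: int) -> np.ndarray:
        return self.multipliers[stratum_index]

    def is_stratum_invariant(self) -> bool:
        return all(
            np.array_equal(self.multipliers[0], m) for m in self.multipliers[1:]
        )


def _symmetric_override(m: np.ndarray, i: int, k: int, value: float) -> None:
    m[i, k] = value
    m[k, i] = value


def build_scenario(
    name: str,
    areas: Sequence[str],
    connectivity: ConnectivitySpec | None = None,
    strata: Sequence[TimeStratum] | None = None,
    *,
    corridor: tuple[str, str] = ("Mesoamerica", "Pacific"),
    caribbean: str = "Caribbean",
    gaarlandia_multiplier: float = GAARLANDIA_CARIBBEAN,
) -> DispersalScenario:
    """Construct one of the four shipped dispersal scenarios.

    The ``corridor`` pair is the Central <-> South America connection whose
    multiplier tracks the closing of the gap between the two continents;
    ``caribbean`` names the area whose routes are elevated in the
    GAARlandia stratum (30-40 mya).
    """
    if name not in SCENARIO_NAMES:
        raise ScenarioError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    areas = tuple(areas)
    strata = tuple(strata) if strata is not None else default_strata()

    if name == "null":
        n = len(areas)
        mats = tuple(np.ones((n, n)) for _ in strata)
        return DispersalScenario(name, areas, strata, mats)

    if connectivity is None:
        raise ScenarioError(f"scenario {name!r} requires a ConnectivitySpec")
    if tuple(connectivity.area_names) != areas:
        raise ScenarioError("connectivity area order must match the area list")
    base = connectivity.baseline_matrix()
    ci, ck = areas.index(corridor[0]), areas.index(corridor[1])

    mats = []
    for s in strata:
        m = base.copy()
        if name == "panama":
            # corridor nearly shut before the isthmus closed at 3 mya
            if s.younger_bound >= 3:
                _symmetric_override(m, ci, ck, CORRIDOR_SHUT)
        elif name in ("closing_americas", "gaarlandia"):
            if 3 <= s.younger_bound < 20:
                _symmetric_override(m, ci, ck, 0.5)
            elif s.younger_bound >= 20:
                _symmetric_override(m, ci, ck, CORRIDOR_SHUT)
            if name == "gaarlandia" and s.younger_bound == 30:
                # Greater Antilles-Aves Ridge connection: raise every
                # route to and from the Caribbean that sits below the
                # elevated value
                bi = areas.index(caribbean)
                for j in range(len(areas)):
                    if j != bi:
                        val = max(m[bi, j], gaarlandia_multiplier)
                        _symmetric_override(m, bi, j, val)
        mats.append(m)
    return DispersalScenario(name, areas, strata, tuple(mats))
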