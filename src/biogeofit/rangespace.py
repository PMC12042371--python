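"""Geographic areas, range state spaces and tip-geography files.

A lineage's geographic range is a subset of discrete operational areas.
The state space of the biogeographic Markov process enumerates every
subset up to a maximum range size, plus the empty (null) range.  The
null range is a valid interior state of the process — a lineage can lose
its last area along a branch — but it is never a legal observation at a
tip, because sampled tips are extant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Mapping

__all__ = [
    "Area",
    "GeoRange",
    "StateSpace",
    "Geography",
    "build_state_space",
    "read_geography",
    "write_geography",
    "read_geography_csv",
    "write_geography_csv",
    "GeographyError",
]


class GeographyError(ValueError):
    """Raised for malformed geography files or illegal ranges."""


@dataclass(frozen=True)
class Area:
    """A discrete operational area (an atom of a species range)."""

    name: str
    index: int


@dataclass(frozen=True, order=True)
class GeoRange:
    """A subset of area indices encoded as a bitset."""

    bits: int

    @classmethod
    def from_indices(cls, indices: Iterable[int]) -> "GeoRange":
        bits = 0
        for i in indices:
            bits |= 1 << i
        return cls(bits)

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    @property
    def is_null(self) -> bool:
        return self.bits == 0

    def indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.bits.bit_length()) if self.bits >> i & 1)

    def contains(self, index: int) -> bool:
        return bool(self.bits >> index & 1)

    def union(self, other: "GeoRange") -> "GeoRange":
        return GeoRange(self.bits | other.bits)

    def __iter__(self):
        return iter(self.indices())


NULL_RANGE = GeoRange(0)


@dataclass
class StateSpace:
    """Every geographic range of size <= ``max_range_size`` plus the null range.

    States are ordered deterministically: the null range first, then by
    range size, then lexicographically on the sorted area indices.  That
    order indexes the rows/columns of the anagenetic rate matrix.
    """

    areas: tuple[Area, ...]
    max_range_size: int
    states: tuple[GeoRange, ...] = field(init=False)
    _index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.areas)
        if n < 1:
            raise ValueError("at least one area is required")
        if not 1 <= self.max_range_size <= n:
            raise ValueError(
                f"max_range_size must be in [1, {n}], got {self.max_range_size}"
            )
        names = [a.name for a in self.areas]
        if len(set(names)) != len(names):
            raise ValueError("area names must be unique")
        states = [NULL_RANGE]
        for k in range(1, self.max_range_size + 1):
            for combo in combinations(range(n), k):
                states.append(GeoRange.from_indices(combo))
        self.states = tuple(states)
        self._index = {s.bits: i for i, s in enumerate(self.states)}

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index_of(self, r: GeoRange) -> int:
        try:
            return self._index[r.bits]
        except KeyError:
            raise KeyError(f"range {r} not in state space") from None

    def __contains__(self, r: GeoRange) -> bool:
        return r.bits in self._index

    def range_label(self, r: GeoRange) -> str:
        if r.is_null:
            return "null"
        return "+".join(self.areas[i].name for i in r.indices())

    def decode(self, binary: str) -> GeoRange:
        """Decode a presence/absence string in area order (e.g. ``"0100100000"``)."""
        if len(binary) != self.n_areas:
            raise GeographyError(
                f"expected {self.n_areas} presence/absence digits, got {len(binary)}"
            )
        if set(binary) - {"0", "1"}:
            raise GeographyError(f"presence/absence string must be binary: {binary!r}")
        return GeoRange.from_indices(i for i, c in enumerate(binary) if c == "1")

    def encode(self, r: GeoRange) -> str:
        return "".join("1" if r.contains(i) else "0" for i in range(self.n_areas))


def build_state_space(areas: Iterable[str], max_range_size: int) -> StateSpace:
    """Enumerate the range state space over named areas.

    The state count is ``1 + sum_{k=1..max} C(n, k)``; e.g. 10 areas with
    at most two areas per range give 1 + 10 + 45 = 56 states.
    """
    area_objs = tuple(Area(name, i) for i, name in enumerate(areas))
    return StateSpace(area_objs, max_range_size)


def expected_state_count(n_areas: int, max_range_size: int) -> int:
    """Closed-form state count: null range plus all subsets up to the cap."""
    return 1 + sum(comb(n_areas, k) for k in range(1, max_range_size + 1))


@dataclass
class Geography:
    """Observed tip ranges: a mapping taxon label -> GeoRange."""

    space: StateSpace
    ranges: dict[str, GeoRange]

    def __post_init__(self) -> None:
        for taxon, r in self.ranges.items():
            if r.is_null:
                raise GeographyError(f"taxon {taxon!r} has an empty range")
            if r not in self.space:
                raise GeographyError(
                    f"taxon {taxon!r} range exceeds max size "
                    f"{self.space.max_range_size}"
                )

    def __getitem__(self, taxon: str) -> GeoRange:
        return self.ranges[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ranges

    def __len__(self) -> int:
        return len(self.ranges)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.ranges)


def read_geography(path, space: StateSpace) -> Geography:
    """Read a Lagrange/PHYLIP-style tip geography file.

    Format::

        <n_taxa> <n_areas> (<area names ...>)
        <taxon> <binary presence/absence string>
        ...
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise GeographyError("empty geography file")
    header = lines[0]
    fields = header.replace("(", " ").replace(")", " ").split()
    try:
        n_taxa, n_areas = int(fields[0]), int(fields[1])
    except (IndexError, ValueError):
        raise GeographyError(f"malformed geography header: {header!r}") from None
    if n_areas != space.n_areas:
        raise GeographyError(
            f"header declares {n_areas} areas but state space has {space.n_areas}"
        )
    names = fields[2:]
    if names and names != [a.name for a in space.areas]:
        raise GeographyError("area names in header do not match the state space")
    ranges: dict[str, GeoRange] = {}
    for line in lines[1:]:
        parts = line.split()
        if len(parts) != 2:
            raise GeographyError(f"malformed geography row: {line!r}")
        taxon, binary = parts
        if taxon in ranges:
            raise GeographyError(f"duplicate taxon {taxon!r}")
        ranges[taxon] = space.decode(binary)
    if len(ranges) != n_taxa:
        raise GeographyError(
            f"header declares {n_taxa} taxa but {len(ranges)} rows were read"
        )
    return Geography(space, ranges)


def write_geography(geo: Geography, path) -> None:
    """Write a Geography in the Lagrange/PHYLIP-style dialect read above."""
    space = geo.space
    names = " ".join(a.name for a in space.areas)
    with open(path, "w") as fh:
        fh.write(f"{len(geo.ranges)} {space.n_areas} ({names})\n")
        for taxon, r in geo.ranges.items():
            fh.write(f"{taxon} {space.encode(r)}\n")


def read_geography_csv(path, space: StateSpace) -> Geography:
    """Read geography from CSV with columns ``taxon, areas`` (areas ';'-separated)."""
    by_name = {a.name: a.index for a in space.areas}
    ranges: dict[str, GeoRange] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            taxon = row["taxon"].strip()
            area_names = [s.strip() for s in row["areas"].split(";") if s.strip()]
            try:
                idx = [by_name[nm] for nm in area_names]
            except KeyError as exc:
                raise GeographyError(f"unknown area {exc} for taxon {taxon!r}") from None
            ranges[taxon] = GeoRange.from_indices(idx)
    return Geography(space, ranges)


def write_geography_csv(geo: Geography, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["taxon", "areas"])
        for taxon, r in geo.ranges.items():
            names = ";".join(geo.space.areas[i].name for i in r.indices())
            writer.writerow([taxon, names])
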