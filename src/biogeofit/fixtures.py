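"""Packaged 39-taxon Magnoliaceae fixture: chronogram, geography, scenarios.

The fixture chronogram carries the published clade ages at the
constrained nodes (root of the family at 92.92 mya, crown of *Magnolia*
at 44.02 mya, and so on); internal nodes without a published age are
placed by deterministic even division of the enclosing age interval, so
the tree is an illustrative, documented stand-in for the posterior
maximum-clade-credibility tree, not a reproduction of it.  Likewise the
tip geography is a best-effort transcription of the printed localities
into the ten operational areas, shipped as an editable mapping.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .chronogram import Chronogram, Node, interpolate_ages
from .rangespace import Geography, GeoRange, StateSpace, build_state_space
from .scenarios import (
    ConnectivitySpec,
    DispersalScenario,
    build_scenario,
    default_strata,
)

__all__ = [
    "AREA_NAMES",
    "MAX_RANGE_SIZE",
    "build_paper_state_space",
    "build_paper_chronogram",
    "build_paper_geography",
    "paper_connectivity",
    "paper_scenarios",
    "TABLE_CLADE_AGES",
]

#: The ten operational areas, in the fixed file-encoding order.
AREA_NAMES = (
    "Andes-North",
    "Brazil-Atlantic",
    "Brazil-Boreal",
    "Brazil-South",
    "Caribbean",
    "Mesoamerica",
    "Mexican-Transition-Zone",
    "Pacific",
    "Nearctic",
    "Asia",
)

#: Maximum observed range size: at most two areas per species.
MAX_RANGE_SIZE = 2

#: Published mean crown ages (mya) of the named clades.
TABLE_CLADE_AGES = {
    "Magnoliaceae": 92.92,
    "Magnolia": 44.02,
    "CladeI_CladeII": 38.91,
    "CladeI_Talauma": 35.97,
    "subsect_Talauma": 13.26,
    "Cubenses_Dugandiodendron": 14.08,
    "Cubenses": 10.9,
    "Dugandiodendron": 10.33,
    "CladeII": 30.26,
    "Magnolia_Macrophylla": 22.98,
    "sect_Magnolia": 13.83,
    "sect_Macrophylla": 6.0,
    "KRMGMY": 14.69,
    "Yulania": 9.7,
}


def _data_text(name: str) -> str:
    return resources.files("biogeofit.data").joinpath(name).read_text()


def build_paper_state_space() -> StateSpace:
    """Ten areas, ranges of at most two areas: 56 states."""
    return build_state_space(AREA_NAMES, MAX_RANGE_SIZE)


def paper_connectivity() -> ConnectivitySpec:
    """The shipped land/water classification of the ten areas."""
    doc = yaml.safe_load(_data_text("connectivity.yaml"))
    spec = ConnectivitySpec(area_names=tuple(doc["areas"]))
    for rel, pairs in doc["relations"].items():
        for a, b in pairs:
            spec.set(a, b, rel)
    return spec


def paper_scenarios() -> dict[str, DispersalScenario]:
    """All four shipped dispersal scenarios over the five time strata."""
    conn = paper_connectivity()
    strata = default_strata()
    return {
        name: build_scenario(name, AREA_NAMES, conn, strata)
        for name in ("null", "panama", "closing_americas", "gaarlandia")
    }


def build_paper_geography(space: StateSpace | None = None) -> Geography:
    """Tip ranges of the 39 fixture taxa over the ten areas."""
    if space is None:
        space = build_paper_state_space()
    doc = yaml.safe_load(_data_text("magnolia_geography.yaml"))
    gazetteer: dict[str, str] = doc["gazetteer"]
    by_name = {a.name: a.index for a in space.areas}
    ranges: dict[str, GeoRange] = {}
    for taxon, locality in doc["taxa"].items():
        entry = gazetteer[locality]
        areas = entry if isinstance(entry, list) else [entry]
        ranges[taxon] = GeoRange.from_indices(by_name[a] for a in areas)
    return Geography(space, ranges)


# -- fixture chronogram -------------------------------------------------------

# Nested (age-or-None, left, right) tuples; a bare string is a tip.
# Ages come from the published table; None marks nodes placed by
# interpolation.  Within-subsection topologies not published at node
# level are resolved arbitrarily but deterministically (illustrative).
_A = TABLE_CLADE_AGES

_SUBSECT_TALAUMA = (
    _A["subsect_Talauma"],
    # northern (Mexico / Central America / Caribbean) subclade
    (None,
     (None, (None, "M_lacandonica", "M_macrocarpa"),
            (None, "M_mexicana", "M_ofeliae")),
     (None, (None, "M_zoquepopolucae", "M_wetteri"),
            (None, "M_allenii", "M_dodecapetala"))),
    # South American subclade
    (None,
     (None, (None, "M_kichuana", "M_pastazaensis"),
            (None, "M_zamorana", "M_rimachii")),
     (None, (None, "M_silvioi", "M_virolinensis"),
            (None, "M_wolfii", "M_ovata"))),
)

_DUGANDIODENDRON = (
    _A["Dugandiodendron"],
    "M_bankardiorum",
    (None, "M_coronata", (None, "M_jaenensis", "M_ptaritepuiana")),
)

_CLADE_I = (
    _A["CladeI_Talauma"],
    _SUBSECT_TALAUMA,
    (
        _A["Cubenses_Dugandiodendron"],
        (_A["Cubenses"], "M_emarginata", "M_splendens"),
        _DUGANDIODENDRON,
    ),
)

_SECT_MACROPHYLLA = (
    _A["sect_Macrophylla"],
    "M_grandiflora",
    (None, "M_macrophylla",
     (None, "M_dealbata", (None, "M_rzedowskiana", "M_vovidesii"))),
)

_KRMGMY = (
    _A["KRMGMY"],
    "M_septentrionalis",
    (None, "M_obovata",
     (None, "M_grandis",
      (None, "M_kachirachirai",
       (None, "M_foveolata",
        (_A["Yulania"], "M_acuminata", "M_biondii"))))),
)

_CLADE_II = (
    _A["CladeII"],
    (
        _A["Magnolia_Macrophylla"],
        (_A["sect_Magnolia"], "M_iltisiana",
         (None, "M_panamensis", "M_sharpii")),
        _SECT_MACROPHYLLA,
    ),
    _KRMGMY,
)

_TOPOLOGY = (
    _A["Magnoliaceae"],
    "L_tulipifera",
    (
        _A["Magnolia"],
        "M_henryi",
        (_A["CladeI_CladeII"], _CLADE_I, _CLADE_II),
    ),
)


def _build(defn) -> Node:
    if isinstance(defn, str):
        return Node(label=defn, age=0.0)
    age, left, right = defn
    node = Node(age=age)
    node.add_child(_build(left))
    node.add_child(_build(right))
    return node


def build_paper_chronogram() -> Chronogram:
    """The 39-taxon fixture chronogram with published clade ages."""
    root = _build(_TOPOLOGY)
    interpolate_ages(root)
    return Chronogram(root)


def load_packaged_chronogram() -> Chronogram:
    """The same fixture tree, read from the shipped Newick file."""
    from .chronogram import parse_newick

    return parse_newick(_data_text("magnolia_chronogram.nwk"))
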