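"""Rectangular grid of developing-brain substructures.

The level-5 substructures of the developing mouse brain ontology can be laid
out, with slight distortion, on a rectangular grid: 20 segments along the
anterior-posterior (AP) axis times 4 longitudinal zones along the
dorsal-ventral (DV) axis — roof, alar, basal and floor plates — for 80
blocks in total.  Coordinates are 1-based and inclusive: ``ap=1`` is the
anterior (forebrain) end, ``dv=1`` the roof (dorsal) plate and ``dv=n_dv``
the floor (ventral) plate.

Adjacency is 4-neighbor (von Neumann).  The flattening misrepresents
anatomical neighborhood at two interfaces (TelA–p3R and r1A–isR); those
"discrepancy interfaces" are severed from the adjacency by default and are
configurable, since their exact grid positions are not fixed by the ontology
layout.  The defaults used here are placeholders (the roof–alar interfaces
of the telencephalic and r1 columns) and should be overridden when the true
positions are known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional

import yaml


class GridConfigError(ValueError):
    """Raised for an inconsistent grid or group configuration."""


class CellCoord(NamedTuple):
    """1-based grid coordinate: ``ap`` anterior→posterior, ``dv`` roof→floor."""

    ap: int
    dv: int


#: Placeholder positions for the two anatomically-wrong grid interfaces
#: (TelA–p3R and r1A–isR).  Severed from the adjacency by default.
DEFAULT_DISCREPANCY_INTERFACES: tuple[tuple[CellCoord, CellCoord], ...] = (
    (CellCoord(1, 1), CellCoord(1, 2)),
    (CellCoord(8, 1), CellCoord(8, 2)),
)


def _as_pair(pair: Iterable) -> tuple[CellCoord, CellCoord]:
    a, b = pair
    return (CellCoord(*a), CellCoord(*b))


@dataclass(frozen=True)
class GridSpec:
    """Shape and topology of the substructure grid."""

    n_ap: int = 20
    n_dv: int = 4
    discrepancy_interfaces: tuple[tuple[CellCoord, CellCoord], ...] = (
        DEFAULT_DISCREPANCY_INTERFACES
    )
    connectivity: str = "4-neighbor"

    def __post_init__(self) -> None:
        if self.n_ap < 1 or self.n_dv < 1:
            raise GridConfigError("grid dimensions must be positive")
        if self.connectivity != "4-neighbor":
            raise GridConfigError(
                f"unsupported connectivity {self.connectivity!r}"
            )
        pairs = tuple(_as_pair(p) for p in self.discrepancy_interfaces)
        object.__setattr__(self, "discrepancy_interfaces", pairs)
        for a, b in pairs:
            if not (self.in_bounds(a) and self.in_bounds(b)):
                raise GridConfigError(
                    f"discrepancy interface {a}-{b} out of grid bounds"
                )
            if abs(a.ap - b.ap) + abs(a.dv - b.dv) != 1:
                raise GridConfigError(
                    f"discrepancy interface {a}-{b} is not grid-adjacent"
                )

    @property
    def n_cells(self) -> int:
        return self.n_ap * self.n_dv

    def in_bounds(self, c: CellCoord) -> bool:
        return 1 <= c.ap <= self.n_ap and 1 <= c.dv <= self.n_dv

    def cells(self) -> Iterator[CellCoord]:
        for ap in range(1, self.n_ap + 1):
            for dv in range(1, self.n_dv + 1):
                yield CellCoord(ap, dv)


def build_adjacency(spec: GridSpec) -> dict[CellCoord, frozenset[CellCoord]]:
    """4-neighborhood of every grid cell, minus the severed interfaces.

    The result is symmetric and irreflexive; every cell is present as a key
    even if isolated.
    """
    severed = {frozenset(p) for p in spec.discrepancy_interfaces}
    adj: dict[CellCoord, set[CellCoord]] = {c: set() for c in spec.cells()}
    for c in spec.cells():
        for dap, ddv in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = CellCoord(c.ap + dap, c.dv + ddv)
            if spec.in_bounds(nb) and frozenset((c, nb)) not in severed:
                adj[c].add(nb)
    return {c: frozenset(ns) for c, ns in adj.items()}


def adjacency_to_json(adj: dict[CellCoord, frozenset[CellCoord]]) -> str:
    """Stable JSON dump of an adjacency map, for debugging and inspection."""
    payload = {
        f"{c.ap},{c.dv}": sorted([nb.ap, nb.dv] for nb in ns)
        for c, ns in sorted(adj.items())
    }
    return json.dumps(payload, indent=1, sort_keys=True)


@dataclass(frozen=True)
class RegionGroup:
    """One coarse region group.

    A group is defined either by inclusive AP/DV coordinate ranges (an
    unset range imposes no constraint, so an empty definition covers the
    whole grid — that is the control group) or by an explicit list of
    1-based pattern indices for pattern-membership analyses.
    """

    ap_range: Optional[tuple[int, int]] = None
    dv_range: Optional[tuple[int, int]] = None
    patterns: Optional[tuple[int, ...]] = None


@dataclass(frozen=True)
class RegionGroupConfig:
    """Named coarse region groups (forebrain / hindbrain / dorsal / ventral / control)."""

    groups: dict[str, RegionGroup] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RegionGroupConfig":
        # Default coordinate ranges are documented placeholders (the source
        # layout does not pin them down numerically); override via config.
        return cls(
            groups={
                "forebrain": RegionGroup(ap_range=(1, 6)),
                "hindbrain": RegionGroup(ap_range=(9, 20)),
                "dorsal": RegionGroup(dv_range=(1, 2)),
                "ventral": RegionGroup(dv_range=(3, 4)),
                "control": RegionGroup(),
            }
        )

    def __getitem__(self, name: str) -> RegionGroup:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(f"unknown region group {name!r}") from None


def cells_in_group(
    config: RegionGroupConfig, group: str, spec: GridSpec
) -> frozenset[CellCoord]:
    """Grid cells belonging to a named group (pure function of config).

    A group with no coordinate constraint (the control group) returns all
    cells.  An inverted range (lo > hi) denotes an empty range.
    """
    g = config[group]

    def in_range(v: int, rng: Optional[tuple[int, int]]) -> bool:
        return rng is None or rng[0] <= v <= rng[1]

    return frozenset(
        c
        for c in spec.cells()
        if in_range(c.ap, g.ap_range) and in_range(c.dv, g.dv_range)
    )


def load_grid_config(path) -> tuple[GridSpec, RegionGroupConfig]:
    """Read a YAML grid + group config.

    Layout::

        grid:
          n_ap: 20
          n_dv: 4
          discrepancy_interfaces: [[[1, 1], [1, 2]], [[8, 1], [8, 2]]]
        groups:
          forebrain: {ap: [1, 6]}
          dorsal: {dv: [1, 2]}
          posterior_patterns: {patterns: [1, 2, 5]}
          control: {}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    grid_raw = raw.get("grid", {})
    kwargs: dict = {}
    if "n_ap" in grid_raw:
        kwargs["n_ap"] = int(grid_raw["n_ap"])
    if "n_dv" in grid_raw:
        kwargs["n_dv"] = int(grid_raw["n_dv"])
    if "discrepancy_interfaces" in grid_raw:
        kwargs["discrepancy_interfaces"] = tuple(
            _as_pair(p) for p in grid_raw["discrepancy_interfaces"]
        )
    spec = GridSpec(**kwargs)
    groups: dict[str, RegionGroup] = {}
    for name, g in (raw.get("groups") or {}).items():
        g = g or {}
        groups[name] = RegionGroup(
            ap_range=tuple(g["ap"]) if "ap" in g else None,
            dv_range=tuple(g["dv"]) if "dv" in g else None,
            patterns=tuple(g["patterns"]) if "patterns" in g else None,
        )
    config = RegionGroupConfig(groups=groups) if groups else RegionGroupConfig.default()
    return spec, config
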