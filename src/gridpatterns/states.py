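"""Global expression states: 7-bit per-gene vectors over developmental time.

A gene is called *globally expressed* at a time point when the largest
contiguous expressed component of its demarcated slice contains strictly
more than half of the substructures with valid data.  The alternative
count-based rule (total expressed substructures exceeding half, regardless
of contiguity) is available via ``rule="cell-count"`` because both wordings
appear in descriptions of the method.

Stacking the seven binary calls in developmental order
(E11.5 ... P28) gives each gene a global expression state vector; genes are
then grouped by state and the states ranked by gene count.

The half-grid rule is justified by a null model: with each cell expressed
independently with probability p, the largest connected component of the
resulting random binary grid is small compared to half the grid for
moderate p, so a component spanning more than half the valid cells is very
unlikely to arise from spatially unstructured expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .grid import CellCoord, GridSpec, build_adjacency
from .io import TIMEPOINTS, timepoint_index
from .quantize import QuantizedSlice

Bits = tuple[int, ...]


def is_global(q: QuantizedSlice, rule: str = "largest-component") -> int:
    """1 iff the slice is globally expressed under the chosen rule (strict >)."""
    if q.n_valid == 0:
        raise ValueError("cannot call global expression on a slice with no valid data")
    if rule == "largest-component":
        measure = q.largest_component_size
    elif rule == "cell-count":
        measure = q.n_expressed
    else:
        raise ValueError(f"unknown rule {rule!r}")
    # exact rational comparison: size > n_valid / 2  <=>  2 * size > n_valid
    return int(2 * measure > q.n_valid)


@dataclass(frozen=True)
class GlobalStateVector:
    gene: str
    bits: Bits

    def __post_init__(self) -> None:
        if len(self.bits) != len(TIMEPOINTS) or any(b not in (0, 1) for b in self.bits):
            raise ValueError("bits must be a 7-tuple of 0/1 in canonical time order")

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


def state_vector(
    gene: str,
    slices: Mapping[str, Optional[QuantizedSlice]],
    rule: str = "largest-component",
) -> GlobalStateVector:
    """Build a gene's 7-bit state vector from its per-timepoint slices.

    Time points absent from ``slices`` (or mapped to None) yield bit 0: a
    gene cannot be called globally expressed without data.
    """
    bits = []
    for tp in TIMEPOINTS:
        q = slices.get(tp)
        bits.append(0 if q is None else is_global(q, rule=rule))
    return GlobalStateVector(gene, tuple(bits))


def state_vectors(
    quantized: Mapping[tuple[str, str], QuantizedSlice],
    rule: str = "largest-component",
) -> list[GlobalStateVector]:
    """State vectors for every gene appearing in a quantized-slice map."""
    genes = list(dict.fromkeys(g for g, _ in quantized))
    return [
        state_vector(
            g, {tp: quantized.get((g, tp)) for tp in TIMEPOINTS}, rule=rule
        )
        for g in genes
    ]


@dataclass(frozen=True)
class StateRanking:
    """States sorted by descending gene count; ties broken lexicographically."""

    rows: tuple[tuple[Bits, int], ...]

    @classmethod
    def from_counts(cls, rows: Iterable[tuple[Sequence[int], int]]) -> "StateRanking":
        """Rank externally tabulated (state, gene count) rows.

        Rows are taken as given (no merging of repeated states), so a
        published count table can be re-ranked faithfully.
        """
        normalized = [(tuple(int(b) for b in bits), int(n)) for bits, n in rows]
        normalized.sort(key=lambda r: (-r[1], r[0]))
        return cls(tuple(normalized))

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.rows)


def rank_states(vectors: Iterable[GlobalStateVector]) -> StateRanking:
    """Count genes per state and sort states by decreasing gene count."""
    counts: dict[Bits, int] = {}
    for v in vectors:
        counts[v.bits] = counts.get(v.bits, 0) + 1
    return StateRanking.from_counts(counts.items())


def count_rank_window(
    ranking: StateRanking, rank_from: int, rank_to: int, timepoint: str, bit: int
) -> int:
    """How many states at ranks [rank_from, rank_to] (1-based, inclusive)
    carry ``bit`` at ``timepoint``."""
    if not (1 <= rank_from <= rank_to <= len(ranking.rows)):
        raise IndexError(
            f"rank window [{rank_from}, {rank_to}] outside 1..{len(ranking.rows)}"
        )
    t = timepoint_index(timepoint)
    return sum(
        1 for bits, _ in ranking.rows[rank_from - 1 : rank_to] if bits[t] == bit
    )


def mean_expressed_substructures(slices: Iterable[QuantizedSlice]) -> float:
    """Mean expressed-cell count over slices (meant for non-global slices)."""
    sizes = [q.n_expressed for q in slices]
    if not sizes:
        raise ValueError("no slices given")
    return float(np.mean(sizes))


@dataclass(frozen=True)
class NullModelConfig:
    """Independent-cell null: each grid cell expressed with probability p."""

    p: float
    spec: GridSpec = GridSpec()
    n_sims: int = 1000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")


def _largest_component_size(
    active: set[CellCoord], adjacency: Mapping[CellCoord, frozenset[CellCoord]]
) -> int:
    best = 0
    seen: set[CellCoord] = set()
    for start in active:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            c = stack.pop()
            size += 1
            for nb in adjacency[c]:
                if nb in active and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        best = max(best, size)
    return best


def simulate_largest_component_null(
    cfg: NullModelConfig,
    adjacency: Optional[Mapping[CellCoord, frozenset[CellCoord]]] = None,
) -> np.ndarray:
    """Seeded draws of the largest-component size under the random-grid null."""
    adjacency = adjacency if adjacency is not None else build_adjacency(cfg.spec)
    cells = sorted(adjacency)
    rng = np.random.default_rng(cfg.seed)
    sizes = np.empty(cfg.n_sims, dtype=int)
    for s in range(cfg.n_sims):
        mask = rng.random(len(cells)) < cfg.p
        active = {c for c, m in zip(cells, mask) if m}
        sizes[s] = _largest_component_size(active, adjacency)
    return sizes


def prob_largest_exceeds_half(sizes: np.ndarray, n_cells: int) -> float:
    """Empirical P(largest component > n_cells / 2)."""
    return float(np.mean(2 * sizes > n_cells))


def exceedance_curve(
    ps: Sequence[float],
    spec: GridSpec = GridSpec(),
    n_sims: int = 1000,
    seed: Optional[int] = None,
) -> list[float]:
    """P(largest component > half the grid) across p, with common random
    numbers: each simulation draws one uniform per cell and thresholds it at
    every p, so the per-draw component is monotone in p and the estimated
    curve inherits the true monotonicity of the exceedance probability.
    """
    adjacency = build_adjacency(spec)
    cells = sorted(adjacency)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(ps), dtype=int)
    for _ in range(n_sims):
        u = rng.random(len(cells))
        for k, p in enumerate(ps):
            active = {c for c, uv in zip(cells, u) if uv < p}
            if 2 * _largest_component_size(active, adjacency) > len(cells):
                hits[k] += 1
    return [h / n_sims for h in hits]


def fit_poisson_moment(sizes: np.ndarray) -> float:
    """Descriptive moment-matched Poisson rate for a largest-component sample."""
    return float(np.mean(sizes))
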