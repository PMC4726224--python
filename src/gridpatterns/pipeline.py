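"""End-to-end convenience driver: field → quantization → states → patterns."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .grid import CellCoord, GridSpec, build_adjacency
from .io import ExpressionField
from .patterns import (
    ComponentPool,
    PatternCluster,
    cluster_components,
    filter_components,
    pool_components,
)
from .quantize import QuantizedSlice, demarcate_field
from .states import GlobalStateVector, StateRanking, is_global, rank_states, state_vectors


@dataclass
class PipelineResult:
    quantized: Mapping[tuple[str, str], QuantizedSlice]
    bits: Mapping[tuple[str, str], int]
    vectors: list[GlobalStateVector]
    ranking: StateRanking
    pool: ComponentPool
    clusters: list[PatternCluster]


def run_pipeline(
    field: ExpressionField,
    spec: Optional[GridSpec] = None,
    min_lower: float = 0.2,
    bound: str = "lower",
    global_rule: str = "largest-component",
    min_cells: int = 2,
    max_fraction_of_valid: float = 0.5,
    jaccard_min: float = 0.5,
    min_members: int = 1,
    refine_mean_jaccard: Optional[float] = 0.4,
    adjacency: Optional[Mapping[CellCoord, frozenset[CellCoord]]] = None,
) -> PipelineResult:
    """Run demarcation, global-state calling and pattern clustering.

    The pipeline enables quasi-clique refinement (mean-overlap peel at
    0.4, below the 0.5 edge threshold) because plain single-link
    components chain recurrent patterns to coincidental noise regions;
    pass ``refine_mean_jaccard=None`` for the unrefined partition.
    """
    spec = spec or field.spec
    adjacency = adjacency if adjacency is not None else build_adjacency(spec)
    quantized = demarcate_field(field, adjacency, min_lower=min_lower, bound=bound)
    bits = {key: is_global(q, rule=global_rule) for key, q in quantized.items()}
    vectors = state_vectors(quantized, rule=global_rule)
    ranking = rank_states(vectors)
    pool = filter_components(
        pool_components(quantized, bits),
        min_cells=min_cells,
        max_fraction_of_valid=max_fraction_of_valid,
    )
    clusters = cluster_components(pool, jaccard_min=jaccard_min, min_members=min_members)
    return PipelineResult(quantized, bits, vectors, ranking, pool, clusters)
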