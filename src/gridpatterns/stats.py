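"""Enrichment and group-comparison statistics.

Gene-set enrichment uses the upper-tail hypergeometric test — for a query
of n genes drawn from a universe of N containing a K-gene category,
``p = P(X >= k)`` where k is the observed overlap — with Benjamini-Hochberg
correction across the collection.  Co-expression group selection and the
two-sample Kolmogorov-Smirnov comparison implement the knockout-validation
analysis: genes expressed in a reference region at every prenatal stage
versus genes never expressed there, compared on their mutant/control log2
expression ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .grid import CellCoord
from .quantize import QuantizedSlice

#: The four embryonic stages preceding birth.
PRENATAL_TIMEPOINTS: tuple[str, ...] = ("E11.5", "E13.5", "E15.5", "E18.5")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            collection[parts[0]] = {g for g in parts[2:] if g}
    return collection


@dataclass(frozen=True)
class EnrichmentRow:
    category: str
    k: int  # overlap: query ∩ category
    K: int  # category size within the universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    q_value: float


def hypergeom_enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment with BH correction, sorted by p.

    Categories are intersected with the universe; the query must be a
    subset of the universe.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query")
    if not query_set <= universe_set:
        extra = sorted(query_set - universe_set)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")
    N, n = len(universe_set), len(query_set)
    names, pvals, ks, Ks = [], [], [], []
    for name, members in collection.items():
        cat = set(members) & universe_set
        k = len(cat & query_set)
        # P(X >= k); sf(k-1) is exact for the discrete distribution
        p = float(sps.hypergeom.sf(k - 1, N, len(cat), n))
        names.append(name)
        pvals.append(min(p, 1.0))
        ks.append(k)
        Ks.append(len(cat))
    if not names:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    rows = [
        EnrichmentRow(name, k, K, n, N, p, float(q))
        for name, k, K, p, q in zip(names, ks, Ks, pvals, qvals)
    ]
    rows.sort(key=lambda r: (r.p_value, r.category))
    return rows


@dataclass(frozen=True)
class GroupSelection:
    """Similar-expression and control gene groups for a reference region."""

    similar_group: frozenset[str]
    control_group: frozenset[str]
    region_cells: frozenset[CellCoord]
    timepoints: tuple[str, ...]


def select_coexpression_groups(
    quantized: Mapping[tuple[str, str], QuantizedSlice],
    region_cells: Iterable[CellCoord],
    timepoints: Sequence[str] = PRENATAL_TIMEPOINTS,
    require_all: bool = True,
) -> GroupSelection:
    """Split genes by prenatal expression in a reference region.

    The similar group holds genes with at least one expressed cell inside
    the region at every listed time point (``require_all=False`` relaxes
    this to *any* time point); the control group holds genes with no
    expressed region cell at any of them.  Genes matching neither rule are
    left out.  Slices absent from ``quantized`` count as unexpressed.
    """
    region = frozenset(region_cells)
    if not region:
        raise ValueError("empty region")
    genes = list(dict.fromkeys(g for g, _ in quantized))
    similar, control = set(), set()
    for g in genes:
        hits = []
        for tp in timepoints:
            q = quantized.get((g, tp))
            hits.append(bool(q and (q.cells & region)))
        if all(hits) if require_all else any(hits):
            similar.add(g)
        elif not any(hits):
            control.add(g)
    return GroupSelection(
        frozenset(similar), frozenset(control), region, tuple(timepoints)
    )


def ks_two_sample(
    a: Sequence[float], b: Sequence[float], method: str = "asymp"
) -> tuple[float, float]:
    """Two-sided two-sample KS test: (D, p).

    D is the maximum gap between the two empirical CDFs; the p-value is
    asymptotic by default (``method="exact"`` for small samples).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def read_log2_ratio_table(path) -> dict[str, float]:
    """Two-column TSV (gene, log2_ratio) → mapping; header optional."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if ln == 0 and parts[0].lower() == "gene":
                continue
            value = float(parts[1])
            if not np.isfinite(value):
                raise ValueError(f"non-finite log2 ratio for {parts[0]!r}")
            table[parts[0]] = value
    return table


@dataclass(frozen=True)
class TailSummary:
    """Response-magnitude summary of a gene group's log2 ratios."""

    n: int  # genes found in the table
    n_missing: int  # genes absent from the table (skipped)
    tail_fraction: float  # fraction with |log2 ratio| >= cutoff
    small_fraction: float  # fraction with |log2 ratio| < small_cutoff
    n_up: int  # ratio > 0
    n_down: int  # ratio < 0
    cutoff: float
    small_cutoff: float


def tail_fractions(
    table: Mapping[str, float],
    genes: Iterable[str],
    cutoff: float = 0.1879,
    small_cutoff: float = 0.1,
) -> TailSummary:
    """Fractions of strong / negligible responses in a gene group.

    The default cutoff 0.1879 = log2(1.1386) corresponds to a 13.86%
    fold-change in either direction.  Genes missing from the table are
    skipped and counted in ``n_missing``.
    """
    gene_list = list(dict.fromkeys(genes))
    values = np.array([table[g] for g in gene_list if g in table], dtype=float)
    n_missing = len(gene_list) - len(values)
    if len(values) == 0:
        raise ValueError("no group gene appears in the ratio table")
    return TailSummary(
        n=len(values),
        n_missing=n_missing,
        tail_fraction=float(np.mean(np.abs(values) >= cutoff)),
        small_fraction=float(np.mean(np.abs(values) < small_cutoff)),
        n_up=int(np.sum(values > 0)),
        n_down=int(np.sum(values < 0)),
        cutoff=cutoff,
        small_cutoff=small_cutoff,
    )
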