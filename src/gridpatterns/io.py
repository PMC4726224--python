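"""Reading and writing the energy-table interchange format.

Per-gene, per-time-point expression "energies" (ISH density × intensity
summaries averaged over each substructure) are exchanged as a flat TSV with
header ``gene  timepoint  ap  dv  energy``.  A blank or ``NA`` energy marks
a missing observation; a zero energy is a valid observation, distinct from
missing.  Any (gene, timepoint, cell) triple absent from the table is
missing.  The seven canonical developmental time points are fixed:
E11.5, E13.5, E15.5, E18.5, P4, P14, P28.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .grid import CellCoord, GridSpec

#: Canonical developmental time points, in order.
TIMEPOINTS: tuple[str, ...] = ("E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P28")
N_TIMEPOINTS = len(TIMEPOINTS)
_TP_INDEX = {tp: i for i, tp in enumerate(TIMEPOINTS)}


class EnergyTableError(ValueError):
    """Raised for malformed rows, bad coordinates or duplicate triples."""


def timepoint_index(tp: str) -> int:
    try:
        return _TP_INDEX[tp]
    except KeyError:
        raise EnergyTableError(
            f"unknown timepoint {tp!r}; expected one of {TIMEPOINTS}"
        ) from None


@dataclass
class SliceView:
    """One (gene, timepoint) plane of the field; NaN marks missing cells."""

    gene: str
    timepoint: str
    values: np.ndarray  # shape (n_ap, n_dv), float, NaN = missing

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def observed_items(self) -> Iterator[tuple[CellCoord, float]]:
        n_ap, n_dv = self.values.shape
        for i in range(n_ap):
            for j in range(n_dv):
                v = self.values[i, j]
                if not math.isnan(v):
                    yield CellCoord(i + 1, j + 1), float(v)

    def observed_cells(self) -> frozenset[CellCoord]:
        return frozenset(c for c, _ in self.observed_items())


@dataclass
class ExpressionField:
    """Energies over (gene, timepoint, AP, DV) with a missing mask (NaN)."""

    genes: list[str]
    values: np.ndarray  # shape (n_genes, 7, n_ap, n_dv)
    spec: GridSpec

    def __post_init__(self) -> None:
        expected = (len(self.genes), N_TIMEPOINTS, self.spec.n_ap, self.spec.n_dv)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (not np.all(np.isfinite(observed)) or observed.min() < 0):
            raise ValueError("energies must be finite and non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        if len(self._gene_index) != len(self.genes):
            raise ValueError("duplicate gene identifiers")

    @property
    def timepoints(self) -> tuple[str, ...]:
        return TIMEPOINTS

    def gene_index(self, gene: str) -> int:
        return self._gene_index[gene]

    def slice_view(self, gene: str, timepoint: str) -> SliceView:
        g = self.gene_index(gene)
        t = timepoint_index(timepoint)
        return SliceView(gene, timepoint, self.values[g, t])

    def iter_slices(self) -> Iterator[SliceView]:
        for gene in self.genes:
            for tp in TIMEPOINTS:
                yield self.slice_view(gene, tp)


def empty_field(genes: list[str], spec: GridSpec) -> ExpressionField:
    values = np.full(
        (len(genes), N_TIMEPOINTS, spec.n_ap, spec.n_dv), np.nan, dtype=float
    )
    return ExpressionField(list(genes), values, spec)


def read_energy_table(path, spec: Optional[GridSpec] = None) -> ExpressionField:
    """Parse an energy TSV into an :class:`ExpressionField`.

    Raises :class:`EnergyTableError` on malformed rows, out-of-range
    coordinates, unknown timepoint labels or duplicate
    (gene, timepoint, cell) triples.
    """
    spec = spec or GridSpec()
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "timepoint": str},
        na_values=["", "NA"],
        keep_default_na=False,
    )
    required = ["gene", "timepoint", "ap", "dv", "energy"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise EnergyTableError(f"missing columns: {missing_cols}")
    try:
        df["ap"] = df["ap"].astype(int)
        df["dv"] = df["dv"].astype(int)
        df["energy"] = df["energy"].astype(float)
    except (ValueError, TypeError) as exc:
        raise EnergyTableError(f"malformed row: {exc}") from exc

    for tp in df["timepoint"].unique():
        timepoint_index(tp)
    bad = df[
        (df["ap"] < 1) | (df["ap"] > spec.n_ap) | (df["dv"] < 1) | (df["dv"] > spec.n_dv)
    ]
    if len(bad):
        row = bad.iloc[0]
        raise EnergyTableError(
            f"coordinate (ap={row['ap']}, dv={row['dv']}) outside "
            f"{spec.n_ap}x{spec.n_dv} grid"
        )
    dup = df.duplicated(subset=["gene", "timepoint", "ap", "dv"])
    if dup.any():
        row = df[dup].iloc[0]
        raise EnergyTableError(
            f"duplicate triple ({row['gene']}, {row['timepoint']}, "
            f"{row['ap']},{row['dv']})"
        )
    observed = df[df["energy"].notna()]
    if len(observed) and (
        not np.all(np.isfinite(observed["energy"])) or observed["energy"].min() < 0
    ):
        raise EnergyTableError("energies must be finite and non-negative")

    genes = list(dict.fromkeys(df["gene"]))
    field = empty_field(genes, spec)
    gi = field.gene_index
    for row in observed.itertuples(index=False):
        field.values[gi(row.gene), timepoint_index(row.timepoint), row.ap - 1, row.dv - 1] = (
            row.energy
        )
    return field


def write_energy_table(field: ExpressionField, path) -> None:
    """Write observed entries in canonical (gene, timepoint, ap, dv) order.

    Energies are written with shortest-round-trip float formatting, so
    ``read_energy_table(write_energy_table(f))`` reproduces the field
    bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("gene\ttimepoint\tap\tdv\tenergy\n")
        for gene in sorted(field.genes):
            g = field.gene_index(gene)
            for t, tp in enumerate(TIMEPOINTS):
                plane = field.values[g, t]
                for i in range(field.spec.n_ap):
                    for j in range(field.spec.n_dv):
                        v = plane[i, j]
                        if not math.isnan(v):
                            fh.write(
                                f"{gene}\t{tp}\t{i + 1}\t{j + 1}\t{float(v)!r}\n"
                            )


def filter_genes(field: ExpressionField) -> ExpressionField:
    """Drop genes with no observed value at any time point or cell.

    This is the completeness rule applied to the atlas-derived table; it is
    idempotent and keeps any gene with at least one observation.
    """
    keep = [
        i for i in range(len(field.genes)) if np.any(~np.isnan(field.values[i]))
    ]
    return ExpressionField(
        [field.genes[i] for i in keep], field.values[keep].copy(), field.spec
    )
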