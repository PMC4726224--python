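"""Bundled reference data.

``aba_global_state_counts.tsv`` reproduces the published count table of
top-ranking global expression states from the Allen Developing Mouse Brain
Atlas analysis (29 rows of 7-bit states with their gene counts), for
re-ranking and window-count analyses without the full atlas-derived energy
table.  ``aba_pattern_groups.yaml`` is an example region-group config whose
pattern-index lists follow the published 45-pattern ranking.
"""

from __future__ import annotations

from importlib import resources

from .grid import GridSpec, RegionGroupConfig, load_grid_config
from .states import StateRanking


def _data_path(name: str):
    return resources.files("gridpatterns.data").joinpath(name)


def load_aba_state_ranking() -> StateRanking:
    """The published global-state gene-count table as a :class:`StateRanking`."""
    rows = []
    with _data_path("aba_global_state_counts.tsv").open() as fh:
        header = fh.readline()
        assert header.startswith("E11.5")
        for line in fh:
            parts = line.split()
            if len(parts) == 8:
                rows.append((tuple(int(b) for b in parts[:7]), int(parts[7])))
    return StateRanking.from_counts(rows)


def load_aba_pattern_groups() -> tuple[GridSpec, RegionGroupConfig]:
    """Example grid + region-group config for atlas re-runs."""
    with resources.as_file(_data_path("aba_pattern_groups.yaml")) as p:
        return load_grid_config(p)
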