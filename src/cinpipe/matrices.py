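"""Cell-by-bin matrices: raw read counts and integer copy-number states."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBinning

__all__ = ["BinCountMatrix", "CopyNumberMatrix"]


@dataclass
class BinCountMatrix:
    """Raw read counts per cell (rows) per genomic bin (columns)."""

    binning: GenomeBinning
    counts: np.ndarray  # (n_cells, n_bins) non-negative ints
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x bins)")
        if self.counts.shape[1] != self.binning.n_bins:
            raise ValueError(
                f"counts has {self.counts.shape[1]} columns but binning has "
                f"{self.binning.n_bins} bins"
            )
        if len(self.cell_ids) != self.counts.shape[0]:
            raise ValueError("cell_ids length does not match row count")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class CopyNumberMatrix:
    """Integer copy-number state per cell per bin.

    This is the substrate of all karyotype scores: rows are single cells,
    columns are genomic bins in chromosome order, values are integer copy
    numbers in ``[0, max_state]``.
    """

    binning: GenomeBinning
    states: np.ndarray  # (n_cells, n_bins) ints in [0, max_state]
    cell_ids: list[str]
    max_state: int = 10
    clone_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D (cells x bins)")
        if self.states.shape[1] != self.binning.n_bins:
            raise ValueError("state columns do not match binning")
        if len(self.cell_ids) != self.states.shape[0]:
            raise ValueError("cell_ids length does not match row count")
        if not np.issubdtype(self.states.dtype, np.integer):
            if not np.allclose(self.states, np.round(self.states)):
                raise ValueError("states must be integer")
            self.states = np.round(self.states).astype(np.int64)
        if self.states.size and (self.states.min() < 0 or self.states.max() > self.max_state):
            raise ValueError(f"states outside [0, {self.max_state}]")
        if self.clone_labels is not None and len(self.clone_labels) != self.states.shape[0]:
            raise ValueError("clone_labels length does not match row count")

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]
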