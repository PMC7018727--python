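"""Karyotype scores quantifying chromosomal instability from single cells.

Three summary statistics of a cells-by-bins integer copy-number matrix:

* **aneuploidy score** ``A`` — mean absolute deviation of states from the
  euploid ploidy ``p`` over all cells and bins; 0 iff every state equals
  ``p``.
* **heterogeneity score** ``H`` — mean over bins of the Gini–Simpson
  diversity ``1 - sum_s f_sb**2`` of states across cells, i.e. the
  probability two cells drawn with replacement differ at a random bin;
  in ``[0, 1]``, 0 iff all cells are identical.
* **structural score** ``S`` — copy-number state transitions between
  adjacent bins within a chromosome (boundaries never counted), per Mb of
  genome, normalised to the number of cells: ``S = T / (L * N)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .matrices import CopyNumberMatrix

__all__ = ["CINScores", "aneuploidy_score", "heterogeneity_score",
           "structural_score", "score_matrix"]


@dataclass(frozen=True)
class CINScores:
    """The score triple plus the quantities it was computed from."""

    aneuploidy: float
    heterogeneity: float
    structural: float
    n_cells: int
    genome_length_mb: float
    euploid_ploidy: int
    total_transitions: int

    def as_dict(self) -> dict:
        return asdict(self)


def aneuploidy_score(cn: CopyNumberMatrix, euploid_ploidy: int = 2) -> float:
    """Mean absolute deviation of copy-number states from the euploid ploidy."""
    if cn.n_cells < 1:
        raise ValueError("aneuploidy score requires at least one cell")
    return float(np.mean(np.abs(cn.states - euploid_ploidy)))


def heterogeneity_score(cn: CopyNumberMatrix) -> float:
    """Mean per-bin Gini–Simpson diversity of states across cells."""
    if cn.n_cells < 2:
        raise ValueError("heterogeneity score requires at least two cells")
    n = cn.n_cells
    div = np.empty(cn.states.shape[1])
    for b in range(cn.states.shape[1]):
        _, counts = np.unique(cn.states[:, b], return_counts=True)
        f = counts / n
        div[b] = 1.0 - np.sum(f ** 2)
    return float(div.mean())


def count_transitions(cn: CopyNumberMatrix) -> int:
    """Adjacent-bin state changes within chromosomes, summed over cells."""
    slices = cn.binning.chromosome_slices()
    total = 0
    for sl in slices.values():
        seg = cn.states[:, sl]
        if seg.shape[1] > 1:
            total += int(np.sum(seg[:, 1:] != seg[:, :-1]))
    return total


def structural_score(cn: CopyNumberMatrix) -> float:
    """Within-chromosome state transitions per Mb per cell, ``T / (L * N)``."""
    if cn.n_cells < 1:
        raise ValueError("structural score requires at least one cell")
    T = count_transitions(cn)
    return T / (cn.binning.genome_length_mb * cn.n_cells)


def score_matrix(cn: CopyNumberMatrix, euploid_ploidy: int = 2) -> CINScores:
    """Compute all three karyotype scores of a copy-number matrix."""
    return CINScores(
        aneuploidy=aneuploidy_score(cn, euploid_ploidy),
        heterogeneity=heterogeneity_score(cn) if cn.n_cells >= 2 else 0.0,
        structural=structural_score(cn),
        n_cells=cn.n_cells,
        genome_length_mb=cn.binning.genome_length_mb,
        euploid_ploidy=euploid_ploidy,
        total_transitions=count_transitions(cn),
    )
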