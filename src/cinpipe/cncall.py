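"""Integer copy-number state calling from binned single-cell read counts.

A deliberately transparent caller: per cell, bin counts are normalised to
mean 1, a global scale (the cell's mean copy number) is chosen by grid
search so that scaled values sit closest to integers, states are the
nearest integers, and a short median filter smooths within each chromosome
(never across chromosome boundaries).

Read counts only constrain copy numbers up to a multiplicative constant, so
every integer profile has a family of equally consistent harmonics (the
profile times ``k``, or divided by a common factor of its states — e.g. a
genome-doubled cell looks like a diploid at half the scale). After the grid
search the harmonic whose mean ploidy is closest to ``default_ploidy`` is
kept; an explicit ``assume_ploidy`` override skips the search entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import PipelineError
from .matrices import BinCountMatrix, CopyNumberMatrix

__all__ = ["CallResult", "call_states"]

_SCALE_STEP = 0.05
_TIE_TOL = 1e-9


@dataclass
class CallResult:
    """States for passing cells plus a per-cell quality report.

    ``qc`` has one row per input cell (passing or not): ``cell_id,
    total_reads, passed, scale, residual``. Excluded cells are flagged,
    never silently dropped.
    """

    states: CopyNumberMatrix
    qc: pd.DataFrame


def _fit_scale(normed: np.ndarray, max_state: int, target_ploidy: float) -> tuple[float, float]:
    """Grid-search the mean copy number minimising distance to integers.

    Ties (within 1e-9 of the best residual) break toward the scale whose
    implied mean ploidy is closest to ``target_ploidy``.
    """
    scales = np.arange(1.0, max_state + _SCALE_STEP / 2, _SCALE_STEP)
    scaled = normed[None, :] * scales[:, None]
    nearest = np.round(scaled)
    resid = np.mean((scaled - nearest) ** 2, axis=1)
    # a scale implying states beyond max_state cannot be right
    invalid = nearest.max(axis=1) > max_state
    if not invalid.all():
        resid[invalid] = np.inf
    best = resid.min()
    tied = np.flatnonzero(resid <= best + _TIE_TOL)
    pick = tied[np.argmin(np.abs(scales[tied] - target_ploidy))]
    return float(scales[pick]), float(resid[pick])


def _harmonic_adjust(states: np.ndarray, max_state: int, target_ploidy: float) -> np.ndarray:
    """Pick the harmonic of an integer profile nearest the target ploidy.

    ``states * k`` and ``states / d`` (for common divisors ``d`` of the
    positive states) fit the read counts exactly as well; among them the
    profile whose mean ploidy is closest to ``target_ploidy`` is returned
    (smaller mean on ties, for determinism).
    """
    positive = states[states > 0]
    if positive.size == 0:
        return states
    g = int(np.gcd.reduce(positive))
    candidates = [states // d for d in range(1, g + 1) if g % d == 0]
    base = states // g
    k = 2
    while base.max() * k <= max_state:
        cand = base * k
        if not any(np.array_equal(cand, c) for c in candidates):
            candidates.append(cand)
        k += 1
    return min(candidates, key=lambda c: (abs(float(c.mean()) - target_ploidy),
                                          float(c.mean())))


def call_states(
    counts: BinCountMatrix,
    max_state: int = 10,
    default_ploidy: int = 2,
    smoothing_window: int = 3,
    min_total_reads: int = 0,
    assume_ploidy: float | None = None,
) -> CallResult:
    """Call integer copy-number states per cell from binned read counts.

    Parameters
    ----------
    counts
        Cells-by-bins read counts.
    max_state
        Largest callable state; scaled values are clipped to ``[0, max_state]``.
    default_ploidy
        Mean ploidy preferred when the scale is ambiguous.
    smoothing_window
        Odd median-filter width applied within each chromosome.
    min_total_reads
        Cells with fewer total reads are excluded (and flagged in the QC
        report).
    assume_ploidy
        If given, skip the grid search and scale every cell to this mean
        copy number (resolves e.g. genome-doubled cultures).

    Raises
    ------
    PipelineError
        If every cell fails the read-depth threshold.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd integer")

    totals = counts.counts.sum(axis=1)
    passed = totals >= min_total_reads
    if not passed.any():
        raise PipelineError(
            f"all {counts.n_cells} cells below min_total_reads={min_total_reads}")

    slices = counts.binning.chromosome_slices()
    states_rows, scales, resids = [], [], []
    for i in np.flatnonzero(passed):
        row = counts.counts[i].astype(float)
        mean = row.mean()
        if mean == 0:
            scale, resid = float(default_ploidy), 0.0
            scaled = np.zeros_like(row)
        else:
            normed = row / mean
            if assume_ploidy is not None:
                scale, resid = float(assume_ploidy), float(
                    np.mean((normed * assume_ploidy - np.round(normed * assume_ploidy)) ** 2))
            else:
                scale, resid = _fit_scale(normed, max_state, default_ploidy)
            scaled = normed * scale
        st = np.clip(np.round(scaled), 0, max_state).astype(np.int64)
        if assume_ploidy is None:
            st = _harmonic_adjust(st, max_state, default_ploidy)
        if smoothing_window > 1:
            for sl in slices.values():
                st[sl] = median_filter(st[sl], size=smoothing_window, mode="nearest")
        states_rows.append(st)
        scales.append(scale)
        resids.append(resid)

    qc = pd.DataFrame({
        "cell_id": counts.cell_ids,
        "total_reads": totals,
        "passed": passed,
        "scale": np.where(passed, _expand(scales, passed), np.nan),
        "residual": np.where(passed, _expand(resids, passed), np.nan),
    })
    cn = CopyNumberMatrix(
        binning=counts.binning,
        states=np.vstack(states_rows),
        cell_ids=[counts.cell_ids[i] for i in np.flatnonzero(passed)],
        max_state=max_state,
    )
    return CallResult(states=cn, qc=qc)


def _expand(values: list[float], mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out
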