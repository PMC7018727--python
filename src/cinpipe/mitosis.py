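"""Mitotic timing and cell-fate profiling from time-lapse annotation tables.

Input is a fate table (one row per filmed cell) with a mitotic duration in
minutes (nuclear envelope breakdown to anaphase onset or mitotic exit), a
semicolon-joined set of mitotic-error annotations (anaphase bridges,
lagging chromosomes, multipolar spindles, cohesion fatigue, premature or
unaligned anaphase, cytokinesis failure, chromosome ejection) and a
terminal fate (division, slippage, death in mitosis / interphase, fusion,
or never entering mitosis). The same schema serves 2D and 3D cultures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TimingStats", "FateComposition", "timing_summary",
           "frequency_regression", "fate_summary"]

# the recommended minimum cohort size for timing distributions
DEFAULT_MIN_N = 100


@dataclass(frozen=True)
class TimingStats:
    """Summary of a mitotic-duration distribution (minutes).

    ``skewness`` is the adjusted Fisher–Pearson moment estimator — a
    well-defined sample statistic standing in for regression-based skew
    diagnostics some commercial packages report. ``low_n`` flags cohorts
    smaller than the recommended minimum; ``degenerate`` flags an
    all-equal sample (variance 0, skewness reported as 0).
    """

    n: int
    mean: float
    variance: float
    skewness: float
    median: float
    iqr_low: float
    iqr_high: float
    p10: float
    p90: float
    low_n: bool = False
    degenerate: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def timing_summary(durations, min_n: int = DEFAULT_MIN_N) -> TimingStats:
    """Mean/variance/skewness and percentile summary of mitotic durations."""
    x = np.asarray([d for d in durations if not (isinstance(d, float) and np.isnan(d))],
                   dtype=float)
    if x.size == 0:
        raise ValueError("timing_summary requires at least one duration")
    degenerate = bool(np.all(x == x[0]))
    if degenerate or x.size < 3:
        skew = 0.0
    else:
        skew = float(stats.skew(x, bias=False))
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return TimingStats(
        n=int(x.size),
        mean=float(x.mean()),
        variance=float(x.var(ddof=1)) if x.size > 1 else 0.0,
        skewness=skew,
        median=float(med), iqr_low=float(q1), iqr_high=float(q3),
        p10=float(p10), p90=float(p90),
        low_n=x.size < min_n,
        degenerate=degenerate,
    )


def frequency_regression(durations, bin_width: float = 10.0):
    """OLS of the relative-frequency histogram against bin midpoints.

    Bins of the given width start at 0; only occupied bins enter the
    regression. Returns ``(histogram_frame, slope, intercept, r_squared)``
    where the frame has columns ``midpoint`` and ``rel_freq``.
    """
    x = np.asarray(list(durations), dtype=float)
    x = x[~np.isnan(x)]
    if np.unique(x).size < 2:
        raise ValueError("frequency_regression requires >= 2 distinct values")
    edges = np.arange(0.0, x.max() + bin_width, bin_width)
    if edges[-1] <= x.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(x, bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2
    occupied = counts > 0
    if occupied.sum() < 2:
        raise ValueError("regression undefined: a single occupied bin")
    rel = counts[occupied] / x.size
    fit = stats.linregress(mids[occupied], rel)
    hist = pd.DataFrame({"midpoint": mids[occupied], "rel_freq": rel})
    return hist, float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass(frozen=True)
class FateComposition:
    """Fate and mitotic-error composition of a filmed cohort.

    ``fate_pct`` is over all filmed cells; ``error_pct`` and the pie triple
    (normal / anaphase-bridges-only / all other defects combined) are over
    cells that entered mitosis. ``bridges_only`` counts mitoses whose
    annotation set is exactly {anaphase_bridge}.
    """

    n_cells: int
    n_mitoses: int
    fate_pct: dict[str, float]
    error_pct: dict[str, float]
    abnormal_pct: float
    pie_triple: tuple[float, float, float]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["pie_triple"] = list(self.pie_triple)
        return d


def _annotation_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return frozenset()
    return frozenset(str(value).split(";"))


def fate_summary(table: pd.DataFrame, sample: str | None = None,
                 condition: str | None = None) -> FateComposition:
    """Summarise terminal fates and mitotic-error annotations of a cohort.

    Filters by ``sample`` and/or ``condition`` when given; raises if no
    record matches the filter.
    """
    sub = table
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if len(sub) == 0:
        raise ValueError(
            f"no records match sample={sample!r} condition={condition!r}")

    n_cells = len(sub)
    fates = sub["terminal_fate"]
    fate_pct = {f: 100.0 * int((fates == f).sum()) / n_cells
                for f in sorted(fates.unique())}

    mitotic = sub[fates != "interphase_no_mitosis"]
    n_mit = len(mitotic)
    ann_sets = [_annotation_set(a) for a in mitotic["annotations"]]
    error_pct: dict[str, float] = {}
    if n_mit:
        all_terms = sorted(set().union(*ann_sets)) if ann_sets else []
        for term in all_terms:
            error_pct[term] = 100.0 * sum(term in s for s in ann_sets) / n_mit
    n_abnormal = sum(1 for s in ann_sets if s)
    n_bridges_only = sum(1 for s in ann_sets if s == {"anaphase_bridge"})
    n_other = n_abnormal - n_bridges_only
    n_normal = n_mit - n_abnormal
    if n_mit:
        pie = (100.0 * n_normal / n_mit, 100.0 * n_bridges_only / n_mit,
               100.0 * n_other / n_mit)
        abnormal = 100.0 * n_abnormal / n_mit
    else:
        pie = (0.0, 0.0, 0.0)
        abnormal = 0.0
    return FateComposition(
        n_cells=n_cells, n_mitoses=n_mit,
        fate_pct=fate_pct, error_pct=error_pct,
        abnormal_pct=abnormal, pie_triple=pie,
    )
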