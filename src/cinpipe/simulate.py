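"""Seeded generators for every synthetic input the pipeline consumes.

The generators emulate the statistical structure of the study's four data
streams without any external downloads:

* clonal integer copy-number karyotypes built from an event grammar able to
  express the four recurrent archetypes seen in patient-derived ovarian
  cancer cultures — whole-chromosome aneuploidies, heavily rearranged
  chromosomes, monosomies and tetrasomies — plus per-cell whole-chromosome
  mis-segregation noise and overdispersed (negative-binomial) read-count
  emission;
* mitotic cohorts with categorical fate/error mixtures and right-skewed
  (log-normal) mitotic durations;
* exponential-to-plateau growth curves modulated by a four-parameter
  logistic drug effect with multiplicative measurement noise;
* paired tumour/stroma allele-count tables with binomial sampling around
  germline / somatic / LOH genotype configurations.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genome import GenomeBinning
from .matrices import BinCountMatrix, CopyNumberMatrix

__all__ = [
    "CNEvent", "CloneSpec", "FateModel", "DrugEffect", "GrowthModel",
    "simulate_karyotypes", "simulate_read_counts", "simulate_mitosis_cohort",
    "simulate_growth", "simulate_variant_pairs", "archetype_presets",
    "ERROR_ANNOTATIONS", "TERMINAL_FATES", "FATE_CATEGORIES",
]

EVENT_KINDS = ("whole_gain", "whole_loss", "arm_gain", "arm_loss", "focal_amp", "focal_del")

#: Mitotic-error vocabulary (time-lapse annotation terms).
ERROR_ANNOTATIONS = frozenset({
    "anaphase_bridge", "lagging_chromosome", "multipolar", "cohesion_fatigue",
    "premature_anaphase", "unaligned_anaphase", "cytokinesis_failure",
    "chromosome_ejection",
})

#: Terminal cell fates observed by time-lapse.
TERMINAL_FATES = frozenset({
    "division", "slippage", "death_in_mitosis", "death_in_interphase",
    "interphase_no_mitosis", "fusion",
})

#: Categories a FateModel may assign probability to: "normal", any single
#: mitotic-error annotation (fate: division), or any terminal fate.
FATE_CATEGORIES = frozenset({"normal"}) | ERROR_ANNOTATIONS | TERMINAL_FATES


@dataclass(frozen=True)
class CNEvent:
    """One copy-number event of a clonal karyotype.

    ``kind`` selects the affected region: a whole chromosome, a chromosome
    arm ('p' = proximal half, 'q' = distal half), or an explicit
    ``(start, end)`` span in base pairs (0-based half-open). ``delta`` is the
    signed copy change; gains must be positive, losses negative.
    """

    kind: str
    chromosome: str
    delta: int
    arm: str | None = None
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.kind.endswith(("gain", "amp")) and self.delta <= 0:
            raise ConfigurationError(f"{self.kind} requires positive delta")
        if self.kind.endswith(("loss", "del")) and self.delta >= 0:
            raise ConfigurationError(f"{self.kind} requires negative delta")
        if self.kind.startswith("arm") and self.arm not in ("p", "q"):
            raise ConfigurationError("arm events require arm 'p' or 'q'")
        if self.kind.startswith("focal") and self.span is None:
            raise ConfigurationError("focal events require a (start, end) span")


@dataclass(frozen=True)
class CloneSpec:
    """A clone: its population fraction, base ploidy and copy-number events."""

    label: str
    fraction: float
    base_ploidy: int = 2
    events: tuple[CNEvent, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ConfigurationError(f"clone {self.label!r}: fraction must be in (0, 1]")
        if self.base_ploidy < 1:
            raise ConfigurationError(f"clone {self.label!r}: base_ploidy must be >= 1")
        object.__setattr__(self, "events", tuple(self.events))

    def profile(self, binning: GenomeBinning, max_state: int = 10) -> np.ndarray:
        """Deterministic integer copy-number profile over the binning."""
        states = np.full(binning.n_bins, self.base_ploidy, dtype=np.int64)
        chrom_of = np.array(binning.bin_chromosomes())
        starts = np.array([s for _, s, _ in binning.bins])
        ends = np.array([e for _, _, e in binning.bins])
        for ev in self.events:
            if ev.chromosome not in binning.chromosome_names:
                raise ConfigurationError(
                    f"event references unknown chromosome {ev.chromosome!r}")
            mask = chrom_of == ev.chromosome
            if ev.kind.startswith("arm"):
                mid = binning.chromosome_length(ev.chromosome) // 2
                # a bin belongs to the arm holding its midpoint
                centre = (starts + ends) // 2
                mask &= (centre < mid) if ev.arm == "p" else (centre >= mid)
            elif ev.kind.startswith("focal"):
                lo, hi = ev.span  # type: ignore[misc]
                mask &= (starts < hi) & (ends > lo)
            states[mask] += ev.delta
        if states.min() < 0 or states.max() > max_state:
            raise ConfigurationError(
                f"clone {self.label!r}: events drive states outside [0, {max_state}]")
        return states


def _validate_fractions(clones: list[CloneSpec] | tuple[CloneSpec, ...]) -> np.ndarray:
    if not clones:
        raise ConfigurationError("at least one clone required")
    frac = np.array([c.fraction for c in clones], dtype=float)
    if abs(frac.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"clone fractions sum to {frac.sum()}, not 1")
    return frac / frac.sum()


def simulate_karyotypes(
    binning: GenomeBinning,
    clones: list[CloneSpec] | tuple[CloneSpec, ...],
    n_cells: int,
    missegregation_rate: float = 0.0,
    max_state: int = 10,
    seed: int = 0,
) -> CopyNumberMatrix:
    """Draw single-cell karyotypes from a clonal mixture with mis-segregation.

    Each cell is assigned a clone according to the clone fractions and
    receives the clone's deterministic profile; then each chromosome
    independently gains or loses one whole copy (equal sign probability)
    with probability ``missegregation_rate``. States are clipped to
    ``[0, max_state]``; clipped events are reported as a warning.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if not (0 <= missegregation_rate < 1):
        raise ConfigurationError("missegregation_rate must be in [0, 1)")
    frac = _validate_fractions(clones)
    profiles = np.stack([c.profile(binning, max_state) for c in clones])

    rng = np.random.default_rng(seed)
    assignment = rng.choice(len(clones), size=n_cells, p=frac)
    states = profiles[assignment].copy()

    chrom_of = np.array(binning.bin_chromosomes())
    n_chrom = len(binning.chromosome_names)
    hit = rng.random((n_cells, n_chrom)) < missegregation_rate
    signs = rng.integers(0, 2, size=(n_cells, n_chrom)) * 2 - 1
    delta_per_chrom = np.where(hit, signs, 0)
    for k, name in enumerate(binning.chromosome_names):
        cols = chrom_of == name
        states[:, cols] += delta_per_chrom[:, k][:, None]

    n_clipped = int(np.sum((states < 0) | (states > max_state)))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} bin states fell outside [0, {max_state}] and were clipped",
            stacklevel=2)
    states = np.clip(states, 0, max_state)

    return CopyNumberMatrix(
        binning=binning,
        states=states,
        cell_ids=[f"cell_{i:04d}" for i in range(n_cells)],
        max_state=max_state,
        clone_labels=[clones[a].label for a in assignment],
    )


def simulate_read_counts(
    truth: CopyNumberMatrix,
    reads_per_copy: float = 100.0,
    dispersion: float = 0.0,
    background: float = 1.0,
    seed: int = 0,
    deterministic: bool = False,
) -> BinCountMatrix:
    """Emit binned read counts from a true copy-number matrix.

    Counts are negative-binomial with mean ``state * reads_per_copy``
    (``background`` where the state is 0) and variance
    ``mean * (1 + dispersion * mean)``; ``dispersion=0`` reduces to Poisson.
    With ``deterministic=True`` the counts equal the rounded means exactly.
    """
    if reads_per_copy <= 0:
        raise ConfigurationError("reads_per_copy must be positive")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    if background < 0:
        raise ConfigurationError("background must be >= 0")

    mean = np.where(truth.states > 0, truth.states * reads_per_copy, background)
    if deterministic:
        counts = np.round(mean).astype(np.int64)
    else:
        rng = np.random.default_rng(seed)
        if dispersion == 0:
            counts = rng.poisson(mean)
        else:
            # Gamma-Poisson mixture: var = mean + dispersion * mean^2
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
            counts = rng.poisson(lam)
    return BinCountMatrix(binning=truth.binning, counts=counts, cell_ids=list(truth.cell_ids))


# ---------------------------------------------------------------------------
# mitotic cohorts


@dataclass(frozen=True)
class FateModel:
    """Categorical mixture of mitotic outcomes with log-normal durations.

    ``category_probabilities`` maps fate vocabulary terms ("normal", a
    mitotic-error annotation, or a terminal fate) to probabilities summing
    to 1. ``duration_model`` gives per-category (log-mean, log-sd) of the
    mitotic duration in minutes; categories without an entry use
    ``default_duration``.
    """

    category_probabilities: dict[str, float]
    duration_model: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_duration: tuple[float, float] = (np.log(45.0), 0.35)

    def __post_init__(self) -> None:
        if not self.category_probabilities:
            raise ConfigurationError("category_probabilities must be non-empty")
        for cat in self.category_probabilities:
            if cat not in FATE_CATEGORIES:
                raise ConfigurationError(f"unknown fate category {cat!r}")
        total = sum(self.category_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"category probabilities sum to {total}, not 1")
        for cat, (_, log_sd) in self.duration_model.items():
            if log_sd < 0:
                raise ConfigurationError(f"category {cat!r}: log-sd must be >= 0")


def _category_record(category: str) -> tuple[str, str]:
    """Map a fate category to (annotations, terminal_fate)."""
    if category == "normal":
        return "", "division"
    if category in ERROR_ANNOTATIONS:
        return category, "division"
    return "", category  # a terminal fate


def simulate_mitosis_cohort(
    model: FateModel,
    n_cells: int,
    condition: str = "untreated",
    seed: int = 0,
    sample: str = "sim",
) -> pd.DataFrame:
    """Simulate a time-lapse mitosis annotation table (one row per cell).

    Columns: ``cell_id, sample, condition, duration_min, annotations,
    terminal_fate``; ``annotations`` is a semicolon-joined subset of the
    mitotic-error vocabulary; ``duration_min`` is NaN for cells that never
    enter mitosis.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    cats = sorted(model.category_probabilities)
    probs = np.array([model.category_probabilities[c] for c in cats])
    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(cats), size=n_cells, p=probs / probs.sum())

    rows = []
    for i, ci in enumerate(drawn):
        cat = cats[ci]
        annotations, fate = _category_record(cat)
        if fate == "interphase_no_mitosis":
            duration = np.nan
        else:
            log_mean, log_sd = model.duration_model.get(cat, model.default_duration)
            duration = float(rng.lognormal(mean=log_mean, sigma=log_sd))
        rows.append((f"{sample}_{condition}_{i:04d}", sample, condition,
                     duration, annotations, fate))
    return pd.DataFrame(
        rows, columns=["cell_id", "sample", "condition", "duration_min",
                       "annotations", "terminal_fate"])


# ---------------------------------------------------------------------------
# growth curves


@dataclass(frozen=True)
class DrugEffect:
    """Four-parameter logistic suppression of growth.

    The retained growth fraction at concentration ``c`` (µM) is
    ``f(c) = bottom + (top - bottom) / (1 + (c / ec50_uM) ** hill)``,
    so ``f`` falls from ``top`` (vehicle) to ``bottom`` with midpoint at
    ``ec50_uM``.
    """

    ec50_uM: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0:
            raise ConfigurationError("ec50_uM must be positive")
        if not (0 <= self.bottom <= self.top):
            raise ConfigurationError("require 0 <= bottom <= top")

    def retained_fraction(self, conc_uM: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(conc_uM, dtype=float)
        f = np.where(c > 0,
                     self.bottom + (self.top - self.bottom) / (1.0 + (c / self.ec50_uM) ** self.hill),
                     self.top)
        return f if f.ndim else float(f)


@dataclass(frozen=True)
class GrowthModel:
    """Exponential (optionally logistic-plateau) proliferation model.

    ``initial_count`` objects grow with the given ``doubling_time`` (hours);
    if ``carrying_capacity`` is set the vehicle curve is logistic with that
    plateau. A drug at concentration ``c`` scales the net growth increment
    by ``drug_effect.retained_fraction(c)``, so the drugged curve is
    ``N0 + f(c) * (N_vehicle(t) - N0)``. Measurement noise is multiplicative
    with coefficient of variation ``noise_cv``.
    """

    initial_count: float = 100.0
    doubling_time: float = 24.0
    carrying_capacity: float | None = None
    drug_effect: DrugEffect | None = None
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ConfigurationError("doubling_time must be positive")
        if self.initial_count <= 0:
            raise ConfigurationError("initial_count must be positive")
        if self.carrying_capacity is not None and self.carrying_capacity <= self.initial_count:
            raise ConfigurationError("carrying_capacity must exceed initial_count")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")

    def vehicle_curve(self, t_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        if self.carrying_capacity is None:
            return self.initial_count * 2.0 ** (t / self.doubling_time)
        K, N0 = self.carrying_capacity, self.initial_count
        return K / (1.0 + (K / N0 - 1.0) * 2.0 ** (-t / self.doubling_time))


def simulate_growth(
    model: GrowthModel,
    concentrations: list[float] | tuple[float, ...],
    timepoints: np.ndarray | list[float],
    replicates: int = 1,
    seed: int = 0,
    sample: str = "sim",
    condition: str = "drug",
) -> pd.DataFrame:
    """Simulate a plate of growth-readout time series.

    Returns a long-format table with columns ``sample, condition,
    concentration_uM, replicate, time_h, value`` (concentration 0 = vehicle).
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ConfigurationError("timepoints must be strictly increasing (>= 2 points)")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if any(c < 0 for c in concentrations):
        raise ConfigurationError("concentrations must be non-negative")
    if any(c > 0 for c in concentrations) and model.drug_effect is None:
        raise ConfigurationError("non-vehicle concentrations require a drug_effect")

    rng = np.random.default_rng(seed)
    veh = model.vehicle_curve(t)
    frames = []
    for conc in concentrations:
        f = 1.0 if conc == 0 else model.drug_effect.retained_fraction(conc)  # type: ignore[union-attr]
        clean = model.initial_count + f * (veh - model.initial_count)
        for rep in range(replicates):
            if model.noise_cv > 0:
                sigma = np.sqrt(np.log1p(model.noise_cv ** 2))
                factor = np.exp(rng.normal(0.0, sigma, size=t.size) - sigma ** 2 / 2)
            else:
                factor = 1.0
            frames.append(pd.DataFrame({
                "sample": sample, "condition": condition,
                "concentration_uM": conc, "replicate": rep,
                "time_h": t, "value": clean * factor,
            }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# paired tumour/stroma variants

_BASES = np.array(list("ACGT"))


def simulate_variant_pairs(
    n_per_class: dict[str, int],
    depth: float = 30.0,
    seed: int = 0,
    somatic_af_range: tuple[float, float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Simulate paired tumour/stroma allele-count tables with truth labels.

    Genotype configurations per class: germline loci share an allele
    fraction of 0.5 or 1.0 in both compartments; somatic loci have stromal
    fraction 0 and tumour fraction uniform in ``somatic_af_range``; LOH loci
    have stromal 0.5 and tumour 1.0; reference loci carry the alt allele in
    neither compartment. Depths are Poisson around ``depth`` (minimum 1);
    alt counts binomial around the locus fraction.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    valid = {"germline", "somatic", "loh", "reference"}
    unknown = set(n_per_class) - valid
    if unknown:
        raise ConfigurationError(f"unknown variant classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    for cls in sorted(n_per_class):
        for _ in range(int(n_per_class[cls])):
            pos += 1000
            if cls == "germline":
                af = float(rng.choice([0.5, 1.0]))
                t_af, s_af = af, af
            elif cls == "somatic":
                t_af = float(rng.uniform(*somatic_af_range))
                s_af = 0.0
            elif cls == "loh":
                t_af, s_af = 1.0, 0.5
            else:
                t_af, s_af = 0.0, 0.0
            t_depth = max(1, int(rng.poisson(depth)))
            s_depth = max(1, int(rng.poisson(depth)))
            t_alt = int(rng.binomial(t_depth, t_af))
            s_alt = int(rng.binomial(s_depth, s_af))
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(("chr1", pos, _BASES[ref], _BASES[alt],
                         t_depth - t_alt, t_alt, s_depth - s_alt, s_alt, cls))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt",
                       "t_ref", "t_alt", "s_ref", "s_alt", "truth_class"])


# ---------------------------------------------------------------------------
# archetype presets


def archetype_presets() -> dict[str, dict]:
    """Clonal presets reproducing the four recurrent karyotype archetypes.

    Keys: ``whole_chromosome`` (clonally pure whole-chromosome
    aneuploidies), ``rearranged`` (many within-chromosome transitions),
    ``monosomy`` (whole-chromosome losses to single copy) and ``tetrasomy``
    (whole-chromosome gains to four copies). Each value carries the clone
    list and a suggested mis-segregation rate; the whole-chromosome preset
    is clonally pure (rate 0).
    """
    return {
        "whole_chromosome": {
            "clones": (CloneSpec("WC", 1.0, 2, (
                CNEvent("whole_gain", "chr2", +1),
                CNEvent("whole_loss", "chr4", -1),
            )),),
            "missegregation_rate": 0.0,
        },
        "rearranged": {
            "clones": (CloneSpec("RE", 1.0, 2, (
                CNEvent("arm_gain", "chr1", +1, arm="p"),
                CNEvent("focal_amp", "chr1", +1, span=(90_000_000, 110_000_000)),
                CNEvent("focal_amp", "chr2", +2, span=(20_000_000, 40_000_000)),
                CNEvent("focal_del", "chr3", -1, span=(10_000_000, 30_000_000)),
                CNEvent("focal_del", "chr3", -1, span=(60_000_000, 75_000_000)),
                CNEvent("arm_loss", "chr5", -1, arm="q"),
            )),),
            "missegregation_rate": 0.02,
        },
        "monosomy": {
            "clones": (CloneSpec("MO", 1.0, 2, (
                CNEvent("whole_loss", "chr3", -1),
                CNEvent("whole_loss", "chr5", -1),
            )),),
            "missegregation_rate": 0.02,
        },
        "tetrasomy": {
            "clones": (CloneSpec("TE", 1.0, 2, (
                CNEvent("whole_gain", "chr1", +2),
            )),),
            "missegregation_rate": 0.02,
        },
    }
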