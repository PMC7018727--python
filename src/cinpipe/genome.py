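"""Genome binning for single-cell copy-number analysis.

Copy-number states are called and scored on fixed-width genomic bins
(1 Mb by default, matching shallow scWGS practice). A :class:`GenomeBinning`
tiles each chromosome contiguously with half-open 0-based bins; the final
bin of a chromosome may be short. The total genome length in Mb (``L``)
is the denominator of the structural score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = ["GenomeBinning", "toy_genome", "hg38_like_genome"]


@dataclass(frozen=True)
class GenomeBinning:
    """Contiguous fixed-width binning of a genome.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in base pairs (default 1 Mb).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = 1_000_000
    bins: tuple[tuple[str, int, int], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        bins: list[tuple[str, int, int]] = []
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            start = 0
            while start < length:
                end = min(start + self.bin_size, length)
                bins.append((name, start, end))
                start = end
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        object.__setattr__(self, "bins", tuple(bins))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def genome_length_mb(self) -> float:
        """Total genome length in megabases (the ``L`` of the structural score)."""
        return sum(l for _, l in self.chromosomes) / 1e6

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def chromosome_length(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(f"unknown chromosome {name!r}")

    def bin_chromosomes(self) -> list[str]:
        """Chromosome name of each bin, in bin order."""
        return [c for c, _, _ in self.bins]

    def chromosome_slices(self) -> dict[str, slice]:
        """Map chromosome name -> slice of its bins in the global bin order."""
        out: dict[str, slice] = {}
        start = 0
        for name, _ in self.chromosomes:
            n = sum(1 for c, _, _ in self.bins if c == name)
            out[name] = slice(start, start + n)
            start += n
        return out

    def bin_labels(self) -> list[str]:
        """``chrom:start-end`` identifiers, used as matrix column headers."""
        return [f"{c}:{s}-{e}" for c, s, e in self.bins]


def toy_genome(bin_size: int = 1_000_000) -> GenomeBinning:
    """Reduced 5-chromosome genome (500 Mb total) for fast simulation and tests."""
    chroms = (("chr1", 120_000_000), ("chr2", 110_000_000), ("chr3", 100_000_000),
              ("chr4", 90_000_000), ("chr5", 80_000_000))
    return GenomeBinning(chromosomes=chroms, bin_size=bin_size)


#: GRCh38 assembly chromosome lengths (autosomes + X), rounded to the kb.
_HG38_LENGTHS = {
    "chr1": 248_956_000, "chr2": 242_194_000, "chr3": 198_296_000,
    "chr4": 190_215_000, "chr5": 181_538_000, "chr6": 170_806_000,
    "chr7": 159_346_000, "chr8": 145_139_000, "chr9": 138_395_000,
    "chr10": 133_797_000, "chr11": 135_087_000, "chr12": 133_275_000,
    "chr13": 114_364_000, "chr14": 107_044_000, "chr15": 101_991_000,
    "chr16": 90_338_000, "chr17": 83_257_000, "chr18": 80_373_000,
    "chr19": 58_618_000, "chr20": 64_444_000, "chr21": 46_710_000,
    "chr22": 50_818_000, "chrX": 156_041_000,
}


def hg38_like_genome(bin_size: int = 1_000_000) -> GenomeBinning:
    """Human-scale binning with GRCh38-like chromosome lengths."""
    return GenomeBinning(chromosomes=tuple(_HG38_LENGTHS.items()), bin_size=bin_size)
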