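"""Paired tumour/stroma variant classification.

With the patient's cultured stromal cells as the germline baseline, each
exome locus with tumour and stromal ref/alt read counts is classified:

* **germline** — the variant is present with matching genotype class in
  both compartments;
* **somatic** — the stroma matches the reference, the tumour carries the
  variant, and the allele-frequency difference is significant (one-sided
  Fisher exact test on the 2x2 allele-count table);
* **loh** — loss of heterozygosity: the stroma is heterozygous but the
  tumour is homozygous for the variant allele;
* **reference** — the variant allele is absent from both compartments;
* **ambiguous** — insufficient depth or a discordant configuration none of
  the rules covers.

The decision order is reference, LOH, somatic, germline, ambiguous; the
Fisher p-value is reported for every classifiable locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import fisher_exact

__all__ = ["ClassThresholds", "classify_variant", "classify_table", "CLASSES"]

CLASSES = ("germline", "somatic", "loh", "reference", "ambiguous")


@dataclass(frozen=True)
class ClassThresholds:
    """Numeric thresholds of the classification rules.

    ``presence_af``/``min_alt_reads`` define when a variant counts as
    present in a compartment; ``het_band`` is the heterozygous
    allele-fraction band; ``hom_af`` the homozygous cut-off; ``alpha`` the
    significance level of the somatic allele-frequency test.
    """

    min_depth: int = 20
    presence_af: float = 0.10
    min_alt_reads: int = 4
    het_band: tuple[float, float] = (0.25, 0.75)
    hom_af: float = 0.90
    alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not (0 < self.presence_af < lo < hi < self.hom_af <= 1):
            raise ValueError("require 0 < presence_af < het low < het high < hom_af <= 1")

    def present(self, alt: int, depth: int) -> bool:
        return depth > 0 and alt >= self.min_alt_reads and alt / depth >= self.presence_af

    def genotype(self, alt: int, depth: int) -> str:
        """'ref', 'het', 'hom' or 'other' for one compartment."""
        if depth == 0:
            return "other"
        af = alt / depth
        if not self.present(alt, depth):
            return "ref"
        if self.het_band[0] <= af <= self.het_band[1]:
            return "het"
        if af >= self.hom_af:
            return "hom"
        return "other"


def classify_variant(t_ref: int, t_alt: int, s_ref: int, s_alt: int,
                     th: ClassThresholds | None = None) -> tuple[str, float]:
    """Classify one locus; returns ``(class, fisher_p)``.

    The Fisher test is one-sided for a greater tumour alt fraction, on the
    table ``[[t_alt, t_ref], [s_alt, s_ref]]``.
    """
    th = th or ClassThresholds()
    if min(t_ref, t_alt, s_ref, s_alt) < 0:
        raise ValueError("negative read counts")
    t_depth, s_depth = t_ref + t_alt, s_ref + s_alt
    _, p = fisher_exact([[t_alt, t_ref], [s_alt, s_ref]], alternative="greater")
    p = float(p)

    if t_depth < th.min_depth or s_depth < th.min_depth:
        return "ambiguous", p

    t_geno = th.genotype(t_alt, t_depth)
    s_geno = th.genotype(s_alt, s_depth)

    if t_geno == "ref" and s_geno == "ref":
        return "reference", p
    if s_geno == "het" and t_geno == "hom":
        return "loh", p
    if s_geno == "ref" and th.present(t_alt, t_depth) and p < th.alpha:
        return "somatic", p
    if t_geno != "ref" and s_geno != "ref" and t_geno == s_geno and t_geno != "other":
        return "germline", p
    return "ambiguous", p


def classify_table(table: pd.DataFrame,
                   th: ClassThresholds | None = None) -> pd.DataFrame:
    """Classify every row of a paired allele-count table.

    Expects columns ``t_ref, t_alt, s_ref, s_alt``; returns a copy with
    ``class`` and ``p_value`` columns appended. Rows with malformed counts
    get class ``error`` and classification continues.
    """
    th = th or ClassThresholds()
    classes, pvals = [], []
    for row in table.itertuples(index=False):
        try:
            cls, p = classify_variant(int(row.t_ref), int(row.t_alt),
                                      int(row.s_ref), int(row.s_alt), th)
        except (ValueError, TypeError):
            cls, p = "error", float("nan")
        classes.append(cls)
        pvals.append(p)
    out = table.copy()
    out["class"] = classes
    out["p_value"] = pvals
    return out
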