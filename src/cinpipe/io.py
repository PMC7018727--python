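"""Readers and writers for the pipeline's on-disk formats.

Conventions: bin definitions are BED (0-based half-open); cell-by-bin
matrices are TSV with a ``cell_id`` column and ``chrom:start-end`` column
headers; fate tables and growth curves are long-format CSV; paired variant
tables are TSV with 1-based positions (VCF convention). Every writer's
output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeBinning
from .matrices import BinCountMatrix, CopyNumberMatrix

__all__ = [
    "write_bins_bed", "read_bins_bed",
    "write_matrix_tsv", "read_counts_tsv", "read_states_tsv",
    "write_fate_csv", "read_fate_csv",
    "write_growth_csv", "read_growth_csv",
    "write_variants_tsv", "read_variants_tsv", "read_vcf_pairs",
    "write_json",
]

FATE_COLUMNS = ["cell_id", "sample", "condition", "duration_min",
                "annotations", "terminal_fate"]
GROWTH_COLUMNS = ["sample", "condition", "concentration_uM", "replicate",
                  "time_h", "value"]
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "t_ref", "t_alt", "s_ref", "s_alt"]


# --- bins -------------------------------------------------------------------

def write_bins_bed(binning: GenomeBinning, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in binning.bins:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bins_bed(path: str | Path) -> GenomeBinning:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end"], comment="#")
    chroms: list[tuple[str, int]] = []
    for chrom in df["chrom"].drop_duplicates():
        sub = df[df["chrom"] == chrom]
        chroms.append((str(chrom), int(sub["end"].max())))
    bin_size = int((df["end"] - df["start"]).max())
    binning = GenomeBinning(chromosomes=tuple(chroms), bin_size=bin_size)
    got = [(str(c), int(s), int(e)) for c, s, e in
           df[["chrom", "start", "end"]].itertuples(index=False)]
    if got != list(binning.bins):
        raise ValueError("BED bins do not tile the genome contiguously at a "
                         "fixed bin size; cannot reconstruct the binning")
    return binning


# --- cell-by-bin matrices ---------------------------------------------------

def write_matrix_tsv(matrix: BinCountMatrix | CopyNumberMatrix, path: str | Path) -> None:
    values = matrix.counts if isinstance(matrix, BinCountMatrix) else matrix.states
    df = pd.DataFrame(values, columns=matrix.binning.bin_labels())
    df.insert(0, "cell_id", matrix.cell_ids)
    df.to_csv(path, sep="\t", index=False)


def _read_matrix(path: str | Path, binning: GenomeBinning | None):
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "cell_id":
        raise ValueError("matrix TSV must start with a cell_id column")
    cell_ids = df["cell_id"].astype(str).tolist()
    values = df.drop(columns="cell_id").to_numpy(dtype=np.int64)
    labels = list(df.columns[1:])
    if binning is None:
        binning = _binning_from_labels(labels)
    elif labels != binning.bin_labels():
        raise ValueError("matrix columns do not match the provided binning")
    return binning, values, cell_ids


def _binning_from_labels(labels: list[str]) -> GenomeBinning:
    chroms: dict[str, int] = {}
    sizes = []
    for lab in labels:
        chrom, span = lab.rsplit(":", 1)
        start, end = (int(x) for x in span.split("-"))
        chroms[chrom] = max(chroms.get(chrom, 0), end)
        sizes.append(end - start)
    return GenomeBinning(chromosomes=tuple(chroms.items()), bin_size=max(sizes))


def read_counts_tsv(path: str | Path, binning: GenomeBinning | None = None) -> BinCountMatrix:
    binning, values, cell_ids = _read_matrix(path, binning)
    return BinCountMatrix(binning=binning, counts=values, cell_ids=cell_ids)


def read_states_tsv(path: str | Path, binning: GenomeBinning | None = None,
                    max_state: int = 10) -> CopyNumberMatrix:
    binning, values, cell_ids = _read_matrix(path, binning)
    return CopyNumberMatrix(binning=binning, states=values, cell_ids=cell_ids,
                            max_state=max(max_state, int(values.max(initial=0))))


# --- fate tables ------------------------------------------------------------

def write_fate_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[FATE_COLUMNS].to_csv(path, index=False)


def read_fate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"annotations": str}, keep_default_na=True)
    missing = [c for c in FATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fate CSV missing columns: {missing}")
    df["annotations"] = df["annotations"].fillna("")
    return df[FATE_COLUMNS]


# --- growth curves ----------------------------------------------------------

def write_growth_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[GROWTH_COLUMNS].to_csv(path, index=False)


def read_growth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth CSV missing columns: {missing}")
    return df[GROWTH_COLUMNS]


# --- variant tables ---------------------------------------------------------

def write_variants_tsv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in table.columns
            if c in VARIANT_COLUMNS + ["truth_class", "class", "p_value"]]
    table[cols].to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV missing columns: {missing}")
    return df


def read_vcf_pairs(path: str | Path, tumour_sample: str,
                   stroma_sample: str) -> pd.DataFrame:
    """Read paired allelic depths from a VCF with per-sample AD fields.

    Multi-allelic sites are split into one observation per alt allele.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        ti, si = samples.index(tumour_sample), samples.index(stroma_sample)
    except ValueError as exc:
        raise ValueError(f"sample not in VCF: {exc}") from exc
    rows = []
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            continue
        for k, alt in enumerate(rec.ALT):
            rows.append((rec.CHROM, rec.POS, rec.REF, alt,
                         int(ad[ti][0]), int(ad[ti][k + 1]),
                         int(ad[si][0]), int(ad[si][k + 1])))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


# --- json -------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
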