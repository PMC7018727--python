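#!/usr/bin/env python
"""Paired tumour/stroma variant classification and its confusion matrix.

Reads the truth-labelled variant table from 01_simulate_inputs.py, runs
the germline / somatic / LOH classifier at default thresholds and writes
results/variant_calls.tsv plus a per-class recall summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from cinpipe import io
from cinpipe.variants import classify_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/inputs"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pairs = pd.read_csv(args.inputs / "variant_pairs.tsv", sep="\t")
    calls = classify_table(pairs)
    io.write_variants_tsv(calls, args.out / "variant_calls.tsv")

    confusion = pd.crosstab(calls["truth_class"], calls["class"])
    print(confusion, "\n")
    for cls in confusion.index:
        sub = calls[calls["truth_class"] == cls]
        recall = (sub["class"] == cls).mean()
        print(f"{cls:10s} recall {100 * recall:.1f}%")
    confusion.to_csv(args.out / "variant_confusion.tsv", sep="\t")
    print(f"\nwrote {args.out / 'variant_calls.tsv'}")


if __name__ == "__main__":
    main()
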