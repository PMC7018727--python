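#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/: the toy-genome bin BED, ground-truth and
read-count matrices for the four karyotype archetypes, time-lapse fate
tables for an untreated and two paclitaxel conditions, cisplatin growth
curves, and a paired tumour/stroma variant table with truth labels.
"""

import argparse
from pathlib import Path

import numpy as np

from cinpipe import io
from cinpipe.genome import toy_genome
from cinpipe.simulate import (DrugEffect, FateModel, GrowthModel,
                              archetype_presets, simulate_growth,
                              simulate_karyotypes, simulate_mitosis_cohort,
                              simulate_read_counts, simulate_variant_pairs)

# fate mixtures emulating an untreated culture with frequent segregation
# errors and the paclitaxel dose escalation seen in drug-response filming
FATE_MODELS = {
    "untreated": FateModel(
        {"normal": 0.48, "anaphase_bridge": 0.20, "lagging_chromosome": 0.15,
         "premature_anaphase": 0.12, "multipolar": 0.05},
        duration_model={"normal": (np.log(40), 0.3),
                        "anaphase_bridge": (np.log(70), 0.4),
                        "lagging_chromosome": (np.log(65), 0.4),
                        "premature_anaphase": (np.log(30), 0.3),
                        "multipolar": (np.log(90), 0.5)}),
    "paclitaxel_10nM": FateModel(
        {"normal": 0.25, "anaphase_bridge": 0.20, "multipolar": 0.25,
         "slippage": 0.20, "death_in_mitosis": 0.10},
        duration_model={"slippage": (np.log(400), 0.5),
                        "death_in_mitosis": (np.log(500), 0.5)}),
    "paclitaxel_100nM": FateModel(
        {"normal": 0.14, "slippage": 0.32, "death_in_mitosis": 0.22,
         "multipolar": 0.20, "interphase_no_mitosis": 0.12},
        duration_model={"slippage": (np.log(600), 0.5),
                        "death_in_mitosis": (np.log(700), 0.5)}),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/inputs"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    binning = toy_genome()
    io.write_bins_bed(binning, out / "bins.bed")
    for k, (name, spec) in enumerate(sorted(archetype_presets().items())):
        truth = simulate_karyotypes(binning, spec["clones"], n_cells=50,
                                    missegregation_rate=spec["missegregation_rate"],
                                    seed=args.seed + 17 * k)
        counts = simulate_read_counts(truth, reads_per_copy=100,
                                      seed=args.seed + 17 * k + 1)
        io.write_matrix_tsv(truth, out / f"{name}.truth.tsv")
        io.write_matrix_tsv(counts, out / f"{name}.counts.tsv")
        print(f"karyotypes: {name:18s} 50 cells, {binning.n_bins} bins")

    import pandas as pd
    tables = [simulate_mitosis_cohort(m, 200, condition=cond, sample="OCMsim",
                                      seed=args.seed + 100 + i)
              for i, (cond, m) in enumerate(sorted(FATE_MODELS.items()))]
    fates = pd.concat(tables, ignore_index=True)
    io.write_fate_csv(fates, out / "fates.csv")
    print(f"mitosis: {len(fates)} filmed cells across {len(FATE_MODELS)} conditions")

    concs = 0.6 * 10.0 ** (0.5 * (np.arange(9) - 4))
    model = GrowthModel(initial_count=100, doubling_time=24,
                        drug_effect=DrugEffect(ec50_uM=0.6), noise_cv=0.05)
    growth = simulate_growth(model, [0.0, *concs], np.arange(0, 73, 4.0),
                             replicates=3, seed=args.seed + 200,
                             sample="OCMsim", condition="cisplatin")
    io.write_growth_csv(growth, out / "growth.csv")
    print(f"growth: {growth[['concentration_uM','replicate']].drop_duplicates().shape[0]} wells")

    pairs = simulate_variant_pairs({"germline": 120, "somatic": 60, "loh": 40,
                                    "reference": 80}, depth=60,
                                   seed=args.seed + 300)
    io.write_variants_tsv(pairs, out / "variant_pairs.tsv")
    print(f"variants: {len(pairs)} paired loci written")


if __name__ == "__main__":
    main()
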