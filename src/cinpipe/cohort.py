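"""Cohort bookkeeping: culture establishment rates.

A cohort manifest has one row per collected sample with the patient it
came from, whether a culture was attempted from it, whether the culture
was established, the sample type (ascites or solid) and the chemotherapy
state at collection. Two rates are reported: the per-sample rate
(established / attempted samples) and the per-patient rate (patients with
at least one established culture / patients with at least one attempted
sample).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

__all__ = ["EstablishmentRates", "establishment_rates",
           "validate_manifest", "ovarian_cohort_manifest"]

MANIFEST_COLUMNS = ["sample_id", "patient_id", "attempted", "established",
                    "sample_type", "chemo_state"]


@dataclass(frozen=True)
class EstablishmentRates:
    sample_rate_pct: float
    patient_rate_pct: float
    n_samples_attempted: int
    n_samples_established: int
    n_patients_attempted: int
    n_patients_established: int

    def as_dict(self) -> dict:
        return asdict(self)


def validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS[:4] if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if (manifest["patient_id"].astype(str).str.len() == 0).any():
        raise ValueError("empty patient ids in manifest")
    bad = manifest["established"].astype(bool) & ~manifest["attempted"].astype(bool)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows established without being attempted")


def establishment_rates(manifest: pd.DataFrame) -> EstablishmentRates:
    """Per-sample and per-patient culture establishment rates (percent).

    Rates are rounded to one decimal place; the raw counts are returned
    alongside.
    """
    validate_manifest(manifest)
    attempted = manifest[manifest["attempted"].astype(bool)]
    if len(attempted) == 0:
        raise ValueError("no attempted samples in manifest")
    established = attempted[attempted["established"].astype(bool)]
    pat_attempted = attempted["patient_id"].nunique()
    pat_established = established["patient_id"].nunique()
    return EstablishmentRates(
        sample_rate_pct=round(100.0 * len(established) / len(attempted), 1),
        patient_rate_pct=round(100.0 * pat_established / pat_attempted, 1),
        n_samples_attempted=len(attempted),
        n_samples_established=len(established),
        n_patients_attempted=int(pat_attempted),
        n_patients_established=int(pat_established),
    )


def ovarian_cohort_manifest() -> pd.DataFrame:
    """Manifest encoding the ovarian-cancer programme's cohort bookkeeping.

    312 collected samples from 135 patients; cultures attempted from 290
    samples; 76 cultures established, spread over 44 patients. Every
    patient has at least one attempted sample, so the per-patient
    denominator is the full set of 135 patients. Sample identities are
    synthetic placeholders; only the counts carry meaning.
    """
    n_patients, n_samples = 135, 312
    n_unattempted, n_established, n_est_patients = 312 - 290, 76, 44

    # two samples per patient, the remainder as third samples
    patient_of: list[int] = []
    for p in range(n_patients):
        patient_of += [p, p]
    for p in range(n_samples - 2 * n_patients):
        patient_of.append(p)

    rows = []
    # unattempted: third samples of the last patients that have one
    unattempted_idx = set(range(n_samples - n_unattempted, n_samples))
    # established: 76 = 2*32 + 12 over patients 0..43
    established_quota = {p: (2 if p < n_est_patients - (2 * n_est_patients - n_established)
                             else 1) for p in range(n_est_patients)}
    given: dict[int, int] = {}
    for i, p in enumerate(patient_of):
        attempted = i not in unattempted_idx
        established = False
        if attempted and p in established_quota and given.get(p, 0) < established_quota[p]:
            established = True
            given[p] = given.get(p, 0) + 1
        rows.append((f"S{i + 1:03d}", f"P{p + 1:03d}", attempted, established,
                     "ascites" if i % 2 == 0 else "solid",
                     "naive" if p % 2 == 0 else "relapsed"))
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
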