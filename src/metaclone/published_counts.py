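"""Worked-example fixture: headline counts from a 15-patient paired
colorectal primary / liver-metastasis WES cohort.

These are transcribed cohort-level counts (numerators and denominators), not
patient-level data; the builders below expand them into minimal tables so
the cohort summary operations can recompute each reported percentage:

* WNT/beta-catenin pathway genes (APC, AXIN1, AMER1, TCF7L2, KMT2D) mutated
  in 12 of 15 patients (80%).
* HGF/MET pathway genes (KRAS, COL5A1, HGF) mutated in 9 of 15 patients (60%).
* SYNE1 mutated in 11 of 30 tumor samples (37%).
* HLA-LOH positive in 4 of 15 patients overall (26%), 2 of 15 in primaries
  (13%), 4 of 15 in metastases (26%).

The tables are synthetic expansions of published counts: which patients carry
which hit is arbitrary, only the counts are meaningful.
"""

from __future__ import annotations

import pandas as pd

WNT_PATHWAY = ["APC", "AXIN1", "AMER1", "TCF7L2", "KMT2D"]
HGF_MET_PATHWAY = ["KRAS", "COL5A1", "HGF"]

N_PATIENTS = 15
WNT_PATIENTS = 12
HGF_PATIENTS = 9
SYNE1_SAMPLES = 11
LOH_PATIENTS_ANY = 4
LOH_PATIENTS_PRIMARY = 2
LOH_PATIENTS_METASTASIS = 4


def patients() -> list[str]:
    return [f"P{i}" for i in range(1, N_PATIENTS + 1)]


def cohort_mutation_table() -> pd.DataFrame:
    """Minimal mutation table (patient, sample, gene) matching the cohort counts."""
    rows = []
    samples: list[tuple[str, str]] = []
    for p in patients():
        samples.append((p, f"{p}_P"))
        samples.append((p, f"{p}_M"))
    # every sample gets a filler gene so sample/patient universes are complete
    for p, s in samples:
        rows.append({"patient": p, "sample": s, "gene": "TTN"})
    for p in patients()[:WNT_PATIENTS]:
        rows.append({"patient": p, "sample": f"{p}_P", "gene": "APC"})
    for p in patients()[:HGF_PATIENTS]:
        rows.append({"patient": p, "sample": f"{p}_P", "gene": "KRAS"})
    for _, s in samples[:SYNE1_SAMPLES]:
        rows.append({"patient": s.split("_")[0], "sample": s, "gene": "SYNE1"})
    return pd.DataFrame(rows, columns=["patient", "sample", "gene"])


def cohort_loh_table() -> pd.DataFrame:
    """Per-patient/lesion HLA-LOH flags matching the cohort incidences.

    LOH-positive primaries are a subset of LOH-positive metastases, consistent
    with the overall incidence equalling the metastasis incidence.
    """
    rows = []
    for i, p in enumerate(patients(), start=1):
        rows.append({"patient": p, "lesion": "primary", "is_loh": i <= LOH_PATIENTS_PRIMARY})
        rows.append(
            {"patient": p, "lesion": "metastasis", "is_loh": i <= LOH_PATIENTS_METASTASIS}
        )
    return pd.DataFrame(rows, columns=["patient", "lesion", "is_loh"])
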