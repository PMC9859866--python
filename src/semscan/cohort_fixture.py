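"""Packaged clinical twin cohort (congenital hypothyroidism) with summary ops.

The fixture transcribes the published clinical tables of a CH twin cohort:
23 twin pairs (10 MZ, 13 DZ), 46 subjects, with neonatal-screening and
diagnostic TSH/FT4, thyroid ultrasound morphology, final diagnosis at
re-evaluation (P permanent / T transient / E euthyroid), candidate-gene
variant annotations and the per-subject hypo-methylated SEM count.

Case status is the affected-row status of the source tables, not the final
diagnosis: one discordant MZ co-twin (pair 9, twin B) was euthyroid on
neonatal screening and throughout the study window but later re-classified
P — it is a control here, which is what reproduces the published group
sizes (27 cases / 19 controls) and the morphology counts.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from semscan.io_model import SampleSheet, ValidationError
from semscan.burden_analysis import GroupSummary, summarize_burden

FIXTURE_SHA256 = "e0867c14b8ab19952581bc550171acc1602cf644d6f70eeb905c40fb23c7e93f"

MORPHOLOGIES = {"GIS", "athyreosis", "hemiagenesis", "ectopy", "hypoplasia"}
DYSGENESIS = MORPHOLOGIES - {"GIS"}
FINAL_DIAGNOSES = {"P", "T", "E"}


class PackagingError(ValidationError):
    """The packaged fixture does not match its recorded checksum or invariants."""


def load_clinical_fixture() -> pd.DataFrame:
    """Load and validate the 46-subject clinical table."""
    ref = resources.files("semscan.data").joinpath("clinical_fixture.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != FIXTURE_SHA256:
        raise PackagingError(f"clinical fixture checksum mismatch: {digest}")
    df = pd.read_csv(
        ref.open("r"),
        dtype={"pair": int, "twin": str, "is_case": int, "hypo_sems": int},
    )
    if len(df) != 46 or df["pair"].nunique() != 23:
        raise PackagingError("fixture must contain 46 records over 23 pairs")
    if not set(df["morphology"]) <= MORPHOLOGIES:
        raise PackagingError(f"unknown morphology: {set(df['morphology']) - MORPHOLOGIES}")
    if not set(df["final_diagnosis"]) <= FINAL_DIAGNOSES:
        raise PackagingError("unknown final diagnosis label")
    if (df["hypo_sems"] <= 0).any():
        raise PackagingError("hypo-SEM counts must be positive")
    df["sample_id"] = df["pair"].astype(str) + df["twin"]
    return df


def fixture_sample_sheet(records: pd.DataFrame) -> SampleSheet:
    """Cohort-metadata view of the fixture (family = twin pair)."""
    t = pd.DataFrame(
        {
            "sample_id": records["sample_id"],
            "family_id": "F" + records["pair"].astype(str),
            "pair_id": "P" + records["pair"].astype(str),
            "zygosity": records["zygosity"],
            "group": np.where(records["is_case"] == 1, "case", "control"),
            "sex": records["sex"],
            "batch": "array1",
        }
    )
    return SampleSheet(t)


def cohort_counts(records: pd.DataFrame) -> dict[str, int]:
    """Clinical summary counts of the cohort."""
    cases = records[records["is_case"] == 1]
    pair_cases = records.groupby("pair")["is_case"].sum()
    zyg_of_pair = records.groupby("pair")["zygosity"].first()
    gis_cases = cases[cases["morphology"] == "GIS"]
    morphology_counts = cases["morphology"].value_counts().to_dict()
    return {
        "n_records": len(records),
        "n_cases": int(len(cases)),
        "n_controls": int(len(records) - len(cases)),
        "n_pairs": int(records["pair"].nunique()),
        "n_mz_pairs": int((zyg_of_pair == "MZ").sum()),
        "n_dz_pairs": int((zyg_of_pair == "DZ").sum()),
        "n_concordant_pairs": int((pair_cases == 2).sum()),
        "n_discordant_pairs": int((pair_cases == 1).sum()),
        "mz_cases": int(cases["zygosity"].eq("MZ").sum()),
        "dz_cases": int(cases["zygosity"].eq("DZ").sum()),
        "dysgenesis_cases": int(cases["morphology"].isin(DYSGENESIS).sum()),
        "athyreosis_cases": morphology_counts.get("athyreosis", 0),
        "hemiagenesis_cases": morphology_counts.get("hemiagenesis", 0),
        "ectopy_cases": morphology_counts.get("ectopy", 0),
        "hypoplasia_cases": morphology_counts.get("hypoplasia", 0),
        "gis_cases": int(len(gis_cases)),
        "permanent_cases": int(cases["final_diagnosis"].eq("P").sum()),
        "transient_cases": int(cases["final_diagnosis"].eq("T").sum()),
        "gis_permanent_cases": int(gis_cases["final_diagnosis"].eq("P").sum()),
        # Any annotated variant, whatever its classification (PA/B/V), counts.
        "variant_carrier_cases": int((cases["mutations"] != "WT").sum()),
    }


def fixture_burden(records: pd.DataFrame) -> pd.DataFrame:
    """Hypo-SEM counts of the fixture as a burden table.

    Hyper-methylated counts are not part of the published tables and are
    absent (zero with undefined log).
    """
    return pd.DataFrame(
        {
            "sample_id": records["sample_id"],
            "n_hypo": records["hypo_sems"].astype(np.int64),
            "n_hyper": 0,
            "ln_hypo": np.log(records["hypo_sems"].astype(float)),
            "ln_hyper": np.nan,
        }
    )


def table_burden_stats(records: pd.DataFrame) -> list[GroupSummary]:
    """ln hypo-SEM quantiles per group from the fixture counts."""
    return summarize_burden(fixture_burden(records), fixture_sample_sheet(records), "hypo")
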