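"""Readers, writers and validated containers for methylation-array tables.

Conventions
-----------
* Beta matrices are stored probes x samples (array-export orientation);
  values are methylation fractions in [0, 1], empty cells are missing.
* Manifest positions are 1-based inclusive basepair coordinates; every
  exported interval (BED) is 0-based half-open.
* All on-disk tables are plain text: TSV for matrices/manifests/results,
  CSV for sample sheets, BED for regions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SemscanError(Exception):
    """Base class for semscan errors."""


class FormatError(SemscanError):
    """A file does not conform to the expected layout."""


class ValidationError(SemscanError):
    """Parsed content violates a domain invariant."""


VALID_GROUPS = {"case", "control", "reference"}
VALID_ZYGOSITY = {"MZ", "DZ"}
VALID_SEX = {"M", "F"}
SAMPLE_SHEET_COLUMNS = ["sample_id", "family_id", "pair_id", "zygosity", "group", "sex", "batch"]
SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Probes x samples methylation beta fractions with missing values as NaN."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)])


def read_beta_matrix(path) -> BetaMatrix:
    """Read a TSV beta matrix: header row of sample ids, first column probe ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[""])
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", float_format="%.6f", index_label="probe_id", na_rep="")


# ---------------------------------------------------------------------------
# SampleSheet


@dataclass
class SampleSheet:
    """Cohort metadata: one row per sample, with family / twin-pair structure."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def validate(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample sheet missing required columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        bad_group = set(t["group"]) - VALID_GROUPS
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        bad_zyg = set(t["zygosity"]) - VALID_ZYGOSITY
        if bad_zyg:
            raise ValidationError(f"unknown zygosity labels: {sorted(bad_zyg)}")
        bad_sex = set(t["sex"]) - VALID_SEX
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        sizes = t.groupby("pair_id").size()
        too_big = sizes[sizes > 2]
        if len(too_big):
            raise ValidationError(f"pair {too_big.index[0]!r} has {too_big.iloc[0]} members (max 2)")
        zyg_per_pair = t.groupby("pair_id")["zygosity"].nunique()
        mixed = zyg_per_pair[zyg_per_pair > 1]
        if len(mixed):
            raise ValidationError(f"pair {mixed.index[0]!r} has discordant zygosity labels")

    def samples_in_group(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def discordant_pairs(self) -> pd.DataFrame:
        """Complete twin pairs with exactly one case and one control.

        Returns a frame with columns pair_id, case_id, control_id, family_id, zygosity.
        """
        rows = []
        for pair_id, sub in self.table.groupby("pair_id"):
            if len(sub) != 2:
                continue
            groups = set(sub["group"])
            if groups == {"case", "control"}:
                case = sub.loc[sub["group"] == "case"].iloc[0]
                ctrl = sub.loc[sub["group"] == "control"].iloc[0]
                rows.append(
                    {
                        "pair_id": pair_id,
                        "case_id": case["sample_id"],
                        "control_id": ctrl["sample_id"],
                        "family_id": case["family_id"],
                        "zygosity": case["zygosity"],
                    }
                )
        return pd.DataFrame(rows, columns=["pair_id", "case_id", "control_id", "family_id", "zygosity"])


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CpGManifest


@dataclass
class CpGManifest:
    """Probe annotation: chromosome, 1-based position, gene symbols, region class.

    gene_symbols is a ';'-separated string per probe (may be empty).
    The table is kept sorted by (chromosome, position).
    """

    table: pd.DataFrame
    flag_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        required = ["probe_id", "chromosome", "position"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"manifest missing required columns: {missing}")
        t = self.table.copy()
        if "gene_symbols" not in t.columns:
            t["gene_symbols"] = ""
        if "region_class" not in t.columns:
            t["region_class"] = "other"
        t["gene_symbols"] = t["gene_symbols"].fillna("")
        t["position"] = t["position"].astype(np.int64)
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id in manifest: {dup!r}")
        if (t["position"] <= 0).any():
            bad = t.loc[t["position"] <= 0].iloc[0]
            raise ValidationError(f"non-positive position {bad['position']} for probe {bad['probe_id']!r}")
        t = t.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
        dup_pos = t.duplicated(subset=["chromosome", "position"])
        if dup_pos.any():
            bad = t.loc[dup_pos].iloc[0]
            raise ValidationError(
                f"duplicate coordinate {bad['chromosome']}:{bad['position']} (probe {bad['probe_id']!r})"
            )
        if self.flag_sex_chromosomes:
            t["is_sex_chromosome"] = t["chromosome"].isin(SEX_CHROMOSOMES)
        self.table = t

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def genes_for_probes(self, probe_ids) -> dict[str, list[str]]:
        """Map probe id -> list of annotated gene symbols (possibly empty)."""
        sub = self.table.set_index("probe_id").loc[list(probe_ids), "gene_symbols"]
        return {p: [g for g in s.split(";") if g] for p, s in sub.items()}

    def drop_sex_chromosomes(self) -> "CpGManifest":
        keep = ~self.table["chromosome"].isin(SEX_CHROMOSOMES)
        return CpGManifest(self.table.loc[keep].drop(columns=["is_sex_chromosome"], errors="ignore"))


def read_manifest(path) -> CpGManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str, "gene_symbols": str})
    return CpGManifest(df)


def write_manifest(manifest: CpGManifest, path) -> None:
    cols = ["probe_id", "chromosome", "position", "gene_symbols", "region_class"]
    manifest.table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED export for regions


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED (0-based half-open).

    Expects columns chromosome, start (1-based inclusive), end (1-based
    inclusive), direction, gene_symbols; name = 'direction:gene,gene'.
    """
    with open(path, "w") as fh:
        for _, row in regions.iterrows():
            genes = row.get("gene_symbols", "")
            if isinstance(genes, (list, tuple, set)):
                genes = ",".join(sorted(genes))
            name = f"{row['direction']}:{genes}"
            fh.write(f"{row['chromosome']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{name}\n")


def read_regions_bed(path) -> pd.DataFrame:
    """Read a BED written by :func:`write_regions_bed`; returns 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name = line.split("\t")[:4]
            direction, _, genes = name.partition(":")
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(start) + 1,
                    "end": int(end),
                    "direction": direction,
                    "gene_symbols": genes,
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "direction", "gene_symbols"])
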