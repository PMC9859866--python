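"""Gene annotation of SEM calls and three-population set algebra.

A gene enters a population x direction set when at least one SEM of that
direction, in at least one sample of that population, falls on a probe
annotated to it. "Univocal" genes belong to exactly one of the three
populations (cases, controls, reference) within a direction; they are the
candidate loci specific to that group's epigenetic drift. Cross-direction
intersections flag genes epimutated in opposite directions in opposite
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from semscan.io_model import CpGManifest, SampleSheet, ValidationError

POPULATIONS = ("cases", "controls", "reference")
_GROUP_TO_POP = {"case": "cases", "control": "controls", "reference": "reference"}

#: Genes examined in the congenital-hypothyroidism candidate screen:
#: dyshormonogenesis and dysgenesis genes plus imprinted loci flagged by
#: region analysis.
DEFAULT_CANDIDATES = (
    "DUOX2",
    "DUOXA2",
    "TPO",
    "PAX8",
    "NKX2-1",
    "NKX2-5",
    "GLIS3",
    "SLC26A4",
    "FOXI1",
    "TSHB",
    "BICC1",
    "FAM50B",
    "MEG8",
)


@dataclass
class PopulationGeneSets:
    """Per population x direction: gene -> evidence, where evidence maps
    sample_id -> number of supporting SEM calls."""

    sets: dict  # sets[population][direction][gene] = {sample_id: count}

    def genes(self, population: str, direction: str) -> set[str]:
        return set(self.sets.get(population, {}).get(direction, {}))

    def evidence_count(self, population: str, direction: str, gene: str) -> int:
        ev = self.sets.get(population, {}).get(direction, {}).get(gene, {})
        return sum(ev.values())


@dataclass
class VennResult:
    univocal_cases: dict[str, set[str]]  # direction -> genes only in cases
    univocal_controls: dict[str, set[str]]
    cross_controls_hyper_cases_hypo: set[str]
    cross_cases_hyper_controls_hypo: set[str]
    cases_both_directions: set[str]  # hyper AND hypo in cases (any overlap status)
    cases_both_directions_univocal: set[str]  # restricted to case-univocal in both

    def counts(self) -> dict[str, int]:
        return {
            "univocal_cases_hypo": len(self.univocal_cases["hypo"]),
            "univocal_controls_hypo": len(self.univocal_controls["hypo"]),
            "univocal_cases_hyper": len(self.univocal_cases["hyper"]),
            "univocal_controls_hyper": len(self.univocal_controls["hyper"]),
            "cross_controls_hyper_cases_hypo": len(self.cross_controls_hyper_cases_hypo),
            "cross_cases_hyper_controls_hypo": len(self.cross_cases_hyper_controls_hypo),
            "cases_both_directions": len(self.cases_both_directions),
            "cases_both_directions_univocal": len(self.cases_both_directions_univocal),
        }


def annotate_sem_genes(
    calls: pd.DataFrame, manifest: CpGManifest, sheet: SampleSheet
) -> PopulationGeneSets:
    """Annotate SEM calls to genes, split by population and direction.

    Multi-gene probes contribute to every listed gene; unannotated probes
    contribute nothing. A called probe absent from the manifest is an error.
    """
    gene_map = dict(zip(manifest.table["probe_id"], manifest.table["gene_symbols"]))
    pop_of = dict(zip(sheet.table["sample_id"], sheet.table["group"].map(_GROUP_TO_POP)))
    sets: dict = {p: {"hypo": {}, "hyper": {}} for p in POPULATIONS}
    for sample_id, probe_id, direction in calls[["sample_id", "probe_id", "direction"]].itertuples(index=False):
        if probe_id not in gene_map:
            raise ValidationError(f"called probe {probe_id!r} missing from manifest")
        pop = pop_of.get(sample_id)
        if pop is None:
            continue
        for gene in gene_map[probe_id].split(";"):
            if not gene:
                continue
            ev = sets[pop][direction].setdefault(gene, {})
            ev[sample_id] = ev.get(sample_id, 0) + 1
    return PopulationGeneSets(sets)


def venn_univocal(popsets: PopulationGeneSets) -> VennResult:
    """Univocal gene lists per direction plus cross-direction intersections."""
    uc, uo = {}, {}
    for d in ("hypo", "hyper"):
        cases = popsets.genes("cases", d)
        controls = popsets.genes("controls", d)
        reference = popsets.genes("reference", d)
        uc[d] = cases - controls - reference
        uo[d] = controls - cases - reference
    cases_hypo_all = popsets.genes("cases", "hypo")
    cases_hyper_all = popsets.genes("cases", "hyper")
    return VennResult(
        univocal_cases=uc,
        univocal_controls=uo,
        cross_controls_hyper_cases_hypo=uo["hyper"] & uc["hypo"],
        cross_cases_hyper_controls_hypo=uc["hyper"] & uo["hypo"],
        cases_both_directions=cases_hypo_all & cases_hyper_all,
        cases_both_directions_univocal=uc["hypo"] & uc["hyper"],
    )


def candidate_gene_screen(
    venn: VennResult,
    popsets: PopulationGeneSets | None = None,
    candidates=DEFAULT_CANDIDATES,
) -> pd.DataFrame:
    """Intersect candidate genes with the univocal sets.

    One row per candidate with boolean flags per univocal set/direction and,
    when population sets are supplied, the supporting case samples.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    rows = []
    for gene in candidates:
        row = {
            "gene": gene,
            "univocal_cases_hypo": gene in venn.univocal_cases["hypo"],
            "univocal_cases_hyper": gene in venn.univocal_cases["hyper"],
            "univocal_controls_hypo": gene in venn.univocal_controls["hypo"],
            "univocal_controls_hyper": gene in venn.univocal_controls["hyper"],
        }
        samples: set[str] = set()
        if popsets is not None:
            for d in ("hypo", "hyper"):
                if row[f"univocal_cases_{d}"]:
                    samples |= set(popsets.sets["cases"][d].get(gene, {}))
                if row[f"univocal_controls_{d}"]:
                    samples |= set(popsets.sets["controls"][d].get(gene, {}))
        row["supporting_samples"] = ";".join(sorted(samples))
        row["any_hit"] = any(
            row[k]
            for k in (
                "univocal_cases_hypo",
                "univocal_cases_hyper",
                "univocal_controls_hypo",
                "univocal_controls_hyper",
            )
        )
        rows.append(row)
    return pd.DataFrame(rows)
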