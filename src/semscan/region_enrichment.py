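"""Per-sample detection of genomic regions enriched in same-direction SEMs.

For each sample and direction, a window of ``window_probes`` consecutive
usable probes slides along each chromosome (step 1). The SEM count k in a
window is tested against Binomial(window_probes, r) with r the sample's
genome-wide SEM rate for that direction (calls / usable probes): an excess
of same-direction outliers concentrated in one locus is unlikely under the
genome-wide rate. P-values are Benjamini-Hochberg adjusted across all
windows of that sample x direction; windows with q <= q_max and k >=
min_sems are merged when they overlap. A merged region keeps the minimum
p/q of its windows and counts its distinct SEM probes.

The window is defined in probes, not basepairs, so the scan is invariant to
probe density; the binomial tail is exact at these small counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from semscan.io_model import CpGManifest, ValidationError

REGION_COLUMNS = [
    "sample_id",
    "chromosome",
    "start_probe",
    "end_probe",
    "start",
    "end",
    "direction",
    "k",
    "m",
    "p_enrich",
    "q",
    "gene_symbols",
]


def scan_enriched_regions(
    calls: pd.DataFrame,
    manifest: CpGManifest,
    usable_probes=None,
    window_probes: int = 10,
    min_sems: int = 3,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Scan for SEM-enriched regions per sample and direction.

    Parameters
    ----------
    calls:
        Long SEM call table (sample_id, probe_id, direction).
    manifest:
        Sorted probe annotation; defines probe order along chromosomes.
    usable_probes:
        Probe ids over which SEMs could have been called (the threshold
        table's usable set). Defaults to all manifest probes.
    """
    if window_probes < min_sems:
        raise ValidationError("window_probes must be >= min_sems")
    mt = manifest.table
    if usable_probes is None:
        usable_mask = np.ones(len(mt), dtype=bool)
    else:
        usable_mask = mt["probe_id"].isin(set(usable_probes)).to_numpy()
    unknown = set(calls["probe_id"]) - set(mt["probe_id"])
    if unknown:
        raise ValidationError(f"called probes missing from manifest: {sorted(unknown)[:5]}")

    # Usable probes in manifest order, per chromosome.
    usable = mt.loc[usable_mask].reset_index(drop=True)
    n_usable = len(usable)
    if n_usable == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    probe_pos = {p: i for i, p in enumerate(usable["probe_id"])}
    genes = usable["gene_symbols"].to_numpy()
    positions = usable["position"].to_numpy()
    chroms = usable["chromosome"].to_numpy()

    regions = []
    for (sample_id, direction), sub in calls.groupby(["sample_id", "direction"], observed=True):
        hit = np.zeros(n_usable, dtype=bool)
        for p in sub["probe_id"]:
            i = probe_pos.get(p)
            if i is not None:
                hit[i] = True
        n_calls = int(hit.sum())
        if n_calls == 0:
            continue
        rate = n_calls / n_usable
        windows = []  # (chrom, start idx, end idx inclusive, k)
        for chrom in pd.unique(chroms):
            idx = np.nonzero(chroms == chrom)[0]
            if len(idx) < window_probes:
                continue
            h = hit[idx].astype(np.int64)
            csum = np.concatenate([[0], np.cumsum(h)])
            k = csum[window_probes:] - csum[:-window_probes]  # count per window
            for w0 in range(len(idx) - window_probes + 1):
                windows.append((chrom, idx[w0], idx[w0 + window_probes - 1], int(k[w0])))
        if not windows:
            continue
        ks = np.array([w[3] for w in windows])
        pvals = scipy.stats.binom.sf(ks - 1, window_probes, rate)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        keep = (qvals <= q_max) & (ks >= min_sems)
        if not keep.any():
            continue
        # Merge overlapping passing windows per chromosome.
        passing = sorted(
            (windows[i][0], windows[i][1], windows[i][2], pvals[i], qvals[i])
            for i in np.nonzero(keep)[0]
        )
        merged = []
        for chrom, s, e, p, q in passing:
            if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (chrom, prev[1], max(prev[2], e), min(prev[3], p), min(prev[4], q))
            else:
                merged.append((chrom, s, e, p, q))
        for chrom, s, e, p, q in merged:
            span = slice(s, e + 1)
            sem_idx = np.nonzero(hit[span])[0] + s
            gene_set = sorted(
                {g for i in sem_idx for g in genes[i].split(";") if g}
            )
            regions.append(
                {
                    "sample_id": sample_id,
                    "chromosome": chrom,
                    "start_probe": int(s),
                    "end_probe": int(e),
                    "start": int(positions[s]),
                    "end": int(positions[e]),
                    "direction": direction,
                    "k": int(len(sem_idx)),
                    "m": int(e - s + 1),
                    "p_enrich": float(p),
                    "q": float(q),
                    "gene_symbols": ";".join(gene_set),
                }
            )
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    return out.sort_values(["sample_id", "direction", "chromosome", "start_probe"]).reset_index(drop=True)


def merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping regions within sample x direction x chromosome.

    Idempotent: applying it to already-merged output changes nothing.
    """
    if regions.empty:
        return regions.copy()
    rows = []
    for _, sub in regions.groupby(["sample_id", "direction", "chromosome"], observed=True):
        sub = sub.sort_values("start_probe")
        cur = None
        for _, r in sub.iterrows():
            if cur is not None and r["start_probe"] <= cur["end_probe"]:
                cur["end_probe"] = max(cur["end_probe"], r["end_probe"])
                cur["end"] = max(cur["end"], r["end"])
                cur["p_enrich"] = min(cur["p_enrich"], r["p_enrich"])
                cur["q"] = min(cur["q"], r["q"])
                cur["k"] = max(cur["k"], r["k"])
                cur["m"] = cur["end_probe"] - cur["start_probe"] + 1
                gs = set(cur["gene_symbols"].split(";")) | set(r["gene_symbols"].split(";"))
                cur["gene_symbols"] = ";".join(sorted(g for g in gs if g))
            else:
                if cur is not None:
                    rows.append(cur)
                cur = r.to_dict()
        rows.append(cur)
    return (
        pd.DataFrame(rows, columns=regions.columns)
        .sort_values(["sample_id", "direction", "chromosome", "start_probe"])
        .reset_index(drop=True)
    )


def compare_region_genes(
    case_regions: pd.DataFrame,
    control_regions: pd.DataFrame,
    reference_regions: pd.DataFrame,
) -> dict:
    """Three-population comparison of region-annotated genes, by direction.

    Returns, per direction, genes found only in case regions, only in
    control regions, and the shared set; each gene keeps the sample ids it
    was detected in (the per-subject provenance, e.g. a gene tied to one
    specific twin).
    """

    def gene_samples(regions: pd.DataFrame, direction: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        if regions.empty:
            return out
        sub = regions[regions["direction"] == direction]
        for _, r in sub.iterrows():
            for g in str(r["gene_symbols"]).split(";"):
                if g:
                    out.setdefault(g, set()).add(r["sample_id"])
        return out

    result = {}
    for direction in ("hypo", "hyper"):
        cs = gene_samples(case_regions, direction)
        ct = gene_samples(control_regions, direction)
        rf = gene_samples(reference_regions, direction)
        cases_only = set(cs) - set(ct) - set(rf)
        controls_only = set(ct) - set(cs) - set(rf)
        shared = set(cs) & set(ct)
        result[direction] = {
            "cases_only": {g: sorted(cs[g]) for g in sorted(cases_only)},
            "controls_only": {g: sorted(ct[g]) for g in sorted(controls_only)},
            "shared": sorted(shared),
        }
    return result
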