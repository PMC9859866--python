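"""Simplified paired differential-methylation analysis at site and region level.

Within-pair contrasts (case twin minus control twin of each discordant
pair) are tested on the M-value scale, M = log2(beta / (1 - beta)) with
betas clamped away from {0, 1}, using a one-sample t-test against zero per
site, followed by Benjamini-Hochberg adjustment across sites. Region-level
tests average member-probe M-values per sample first and apply the same
paired test, with BH within each region class (genes, promoters, CpG
islands, fixed tilings).

This is a deliberately plain paired t pipeline: no empirical-Bayes variance
moderation and no combined-rank scoring. Reported effect sizes are mean
paired beta differences; p-values come from the M-scale test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from semscan.io_model import BetaMatrix, CpGManifest, SampleSheet, ValidationError

DEFAULT_EPSILON = 1e-3
DEFAULT_PROMOTER_WINDOW = 1500  # bp upstream of a gene's first probe
DEFAULT_TILING_WIDTH = 5000  # bp

REGION_CLASSES = ("gene", "promoter", "island", "tiling")


def beta_to_m(values, epsilon: float = DEFAULT_EPSILON):
    """Logit-2 transform of beta values with clamping to [eps, 1 - eps]."""
    arr = np.asarray(values, dtype=float)
    clamped = np.clip(arr, epsilon, 1.0 - epsilon)
    return np.log2(clamped / (1.0 - clamped))


def _paired_matrices(beta: BetaMatrix, sheet: SampleSheet):
    pairs = sheet.discordant_pairs()
    if len(pairs) < 3:
        raise ValidationError(f"need >=3 complete discordant pairs, got {len(pairs)}")
    case_vals = beta.values.loc[:, pairs["case_id"]].to_numpy(dtype=float)
    ctrl_vals = beta.values.loc[:, pairs["control_id"]].to_numpy(dtype=float)
    return pairs, case_vals, ctrl_vals


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rowwise one-sample t against 0 with NaN pair dropping.

    Returns (t, p, n_pairs). Rows with < 3 complete pairs get NaN statistics;
    rows with zero variance get p = 1 when the mean difference is zero, else
    p = 0 (an exactly constant nonzero shift).
    """
    n = np.sum(np.isfinite(diffs), axis=1)
    mean = np.nanmean(np.where(np.isfinite(diffs), diffs, np.nan), axis=1)
    sd = np.nanstd(np.where(np.isfinite(diffs), diffs, np.nan), axis=1, ddof=1)
    t = np.full(diffs.shape[0], np.nan)
    p = np.full(diffs.shape[0], np.nan)
    ok = n >= 3
    pos_sd = ok & (sd > 0)
    t[pos_sd] = mean[pos_sd] / (sd[pos_sd] / np.sqrt(n[pos_sd]))
    p[pos_sd] = 2.0 * scipy.stats.t.sf(np.abs(t[pos_sd]), n[pos_sd] - 1)
    zero_sd = ok & (sd == 0)
    t[zero_sd] = 0.0
    p[zero_sd] = np.where(mean[zero_sd] == 0, 1.0, 0.0)
    return t, p, n


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def paired_site_test(
    beta: BetaMatrix, sheet: SampleSheet, epsilon: float = DEFAULT_EPSILON
) -> pd.DataFrame:
    """Per-probe paired test on M-values across discordant twin pairs.

    Returns probe_id, mean_beta_diff (case - control), t, p, q, n_pairs.
    """
    pairs, case_b, ctrl_b = _paired_matrices(beta, sheet)
    m_diff = beta_to_m(case_b, epsilon) - beta_to_m(ctrl_b, epsilon)
    with np.errstate(invalid="ignore"):
        b_diff = case_b - ctrl_b
        t, p, n = _paired_t(m_diff)
        mean_b = np.nanmean(np.where(np.isfinite(b_diff), b_diff, np.nan), axis=1)
    return pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "mean_beta_diff": mean_b,
            "t": t,
            "p": p,
            "q": _bh(p),
            "n_pairs": n,
        }
    ).reset_index(drop=True)


def define_regions(
    manifest: CpGManifest,
    region_class: str,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    tiling_width: int = DEFAULT_TILING_WIDTH,
) -> dict[str, list[str]]:
    """Region id -> member probe ids, derived from the manifest.

    genes: probes sharing a gene symbol; promoters: probes within
    promoter_window bp upstream of a gene's first probe; islands: probes
    with manifest class 'island', grouped by gene context (or chromosome
    runs when unannotated); tilings: fixed genomic windows of tiling_width.
    """
    if region_class not in REGION_CLASSES:
        raise ValidationError(f"region class must be one of {REGION_CLASSES}")
    mt = manifest.table
    regions: dict[str, list[str]] = {}
    if region_class in ("gene", "promoter"):
        gene_probes: dict[str, list[tuple[str, int, str]]] = {}
        for probe, chrom, pos, syms in mt[["probe_id", "chromosome", "position", "gene_symbols"]].itertuples(index=False):
            for g in str(syms).split(";"):
                if g:
                    gene_probes.setdefault(g, []).append((chrom, int(pos), probe))
        if region_class == "gene":
            for g, items in gene_probes.items():
                regions[g] = [p for _, _, p in sorted(items)]
        else:
            by_chrom = {c: sub for c, sub in mt.groupby("chromosome")}
            for g, items in gene_probes.items():
                chrom, first_pos, _ = min(items)
                sub = by_chrom[chrom]
                mask = (sub["position"] >= first_pos - promoter_window) & (sub["position"] < first_pos)
                members = sub.loc[mask, "probe_id"].tolist()
                if members:
                    regions[f"{g}_promoter"] = members
    elif region_class == "island":
        isl = mt[mt["region_class"] == "island"]
        for (chrom, syms), sub in isl.groupby(["chromosome", "gene_symbols"]):
            rid = f"island_{chrom}_{syms}" if syms else f"island_{chrom}_{sub['position'].iloc[0]}"
            regions[rid] = sub["probe_id"].tolist()
    else:  # tiling
        tile = (mt["position"] // tiling_width).astype(int)
        for (chrom, t), sub in mt.groupby([mt["chromosome"], tile]):
            regions[f"{chrom}_tile{t}"] = sub["probe_id"].tolist()
    return regions


def region_test(
    beta: BetaMatrix,
    sheet: SampleSheet,
    manifest: CpGManifest,
    region_class: str,
    epsilon: float = DEFAULT_EPSILON,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    tiling_width: int = DEFAULT_TILING_WIDTH,
) -> pd.DataFrame:
    """Paired region-level test: average member-probe M per sample, then
    the paired t across discordant pairs; BH within the region class."""
    regions = define_regions(manifest, region_class, promoter_window, tiling_width)
    pairs, _, _ = _paired_matrices(beta, sheet)
    probe_index = {p: i for i, p in enumerate(beta.probe_ids)}
    m_all = beta_to_m(beta.values.to_numpy(dtype=float), epsilon)
    b_all = beta.values.to_numpy(dtype=float)
    case_cols = [beta.sample_ids.get_loc(s) for s in pairs["case_id"]]
    ctrl_cols = [beta.sample_ids.get_loc(s) for s in pairs["control_id"]]

    rows, diffs_m, diffs_b = [], [], []
    for rid in sorted(regions):
        member_rows = [probe_index[p] for p in regions[rid] if p in probe_index]
        if not member_rows:
            continue
        with np.errstate(invalid="ignore"):
            m_mean = np.nanmean(m_all[member_rows], axis=0)
            b_mean = np.nanmean(b_all[member_rows], axis=0)
        diffs_m.append(m_mean[case_cols] - m_mean[ctrl_cols])
        diffs_b.append(b_mean[case_cols] - b_mean[ctrl_cols])
        rows.append({"region_id": rid, "region_class": region_class, "n_probes": len(member_rows)})
    if not rows:
        return pd.DataFrame(
            columns=["region_id", "region_class", "n_probes", "mean_beta_diff", "t", "p", "q", "n_pairs"]
        )
    dm = np.vstack(diffs_m)
    db = np.vstack(diffs_b)
    t, p, n = _paired_t(dm)
    out = pd.DataFrame(rows)
    with np.errstate(invalid="ignore"):
        out["mean_beta_diff"] = np.nanmean(np.where(np.isfinite(db), db, np.nan), axis=1)
    out["t"] = t
    out["p"] = p
    out["q"] = _bh(p)
    out["n_pairs"] = n
    return out


def volcano_table(stats: pd.DataFrame, id_column: str = "probe_id") -> pd.DataFrame:
    """Effect size vs -log10 p table for plotting."""
    out = stats[[id_column, "mean_beta_diff", "p"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    return out
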