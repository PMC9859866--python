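"""Per-probe outlier thresholds and stochastic epigenetic mutation (SEM) calling.

A SEM at probe p in sample s is a beta value strictly outside the Tukey
extreme-outlier fence computed across a reference sample set:

    lower_p = Q1_p - 3 * IQR_p        hypo-methylated SEM:  beta < lower_p
    upper_p = Q3_p + 3 * IQR_p        hyper-methylated SEM: beta > upper_p

Quartiles use linear interpolation between order statistics (position
1 + (n - 1) * q), i.e. numpy's default quantile method. Thresholds are not
clamped to [0, 1]: a probe whose fence leaves the unit interval simply can
never be called in that direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from semscan.io_model import BetaMatrix, ValidationError

MIN_REFERENCE_SAMPLES = 4
DEFAULT_IQR_FLOOR = 1e-6

THRESHOLD_COLUMNS = ["q1", "q3", "iqr", "lower", "upper", "usable"]


def compute_reference_thresholds(
    beta: BetaMatrix,
    reference_ids=None,
    iqr_floor: float = DEFAULT_IQR_FLOOR,
) -> pd.DataFrame:
    """Compute per-probe quartiles and SEM fences on a reference sample set.

    Parameters
    ----------
    beta:
        Full beta matrix (probes x samples).
    reference_ids:
        Samples defining the reference distribution; default all samples.
    iqr_floor:
        Probes with IQR below this are flagged unusable (numerically
        constant across the reference; any fence would be degenerate).

    Returns
    -------
    DataFrame indexed by probe id with columns q1, q3, iqr, lower, upper,
    usable. Probes with missing reference values are flagged unusable and
    carry NaN statistics.
    """
    if reference_ids is None:
        reference_ids = list(beta.sample_ids)
    reference_ids = list(reference_ids)
    unknown = [s for s in reference_ids if s not in beta.sample_ids]
    if unknown:
        raise ValidationError(f"reference ids not in matrix: {unknown}")
    if len(reference_ids) < MIN_REFERENCE_SAMPLES:
        raise ValidationError(
            f"need at least {MIN_REFERENCE_SAMPLES} reference samples, got {len(reference_ids)}"
        )
    ref = beta.values.loc[:, reference_ids].to_numpy(dtype=float)
    complete = ~np.isnan(ref).any(axis=1)
    q1 = np.full(ref.shape[0], np.nan)
    q3 = np.full(ref.shape[0], np.nan)
    if complete.any():
        qs = np.quantile(ref[complete], [0.25, 0.75], axis=1)
        q1[complete], q3[complete] = qs[0], qs[1]
    iqr = q3 - q1
    out = pd.DataFrame(
        {
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "lower": q1 - 3.0 * iqr,
            "upper": q3 + 3.0 * iqr,
            "usable": complete & (iqr >= iqr_floor),
        },
        index=beta.probe_ids.copy(),
    )
    out.index.name = "probe_id"
    return out


def call_sems(beta: BetaMatrix, thresholds: pd.DataFrame, target_ids=None) -> pd.DataFrame:
    """Call hypo-/hyper-methylated SEMs for target samples against thresholds.

    Strict inequalities; unusable probes and missing values are never called.
    Returns a long DataFrame with columns sample_id, probe_id, direction,
    beta, threshold (the fence that was exceeded).
    """
    if not beta.probe_ids.equals(thresholds.index):
        raise ValidationError("probe ids of beta matrix and thresholds do not match")
    if target_ids is None:
        target_ids = list(beta.sample_ids)
    target_ids = list(target_ids)
    unknown = [s for s in target_ids if s not in beta.sample_ids]
    if unknown:
        raise ValidationError(f"target ids not in matrix: {unknown}")

    vals = beta.values.loc[:, target_ids].to_numpy(dtype=float)
    usable = thresholds["usable"].to_numpy(dtype=bool)
    lower = thresholds["lower"].to_numpy(dtype=float)
    upper = thresholds["upper"].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        hypo = usable[:, None] & (vals < lower[:, None])
        hyper = usable[:, None] & (vals > upper[:, None])

    probe_index = beta.probe_ids.to_numpy()
    frames = []
    for mask, direction, fence in ((hypo, "hypo", lower), (hyper, "hyper", upper)):
        pi, si = np.nonzero(mask)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.asarray(target_ids, dtype=object)[si],
                    "probe_id": probe_index[pi],
                    "direction": direction,
                    "beta": vals[pi, si],
                    "threshold": fence[pi],
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)
    calls = calls.sort_values(["sample_id", "probe_id", "direction"], kind="mergesort").reset_index(drop=True)
    return calls


def burden(calls: pd.DataFrame, target_ids) -> pd.DataFrame:
    """Per-sample SEM counts by direction with natural-log transforms.

    Samples with zero calls in a direction get count 0 and NaN ln (the log
    of a zero count is undefined; downstream models exclude such samples).
    """
    target_ids = list(target_ids)
    counts = (
        calls.groupby(["sample_id", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(target_ids, fill_value=0)
    )
    n_hypo = counts["hypo"] if "hypo" in counts else pd.Series(0, index=counts.index)
    n_hyper = counts["hyper"] if "hyper" in counts else pd.Series(0, index=counts.index)
    out = pd.DataFrame(
        {
            "sample_id": target_ids,
            "n_hypo": n_hypo.to_numpy(dtype=np.int64),
            "n_hyper": n_hyper.to_numpy(dtype=np.int64),
        }
    )
    with np.errstate(divide="ignore"):
        out["ln_hypo"] = np.where(out["n_hypo"] > 0, np.log(out["n_hypo"].to_numpy(dtype=float)), np.nan)
        out["ln_hyper"] = np.where(out["n_hyper"] > 0, np.log(out["n_hyper"].to_numpy(dtype=float)), np.nan)
    return out
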