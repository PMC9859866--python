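"""Twin-structured synthetic beta matrices with known spiked epimutations.

The generator emulates the statistical structure of a 450K-style twin cohort:

* per-probe baseline means drawn from a bimodal mixture (unmethylated mode
  near 0.1, methylated mode near 0.85, minor intermediate mass);
* a per-family random shift shared by co-twins at each probe, with an extra
  pair-level shift for monozygotic (MZ) pairs so MZ within-pair correlation
  exceeds DZ correlation;
* i.i.d. Gaussian noise, values truncated to [0, 1];
* spiked single-probe SEMs at Poisson group-specific rates, displaced beyond
  the clean-cohort outlier fences by a guaranteed margin;
* optional spiked contiguous clusters of same-direction SEMs in designated
  samples (the testbed for region-enrichment scanning).

Every spike is recorded in a TruthSet so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from semscan.io_model import BetaMatrix, CpGManifest, SampleSheet, ValidationError
from semscan.sem_calling import compute_reference_thresholds

# Beta-mixture parameters for baseline probe means (array-like bimodality).
_LOW_MODE, _HIGH_MODE = 0.10, 0.85
_MODE_SD = 0.02
_MODE_WEIGHTS = (0.45, 0.45, 0.10)  # low, high, intermediate
_INTERMEDIATE_RANGE = (0.30, 0.70)

# Values are clamped here after spiking so they stay strictly inside (0, 1).
_CLAMP_LO, _CLAMP_HI = 0.001, 0.999


@dataclass(frozen=True)
class ClusterSpike:
    """A contiguous run of same-direction spiked SEMs in one sample.

    role/index address the receiving sample ('case' 0 = first case in
    sample-sheet order); chromosome is the synthetic chromosome label;
    start_probe is the 0-based index of the first spiked probe within that
    chromosome; span is the number of consecutive probes spiked.
    """

    role: str  # 'case' or 'control'
    index: int
    chromosome: str
    start_probe: int
    span: int
    direction: str  # 'hypo' or 'hyper'

    def __post_init__(self):
        if self.role not in ("case", "control"):
            raise ValidationError(f"unknown cluster role {self.role!r}")
        if self.direction not in ("hypo", "hyper"):
            raise ValidationError(f"unknown cluster direction {self.direction!r}")
        if self.span < 2:
            raise ValidationError("cluster span must be >= 2 probes")


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a synthetic twin cohort.

    sem_rate_control is the expected number of spiked SEMs per control
    sample (both directions combined); hypo_fraction is the share of those
    that are hypo-methylated. Cases receive hypo spikes at
    sem_rate_control * hypo_fraction * sem_rate_case_multiplier (the case
    excess acts on the hypo direction); hyper rates are group-independent.
    """

    n_pairs_mz: int = 10
    n_pairs_dz: int = 10
    n_concordant_pairs: int = 4  # both twins affected; remaining pairs discordant
    n_probes: int = 20_000
    n_chromosomes: int = 4
    probes_per_gene: int = 10
    sem_rate_control: float = 100.0
    sem_rate_case_multiplier: float = 1.5
    hypo_fraction: float = 0.5
    cluster_spikes: tuple[ClusterSpike, ...] = ()
    family_effect_sd: float = 0.02
    mz_pair_effect_sd: float = 0.015
    noise_sd: float = 0.025
    spike_min_displacement: float = 0.15
    cluster_min_displacement: float = 0.20
    nb_dispersion: float | None = None  # negative-binomial overdispersion; None = Poisson
    seed: int = 0

    def __post_init__(self):
        if self.sem_rate_control < 0:
            raise ValidationError("sem_rate_control must be >= 0")
        if self.sem_rate_case_multiplier < 1:
            raise ValidationError("sem_rate_case_multiplier must be >= 1")
        if not 0.0 <= self.hypo_fraction <= 1.0:
            raise ValidationError("hypo_fraction must be in [0, 1]")
        if self.n_concordant_pairs > self.n_pairs_mz + self.n_pairs_dz:
            raise ValidationError("more concordant pairs than pairs")


@dataclass
class TruthSet:
    """Ground truth of all spiked epimutations.

    sems: columns sample_id, probe_id, direction (unique triples).
    clusters: columns sample_id, chromosome, start_probe, end_probe
    (0-based inclusive indices within chromosome), start, end (1-based bp),
    direction, probe_ids (';'-joined).
    """

    sems: pd.DataFrame
    clusters: pd.DataFrame

    def spike_counts(self, direction: str | None = None) -> pd.Series:
        sub = self.sems if direction is None else self.sems[self.sems["direction"] == direction]
        return sub.groupby("sample_id").size()


def generate_manifest(
    n_probes: int,
    n_chromosomes: int = 4,
    probes_per_gene: int = 10,
    seed: int = 0,
    gap_range: tuple[int, int] = (200, 2000),
) -> CpGManifest:
    """Synthetic CpG manifest: sorted positions, block-wise gene symbols.

    Probes are split evenly across chromosomes; inter-probe gaps are drawn
    uniformly from gap_range (bp). Consecutive blocks of probes_per_gene
    probes share a synthetic gene symbol; the first two probes of each gene
    block are classed 'island', the rest 'gene body'.
    """
    if n_probes <= 0:
        raise ValidationError("n_probes must be positive")
    if n_chromosomes <= 0 or probes_per_gene <= 0:
        raise ValidationError("n_chromosomes and probes_per_gene must be positive")
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_probes // n_chromosomes, dtype=int)
    per_chrom[: n_probes % n_chromosomes] += 1
    rows = []
    probe_no = 0
    for ci, count in enumerate(per_chrom, start=1):
        gaps = rng.integers(gap_range[0], gap_range[1] + 1, size=count)
        positions = 1000 + np.cumsum(gaps)
        for k in range(count):
            gene_block = k // probes_per_gene
            within = k % probes_per_gene
            rows.append(
                {
                    "probe_id": f"cg{probe_no:08d}",
                    "chromosome": f"chr{ci}",
                    "position": int(positions[k]),
                    "gene_symbols": f"GENE{ci}_{gene_block}",
                    "region_class": "island" if within < 2 else "gene body",
                }
            )
            probe_no += 1
    return CpGManifest(pd.DataFrame(rows))


def _build_sample_sheet(design: CohortDesign, rng: np.random.Generator) -> SampleSheet:
    rows = []
    n_pairs = design.n_pairs_mz + design.n_pairs_dz
    # Concordant (both-case) pairs are spread over zygosities: alternate MZ/DZ.
    concordant = set()
    mz_ids = list(range(design.n_pairs_mz))
    dz_ids = list(range(design.n_pairs_mz, n_pairs))
    take_mz = True
    while len(concordant) < design.n_concordant_pairs:
        pool = mz_ids if (take_mz and mz_ids) else dz_ids
        if not pool:
            pool = mz_ids or dz_ids
        concordant.add(pool.pop(0))
        take_mz = not take_mz
    for p in range(n_pairs):
        zyg = "MZ" if p < design.n_pairs_mz else "DZ"
        pair_sex = rng.choice(["M", "F"])
        for letter in ("A", "B"):
            group = "case" if (p in concordant or letter == "A") else "control"
            sex = pair_sex if zyg == "MZ" else rng.choice(["M", "F"])
            rows.append(
                {
                    "sample_id": f"S{p + 1:02d}{letter}",
                    "family_id": f"F{p + 1:02d}",
                    "pair_id": f"P{p + 1:02d}",
                    "zygosity": zyg,
                    "group": group,
                    "sex": sex,
                    "batch": f"b{(p % 2) + 1}",
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def _spike_counts(rng: np.random.Generator, rate: float, n: int, nb_dispersion: float | None) -> np.ndarray:
    if rate == 0:
        return np.zeros(n, dtype=int)
    if nb_dispersion is None:
        return rng.poisson(rate, size=n)
    # NB parameterised by mean and dispersion k: var = mu + mu^2 / k.
    k = nb_dispersion
    p = k / (k + rate)
    return rng.negative_binomial(k, p, size=n)


def generate_cohort(design: CohortDesign, manifest: CpGManifest):
    """Generate (BetaMatrix, SampleSheet, TruthSet) for a twin cohort design.

    Single-probe spikes are placed only on probes where the displacement
    guarantee is attainable inside (0, 1): hypo spikes need the clean lower
    fence minus the displacement to stay above 0.001, symmetrically for
    hyper. Cluster spans are made callable by forcing the baseline of their
    probes to the opposite methylation mode before the clean fences are
    computed.
    """
    if len(manifest.table) != design.n_probes:
        raise ValidationError(
            f"manifest has {len(manifest.table)} probes, design expects {design.n_probes}"
        )
    ss = np.random.SeedSequence(design.seed)
    rng_sheet, rng_base, rng_noise, rng_spike = [np.random.default_rng(s) for s in ss.spawn(4)]

    sheet = _build_sample_sheet(design, rng_sheet)
    samples = sheet.table
    n_samples = len(samples)
    n_probes = design.n_probes

    chrom = manifest.table["chromosome"].to_numpy()
    # 0-based probe index within each chromosome, in manifest (sorted) order.
    within_idx = manifest.table.groupby("chromosome").cumcount().to_numpy()
    probe_ids = manifest.table["probe_id"].to_numpy()

    # --- resolve cluster spikes to matrix coordinates -----------------------
    case_ids = samples.loc[samples["group"] == "case", "sample_id"].tolist()
    control_ids = samples.loc[samples["group"] == "control", "sample_id"].tolist()
    cluster_rows = []
    cluster_probe_rows: list[tuple[int, int, str]] = []  # (probe row, sample col, direction)
    sample_col = {s: j for j, s in enumerate(samples["sample_id"])}
    spans_by_sample: dict[str, list[tuple[int, int]]] = {}
    for cs in design.cluster_spikes:
        pool = case_ids if cs.role == "case" else control_ids
        if cs.index >= len(pool):
            raise ValidationError(f"cluster role {cs.role}[{cs.index}] exceeds group size {len(pool)}")
        sid = pool[cs.index]
        on_chrom = np.nonzero(chrom == cs.chromosome)[0]
        if len(on_chrom) == 0:
            raise ValidationError(f"chromosome {cs.chromosome!r} not in manifest")
        if cs.start_probe + cs.span > len(on_chrom):
            raise ValidationError(
                f"cluster span [{cs.start_probe}, {cs.start_probe + cs.span}) exceeds "
                f"{cs.chromosome} probe count {len(on_chrom)}"
            )
        for s0, s1 in spans_by_sample.get(sid, []):
            if cs.start_probe < s1 and s0 < cs.start_probe + cs.span:
                raise ValidationError(f"overlapping cluster spans for sample {sid}")
        spans_by_sample.setdefault(sid, []).append((cs.start_probe, cs.start_probe + cs.span))
        rows = on_chrom[cs.start_probe : cs.start_probe + cs.span]
        for r in rows:
            cluster_probe_rows.append((r, sample_col[sid], cs.direction))
        cluster_rows.append(
            {
                "sample_id": sid,
                "chromosome": cs.chromosome,
                "start_probe": cs.start_probe,
                "end_probe": cs.start_probe + cs.span - 1,
                "start": int(manifest.table["position"].iloc[rows[0]]),
                "end": int(manifest.table["position"].iloc[rows[-1]]),
                "direction": cs.direction,
                "probe_ids": ";".join(probe_ids[rows]),
            }
        )

    # --- baseline means ------------------------------------------------------
    mode = rng_base.choice(3, size=n_probes, p=_MODE_WEIGHTS)
    base = np.empty(n_probes)
    base[mode == 0] = rng_base.normal(_LOW_MODE, _MODE_SD, size=int((mode == 0).sum()))
    base[mode == 1] = rng_base.normal(_HIGH_MODE, _MODE_SD, size=int((mode == 1).sum()))
    base[mode == 2] = rng_base.uniform(*_INTERMEDIATE_RANGE, size=int((mode == 2).sum()))
    base = np.clip(base, 0.02, 0.98)
    # Force cluster-span probes to the mode that makes their direction callable.
    for r, _, direction in cluster_probe_rows:
        target = _HIGH_MODE if direction == "hypo" else _LOW_MODE
        base[r] = np.clip(rng_base.normal(target, _MODE_SD), 0.02, 0.98)

    # --- family / pair structure and noise ----------------------------------
    fam_codes, fam_index = pd.factorize(samples["family_id"])
    fam_shift = rng_noise.normal(0.0, design.family_effect_sd, size=(n_probes, len(fam_index)))
    values = base[:, None] + fam_shift[:, fam_codes]
    is_mz = (samples["zygosity"] == "MZ").to_numpy()
    if is_mz.any() and design.mz_pair_effect_sd > 0:
        pair_codes, pair_index = pd.factorize(samples["pair_id"])
        mz_shift = rng_noise.normal(0.0, design.mz_pair_effect_sd, size=(n_probes, len(pair_index)))
        values[:, is_mz] += mz_shift[:, pair_codes[is_mz]]
    values += rng_noise.normal(0.0, design.noise_sd, size=(n_probes, n_samples))
    np.clip(values, 0.0, 1.0, out=values)

    # --- clean fences and feasible spike targets -----------------------------
    clean = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=samples["sample_id"]))
    fences = compute_reference_thresholds(clean)
    lower = fences["lower"].to_numpy()
    upper = fences["upper"].to_numpy()
    usable = fences["usable"].to_numpy()
    d = design.spike_min_displacement
    hypo_ok = usable & (lower - d >= _CLAMP_LO)
    hyper_ok = usable & (upper + d <= _CLAMP_HI)
    cluster_rows_set = {r for r, _, _ in cluster_probe_rows}

    # --- single-probe spikes --------------------------------------------------
    rate_hypo_ctrl = design.sem_rate_control * design.hypo_fraction
    rate_hyper = design.sem_rate_control * (1.0 - design.hypo_fraction)
    is_case = (samples["group"] == "case").to_numpy()
    n_hypo = np.where(
        is_case,
        _spike_counts(rng_spike, rate_hypo_ctrl * design.sem_rate_case_multiplier, n_samples, design.nb_dispersion),
        _spike_counts(rng_spike, rate_hypo_ctrl, n_samples, design.nb_dispersion),
    )
    n_hyper = _spike_counts(rng_spike, rate_hyper, n_samples, design.nb_dispersion)

    sem_rows = []
    for j in range(n_samples):
        sid = samples["sample_id"].iloc[j]
        taken: set[int] = set()  # a (sample, probe) is spiked in one direction at most
        for direction, count, ok_mask, sign in (
            ("hypo", int(n_hypo[j]), hypo_ok, -1.0),
            ("hyper", int(n_hyper[j]), hyper_ok, +1.0),
        ):
            if count == 0:
                continue
            candidates = np.nonzero(ok_mask)[0]
            excluded = cluster_rows_set | taken
            if excluded:
                candidates = candidates[~np.isin(candidates, list(excluded))]
            if count > len(candidates):
                count = len(candidates)
            chosen = rng_spike.choice(candidates, size=count, replace=False)
            extra = rng_spike.uniform(0.0, 0.10, size=count)
            if sign < 0:
                values[chosen, j] = np.maximum(_CLAMP_LO, lower[chosen] - d - extra)
            else:
                values[chosen, j] = np.minimum(_CLAMP_HI, upper[chosen] + d + extra)
            taken.update(int(r) for r in chosen)
            for r in chosen:
                sem_rows.append({"sample_id": sid, "probe_id": probe_ids[r], "direction": direction})

    # --- cluster spikes -------------------------------------------------------
    dc = design.cluster_min_displacement
    for r, j, direction in cluster_probe_rows:
        extra = rng_spike.uniform(0.0, 0.05)
        if direction == "hypo":
            values[r, j] = max(_CLAMP_LO, lower[r] - dc - extra)
        else:
            values[r, j] = min(_CLAMP_HI, upper[r] + dc + extra)

    beta = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=samples["sample_id"]))
    truth = TruthSet(
        sems=pd.DataFrame(sem_rows, columns=["sample_id", "probe_id", "direction"]),
        clusters=pd.DataFrame(
            cluster_rows,
            columns=[
                "sample_id",
                "chromosome",
                "start_probe",
                "end_probe",
                "start",
                "end",
                "direction",
                "probe_ids",
            ],
        ),
    )
    return beta, sheet, truth
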