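import numpy as np
import pandas as pd
import pytest

from semscan import synthetic, sem_calling
from semscan.io_model import BetaMatrix, CpGManifest, SampleSheet


@pytest.fixture(scope="session")
def small_design():
    """Desk-scale twin cohort design used across integration tests."""
    return synthetic.CohortDesign(
        n_pairs_mz=10,
        n_pairs_dz=10,
        n_concordant_pairs=4,
        n_probes=2000,
        sem_rate_control=40,
        sem_rate_case_multiplier=1.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    manifest = synthetic.generate_manifest(
        small_design.n_probes,
        small_design.n_chromosomes,
        small_design.probes_per_gene,
        seed=small_design.seed,
    )
    beta, sheet, truth = synthetic.generate_cohort(small_design, manifest)
    return manifest, beta, sheet, truth


@pytest.fixture(scope="session")
def small_calls(small_cohort):
    _, beta, _, _ = small_cohort
    thresholds = sem_calling.compute_reference_thresholds(beta)
    calls = sem_calling.call_sems(beta, thresholds)
    return thresholds, calls


@pytest.fixture
def tiny_sheet():
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "family_id": ["f1", "f1", "f2", "f2"],
                "pair_id": ["p1", "p1", "p2", "p2"],
                "zygosity": ["MZ", "MZ", "DZ", "DZ"],
                "group": ["case", "control", "case", "control"],
                "sex": ["F", "F", "M", "M"],
                "batch": ["b1", "b1", "b2", "b2"],
            }
        )
    )


@pytest.fixture
def tiny_manifest():
    return CpGManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(6)],
                "chromosome": ["chr1"] * 4 + ["chr2"] * 2,
                "position": [100, 400, 900, 1500, 200, 700],
                "gene_symbols": ["G1", "G1;G2", "G2", "", "G3", "G3"],
                "region_class": ["island", "gene body", "gene body", "other", "island", "gene body"],
            }
        )
    )
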