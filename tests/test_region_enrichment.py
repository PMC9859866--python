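import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from semscan import region_enrichment as re_mod
from semscan.io_model import CpGManifest, ValidationError
from semscan.region_enrichment import compare_region_genes, merge_regions, scan_enriched_regions


def linear_manifest(n, chrom="chr1", start_gene=0, probes_per_gene=10):
    return CpGManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "chromosome": chrom,
                "position": 1000 + 500 * np.arange(n),
                "gene_symbols": [f"G{start_gene + i // probes_per_gene}" for i in range(n)],
            }
        )
    )


def calls_frame(triples):
    return pd.DataFrame(triples, columns=["sample_id", "probe_id", "direction"])


def oracle_scan(calls, manifest, window_probes=10, min_sems=3, q_max=0.05):
    """Independent plain-loop window enumeration with the same test definition."""
    mt = manifest.table
    out = []
    for (sample, direction), sub in calls.groupby(["sample_id", "direction"]):
        hits = set(sub["probe_id"])
        hit_vec = mt["probe_id"].isin(hits).to_numpy()
        rate = hit_vec.sum() / len(mt)
        wins = []
        for chrom in mt["chromosome"].unique():
            idx = np.nonzero((mt["chromosome"] == chrom).to_numpy())[0]
            for w in range(len(idx) - window_probes + 1):
                rows = idx[w : w + window_probes]
                k = int(hit_vec[rows].sum())
                wins.append((chrom, rows[0], rows[-1], k))
        if not wins:
            continue
        p = np.array([scipy.stats.binom.sf(k - 1, window_probes, rate) for *_, k in wins])
        q = multipletests(p, method="fdr_bh")[1]
        passing = [
            (c, s, e, pv, qv)
            for (c, s, e, k), pv, qv in zip(wins, p, q)
            if qv <= q_max and k >= min_sems
        ]
        passing.sort()
        merged = []
        for c, s, e, pv, qv in passing:
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                pc, ps, pe, pp, pq = merged[-1]
                merged[-1] = (c, ps, max(pe, e), min(pp, pv), min(pq, qv))
            else:
                merged.append((c, s, e, pv, qv))
        for c, s, e, pv, qv in merged:
            out.append((sample, direction, c, s, e, pv, qv))
    return sorted(out)


class TestScan:
    def test_zero_calls_empty(self, tiny_manifest):
        regions = scan_enriched_regions(calls_frame([]), tiny_manifest)
        assert regions.empty

    def test_window_smaller_than_min_sems_rejected(self, tiny_manifest):
        with pytest.raises(ValidationError):
            scan_enriched_regions(calls_frame([]), tiny_manifest, window_probes=2, min_sems=3)

    def test_binomial_tail_hand_computed(self):
        """8 SEMs in one 10-probe window of a 10,000-probe genome, overall rate 0.001."""
        manifest = linear_manifest(10_000)
        triples = [("s1", f"cg{i}", "hypo") for i in range(100, 108)]
        triples += [("s1", "cg5000", "hypo"), ("s1", "cg7000", "hypo")]  # 10 calls total
        regions = scan_enriched_regions(calls_frame(triples), manifest)
        hit = regions[(regions["start_probe"] <= 100) & (regions["end_probe"] >= 107)]
        assert len(hit) == 1
        expected_p = scipy.stats.binom.sf(7, 10, 10 / 10_000)
        assert hit.iloc[0]["p_enrich"] == pytest.approx(expected_p, rel=1e-9)
        assert hit.iloc[0]["k"] == 8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        manifest = linear_manifest(500)
        # two chromosomes worth of structure via two samples and mixed directions
        triples = []
        for sample in ("sA", "sB"):
            # scattered background plus one deliberate clump
            for i in rng.choice(500, size=10, replace=False):
                triples.append((sample, f"cg{i}", rng.choice(["hypo", "hyper"])))
            start = int(rng.integers(0, 480))
            for i in range(start, start + 6):
                triples.append((sample, f"cg{i}", "hypo"))
        calls = calls_frame(triples).drop_duplicates(["sample_id", "probe_id", "direction"])
        regions = scan_enriched_regions(calls, manifest)
        got = sorted(
            (r["sample_id"], r["direction"], r["chromosome"], r["start_probe"], r["end_probe"],
             r["p_enrich"], r["q"])
            for _, r in regions.iterrows()
        )
        expected = oracle_scan(calls, manifest)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:5] == e[:5]
            assert g[5] == pytest.approx(e[5], rel=1e-9)
            assert g[6] == pytest.approx(e[6], rel=1e-9)

    def test_q_values_monotone_in_p_and_bounded(self):
        manifest = linear_manifest(300)
        rng = np.random.default_rng(5)
        triples = [("s1", f"cg{i}", "hypo") for i in rng.choice(300, 40, replace=False)]
        regions = scan_enriched_regions(calls_frame(triples), manifest, q_max=1.0, min_sems=1)
        if len(regions) > 1:
            ordered = regions.sort_values("p_enrich")
            assert ordered["q"].between(0, 1).all()
            assert (ordered["q"].diff().dropna() >= -1e-12).all()

    def test_merging_idempotent(self):
        manifest = linear_manifest(400)
        triples = [("s1", f"cg{i}", "hypo") for i in list(range(50, 58)) + list(range(61, 69))]
        regions = scan_enriched_regions(calls_frame(triples), manifest)
        merged_once = merge_regions(regions)
        merged_twice = merge_regions(merged_once)
        pd.testing.assert_frame_equal(merged_once, merged_twice)


class TestPopulationComparison:
    def _regions(self, entries):
        return pd.DataFrame(
            [
                {
                    "sample_id": s, "chromosome": "chr1", "start_probe": 0, "end_probe": 1,
                    "start": 1, "end": 2, "direction": d, "k": 3, "m": 10,
                    "p_enrich": 1e-5, "q": 1e-4, "gene_symbols": g,
                }
                for s, d, g in entries
            ],
            columns=re_mod.REGION_COLUMNS,
        )

    def test_set_algebra(self):
        cases = self._regions([("c1", "hypo", "G1;G2")])
        controls = self._regions([("k1", "hypo", "G2")])
        reference = self._regions([])
        out = compare_region_genes(cases, controls, reference)
        assert set(out["hypo"]["cases_only"]) == {"G1"}
        assert out["hypo"]["cases_only"]["G1"] == ["c1"]  # per-subject provenance kept
        assert out["hypo"]["shared"] == ["G2"]

    def test_identical_inputs_no_unique_genes(self):
        r = self._regions([("x", "hyper", "G9")])
        out = compare_region_genes(r, r, r)
        assert not out["hyper"]["cases_only"] and not out["hyper"]["controls_only"]

    def test_spiked_cluster_recovered_end_to_end(self):
        from semscan import sem_calling, synthetic

        design = synthetic.CohortDesign(
            n_probes=2000, sem_rate_control=20,
            cluster_spikes=(synthetic.ClusterSpike("case", 2, "chr2", 100, 9, "hypo"),),
            seed=19,
        )
        manifest = synthetic.generate_manifest(2000, 4, 10, seed=19)
        beta, sheet, truth = synthetic.generate_cohort(design, manifest)
        thr = sem_calling.compute_reference_thresholds(beta)
        calls = sem_calling.call_sems(beta, thr)
        regions = scan_enriched_regions(calls, manifest, usable_probes=thr.index[thr["usable"]])
        case_ids = set(sheet.samples_in_group("case"))
        case_regions = regions[regions["sample_id"].isin(case_ids)]
        ctrl_regions = regions[~regions["sample_id"].isin(case_ids)]
        out = compare_region_genes(case_regions, ctrl_regions, ctrl_regions.iloc[0:0])
        spiked_genes = set()
        probe_gene = dict(zip(manifest.table["probe_id"], manifest.table["gene_symbols"]))
        for p in truth.clusters.iloc[0]["probe_ids"].split(";"):
            spiked_genes.add(probe_gene[p])
        assert spiked_genes <= set(out["hypo"]["cases_only"])
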