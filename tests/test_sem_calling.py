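import numpy as np
import pandas as pd
import pytest

from semscan import sem_calling
from semscan.io_model import BetaMatrix, ValidationError
from semscan.sem_calling import burden, call_sems, compute_reference_thresholds


def manual_quartiles(values):
    """Independent scalar quartiles: linear interpolation at position 1 + (n-1)q."""
    xs = sorted(values)
    n = len(xs)
    out = []
    for q in (0.25, 0.75):
        h = (n - 1) * q
        lo = int(np.floor(h))
        frac = h - lo
        out.append(xs[lo] + frac * (xs[min(lo + 1, n - 1)] - xs[lo]))
    return out


def make_matrix(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


class TestThresholds:
    def test_hand_computed_fences(self):
        bm = make_matrix([[0.40, 0.42, 0.44, 0.46, 0.48]])
        thr = compute_reference_thresholds(bm)
        row = thr.iloc[0]
        assert row["q1"] == pytest.approx(0.42)
        assert row["q3"] == pytest.approx(0.46)
        assert row["iqr"] == pytest.approx(0.04)
        assert row["lower"] == pytest.approx(0.30)
        assert row["upper"] == pytest.approx(0.58)
        assert row["usable"]

    def test_constant_probe_unusable(self):
        bm = make_matrix([[0.5] * 5])
        thr = compute_reference_thresholds(bm)
        assert thr.iloc[0]["iqr"] == 0.0
        assert not thr.iloc[0]["usable"]

    def test_missing_reference_value_unusable(self):
        arr = np.array([[0.1, 0.2, np.nan, 0.3, 0.4]])
        thr = compute_reference_thresholds(make_matrix(arr))
        assert not thr.iloc[0]["usable"]

    def test_too_few_reference_samples(self):
        bm = make_matrix(np.full((2, 3), 0.5))
        with pytest.raises(ValidationError, match="at least 4"):
            compute_reference_thresholds(bm)

    def test_matches_scalar_oracle_on_random_matrix(self):
        rng = np.random.default_rng(5)
        bm = make_matrix(rng.uniform(0, 1, size=(50, 10)))
        thr = compute_reference_thresholds(bm)
        for i, probe in enumerate(bm.probe_ids):
            q1, q3 = manual_quartiles(bm.values.iloc[i])
            assert thr.loc[probe, "q1"] == pytest.approx(q1, abs=1e-12)
            assert thr.loc[probe, "q3"] == pytest.approx(q3, abs=1e-12)
            assert thr.loc[probe, "lower"] == pytest.approx(q1 - 3 * (q3 - q1), abs=1e-12)

    def test_thresholds_not_clamped_to_unit_interval(self):
        bm = make_matrix([[0.02, 0.05, 0.5, 0.95, 0.98]])
        thr = compute_reference_thresholds(bm)
        assert thr.iloc[0]["lower"] < 0.0
        assert thr.iloc[0]["upper"] > 1.0

    def test_iqr_floor_monotonicity(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0, 1, size=(40, 8))
        arr[::5] *= 1e-4  # a few nearly-constant probes
        bm = make_matrix(arr)
        usable = [
            compute_reference_thresholds(bm, iqr_floor=f)["usable"].sum()
            for f in (1e-1, 1e-3, 1e-6)
        ]
        assert usable == sorted(usable)  # shrinking floor never loses usable probes


class TestCalls:
    def test_hypo_call_and_strict_boundary(self):
        # fences from the hand-computed example: lower 0.30, upper 0.58
        arr = np.array([[0.40, 0.42, 0.44, 0.46, 0.48, 0.25, 0.58]])
        bm = make_matrix(arr)
        thr = compute_reference_thresholds(bm, reference_ids=[f"s{j}" for j in range(5)])
        calls = call_sems(bm, thr)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["sample_id"], row["direction"]) == ("s5", "hypo")
        assert row["beta"] == pytest.approx(0.25)
        # 0.58 == upper exactly: strict inequality, no call

    def test_identical_samples_give_zero_calls(self):
        bm = make_matrix(np.tile(np.linspace(0.1, 0.9, 20)[:, None], (1, 6)))
        thr = compute_reference_thresholds(bm)
        assert len(call_sems(bm, thr)) == 0

    def test_probe_mismatch_rejected(self):
        bm = make_matrix(np.full((3, 5), 0.5))
        thr = compute_reference_thresholds(bm)
        other = make_matrix(np.full((2, 5), 0.5))
        with pytest.raises(ValidationError, match="probe ids"):
            call_sems(other, thr)

    def test_missing_values_never_called(self):
        arr = np.array([[0.4, 0.42, 0.44, 0.46, 0.48, np.nan]])
        bm = make_matrix(arr)
        thr = compute_reference_thresholds(bm, reference_ids=[f"s{j}" for j in range(5)])
        assert len(call_sems(bm, thr, ["s5"])) == 0

    def test_vectorized_equals_double_loop_oracle(self):
        rng = np.random.default_rng(17)
        arr = rng.beta(0.5, 0.5, size=(200, 20))
        bm = make_matrix(arr)
        thr = compute_reference_thresholds(bm)
        calls = call_sems(bm, thr)
        expected = set()
        for i, probe in enumerate(bm.probe_ids):
            if not thr.loc[probe, "usable"]:
                continue
            for j, sample in enumerate(bm.sample_ids):
                v = arr[i, j]
                if v < thr.loc[probe, "lower"]:
                    expected.add((sample, probe, "hypo"))
                elif v > thr.loc[probe, "upper"]:
                    expected.add((sample, probe, "hyper"))
        got = set(map(tuple, calls[["sample_id", "probe_id", "direction"]].to_numpy()))
        assert got == expected

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(23)
        arr = rng.uniform(0, 1, size=(60, 12))
        bm = make_matrix(arr)
        perm = rng.permutation(12)
        bm_perm = BetaMatrix(bm.values.iloc[:, perm])
        thr = compute_reference_thresholds(bm)
        thr_perm = compute_reference_thresholds(bm_perm)
        pd.testing.assert_frame_equal(thr, thr_perm)
        calls = call_sems(bm, thr)
        calls_perm = call_sems(bm_perm, thr_perm)
        key = ["sample_id", "probe_id", "direction"]
        assert set(map(tuple, calls[key].to_numpy())) == set(map(tuple, calls_perm[key].to_numpy()))


class TestBurden:
    def test_ln_of_printed_median_count(self):
        calls = pd.DataFrame(
            {"sample_id": ["s1"] * 3163, "probe_id": [f"cg{i}" for i in range(3163)], "direction": "hypo"}
        )
        b = burden(calls, ["s1", "s2"])
        assert b.set_index("sample_id").loc["s1", "ln_hypo"] == pytest.approx(8.059, abs=5e-4)
        # zero-call sample: count 0, ln absent
        assert b.set_index("sample_id").loc["s2", "n_hypo"] == 0
        assert np.isnan(b.set_index("sample_id").loc["s2", "ln_hypo"])

    def test_recovery_against_truth(self):
        """Spiked counts recovered: large reference keeps fences tight."""
        from semscan import synthetic

        design = synthetic.CohortDesign(
            n_pairs_mz=30, n_pairs_dz=30, n_concordant_pairs=0,
            n_probes=5000, sem_rate_control=50, sem_rate_case_multiplier=1.0, seed=13,
        )
        manifest = synthetic.generate_manifest(5000, 4, 10, seed=13)
        beta, sheet, truth = synthetic.generate_cohort(design, manifest)
        thr = compute_reference_thresholds(beta)
        calls = call_sems(beta, thr)
        truth_set = set(map(tuple, truth.sems[["sample_id", "probe_id", "direction"]].to_numpy()))
        got = set(map(tuple, calls[["sample_id", "probe_id", "direction"]].to_numpy()))
        sensitivity = len(truth_set & got) / len(truth_set)
        false_calls = len(got - truth_set)
        assert sensitivity >= 0.95
        assert false_calls <= 0.01 * len(truth_set)
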