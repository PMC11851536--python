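"""Consecutive-runs scanner: oracle equivalence, feasibility, summaries."""

import numpy as np
import pytest

from hrrscan.core import MISSING
from hrrscan.runs import (
    RunParams,
    detect_runs,
    merged_run_intervals,
    pearson_correlation,
    summarize_runs,
)

from conftest import build_matrix
from oracles import brute_force_runs


def _run_set(runs, bp_index):
    return {(bp_index[r.start_bp], bp_index[r.end_bp], r.n_opposite, r.n_missing)
            for r in runs}


class TestDetectRuns:
    def test_single_opposite_absorbed_into_one_run(self):
        # 25 hets at 10 kb spacing with one homozygote in the middle
        g = np.ones(25, dtype=np.int8)
        g[12] = 0
        bp = [10_000 * (j + 1) for j in range(25)]
        runs = detect_runs(build_matrix(g[None, :], bp=bp), RunParams("HRR"))
        assert len(runs) == 1
        r = runs[0]
        assert (r.start_bp, r.end_bp, r.n_snp, r.n_opposite) == (10_000, 250_000, 25, 1)
        assert r.end_bp - r.start_bp == 240_000

    def test_large_gap_splits_below_min_snp(self):
        g = np.ones(25, dtype=np.int8)
        g[12] = 0
        bp = [10_000 * (j + 1) for j in range(25)]
        bp = [b if j < 10 else b + 60_000 for j, b in enumerate(bp)]  # 70 kb gap
        runs = detect_runs(build_matrix(g[None, :], bp=bp), RunParams("HRR"))
        assert runs == []

    def test_all_homozygous_individual_yields_nothing(self):
        g = np.zeros(40, dtype=np.int8)
        runs = detect_runs(build_matrix(g[None, :]), RunParams("HRR"))
        assert runs == []

    @pytest.mark.parametrize("run_type", ["HRR", "ROH"])
    def test_oracle_equivalence_random_instances(self, run_type):
        params = RunParams(run_type, min_snp=5, min_length_bp=20_000,
                           max_gap_bp=50_000, max_opposite=1, max_missing=1)
        rng = np.random.default_rng(123)
        for _ in range(60):
            m = int(rng.integers(5, 61))
            g = rng.choice([0, 1, 2, MISSING], size=m,
                           p=[0.25, 0.45, 0.2, 0.1]).astype(np.int8)
            bp = np.cumsum(rng.integers(1_000, 60_001, size=m))
            G = build_matrix(g[None, :], bp=bp.tolist())
            got = _run_set(detect_runs(G, params), {b: i for i, b in enumerate(bp)})
            assert got == brute_force_runs(g, bp, params)

    def test_every_run_satisfies_feasibility_clauses(self, rng):
        params = RunParams("HRR")
        g = rng.choice([0, 1, 2, MISSING], size=(4, 300),
                       p=[0.1, 0.75, 0.1, 0.05]).astype(np.int8)
        bp = np.cumsum(rng.integers(5_000, 40_001, size=300)).tolist()
        G = build_matrix(g, bp=bp)
        idx = {b: i for i, b in enumerate(bp)}
        for r in detect_runs(G, params):
            i, j = idx[r.start_bp], idx[r.end_bp]
            srow = int(r.sample_id[3:])
            seg = g[srow, i:j + 1]
            assert seg[0] == 1 and seg[-1] == 1
            assert ((seg != 1) & (seg != MISSING)).sum() <= params.max_opposite
            assert (seg == MISSING).sum() <= params.max_missing
            assert np.diff(bp[i:j + 1]).max() <= params.max_gap_bp
            assert j - i + 1 >= params.min_snp
            assert r.end_bp - r.start_bp >= params.min_length_bp

    def test_hrr_invariant_to_allele_relabeling(self, rng):
        g = rng.choice([0, 1, 2, MISSING], size=(3, 200),
                       p=[0.2, 0.6, 0.15, 0.05]).astype(np.int8)
        flipped = np.where(g == MISSING, MISSING, 2 - g).astype(np.int8)
        r1 = detect_runs(build_matrix(g), RunParams("HRR"))
        r2 = detect_runs(build_matrix(flipped), RunParams("HRR"))
        assert r1 == r2

    def test_raising_max_opposite_grows_coverage(self, rng):
        g = rng.choice([0, 1, 2], size=(2, 250), p=[0.15, 0.7, 0.15]).astype(np.int8)
        G = build_matrix(g)

        def covered(max_opp):
            runs = detect_runs(G, RunParams("HRR", max_opposite=max_opp))
            return {(r.sample_id, b) for r in runs
                    for b in range(r.start_bp, r.end_bp + 1, 10_000)}

        assert covered(1) <= covered(3) <= covered(5)


class TestSummaries:
    def test_overlapping_runs_union_coverage(self):
        g = np.ones((1, 30), dtype=np.int8)
        bp = [5_000 * (j + 1) for j in range(30)]
        G = build_matrix(g, bp=bp)
        runs = detect_runs(G, RunParams("HRR", min_snp=5, min_length_bp=20_000))
        s = summarize_runs(runs, G)
        assert s.loc[0, "coverage_bp"] == bp[-1] - bp[0]
        assert s.loc[0, "coverage_fraction"] == 1.0

    def test_zero_runs_summary(self):
        G = build_matrix(np.zeros((2, 25), dtype=np.int8))
        s = summarize_runs([], G)
        assert (s["n_runs"] == 0).all()
        assert (s["coverage_bp"] == 0).all()

    def test_ho_ignores_missing(self):
        G = build_matrix(np.array([[1, 1, 0, MISSING]], dtype=np.int8))
        s = summarize_runs([], G)
        assert s.loc[0, "Ho"] == pytest.approx(2 / 3)

    def test_merged_intervals_union(self):
        g = np.ones((1, 40), dtype=np.int8)
        G = build_matrix(g)
        runs = detect_runs(G, RunParams("HRR"))
        merged = merged_run_intervals(runs)
        assert len(merged) == 1
        assert merged[0].start_bp == 10_000 and merged[0].end_bp == 400_000


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == res.r**2

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])
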