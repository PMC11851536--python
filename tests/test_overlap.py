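"""Hot spots, overlap records, one-way ANOVA and Weir-Cockerham FST."""

import numpy as np
import pytest
from scipy import stats as sps

from hrrscan.core import GenomicInterval
from hrrscan.islands import Island
from hrrscan.overlap import (
    count_overlaps,
    hot_spots,
    one_way_anova,
    pairwise_fst,
    wc84_components,
)
from hrrscan.selection import SelectionSignal
from hrrscan.simulate import SimConfig, simulate_dataset

from conftest import build_matrix
from oracles import brute_force_hotspot_flags


def _features_with_counts(counts):
    """Disjoint regions on one chromosome, region i supported by counts[i] breeds."""
    features = {}
    for i, k in enumerate(counts):
        lo, hi = 1_000_000 * i + 1, 1_000_000 * i + 500_000
        for b in range(k):
            features.setdefault(f"breed{b}", []).append(GenomicInterval("1", lo, hi))
    return features


class TestHotSpots:
    def test_worked_count_vector_flags_only_nine(self):
        counts = [1, 1, 1, 2, 2, 2, 3, 3, 4, 9]
        spots = hot_spots(_features_with_counts(counts))
        sig = [hs for hs in spots if hs.significant]
        assert len(sig) == 1 and sig[0].k == 9
        flagged = brute_force_hotspot_flags(counts, 1.645)
        assert {hs.k for hs in sig} == {counts[i] for i in flagged}

    def test_equal_counts_nothing_significant(self):
        with pytest.warns(UserWarning, match="degenerate"):
            spots = hot_spots(_features_with_counts([2, 2, 2]))
        assert not any(hs.significant for hs in spots)

    def test_two_breeds_identical_interval(self):
        features = {
            "a": [GenomicInterval("1", 100, 200)],
            "b": [GenomicInterval("1", 100, 200)],
        }
        with pytest.warns(UserWarning):
            spots = hot_spots(features)
        assert len(spots) == 1
        assert spots[0].k == 2 and spots[0].supporting_breeds == {"a", "b"}

    def test_region_lengths_sum_to_union(self):
        rng = np.random.default_rng(4)
        features = {}
        for b in range(5):
            ivs = []
            for _ in range(10):
                s = int(rng.integers(1, 10_000_000))
                ivs.append(GenomicInterval("1", s, s + int(rng.integers(1, 500_000))))
            features[f"breed{b}"] = ivs
        spots = hot_spots(features)
        union = np.zeros(11_000_000, dtype=bool)
        for ivs in features.values():
            for iv in ivs:
                union[iv.start_bp : iv.end_bp + 1] = True
        assert sum(hs.end_bp - hs.start_bp + 1 for hs in spots) == int(union.sum())


class TestCountOverlaps:
    ISL = Island("b1", "1", 1000, 2000, 10, 0.5, 0.8, "HRRI")

    def test_partial_overlap_length(self):
        sig = SelectionSignal("b1", "1", 1499, 1001, 3.0)  # covers 1500..2500
        recs = count_overlaps([self.ISL], [sig])
        assert len(recs) == 1 and recs[0].overlap_bp == 501

    def test_different_breeds_do_not_overlap(self):
        sig = SelectionSignal("b2", "1", 1499, 1001, 3.0)
        assert count_overlaps([self.ISL], [sig]) == []
        assert len(count_overlaps([self.ISL], [sig], same_breed=False)) == 1

    def test_nested_island_full_length(self):
        sig = SelectionSignal("b1", "1", 0, 250_000, 3.0)
        recs = count_overlaps([self.ISL], [sig])
        assert recs[0].overlap_bp == self.ISL.end_bp - self.ISL.start_bp + 1


class TestAnova:
    def test_hand_computed_table(self):
        # values 1..6 in groups AAABBB: SSB = 13.5 (df 1), SSW = 4 (df 4),
        # so F = 13.5; cross-checked against scipy's independent computation
        res = one_way_anova([1, 2, 3, 4, 5, 6], list("AAABBB"))
        f_ref, p_ref = sps.f_oneway([1, 2, 3], [4, 5, 6])
        assert res.F == pytest.approx(float(f_ref)) == pytest.approx(13.5)
        assert res.p == pytest.approx(float(p_ref))
        assert res.r_squared == pytest.approx(13.5 / 17.5)

    def test_no_within_variance_r2_one(self):
        res = one_way_anova([1, 1, 1, 2, 2, 2], list("AAABBB"))
        assert res.r_squared == pytest.approx(1.0)
        assert np.isinf(res.F)

    def test_identical_means_f_zero(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], list("AAABBB"))
        assert res.F == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_r2_invariant_to_affine_transform(self, rng):
        y = rng.normal(size=30)
        g = rng.choice(list("ABC"), size=30).tolist()
        r1 = one_way_anova(y, g)
        r2 = one_way_anova(5 * y - 7, g)
        assert r1.r_squared == pytest.approx(r2.r_squared)
        assert r1.F == pytest.approx(r2.F)


class TestFst:
    def test_fixed_differences_give_one(self):
        calls = np.zeros((40, 100), dtype=np.int8)
        calls[20:] = 2
        G = build_matrix(calls, breeds=["A"] * 20 + ["B"] * 20)
        assert pairwise_fst(G).values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_populations_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 3000)
        calls = rng.binomial(2, p, size=(40, 3000)).astype(np.int8)
        G = build_matrix(calls, breeds=["A"] * 20 + ["B"] * 20)
        assert abs(pairwise_fst(G).values[0, 1]) <= 0.02

    def test_hand_evaluated_components(self):
        # n1=n2=10, p1=0.9, p2=0.1, h1=h2=0.18: spreadsheet-style evaluation
        a, b, c = wc84_components(10, 0.9, 0.18, 10, 0.1, 0.18)
        nbar, pbar, hbar = 10.0, 0.5, 0.18
        s2 = (10 * 0.16 + 10 * 0.16) / 10
        nc = (20 - (100 + 100) / 20) / 1
        a_ref = (nbar / nc) * (s2 - (1 / 9) * (0.25 - s2 / 2 - hbar / 4))
        b_ref = (10 / 9) * (0.25 - s2 / 2 - (19 / 40) * hbar)
        c_ref = 0.09
        assert a == pytest.approx(a_ref)
        assert b == pytest.approx(b_ref)
        assert c == pytest.approx(c_ref)
        assert a_ref / (a_ref + b_ref + c_ref) == pytest.approx(0.315 / 0.41)

    def test_matrix_symmetric(self, rng):
        calls = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        G = build_matrix(calls, breeds=["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        V = pairwise_fst(G).values
        assert np.allclose(V, V.T)
        assert np.all(np.diag(V) == 0)

    def test_monotone_in_simulated_divergence(self):
        thetas = []
        for F in (0.05, 0.20):
            G, _ = simulate_dataset(
                SimConfig(seed=11, n_breeds=2, chromosomes=(10_000_000,),
                          breed_divergence=F, missing_rate=0.0)
            )
            thetas.append(pairwise_fst(G).values[0, 1])
        assert thetas[0] < thetas[1]
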