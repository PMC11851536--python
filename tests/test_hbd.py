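"""HBD hidden Markov model: emissions, forward-backward, EM, segment calls."""

import numpy as np
import pytest

from hrrscan.core import MISSING, DomainError
from hrrscan.hbd import (
    HbdModelSpec,
    call_hbd_segments,
    emission_probabilities,
    fit_mixing_em,
    forward_backward,
)
from hrrscan.hbd import _decay, _emission_matrix
from hrrscan.simulate import PlantedFeature, SimConfig, simulate_dataset

from oracles import exhaustive_hmm_loglik

SMALL = HbdModelSpec(hbd_rates=(4.0, 16.0), non_hbd_rate=64.0)


class TestEmissions:
    def test_error_free_hbd_forbids_hets(self):
        spec = HbdModelSpec(error_rate=0.0)
        e = emission_probabilities(1, 0.5, spec)
        assert np.all(e[:-1] == 0.0)
        assert emission_probabilities(0, 0.5, spec)[0] == pytest.approx(0.5)
        assert emission_probabilities(2, 0.5, spec)[0] == pytest.approx(0.5)

    def test_probabilities_sum_to_one_per_state(self):
        spec = HbdModelSpec(error_rate=0.01)
        for p in (0.1, 0.3, 0.7):
            total = sum(emission_probabilities(g, p, spec) for g in (0, 1, 2))
            assert np.allclose(total, 1.0)

    def test_het_emission_under_hbd_with_error(self):
        spec = HbdModelSpec(error_rate=0.001)
        assert emission_probabilities(1, 0.3, spec)[0] == pytest.approx(0.00042)

    def test_missing_is_uninformative(self):
        assert np.all(emission_probabilities(MISSING, 0.5, SMALL) == 1.0)

    def test_frequency_domain_checked(self):
        with pytest.raises(DomainError):
            emission_probabilities(0, 0.0, SMALL)


class TestForwardBackward:
    def test_single_marker_posterior_proportional_to_prior(self):
        g = np.array([0], dtype=np.int8)
        post = forward_backward(g, np.array([0.4]), np.array([1000]), SMALL)
        em = _emission_matrix(g, np.array([0.4]), SMALL)[0]
        expected = SMALL.pi * em
        expected /= expected.sum()
        assert np.allclose(post.gamma[0], expected)

    def test_loglik_matches_exhaustive_path_sum(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = int(rng.integers(2, 7))
            g = rng.integers(0, 3, m).astype(np.int8)
            if m > 2:
                g[rng.integers(0, m)] = MISSING
            freqs = rng.uniform(0.15, 0.85, m)
            pos = np.sort(rng.choice(np.arange(1, 3_000_000), m, replace=False))
            post = forward_backward(g, freqs, pos, SMALL)
            brute = exhaustive_hmm_loglik(
                _emission_matrix(g, freqs, SMALL), _decay(pos, SMALL), SMALL.pi
            )
            assert post.log_likelihood == pytest.approx(brute, abs=1e-8)
            assert np.abs(post.gamma.sum(axis=1) - 1).max() < 1e-9

    def test_distant_markers_decouple(self):
        pos = np.array([1_000, 2_000_000_000])
        freqs = np.array([0.5, 0.5])
        base = forward_backward(np.array([0, 1], np.int8), freqs, pos, SMALL)
        alt = forward_backward(np.array([1, 1], np.int8), freqs, pos, SMALL)
        assert np.allclose(base.gamma[1], alt.gamma[1], atol=1e-9)

    def test_transition_rows_sum_to_one(self):
        # analytic: sum_l T(k,l) = decay + (1-decay) * sum(pi) = 1
        d = 1e-6 * np.array([5_000.0, 50_000.0])
        decay = np.exp(-np.outer(d, SMALL.rates))
        pi = SMALL.pi
        for t in range(2):
            T = decay[t][:, None] * np.eye(3) + (1 - decay[t][:, None]) * pi[None, :]
            assert np.allclose(T.sum(axis=1), 1.0)


def _background_breed(seed=3, n=8):
    cfg = SimConfig(seed=seed, n_breeds=1, individuals_per_breed=n,
                    chromosomes=(8_000_000,), missing_rate=0.0)
    G, _ = simulate_dataset(cfg)
    return G.breed_view("breed1")


class TestEm:
    def test_non_hbd_data_fits_non_hbd_mixing(self):
        Gb = _background_breed()
        fitted, _ = fit_mixing_em(Gb, HbdModelSpec(), max_iter=40)
        assert np.mean([f.mixing[-1] for f in fitted]) >= 0.9

    def test_zero_iterations_keep_uniform_mixing(self):
        Gb = _background_breed(n=3)
        fitted, _ = fit_mixing_em(Gb, HbdModelSpec(), max_iter=0)
        for f in fitted:
            assert np.allclose(f.mixing, 1.0 / f.n_states)

    def test_loglik_non_decreasing(self):
        from hrrscan.hbd import _forward_backward_batch
        Gb = _background_breed(n=4)
        spec = HbdModelSpec()
        freqs = Gb.alt_allele_freq()
        idx = Gb.chrom_marker_index("1")
        em = np.stack([_emission_matrix(Gb.calls[i, idx], freqs[idx], spec)
                       for i in range(Gb.n_samples)])
        dec = _decay(Gb.markers["bp"].to_numpy()[idx], spec)
        pi = np.tile(spec.pi, (Gb.n_samples, 1))
        lls = []
        for _ in range(15):
            gamma, ll = _forward_backward_batch(em, dec, pi)
            lls.append(ll.copy())
            occ = gamma.sum(axis=1)
            pi = occ / occ.sum(axis=1, keepdims=True)
        lls = np.array(lls)
        assert np.all(np.diff(lls, axis=0) >= -1e-9)


class TestSegments:
    def _posterior(self, hbd_prob):
        from hrrscan.hbd import HbdPosterior
        gamma = np.zeros((len(hbd_prob), 3))
        gamma[:, 0] = hbd_prob
        gamma[:, -1] = 1 - np.asarray(hbd_prob)
        return HbdPosterior(gamma, 0.0)

    def test_uniform_high_posterior_spans_chromosome(self):
        pos = np.arange(1, 11) * 10_000
        segs = call_hbd_segments(self._posterior([0.99] * 10), pos, "1", "s1")
        assert len(segs) == 1
        assert (segs[0].start_bp, segs[0].end_bp, segs[0].n_snp) == (10_000, 100_000, 10)

    def test_uniform_low_posterior_yields_nothing(self):
        pos = np.arange(1, 11) * 10_000
        assert call_hbd_segments(self._posterior([0.01] * 10), pos, "1", "s1") == []

    def test_planted_autozygous_tract_recovered(self):
        # 200-marker tract at 15 kb spacing inside a HWE background
        feats = (PlantedFeature("ROH_TRACT", "breed1", "1", 3_000_000, 5_999_999, 1.0),)
        cfg = SimConfig(seed=7, n_breeds=1, chromosomes=(25_000_000,), features=feats)
        G, truth = simulate_dataset(cfg)
        Gb = G.breed_view("breed1")
        _, gammas = fit_mixing_em(Gb, HbdModelSpec(), max_iter=30)
        bp = Gb.markers["bp"].to_numpy()
        tract = (bp >= 3_000_000) & (bp <= 5_999_999)
        in_tract = [gammas[sid]["1"].hbd_probability[tract].mean()
                    for sid in truth[0].carriers]
        assert np.mean(in_tract) >= 0.9
        sid = truth[0].carriers[0]
        segs = call_hbd_segments(gammas[sid]["1"], bp, "1", sid)
        assert any(s.start_bp <= 5_999_999 and s.end_bp >= 3_000_000 for s in segs)

    def test_parameter_recovery_of_hbd_mass(self):
        # ~20% of the genome in autozygous tracts for every individual
        feats = tuple(
            PlantedFeature("ROH_TRACT", "breed1", "1", s, s + 2_499_999, 1.0)
            for s in (2_000_001, 12_000_001)
        )
        cfg = SimConfig(seed=9, n_breeds=1, individuals_per_breed=10,
                        chromosomes=(25_000_000,), missing_rate=0.0, features=feats)
        G, _ = simulate_dataset(cfg)
        fitted, _ = fit_mixing_em(G.breed_view("breed1"), HbdModelSpec(), max_iter=60)
        hbd_mass = np.mean([sum(f.mixing[:-1]) for f in fitted])
        assert abs(hbd_mass - 0.2) <= 0.1
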