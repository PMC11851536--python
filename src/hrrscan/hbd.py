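"""Model-based ROH calling with a multi-class homozygous-by-descent HMM.

States are K homozygous-by-descent (HBD) classes with rates R_k (the
expected segment-length scale: higher rate, shorter and older segments)
plus one non-HBD class.  Between adjacent markers at genetic distance
d = Delta_bp * morgans_per_bp the transition kernel is

    T(k, l) = exp(-R_k d) * [k == l] + (1 - exp(-R_k d)) * pi_l

i.e. with probability exp(-R_k d) the current class persists, otherwise a
new class is drawn from the mixing distribution pi.  HBD states emit a
homozygote for an allele drawn at the population frequency, contaminated
toward Hardy-Weinberg with probability eps; the non-HBD state emits plain
Hardy-Weinberg genotypes.  Mixing proportions are fitted per individual by
EM with an occupancy-weighted M-step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import MISSING, DomainError, GenotypeMatrix
from .runs import Run

DEFAULT_RATES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)


@dataclass(frozen=True)
class HbdModelSpec:
    hbd_rates: tuple[float, ...] = DEFAULT_RATES
    non_hbd_rate: float = 128.0
    mixing: tuple[float, ...] | None = None  # None -> uniform over K+1 states
    error_rate: float = 0.001
    morgans_per_bp: float = 1e-8  # 1 cM/Mb

    def __post_init__(self) -> None:
        rates = tuple(self.hbd_rates)
        if any(r <= 0 for r in rates) or list(rates) != sorted(set(rates)):
            raise ValueError("hbd_rates must be positive and strictly increasing")
        if self.non_hbd_rate <= 0:
            raise ValueError("non_hbd_rate must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.mixing is not None:
            pi = np.asarray(self.mixing, dtype=float)
            if pi.size != self.n_states or (pi < 0).any() or abs(pi.sum() - 1) > 1e-9:
                raise ValueError("mixing must be a probability vector over K+1 states")

    @property
    def n_states(self) -> int:
        return len(self.hbd_rates) + 1

    @property
    def rates(self) -> np.ndarray:
        return np.asarray(tuple(self.hbd_rates) + (self.non_hbd_rate,), dtype=float)

    @property
    def pi(self) -> np.ndarray:
        if self.mixing is None:
            return np.full(self.n_states, 1.0 / self.n_states)
        return np.asarray(self.mixing, dtype=float)


@dataclass
class HbdPosterior:
    gamma: np.ndarray  # (n_markers, n_states); HBD classes first, non-HBD last
    log_likelihood: float

    @property
    def hbd_probability(self) -> np.ndarray:
        """Per-marker total posterior mass on the HBD classes."""
        return self.gamma[:, :-1].sum(axis=1)


def emission_probabilities(genotype: int, p: float, spec: HbdModelSpec) -> np.ndarray:
    """Per-state emission probability of one genotype at allele-B frequency p."""
    if genotype == MISSING:
        return np.ones(spec.n_states)
    if not (0.0 < p < 1.0):
        raise DomainError(f"allele frequency {p} outside (0,1) for a called genotype")
    eps = spec.error_rate
    hwe = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}[genotype]
    hbd = {0: (1 - eps) * (1 - p), 1: 0.0, 2: (1 - eps) * p}[genotype] + eps * hwe
    out = np.full(spec.n_states, hbd)
    out[-1] = hwe
    return out


#: frequency floor for monomorphic sites in the fitting path: fixed sites are
#: nearly uninformative for HBD vs non-HBD and are kept (QC1 applies no MAF
#: filter), with p clamped away from {0, 1} so emissions stay proper.
FREQ_FLOOR = 1e-3


def _emission_matrix(g: np.ndarray, freqs: np.ndarray, spec: HbdModelSpec) -> np.ndarray:
    """(n_markers, n_states) emissions for one individual; vectorized."""
    called = g != MISSING
    p = np.clip(freqs, FREQ_FLOOR, 1 - FREQ_FLOOR)
    eps = spec.error_rate
    hwe = np.select([g == 0, g == 1, g == 2], [(1 - p) ** 2, 2 * p * (1 - p), p**2], 1.0)
    hom = np.select([g == 0, g == 2], [(1 - eps) * (1 - p), (1 - eps) * p], 0.0)
    hbd = np.where(called, hom + eps * hwe, 1.0)
    em = np.repeat(hbd[:, None], spec.n_states, axis=1)
    em[:, -1] = np.where(called, hwe, 1.0)
    return em


def _decay(positions: np.ndarray, spec: HbdModelSpec) -> np.ndarray:
    """(m-1, n_states) persistence probabilities exp(-R_k * d_t)."""
    d = np.diff(positions.astype(float)) * spec.morgans_per_bp
    return np.exp(-np.outer(d, spec.rates))


def _forward_backward_batch(
    em: np.ndarray, decay: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward-backward for a batch of sequences sharing transitions.

    em: (n, m, S) emissions, decay: (m-1, S), pi: (n, S) per-sequence mixing.
    Returns gamma (n, m, S) and per-sequence log-likelihood (n,).
    """
    n, m, S = em.shape
    alpha = np.empty((n, m, S))
    c = np.empty((n, m))
    a = pi * em[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, m):
        dk = decay[t - 1]
        prev = alpha[:, t - 1]
        switch = (prev * (1 - dk)).sum(axis=1)
        pred = prev * dk + pi * switch[:, None]
        a = pred * em[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((n, m, S))
    beta[:, m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        dk = decay[t]
        nb = em[:, t + 1] * beta[:, t + 1]
        mix = (pi * nb).sum(axis=1)
        beta[:, t] = (dk * nb + (1 - dk) * mix[:, None]) / c[:, t + 1, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma, np.log(c).sum(axis=1)


def forward_backward(
    genotypes: np.ndarray,
    freqs: np.ndarray,
    positions: np.ndarray,
    spec: HbdModelSpec,
) -> HbdPosterior:
    """Exact smoothed posteriors for one individual on one chromosome."""
    g = np.asarray(genotypes, dtype=np.int8)
    if g.size < 1:
        raise ValueError("need at least one marker")
    em = _emission_matrix(g, np.asarray(freqs, float), spec)[None, :, :]
    decay = _decay(np.asarray(positions), spec)
    gamma, ll = _forward_backward_batch(em, decay, spec.pi[None, :])
    return HbdPosterior(gamma[0], float(ll[0]))


def fit_mixing_em(
    G_breed: GenotypeMatrix,
    spec: HbdModelSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[list[HbdModelSpec], dict[str, dict[str, HbdPosterior]]]:
    """EM fit of per-individual mixing proportions within one breed.

    Allele frequencies come from the breed itself.  Starts from uniform
    mixing; the M-step sets pi_k proportional to total state occupancy
    (an approximation to segment-count weighting).  Returns the fitted
    spec per individual plus the final posteriors keyed by sample then
    chromosome.
    """
    spec = spec or HbdModelSpec()
    S = spec.n_states
    n = G_breed.n_samples
    freqs = G_breed.alt_allele_freq()
    chrom_data = []
    for chrom in G_breed.chromosomes:
        idx = G_breed.chrom_marker_index(chrom)
        pos = G_breed.markers["bp"].to_numpy()[idx]
        em = np.stack(
            [_emission_matrix(G_breed.calls[i, idx], freqs[idx], spec) for i in range(n)]
        )
        chrom_data.append((chrom, em, _decay(pos, spec)))

    pi = np.tile(spec.pi, (n, 1))
    prev_ll = np.full(n, -np.inf)
    gammas: dict[str, dict[str, HbdPosterior]] = {}
    for _ in range(max(max_iter, 1)):
        ll = np.zeros(n)
        occ = np.zeros((n, S))
        gammas = {sid: {} for sid in G_breed.samples["sample_id"]}
        for chrom, em, decay in chrom_data:
            gamma, ll_c = _forward_backward_batch(em, decay, pi)
            if not np.all(np.isfinite(ll_c)):
                bad = int(np.flatnonzero(~np.isfinite(ll_c))[0])
                raise FloatingPointError(f"non-finite HBD likelihood for sample index {bad}")
            ll += ll_c
            occ += gamma.sum(axis=1)
            for i, sid in enumerate(G_breed.samples["sample_id"]):
                gammas[sid][chrom] = HbdPosterior(gamma[i], float(ll_c[i]))
        if max_iter == 0 or np.all(np.abs(ll - prev_ll) < tol):
            prev_ll = ll
            break
        prev_ll = ll
        pi = occ / occ.sum(axis=1, keepdims=True)
    fitted = [replace(spec, mixing=tuple(pi[i])) for i in range(n)]
    return fitted, gammas


def call_hbd_segments(
    posterior: HbdPosterior,
    positions: np.ndarray,
    chrom: str,
    sample_id: str,
    threshold: float = 0.5,
) -> list[Run]:
    """Maximal marker stretches with summed HBD posterior >= threshold."""
    hbd = posterior.hbd_probability >= threshold
    positions = np.asarray(positions)
    runs: list[Run] = []
    m = hbd.size
    t = 0
    while t < m:
        if hbd[t]:
            s = t
            while t + 1 < m and hbd[t + 1]:
                t += 1
            runs.append(
                Run(sample_id, chrom, int(positions[s]), int(positions[t]),
                    t - s + 1, 0, 0, "ROH")
            )
        t += 1
    return runs
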