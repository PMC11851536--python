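"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the quantity from first principles (exhaustive
enumeration, explicit pairwise sums) without touching the implementation
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def brute_force_runs(genotypes, bp, params):
    """All inclusion-maximal feasible intervals by O(m^2) enumeration.

    ``params`` is a hrrscan RunParams.  Returns a set of
    (start_idx, end_idx, n_opposite, n_missing) tuples.
    """
    g = np.asarray(genotypes)
    bp = np.asarray(bp)
    m = g.size
    missing = g == MISSING
    het = g == 1
    if params.run_type == "HRR":
        target, opposite = het, (~het) & (~missing)
    else:
        target, opposite = (~het) & (~missing), het

    def feasible(i, j):
        if not (target[i] and target[j]):
            return False
        if opposite[i : j + 1].sum() > params.max_opposite:
            return False
        if missing[i : j + 1].sum() > params.max_missing:
            return False
        if j > i and np.diff(bp[i : j + 1]).max() > params.max_gap_bp:
            return False
        if j - i + 1 < params.min_snp:
            return False
        if bp[j] - bp[i] < params.min_length_bp:
            return False
        return True

    feas = [(i, j) for i in range(m) for j in range(i, m) if feasible(i, j)]
    maximal = [
        (i, j)
        for (i, j) in feas
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in feas)
    ]
    return {
        (i, j, int(opposite[i : j + 1].sum()), int(missing[i : j + 1].sum()))
        for (i, j) in maximal
    }


def brute_force_islands(freq, chrom, threshold, min_snp):
    """Threshold-then-group island calling on a share profile.

    Returns a set of (chrom, first_idx, last_idx) member-index tuples.
    """
    freq = np.asarray(freq)
    above = (freq >= threshold) & (freq > 0)
    out = set()
    for c in dict.fromkeys(chrom):
        idx = [i for i, cc in enumerate(chrom) if cc == c]
        group = []
        for i in idx:
            if above[i]:
                group.append(i)
            else:
                if len(group) >= min_snp:
                    out.add((c, group[0], group[-1]))
                group = []
        if len(group) >= min_snp:
            out.add((c, group[0], group[-1]))
    return out


def pairwise_pi(window_calls):
    """Average pairwise difference count over all chromosome pairs.

    ``window_calls``: (n_individuals, n_sites) complete diploid genotypes.
    Each individual contributes two pseudo-haplotypes per site (x alt
    copies among 2n); pi is the sum over sites of differing pairs divided
    by C(2n, 2).
    """
    calls = np.asarray(window_calls)
    n2 = 2 * calls.shape[0]
    total = 0.0
    for s in range(calls.shape[1]):
        x = int(calls[:, s].sum())
        chroms = [1] * x + [0] * (n2 - x)
        diffs = sum(
            1 for a, b in itertools.combinations(range(n2), 2) if chroms[a] != chroms[b]
        )
        total += diffs / (n2 * (n2 - 1) / 2)
    return total


def tajima_d_direct(S, pi, n):
    """Tajima's D from directly summed constants (independent of the package)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def exhaustive_hmm_loglik(em, decay, pi):
    """Log-likelihood by summation over all state paths (tiny instances)."""
    m, S = em.shape
    total = 0.0
    for path in itertools.product(range(S), repeat=m):
        p = pi[path[0]] * em[0, path[0]]
        for t in range(1, m):
            k, l = path[t - 1], path[t]
            trans = decay[t - 1, k] * (k == l) + (1 - decay[t - 1, k]) * pi[l]
            p *= trans * em[t, path[t]]
        total += p
    return float(np.log(total))


def brute_force_hotspot_flags(counts, z_crit):
    """Indices flagged by the z rule computed with plain arithmetic."""
    counts = np.asarray(counts, dtype=float)
    mean = counts.sum() / counts.size
    sd = np.sqrt(((counts - mean) ** 2).sum() / (counts.size - 1))
    if sd == 0:
        return set()
    return {i for i, k in enumerate(counts) if (k - mean) / sd >= z_crit}
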