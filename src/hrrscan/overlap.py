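"""Cross-breed hot spots, island/signal overlap accounting, ANOVA and FST.

Hot spots: the union of all breeds' intervals is decomposed by a sweep line
into maximal regions of constant breed coverage; a region is a hot spot
when its breed count k is a one-sided Z-score outlier (z >= 1.645, p < 0.05)
relative to all regions.  Overlaps between islands and selection signals are
counted within breed.  Differentiation uses the Weir-Cockerham (1984)
two-population theta-hat with ratio-of-sums aggregation over loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MISSING, GenomicInterval, GenotypeMatrix
from .islands import Island
from .selection import SelectionSignal


@dataclass(frozen=True)
class HotSpot:
    chrom: str
    start_bp: int
    end_bp: int
    supporting_breeds: frozenset[str]
    k: int
    z: float
    significant: bool


def _sweep_regions(
    features: dict[str, list[GenomicInterval]]
) -> list[tuple[str, int, int, frozenset[str]]]:
    """Maximal constant-coverage regions (coverage >= 1) per chromosome."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for breed, ivs in features.items():
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start_bp, iv.end_bp, breed))
    regions = []
    for chrom in sorted(by_chrom, key=lambda c: (0, int(c)) if c.isdigit() else (1, c)):
        ivs = by_chrom[chrom]
        cuts = sorted({s for s, _, _ in ivs} | {e + 1 for _, e, _ in ivs})
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            support = frozenset(b for s, e, b in ivs if s <= lo and hi - 1 <= e)
            if support:
                regions.append((chrom, lo, hi - 1, support))
    # merge adjacent regions with identical support (constant-coverage maximality)
    merged: list[tuple[str, int, int, frozenset[str]]] = []
    for reg in regions:
        if merged and merged[-1][0] == reg[0] and merged[-1][2] + 1 == reg[1] \
                and merged[-1][3] == reg[3]:
            prev = merged.pop()
            reg = (prev[0], prev[1], reg[2], prev[3])
        merged.append(reg)
    return merged


def hot_spots(
    features: dict[str, list[GenomicInterval]], z_crit: float = 1.645
) -> list[HotSpot]:
    """Flag regions supported by significantly many breeds.

    Adjacent significant regions are merged (supporting sets unioned, z
    reported as the max over merged components).
    """
    if sum(1 for v in features.values() if v) < 2:
        raise ValueError("hot spots need features from at least 2 breeds")
    regions = _sweep_regions(features)
    counts = np.array([len(sup) for _, _, _, sup in regions], dtype=float)
    if counts.size < 2 or np.std(counts, ddof=1) == 0:
        warnings.warn("degenerate region set (constant breed counts); nothing significant")
        z = np.full(counts.size, np.nan)
    else:
        z = (counts - counts.mean()) / np.std(counts, ddof=1)
    spots = [
        HotSpot(chrom, lo, hi, sup, len(sup), float(z[i]),
                bool(np.isfinite(z[i]) and z[i] >= z_crit))
        for i, (chrom, lo, hi, sup) in enumerate(regions)
    ]
    merged: list[HotSpot] = []
    for hs in spots:
        if (merged and hs.significant and merged[-1].significant
                and merged[-1].chrom == hs.chrom and merged[-1].end_bp + 1 == hs.start_bp):
            prev = merged.pop()
            sup = prev.supporting_breeds | hs.supporting_breeds
            hs = HotSpot(hs.chrom, prev.start_bp, hs.end_bp, sup, len(sup),
                         max(prev.z, hs.z), True)
        merged.append(hs)
    return merged


@dataclass(frozen=True)
class OverlapRecord:
    breed: str
    island: Island
    signal: SelectionSignal
    overlap_bp: int


def count_overlaps(
    islands: list[Island],
    signals: list[SelectionSignal],
    same_breed: bool = True,
) -> list[OverlapRecord]:
    """One record per (island, signal) pair sharing >= 1 bp on a chromosome.

    By default pairs must belong to the same breed; ``same_breed=False``
    enables the cross-breed reading.
    """
    out: list[OverlapRecord] = []
    for isl in islands:
        iv = GenomicInterval(isl.chrom, isl.start_bp, isl.end_bp)
        for sig in signals:
            if same_breed and isl.breed != sig.breed:
                continue
            ov = iv.overlap_bp(sig.interval)
            if ov >= 1:
                out.append(OverlapRecord(isl.breed if same_breed else f"{isl.breed}|{sig.breed}",
                                         isl, sig, ov))
    return out


@dataclass(frozen=True)
class AnovaResult:
    factor: str
    F: float
    p: float
    r_squared: float
    n_groups: int
    n: int


def one_way_anova(values, groups, factor: str = "factor") -> AnovaResult:
    """Classical one-way ANOVA with R^2 = SS_between / SS_total."""
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)})
    sizes = df.groupby("g").size()
    empty = sizes[sizes == 0]
    if len(empty):
        warnings.warn(f"dropping empty groups: {list(empty.index)}")
    k = len(sizes)
    n = len(df)
    if k < 2 or n <= k:
        raise ValueError("ANOVA needs >= 2 groups and total n > group count")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_total = float(((df["y"] - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    F = ms_between / ms_within if ms_within > 0 else np.inf
    p = float(sps.f.sf(F, k - 1, n - k))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return AnovaResult(factor, float(F), p, float(r2), k, n)


def anova_by_factors(
    regions: list[HotSpot], factor_table: pd.DataFrame
) -> list[AnovaResult]:
    """Breed-sharing ANOVA across breed factors.

    Observations are (breed, region) incidences from the sweep-line
    decomposition; the response is the region's breed-sharing count k and
    the group is the breed's level for each factor column.  This numeric
    coding is an interpretive choice, recorded in provenance.
    """
    factors = [c for c in factor_table.columns if c != "breed"]
    level = {f: dict(zip(factor_table["breed"], factor_table[f])) for f in factors}
    results = []
    for f in factors:
        values, groups = [], []
        for hs in regions:
            for breed in sorted(hs.supporting_breeds):
                if breed in level[f]:
                    values.append(hs.k)
                    groups.append(level[f][breed])
        results.append(one_way_anova(values, groups, factor=f))
    return results


# ---------------------------------------------------------------------------
# Weir-Cockerham (1984) two-population FST


def wc84_components(n1, p1, h1, n2, p2, h2):
    """Per-locus variance components (a, b, c) for two populations.

    n_i: diploid sample sizes, p_i: alt-allele frequencies, h_i: observed
    heterozygote frequencies.  Vectorized over loci.
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


@dataclass
class FstMatrix:
    breeds: list[str]
    values: np.ndarray  # symmetric, zero diagonal, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.breeds, columns=self.breeds)


def _breed_site_stats(Gb: GenotypeMatrix):
    calls = Gb.calls
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(nonmiss, calls, 0).sum(axis=0) / (2 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def pairwise_fst(G: GenotypeMatrix, min_samples: int = 2) -> FstMatrix:
    """Multi-locus theta-hat = sum(a) / sum(a+b+c) for every breed pair.

    Loci enter a pair's sums when both breeds have >= ``min_samples``
    called individuals and the pooled frequency is polymorphic.  Negative
    estimates are reported as-is (not clipped).
    """
    breeds = G.breeds
    if len(breeds) < 2:
        raise ValueError("pairwise FST needs >= 2 breeds")
    per_breed = {b: _breed_site_stats(G.breed_view(b)) for b in breeds}
    V = np.zeros((len(breeds), len(breeds)))
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            n1, p1, h1 = per_breed[breeds[i]]
            n2, p2, h2 = per_breed[breeds[j]]
            ok = (n1 >= min_samples) & (n2 >= min_samples)
            pbar = np.where(ok, (n1 * p1 + n2 * p2) / np.maximum(n1 + n2, 1), np.nan)
            ok &= (pbar > 0) & (pbar < 1)
            if not ok.any():
                warnings.warn(f"no co-polymorphic locus for {breeds[i]} vs {breeds[j]}")
                V[i, j] = V[j, i] = np.nan
                continue
            a, b, c = wc84_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
            V[i, j] = V[j, i] = float(a.sum() / (a + b + c).sum())
    return FstMatrix(breeds, V)
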