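"""Breed-level HRR/ROH islands from per-SNP run-sharing frequencies.

For each breed, f_m is the fraction of individuals with at least one run
covering marker m.  Islands are maximal stretches of consecutive markers
(within a chromosome) whose frequency reaches the breed's genome-wide
top-percentile threshold (default top 0.1%, i.e. the 99.9th percentile of
all per-SNP frequencies, linear interpolation), with at least 2 member SNPs
and strictly positive frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .runs import Run


@dataclass
class SnpShareProfile:
    breed: str
    run_type: str
    frequency: np.ndarray  # per marker, aligned with the marker map

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency, dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("share frequencies must lie in [0, 1]")
        self.frequency = f


@dataclass(frozen=True)
class Island:
    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    threshold_used: float
    peak_frequency: float
    island_type: str  # HRRI or ROHI


def snp_share_frequency(
    runs: list[Run], G_breed: GenotypeMatrix, run_type: str
) -> SnpShareProfile:
    """Fraction of the breed's individuals whose runs cover each marker."""
    breed = G_breed.samples["breed"].iat[0] if G_breed.n_samples else ""
    sample_ids = set(G_breed.samples["sample_id"])
    covered = np.zeros((G_breed.n_samples, G_breed.n_markers), dtype=bool)
    pos_of = {sid: i for i, sid in enumerate(G_breed.samples["sample_id"])}
    bp = G_breed.markers["bp"].to_numpy()
    for r in runs:
        if r.run_type != run_type or r.sample_id not in sample_ids:
            continue
        idx = G_breed.chrom_marker_index(r.chrom)
        inside = idx[(bp[idx] >= r.start_bp) & (bp[idx] <= r.end_bp)]
        covered[pos_of[r.sample_id], inside] = True
    freq = covered.mean(axis=0) if G_breed.n_samples else np.zeros(G_breed.n_markers)
    return SnpShareProfile(breed, run_type, freq)


def call_islands(
    profile: SnpShareProfile,
    G_breed: GenotypeMatrix,
    top_percentile: float = 0.1,
    min_snp: int = 2,
) -> list[Island]:
    """Threshold the sharing profile at its top percentile and group SNPs.

    ``top_percentile`` is in percent: 0.1 keeps the top 0.1% of per-SNP
    frequencies (threshold = 99.9th percentile over all markers genome-wide).
    """
    f = profile.frequency
    if f.size == 0:
        raise ValueError("empty share profile")
    T = float(np.quantile(f, 1.0 - top_percentile / 100.0, method="linear"))
    if T <= 0.0:
        warnings.warn(f"breed {profile.breed}: sharing threshold is 0; no islands called")
        return []
    if np.all(f == f[0]):
        warnings.warn(f"breed {profile.breed}: constant sharing profile (degenerate)")
    above = (f >= T) & (f > 0)
    island_type = "HRRI" if profile.run_type == "HRR" else "ROHI"
    out: list[Island] = []
    bp = G_breed.markers["bp"].to_numpy()
    for chrom in G_breed.chromosomes:
        idx = G_breed.chrom_marker_index(chrom)
        mask = above[idx]
        t = 0
        m = idx.size
        while t < m:
            if mask[t]:
                s = t
                while t + 1 < m and mask[t + 1]:
                    t += 1
                if t - s + 1 >= min_snp:
                    member = idx[s : t + 1]
                    out.append(
                        Island(
                            profile.breed, chrom,
                            int(bp[member[0]]), int(bp[member[-1]]),
                            int(member.size), T, float(f[member].max()),
                            island_type,
                        )
                    )
            t += 1
    return out


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.breed, i.island_type, i.chrom, i.start_bp, i.end_bp, i.n_snp,
          i.threshold_used, i.peak_frequency) for i in islands],
        columns=["breed", "island_type", "chrom", "start_bp", "end_bp",
                 "n_snp", "threshold", "peak_frequency"],
    )
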