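"""Quality control and kinship-based sample selection.

Two tiers mirror the study design: QC1 (call-rate only) feeds run/island
detection, QC2 (call rate + MAF >= 0.01) feeds the site-frequency statistics
(Tajima's D, FST).  "Call rate 0.10" is applied as maximum missingness 0.10
per marker and per sample, the PLINK ``--geno``/``--mind`` idiom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, DataError, GenotypeMatrix


@dataclass
class QcReport:
    n_markers_in: int
    n_markers_out: int
    n_samples_in: int
    n_samples_out: int
    removals: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("markers_in", self.n_markers_in),
            ("markers_out", self.n_markers_out),
            ("samples_in", self.n_samples_in),
            ("samples_out", self.n_samples_out),
        ] + sorted(self.removals.items())
        return pd.DataFrame(rows, columns=["quantity", "count"])


def filter_call_rate(
    G: GenotypeMatrix,
    max_missing_marker: float = 0.10,
    max_missing_sample: float = 0.10,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers then samples whose missing fraction exceeds the threshold.

    Marker filter runs first; sample missingness is then evaluated over the
    surviving markers only (PLINK default ordering).
    """
    if not (0 <= max_missing_marker <= 1 and 0 <= max_missing_sample <= 1):
        raise ValueError("missingness thresholds must lie in [0, 1]")
    miss = G.calls == MISSING
    marker_frac = miss.mean(axis=0) if G.n_samples else np.zeros(G.n_markers)
    keep_m = np.flatnonzero(marker_frac <= max_missing_marker)
    if keep_m.size == 0:
        report = QcReport(G.n_markers, 0, G.n_samples, G.n_samples,
                          {"markers_missingness": G.n_markers})
        raise DataError(f"call-rate filter removed all markers; report: {report}")
    G2 = G.subset_markers(keep_m)
    sample_frac = (G2.calls == MISSING).mean(axis=1) if G2.n_markers else np.zeros(G2.n_samples)
    keep_s = np.flatnonzero(sample_frac <= max_missing_sample)
    G3 = G2.subset_samples(keep_s)
    report = QcReport(
        G.n_markers, G3.n_markers, G.n_samples, G3.n_samples,
        {
            "markers_missingness": G.n_markers - G2.n_markers,
            "samples_missingness": G2.n_samples - G3.n_samples,
        },
    )
    return G3, report


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.01) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers with minor-allele frequency below ``min_maf`` (QC2 tier)."""
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    p = G.alt_allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= min_maf)) if min_maf > 0 else np.arange(G.n_markers)
    G2 = G.subset_markers(keep)
    report = QcReport(
        G.n_markers, G2.n_markers, G.n_samples, G.n_samples,
        {"markers_maf": G.n_markers - G2.n_markers},
    )
    return G2, report


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric; NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def kinship_matrix(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> KinshipMatrix:
    """Standardized-genotype relatedness (GRM-style).

    Entry (i, j) averages (g_i - 2p)(g_j - 2p) / (2p(1-p)) over the markers
    non-missing in both samples with 0 < p < 1, where p is the sample-wide
    allele-B frequency (or ``freqs`` when external reference frequencies are
    available; with very few samples the in-sample estimate biases entries
    downward by ~1/(n-1)).  Self-kinship of an outbred individual is ~1, a
    duplicated pair matches its diagonal.
    """
    if G.n_samples < 2:
        raise ValueError("kinship requires at least 2 samples")
    p = G.alt_allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    usable = ~np.isnan(p) & (p > 0) & (p < 1)
    g = G.calls[:, usable].astype(float)
    p = p[usable]
    obs = g != MISSING
    z = np.where(obs, (g - 2 * p) / np.sqrt(2 * p * (1 - p)), 0.0)
    num = z @ z.T
    counts = obs.astype(float) @ obs.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(counts > 0, num / counts, np.nan)
    if np.isnan(K).any():
        warnings.warn("kinship undefined for some sample pairs (no shared markers)")
    return KinshipMatrix(list(G.samples["sample_id"]), K)


def select_unrelated(
    K: KinshipMatrix, breeds: pd.DataFrame, per_breed_n: int = 20
) -> list[str]:
    """Greedy within-breed pruning down to ``per_breed_n`` samples per breed.

    Repeatedly removes the sample with the highest mean kinship to the other
    remaining members of its breed (ties broken by sample_id lexical order).
    Breeds at or under the target size are kept whole.
    """
    if per_breed_n < 1:
        raise ValueError("per_breed_n must be >= 1")
    ids = K.sample_ids
    pos = {s: i for i, s in enumerate(ids)}
    kept: list[str] = []
    for breed in dict.fromkeys(breeds["breed"]):
        members = [s for s in breeds.loc[breeds["breed"] == breed, "sample_id"] if s in pos]
        while len(members) > per_breed_n:
            def mean_kin(s: str) -> float:
                others = [pos[t] for t in members if t != s]
                return float(np.nanmean(K.values[pos[s], others]))

            worst = max(members, key=lambda s: (mean_kin(s), s))
            members.remove(worst)
        kept.extend(members)
    return kept
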