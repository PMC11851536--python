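"""Consecutive-runs detection of heterozygosity-rich regions (HRRs) and ROH.

An interval of consecutive markers [i..j] on one chromosome is *feasible*
for an individual when

  (a) markers i and j are in the target state (heterozygous for HRR,
      homozygous for ROH) and non-missing,
  (b) at most ``max_opposite`` markers inside are in the opposite state,
  (c) at most ``max_missing`` markers inside are missing,
  (d) every adjacent-marker gap is at most ``max_gap_bp``,
  (e) the interval holds at least ``min_snp`` markers, and
  (f) spans at least ``min_length_bp`` (length = bp(j) - bp(i)).

``detect_runs`` emits exactly the inclusion-maximal feasible intervals.
They may overlap; downstream island calling consumes their per-marker
coverage, which is invariant to how overlapping maximal runs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix

RunType = Literal["HRR", "ROH"]

#: default settings: HRR per the study design, ROH as a consecutive-scan utility
HRR_DEFAULTS = dict(min_snp=20, min_length_bp=50_000, max_gap_bp=50_000,
                    max_opposite=3, max_missing=1)
ROH_DEFAULTS = dict(min_snp=20, min_length_bp=50_000, max_gap_bp=50_000,
                    max_opposite=1, max_missing=2)


@dataclass(frozen=True)
class RunParams:
    run_type: RunType = "HRR"
    min_snp: int = 20
    min_length_bp: int = 50_000
    max_gap_bp: int = 50_000
    max_opposite: int = 3
    max_missing: int = 1

    def __post_init__(self) -> None:
        if min(self.min_snp, self.max_gap_bp, self.max_opposite, self.max_missing) < 0:
            raise ValueError("run parameters must be non-negative")
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        if self.run_type not in ("HRR", "ROH"):
            raise ValueError(f"unknown run_type {self.run_type!r}")


@dataclass(frozen=True)
class Run:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    n_opposite: int
    n_missing: int
    run_type: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _states(g: np.ndarray, run_type: RunType) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    missing = g == MISSING
    het = g == 1
    if run_type == "HRR":
        target, opposite = het, (~het) & (~missing)
    else:
        target, opposite = (~het) & (~missing), het
    return target, opposite, missing


def _scan_segment(
    target: np.ndarray, opposite: np.ndarray, missing: np.ndarray, params: RunParams
) -> list[tuple[int, int, int, int]]:
    """Maximal feasible intervals within one gap-free marker segment.

    Returns (i, j, n_opposite, n_missing) index tuples.  For a fixed start,
    the budget-feasible ends form a prefix, and the largest feasible end is
    non-decreasing in the start; a two-pointer sweep therefore finds every
    inclusion-maximal candidate in O(m).
    """
    m = target.size
    copp = np.concatenate([[0], np.cumsum(opposite)])
    cmis = np.concatenate([[0], np.cumsum(missing)])
    # prev_target[j] = largest target index <= j (or -1)
    prev_target = np.where(target, np.arange(m), -1)
    np.maximum.accumulate(prev_target, out=prev_target)

    out: list[tuple[int, int, int, int]] = []
    last_end = -1
    j = 0
    for i in range(m):
        if not target[i]:
            continue
        if j < i:
            j = i
        # extend budget frontier: largest j with counts within budget
        while j + 1 < m and (
            copp[j + 2] - copp[i] <= params.max_opposite
            and cmis[j + 2] - cmis[i] <= params.max_missing
        ):
            j += 1
        end = int(prev_target[j])
        if end < i or end <= last_end:
            continue
        last_end = end
        out.append((i, end, int(copp[end + 1] - copp[i]), int(cmis[end + 1] - cmis[i])))
    return out


def detect_runs(G: GenotypeMatrix, params: RunParams) -> list[Run]:
    """All inclusion-maximal feasible runs, per individual per chromosome."""
    runs: list[Run] = []
    for chrom in G.chromosomes:
        idx = G.chrom_marker_index(chrom)
        bp = G.markers["bp"].to_numpy()[idx]
        if not np.all(np.diff(bp) > 0):
            raise ValueError(f"marker map unsorted on chromosome {chrom}")
        # split at gaps > max_gap_bp: no feasible interval crosses one
        breaks = np.flatnonzero(np.diff(bp) > params.max_gap_bp)
        seg_bounds = np.concatenate([[0], breaks + 1, [bp.size]])
        for si in range(G.n_samples):
            g = G.calls[si, idx]
            target, opposite, missing = _states(g, params.run_type)
            sample_id = G.samples["sample_id"].iat[si]
            for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
                if e - s < params.min_snp:
                    continue
                for i, j, nopp, nmis in _scan_segment(
                    target[s:e], opposite[s:e], missing[s:e], params
                ):
                    i += s
                    j += s
                    if j - i + 1 < params.min_snp:
                        continue
                    if bp[j] - bp[i] < params.min_length_bp:
                        continue
                    runs.append(
                        Run(sample_id, chrom, int(bp[i]), int(bp[j]),
                            j - i + 1, nopp, nmis, params.run_type)
                    )
    return runs


def runs_to_frame(runs: list[Run], samples: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.sample_id, r.chrom, r.start_bp, r.end_bp, r.n_snp,
          r.n_opposite, r.n_missing, r.run_type) for r in runs],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snp",
                 "n_opposite", "n_missing", "run_type"],
    )
    if samples is not None:
        df = df.merge(samples[["sample_id", "breed"]], on="sample_id", how="left")
        df = df[["sample_id", "breed", "chrom", "start_bp", "end_bp", "n_snp",
                 "n_opposite", "n_missing", "run_type"]]
    return df


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Length of the union of [start, end] intervals under the end-start convention."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            total += ce - cs
            cs, ce = s, e
    return total + (ce - cs)


def merged_run_intervals(runs: list[Run]):
    """Union-merge overlapping runs per (sample, chromosome).

    Inclusion-maximal runs may overlap; for run-level accounting (e.g.
    recovery scoring against planted tracts) the merged covered intervals
    are the natural unit.  Returns GenomicIntervals whose chrom is
    ``"<sample_id>|<chrom>"`` so that matching stays within an individual.
    """
    from .core import GenomicInterval

    by: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in runs:
        by.setdefault((r.sample_id, r.chrom), []).append((r.start_bp, r.end_bp))
    out = []
    for (sid, chrom), ivs in sorted(by.items()):
        ivs.sort()
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append(GenomicInterval(f"{sid}|{chrom}", cs, ce, label=sid))
                cs, ce = s, e
        out.append(GenomicInterval(f"{sid}|{chrom}", cs, ce, label=sid))
    return out


def summarize_runs(runs: list[Run], G: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual run count, genome coverage and observed heterozygosity."""
    genome_bp = G.mapped_genome_length_bp()
    ho = G.observed_heterozygosity()
    by_sample: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for r in runs:
        by_sample.setdefault(r.sample_id, {}).setdefault(r.chrom, []).append(
            (r.start_bp, r.end_bp)
        )
    rows = []
    for i in range(G.n_samples):
        sid = G.samples["sample_id"].iat[i]
        per_chrom = by_sample.get(sid, {})
        n_runs = sum(len(v) for v in per_chrom.values())
        cov = sum(_union_length(v) for v in per_chrom.values())
        rows.append(
            {
                "sample_id": sid,
                "breed": G.samples["breed"].iat[i],
                "n_runs": n_runs,
                "coverage_bp": cov,
                "coverage_fraction": cov / genome_bp if genome_bp else 0.0,
                "Ho": ho[i],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r: float
    r_squared: float
    p_value: float
    n: int


def pearson_correlation(
    x, y, names: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Pearson r with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(names, r, r * r, float(res.pvalue), int(x.size))
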