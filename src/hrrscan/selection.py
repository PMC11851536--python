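"""Windowed Tajima's D per breed and balancing-selection signal calling.

D contrasts two estimators of the population mutation rate: nucleotide
diversity pi (average pairwise difference) and Watterson's S/a1.  An excess
of intermediate-frequency variants (pi > S/a1) pushes D positive, the
classic footprint of balancing selection; an excess of rare variants pushes
it negative.  Windows are non-overlapping 250 kb bins anchored at position
0 on each chromosome; per-site chromosome counts handle missingness, with
the normalizing constants evaluated at the window-median sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, DomainError, GenomicInterval, GenotypeMatrix


@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Normalizing constants for a sample of n chromosomes (n >= 4)."""
    if n < 4:
        raise DomainError(f"Tajima constants need n >= 4 chromosomes, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass(frozen=True)
class WindowStat:
    breed: str
    chrom: str
    window_start: int  # 0-based, multiple of window_bp
    window_bp: int
    S: int
    pi: float
    D: float | None  # None when S == 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.window_start + 1, self.window_start + self.window_bp
        )


def window_stats(G_breed: GenotypeMatrix, window_bp: int = 250_000) -> list[WindowStat]:
    """Per-window S, pi and Tajima's D for one breed.

    Sites contribute when at least 4 chromosomes (2 individuals) are called;
    per-site pi = 2x(n_s - x) / (n_s (n_s - 1)) for alt count x.  Windows
    containing no genotyped usable site are not emitted; windows with S = 0
    carry an undefined D.
    """
    breed = G_breed.samples["breed"].iat[0] if G_breed.n_samples else ""
    calls = G_breed.calls
    nonmiss = calls != MISSING
    n_s = 2 * nonmiss.sum(axis=0)
    x = np.where(calls == MISSING, 0, calls).sum(axis=0)
    usable = n_s >= 4
    seg = usable & (x > 0) & (x < n_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = np.where(seg, 2.0 * x * (n_s - x) / (n_s * np.maximum(n_s - 1, 1)), 0.0)
    bp = G_breed.markers["bp"].to_numpy()
    win = (bp - 1) // window_bp
    out: list[WindowStat] = []
    for chrom in G_breed.chromosomes:
        idx = G_breed.chrom_marker_index(chrom)
        idx = idx[usable[idx]]
        if idx.size == 0:
            continue
        for w in np.unique(win[idx]):
            sites = idx[win[idx] == w]
            seg_sites = sites[seg[sites]]
            S = int(seg_sites.size)
            pi = float(pi_site[seg_sites].sum())
            D: float | None = None
            if S >= 1:
                n_med = int(round(float(np.median(n_s[seg_sites]))))
                k = tajima_constants(n_med)
                var = k.e1 * S + k.e2 * S * (S - 1)
                D = float((pi - S / k.a1) / np.sqrt(var))
            out.append(WindowStat(breed, chrom, int(w) * window_bp, window_bp, S, pi, D))
    return out


@dataclass(frozen=True)
class SelectionSignal:
    breed: str
    chrom: str
    window_start: int
    window_bp: int
    D: float

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.window_start + 1, self.window_start + self.window_bp
        )


def threshold_signals(
    stats: list[WindowStat], top_fraction: float = 0.001
) -> list[SelectionSignal]:
    """Per-breed top-fraction windows by D, restricted to positive D.

    The threshold is the (1 - top_fraction) quantile (linear interpolation)
    of the breed's defined D values pooled genome-wide; ties at the
    threshold are all kept.
    """
    out: list[SelectionSignal] = []
    by_breed: dict[str, list[WindowStat]] = {}
    for ws in stats:
        by_breed.setdefault(ws.breed, []).append(ws)
    for breed, wss in by_breed.items():
        defined = [ws for ws in wss if ws.D is not None]
        if not defined:
            warnings.warn(f"breed {breed}: no window with defined D; no signals")
            continue
        d = np.array([ws.D for ws in defined])
        T = float(np.quantile(d, 1.0 - top_fraction, method="linear"))
        for ws in defined:
            if ws.D >= T and ws.D > 0:
                out.append(SelectionSignal(breed, ws.chrom, ws.window_start, ws.window_bp, ws.D))
    return out


def window_stats_to_frame(stats: list[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.breed, w.chrom, w.window_start, w.window_start + w.window_bp,
          w.S, w.pi, w.D) for w in stats],
        columns=["breed", "chrom", "window_start", "window_end", "S", "pi", "D"],
    )


def signals_to_frame(signals: list[SelectionSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.breed, s.chrom, s.window_start, s.window_start + s.window_bp, s.D)
         for s in signals],
        columns=["breed", "chrom", "window_start", "window_end", "D"],
    )
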