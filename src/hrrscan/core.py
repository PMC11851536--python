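"""Core containers for SNP-array genotype analysis.

Genotypes are stored as an (n_samples, n_markers) int8 matrix with codes
0 = homozygous for allele A, 1 = heterozygous, 2 = homozygous for allele B
and ``MISSING`` (-1) for no-calls.  Marker and sample metadata live in
pandas DataFrames.  Physical coordinates are 1-based inclusive throughout;
conversion to 0-based half-open happens only at the BED file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: default autosome labels for the dog genome (configurable everywhere)
DOG_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 39))


class FormatError(ValueError):
    """Malformed input file (wrong field counts, bad magic bytes, ...)."""


class DataError(ValueError):
    """Structurally valid input with impossible content (e.g. >2 alleles)."""


class DomainError(ValueError):
    """Parameter outside its mathematical domain."""


class DependencyError(RuntimeError):
    """A pipeline stage was requested without its upstream artifacts."""


@dataclass(frozen=True)
class GenomicInterval:
    """A closed interval [start_bp, end_bp] on one chromosome (1-based)."""

    chrom: str
    start_bp: int
    end_bp: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"interval start {self.start_bp} > end {self.end_bp} on {self.chrom}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared base pairs (0 if disjoint or on other chrom)."""
        if self.chrom != other.chrom:
            return 0
        lo = max(self.start_bp, other.start_bp)
        hi = min(self.end_bp, other.end_bp)
        return max(0, hi - lo + 1)


def make_marker_map(
    marker_id: Sequence[str],
    chrom: Sequence[str],
    bp: Sequence[int],
    allele_a: Sequence[str] | None = None,
    allele_b: Sequence[str] | None = None,
) -> pd.DataFrame:
    m = len(marker_id)
    df = pd.DataFrame(
        {
            "marker_id": pd.Series(marker_id, dtype=str),
            "chrom": pd.Series(chrom, dtype=str),
            "bp": pd.Series(bp, dtype=np.int64),
            "allele_a": pd.Series(allele_a if allele_a is not None else ["A"] * m, dtype=str),
            "allele_b": pd.Series(allele_b if allele_b is not None else ["B"] * m, dtype=str),
        }
    )
    return df


def make_sample_table(sample_id: Sequence[str], breed: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"sample_id": pd.Series(sample_id, dtype=str), "breed": pd.Series(breed, dtype=str)}
    )


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype calls plus their metadata.

    Invariants (checked by :meth:`validate`): marker map sorted by
    (chrom, bp) with unique positions and ids, unique sample ids, calls of
    shape (n_samples, n_markers) drawn from {0, 1, 2, MISSING}.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        ns, nm = len(self.samples), len(self.markers)
        if self.calls.shape != (ns, nm):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_samples={ns}, n_markers={nm})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0,1,2,MISSING}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        key = self.markers[["chrom", "bp"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, bp) positions")
        if (self.markers["bp"] < 1).any():
            raise ValueError("bp positions must be >= 1")
        # sorted by (chrom, bp); chromosome blocks contiguous
        grp = self.markers.groupby("chrom", sort=False)
        for _, sub in grp:
            if not sub["bp"].is_monotonic_increasing:
                raise ValueError("marker map not sorted by bp within chromosome")
            if sub.index.max() - sub.index.min() + 1 != len(sub):
                raise ValueError("chromosome blocks not contiguous in marker map")

    # -- basic views -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_marker_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def subset_samples(self, idx: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(
            self.samples.iloc[idx].reset_index(drop=True),
            self.markers.copy().reset_index(drop=True),
            self.calls[idx, :].copy(),
        )

    def subset_markers(self, idx: Iterable[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(
            self.samples.copy().reset_index(drop=True),
            self.markers.iloc[idx].reset_index(drop=True),
            self.calls[:, idx].copy(),
        )

    def breed_view(self, breed: str) -> "GenotypeMatrix":
        idx = np.flatnonzero((self.samples["breed"] == breed).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples for breed {breed!r}")
        return self.subset_samples(idx)

    @property
    def breeds(self) -> list[str]:
        return list(dict.fromkeys(self.samples["breed"]))

    # -- elementary statistics ------------------------------------------
    def alt_allele_freq(self) -> np.ndarray:
        """Per-marker frequency of allele B among non-missing calls (NaN if none)."""
        g = np.ma.masked_equal(self.calls, MISSING)
        with np.errstate(invalid="ignore"):
            p = g.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    def observed_heterozygosity(self) -> np.ndarray:
        """Per-sample Ho = het calls / non-missing calls (NaN if fully missing)."""
        nonmiss = (self.calls != MISSING).sum(axis=1)
        het = (self.calls == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)

    def mapped_genome_length_bp(self) -> int:
        """Sum over chromosomes of (last marker bp - first marker bp)."""
        total = 0
        for chrom in self.chromosomes:
            bp = self.markers.loc[self.markers["chrom"] == chrom, "bp"]
            total += int(bp.iloc[-1] - bp.iloc[0])
        return total
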