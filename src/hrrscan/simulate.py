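"""Seeded multi-breed SNP-array simulator with planted features.

The generator emulates the shape of a multi-breed dog SNP-array dataset:
autosomes with ~15 kb marker spacing, 20 individuals per breed, and breeds
differentiated by a Balding-Nichols model (breed allele frequencies drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral frequencies p ~
Uniform(0.05, 0.95)).  Background genotypes are Hardy-Weinberg draws at the
breed frequencies with sites independent (no linkage disequilibrium).

Three feature kinds can be planted, each with a truth record:

* ``HRR_TRACT``   - in a fraction of a breed's individuals, tract markers
  are heterozygous with probability ``intensity`` (default 0.95).
* ``ROH_TRACT``   - carriers are homozygous for an allele drawn at the
  breed frequency, with a 0.01 contamination rate back to Hardy-Weinberg.
* ``BALANCING_WINDOW`` - the window's frequencies are redrawn ~
  Uniform(0.4, 0.6) in every breed and heterozygote probabilities inflated
  by ``intensity`` (default 1.3, renormalized), mimicking long-term
  heterozygote advantage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenomicInterval, GenotypeMatrix, make_marker_map, make_sample_table

FEATURE_KINDS = ("HRR_TRACT", "ROH_TRACT", "BALANCING_WINDOW")


@dataclass(frozen=True)
class PlantedFeature:
    kind: str
    breed: str
    chrom: str
    start_bp: int
    end_bp: int
    carrier_fraction: float = 0.8
    intensity: float | None = None  # kind-specific default when None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("feature start > end")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_bp, self.end_bp, self.kind)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    n_breeds: int = 3
    individuals_per_breed: int = 20
    chromosomes: tuple[int, ...] = (25_000_000, 25_000_000)
    snp_spacing_bp: int = 15_000
    breed_divergence: float = 0.10
    missing_rate: float = 0.02
    features: tuple[PlantedFeature, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.breed_divergence < 1) or not (0 <= self.missing_rate <= 1):
            raise ValueError("divergence and missing_rate must lie in [0, 1)")
        lengths = dict(self.chrom_names_lengths())
        for ft in self.features:
            if ft.chrom not in lengths or ft.end_bp > lengths[ft.chrom]:
                raise ValueError(f"feature {ft} outside chromosome bounds")

    def chrom_names_lengths(self) -> list[tuple[str, int]]:
        return [(str(i + 1), L) for i, L in enumerate(self.chromosomes)]


@dataclass(frozen=True)
class TruthRecord:
    kind: str
    breed: str
    interval: GenomicInterval
    carriers: tuple[str, ...]


def _het_inflated_probs(p: np.ndarray, factor: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotype probabilities with the HWE het share inflated and renormalized."""
    het = np.minimum(2 * p * (1 - p) * factor, 1.0)
    hom_total = (1 - p) ** 2 + p**2
    scale = np.where(hom_total > 0, (1 - het) / hom_total, 0.0)
    return (1 - p) ** 2 * scale, het, p**2 * scale


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Draw a seeded dataset and the truth records of its planted features."""
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names_lengths()
    marker_chrom: list[str] = []
    marker_bp: list[int] = []
    for name, length in chroms:
        pos = np.arange(config.snp_spacing_bp, length + 1, config.snp_spacing_bp)
        marker_chrom.extend([name] * pos.size)
        marker_bp.extend(pos.tolist())
    m = len(marker_bp)
    bp = np.asarray(marker_bp)
    chrom_arr = np.asarray(marker_chrom)
    markers = make_marker_map(
        [f"snp{k + 1}" for k in range(m)], marker_chrom, marker_bp,
        allele_a=["A"] * m, allele_b=["B"] * m,
    )

    def feature_sites(ft: PlantedFeature) -> np.ndarray:
        return np.flatnonzero((chrom_arr == ft.chrom) & (bp >= ft.start_bp) & (bp <= ft.end_bp))

    # reject overlapping planted features of different kinds on shared SNPs
    claimed: dict[int, str] = {}
    for ft in config.features:
        for s in feature_sites(ft):
            if claimed.get(s, ft.kind) != ft.kind:
                raise ValueError(
                    f"planted features of different kinds overlap at marker index {s}"
                )
            claimed[s] = ft.kind

    anc = rng.uniform(0.05, 0.95, size=m)
    F = config.breed_divergence
    breeds = [f"breed{b + 1}" for b in range(config.n_breeds)]
    if F > 0:
        breed_p = rng.beta(anc * (1 - F) / F, (1 - anc) * (1 - F) / F,
                           size=(config.n_breeds, m))
        breed_p = np.clip(breed_p, 1e-4, 1 - 1e-4)
    else:
        breed_p = np.tile(anc, (config.n_breeds, 1))

    # balancing windows override frequencies in every breed
    for ft in config.features:
        if ft.kind == "BALANCING_WINDOW":
            sites = feature_sites(ft)
            breed_p[:, sites] = rng.uniform(0.4, 0.6, size=sites.size)[None, :]

    n_per = config.individuals_per_breed
    sample_ids = [f"{b}_ind{i + 1}" for b in breeds for i in range(n_per)]
    sample_breeds = [b for b in breeds for _ in range(n_per)]
    calls = np.empty((len(sample_ids), m), dtype=np.int8)
    for bi, b in enumerate(breeds):
        rows = slice(bi * n_per, (bi + 1) * n_per)
        calls[rows] = rng.binomial(2, breed_p[bi], size=(n_per, m)).astype(np.int8)
        for ft in config.features:
            if ft.kind != "BALANCING_WINDOW":
                continue
            sites = feature_sites(ft)
            p = breed_p[bi, sites]
            p0, p1, _ = _het_inflated_probs(p, 1.3 if ft.intensity is None else ft.intensity)
            u = rng.random(size=(n_per, sites.size))
            calls[rows.start:rows.stop, sites] = np.select(
                [u < p0, u < p0 + p1], [0, 1], 2
            ).astype(np.int8)

    truth: list[TruthRecord] = []
    sample_arr = np.asarray(sample_ids)
    for ft in config.features:
        bi = breeds.index(ft.breed) if ft.breed in breeds else None
        if ft.kind == "BALANCING_WINDOW":
            members = sample_arr[[i for i, sb in enumerate(sample_breeds) if sb == ft.breed]]
            truth.append(TruthRecord(ft.kind, ft.breed, ft.interval, tuple(members)))
            continue
        if bi is None:
            raise ValueError(f"feature breed {ft.breed!r} not in simulated breeds")
        sites = feature_sites(ft)
        members = np.arange(bi * n_per, (bi + 1) * n_per)
        n_car = int(round(ft.carrier_fraction * n_per))
        carriers = rng.choice(members, size=n_car, replace=False)
        carriers.sort()
        if ft.kind == "HRR_TRACT":
            inten = 0.95 if ft.intensity is None else ft.intensity
            for ci in carriers:
                make_het = rng.random(sites.size) < inten
                calls[ci, sites[make_het]] = 1
        else:  # ROH_TRACT
            p = breed_p[bi, sites]
            for ci in carriers:
                hom = (rng.random(sites.size) < p).astype(np.int8) * 2
                hwe = rng.binomial(2, p).astype(np.int8)
                err = rng.random(sites.size) < 0.01
                calls[ci, sites] = np.where(err, hwe, hom)
        truth.append(
            TruthRecord(ft.kind, ft.breed, ft.interval, tuple(sample_arr[carriers]))
        )

    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        calls[miss] = MISSING

    G = GenotypeMatrix(make_sample_table(sample_ids, sample_breeds), markers, calls)
    return G, truth


def truth_to_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.kind, t.breed, t.interval.chrom, t.interval.start_bp, t.interval.end_bp,
          ",".join(t.carriers)) for t in truth],
        columns=["kind", "breed", "chrom", "start_bp", "end_bp", "carriers"],
    )


@dataclass(frozen=True)
class RecoveryScore:
    n_detected: int
    n_truth: int
    n_matched: int
    precision: float | None
    recall: float | None
    f1: float | None


def score_recovery(
    detected: list[GenomicInterval],
    truth: list[GenomicInterval],
    min_reciprocal_overlap: float = 0.5,
) -> RecoveryScore:
    """Greedy one-to-one interval matching at a reciprocal-overlap cutoff.

    A pair matches when the intersection covers at least the cutoff fraction
    of *each* interval; pairs are consumed in order of descending overlap.
    Precision is undefined (None) with no detections, recall with no truth.
    """
    pairs = []
    for di, d in enumerate(detected):
        for ti, t in enumerate(truth):
            ov = d.overlap_bp(t)
            if ov >= min_reciprocal_overlap * d.length_bp and \
               ov >= min_reciprocal_overlap * t.length_bp:
                pairs.append((ov, di, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched = 0
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched += 1
    precision = matched / len(detected) if detected else None
    recall = matched / len(truth) if truth else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    return RecoveryScore(len(detected), len(truth), matched, precision, recall, f1)


def per_carrier_truth_intervals(truth: list[TruthRecord], kind: str) -> list[GenomicInterval]:
    """Expand truth records into one interval per carrier (label = sample id)."""
    out = []
    for t in truth:
        if t.kind != kind:
            continue
        for sid in t.carriers:
            out.append(GenomicInterval(t.interval.chrom, t.interval.start_bp,
                                       t.interval.end_bp, label=sid))
    return out
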