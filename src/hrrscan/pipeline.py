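"""Full-analysis orchestration from a single YAML config.

Stage graph (QC tiers are deliberately independent, mirroring the study
design): simulate/load -> qc1 -> runs -> islands (HRRI); qc1 -> hbd ->
islands (ROHI); qc2 -> tajima -> signals; islands + signals -> overlap
(hot spots, overlap records, ANOVA); qc2 -> fst.  Every stage writes TSV
artifacts into the output directory and records its parameters in
``provenance.json``; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .core import DependencyError, GenomicInterval, GenotypeMatrix
from .hbd import HbdModelSpec, call_hbd_segments, fit_mixing_em
from .islands import call_islands, islands_to_frame, snp_share_frequency
from .overlap import anova_by_factors, count_overlaps, hot_spots, pairwise_fst
from .qc import filter_call_rate, filter_maf, kinship_matrix, select_unrelated
from .runs import Run, RunParams, detect_runs, runs_to_frame, summarize_runs
from .selection import (
    signals_to_frame,
    threshold_signals,
    window_stats,
    window_stats_to_frame,
)
from .simulate import PlantedFeature, SimConfig, simulate_dataset, truth_to_frame

log = logging.getLogger("hrrscan")

ALL_STAGES = ("simulate", "qc", "runs", "hbd", "islands", "tajima", "overlap", "fst", "anova")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 7
    simulate: SimConfig | None = None
    ped: str | None = None
    map: str | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    hrr: dict[str, Any] = field(default_factory=dict)
    hbd: dict[str, Any] = field(default_factory=dict)
    islands: dict[str, Any] = field(default_factory=dict)
    tajima: dict[str, Any] = field(default_factory=dict)
    hotspots: dict[str, Any] = field(default_factory=dict)
    factors: str | None = None  # path to a breed->factor TSV

    @classmethod
    def from_yaml(cls, path: str | os.PathLike, output_dir: str | None = None,
                  seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.pop("schema", None)
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if cfg.factors is not None and not os.path.isabs(cfg.factors):
            # resolve relative to the config file so runs work from any cwd
            candidate = Path(path).resolve().parent / cfg.factors
            if not Path(cfg.factors).exists() and candidate.exists():
                cfg.factors = str(candidate)
            else:
                parent = Path(path).resolve().parent.parent / cfg.factors
                if not Path(cfg.factors).exists() and parent.exists():
                    cfg.factors = str(parent)
        if output_dir is not None:
            cfg.output_dir = output_dir
        if seed is not None:
            cfg.seed = seed
        if sim is not None:
            feats = tuple(PlantedFeature(**f) for f in sim.pop("features", []))
            sim.setdefault("seed", cfg.seed)
            sim["chromosomes"] = tuple(sim.get("chromosomes", (25_000_000, 25_000_000)))
            cfg.simulate = SimConfig(features=feats, **sim)
        return cfg


def _intervals_from_frame(df: pd.DataFrame, start_col: str, end_col: str,
                          one_based: bool = True) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for _, r in df.iterrows():
        s = int(r[start_col]) + (0 if one_based else 1)
        out.setdefault(str(r["breed"]), []).append(
            GenomicInterval(str(r["chrom"]), s, int(r[end_col]))
        )
    return out


class Pipeline:
    """Stateful driver; stages reload artifacts from the output directory."""

    def __init__(self, config: PipelineConfig):
        self.cfg = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.provenance: dict[str, Any] = {"seed": config.seed, "stages": {}}

    # -- artifact plumbing ----------------------------------------------
    def _path(self, name: str) -> Path:
        return self.out / name

    def _require(self, name: str, stage: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise DependencyError(f"stage '{stage}' needs missing artifact {name}; "
                                  f"run its upstream stage first")
        return p

    def _genotypes(self, tier: str, stage: str) -> GenotypeMatrix:
        ped = self._require(f"{tier}.ped", stage)
        return gio.read_ped_map(ped, self._require(f"{tier}.map", stage))

    def _record(self, stage: str, **params: Any) -> None:
        self.provenance["stages"][stage] = params
        with open(self._path("provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    # -- stages ----------------------------------------------------------
    def stage_simulate(self) -> None:
        if self.cfg.simulate is None:
            raise DependencyError("stage 'simulate' requested without a simulate block")
        G, truth = simulate_dataset(self.cfg.simulate)
        gio.write_ped_map(G, self._path("sim.ped"), self._path("sim.map"))
        gio.write_tsv(truth_to_frame(truth), self._path("truth.tsv"))
        self._record("simulate", **{k: v for k, v in asdict(self.cfg.simulate).items()})
        log.info("simulate: %d samples x %d markers", G.n_samples, G.n_markers)

    def _input_genotypes(self, stage: str) -> GenotypeMatrix:
        if self.cfg.ped and self.cfg.map:
            return gio.read_ped_map(self.cfg.ped, self.cfg.map)
        return self._genotypes("sim", stage)

    def stage_qc(self) -> None:
        G = self._input_genotypes("qc")
        q = self.cfg.qc
        G1, rep1 = filter_call_rate(
            G, q.get("max_missing_marker", 0.10), q.get("max_missing_sample", 0.10)
        )
        per_breed_n = q.get("per_breed_n", 20)
        if (G1.samples.groupby("breed").size() > per_breed_n).any():
            K = kinship_matrix(G1)
            keep = select_unrelated(K, G1.samples, per_breed_n)
            idx = [i for i, s in enumerate(G1.samples["sample_id"]) if s in set(keep)]
            G1 = G1.subset_samples(idx)
        gio.write_ped_map(G1, self._path("qc1.ped"), self._path("qc1.map"))
        G2, rep2 = filter_maf(G1, q.get("min_maf", 0.01))
        gio.write_ped_map(G2, self._path("qc2.ped"), self._path("qc2.map"))
        gio.write_tsv(
            pd.concat([rep1.to_frame().assign(tier="qc1"), rep2.to_frame().assign(tier="qc2")]),
            self._path("qc_report.tsv"),
        )
        self._record("qc", **q)
        log.info("qc: %d -> qc1 %d -> qc2 %d markers", G.n_markers, G1.n_markers, G2.n_markers)

    def stage_runs(self) -> None:
        G = self._genotypes("qc1", "runs")
        params = RunParams(run_type="HRR", **self.cfg.hrr)
        runs = detect_runs(G, params)
        gio.write_tsv(runs_to_frame(runs, G.samples), self._path("runs.tsv"))
        gio.write_tsv(summarize_runs(runs, G), self._path("summaries.tsv"))
        self._record("runs", **asdict(params))
        log.info("runs: %d HRRs detected", len(runs))

    def stage_hbd(self) -> None:
        G = self._genotypes("qc1", "hbd")
        h = dict(self.cfg.hbd)
        threshold = h.pop("threshold", 0.5)
        em_tol = h.pop("em_tol", 1e-6)
        em_max_iter = h.pop("em_max_iter", 200)
        if "rates" in h:
            h["hbd_rates"] = tuple(h.pop("rates"))
        spec = HbdModelSpec(**h)
        segments: list[Run] = []
        for breed in G.breeds:
            Gb = G.breed_view(breed)
            _, gammas = fit_mixing_em(Gb, spec, tol=em_tol, max_iter=em_max_iter)
            for sid, per_chrom in gammas.items():
                for chrom, post in per_chrom.items():
                    idx = Gb.chrom_marker_index(chrom)
                    pos = Gb.markers["bp"].to_numpy()[idx]
                    segments.extend(call_hbd_segments(post, pos, chrom, sid, threshold))
        gio.write_tsv(runs_to_frame(segments, G.samples), self._path("hbd_segments.tsv"))
        self._record("hbd", threshold=threshold, em_tol=em_tol,
                     em_max_iter=em_max_iter, **asdict(spec))
        log.info("hbd: %d HBD segments called", len(segments))

    def _island_pass(self, G: GenotypeMatrix, runs_df: pd.DataFrame, run_type: str):
        from .runs import Run as RunRec
        islands = []
        for breed in G.breeds:
            Gb = G.breed_view(breed)
            sub = runs_df[runs_df["breed"] == breed]
            runs = [RunRec(str(r.sample_id), str(r.chrom), int(r.start_bp), int(r.end_bp),
                           int(r.n_snp), int(r.n_opposite), int(r.n_missing), str(r.run_type))
                    for r in sub.itertuples()]
            profile = snp_share_frequency(runs, Gb, run_type)
            islands.extend(call_islands(profile, Gb, **self.cfg.islands))
        return islands

    def stage_islands(self) -> None:
        G = self._genotypes("qc1", "islands")
        runs_df = gio.read_tsv(self._require("runs.tsv", "islands"))
        islands = self._island_pass(G, runs_df, "HRR")
        if self._path("hbd_segments.tsv").exists():
            islands += self._island_pass(G, gio.read_tsv(self._path("hbd_segments.tsv")), "ROH")
        df = islands_to_frame(islands)
        gio.write_tsv(df, self._path("islands.tsv"))
        gio.write_intervals_bed(
            [GenomicInterval(i.chrom, i.start_bp, i.end_bp, f"{i.breed}:{i.island_type}")
             for i in islands],
            self._path("islands.bed"),
        )
        self._record("islands", percentile_unit="per-SNP sharing frequencies, "
                     "genome-wide per breed (zeros included)", **self.cfg.islands)
        log.info("islands: %d called (%d HRRI)", len(islands),
                 int((df["island_type"] == "HRRI").sum()) if len(df) else 0)

    def stage_tajima(self) -> None:
        G = self._genotypes("qc2", "tajima")
        window_bp = self.cfg.tajima.get("window_bp", 250_000)
        top_fraction = self.cfg.tajima.get("top_fraction", 0.001)
        stats, signals = [], []
        for breed in G.breeds:
            ws = window_stats(G.breed_view(breed), window_bp)
            stats.extend(ws)
            signals.extend(threshold_signals(ws, top_fraction))
        gio.write_tsv(window_stats_to_frame(stats), self._path("windows.tsv"))
        gio.write_tsv(signals_to_frame(signals), self._path("signals.tsv"))
        gio.write_intervals_bed([s.interval for s in signals], self._path("signals.bed"))
        self._record("tajima", window_bp=window_bp, top_fraction=top_fraction)
        log.info("tajima: %d windows, %d signals", len(stats), len(signals))

    def stage_overlap(self) -> None:
        from .islands import Island
        from .selection import SelectionSignal

        idf = gio.read_tsv(self._require("islands.tsv", "overlap"))
        sdf = gio.read_tsv(self._require("signals.tsv", "overlap"))
        z_crit = self.cfg.hotspots.get("z_crit", 1.645)
        hrri = idf[idf["island_type"] == "HRRI"]
        spots_tables = {}
        for name, df, sc, ec, ob in (
            ("hrri", hrri, "start_bp", "end_bp", True),
            ("signal", sdf, "window_start", "window_end", False),
        ):
            feats = _intervals_from_frame(df, sc, ec, one_based=ob) if len(df) else {}
            if sum(1 for v in feats.values() if v) >= 2:
                spots_tables[name] = hot_spots(feats, z_crit)
            else:
                spots_tables[name] = []
        rows = []
        for name, spots in spots_tables.items():
            for hs in spots:
                rows.append((name, hs.chrom, hs.start_bp, hs.end_bp, hs.k,
                             hs.z, hs.significant, ",".join(sorted(hs.supporting_breeds))))
        hs_df = pd.DataFrame(rows, columns=["feature", "chrom", "start_bp", "end_bp",
                                            "k", "z", "significant", "breeds"])
        gio.write_tsv(hs_df, self._path("hotspots.tsv"))
        gio.write_intervals_bed(
            [GenomicInterval(r.chrom, int(r.start_bp), int(r.end_bp), f"{r.feature}:k={r.k}")
             for r in hs_df[hs_df["significant"]].itertuples()],
            self._path("hotspots.bed"),
        )
        islands = [Island(str(r.breed), str(r.chrom), int(r.start_bp), int(r.end_bp),
                          int(r.n_snp), float(r.threshold), float(r.peak_frequency),
                          str(r.island_type))
                   for r in hrri.itertuples()]
        signals = [SelectionSignal(str(r.breed), str(r.chrom), int(r.window_start),
                                   int(r.window_end) - int(r.window_start), float(r.D))
                   for r in sdf.itertuples()]
        recs = count_overlaps(islands, signals)
        gio.write_tsv(
            pd.DataFrame(
                [(r.breed, r.island.chrom, r.island.start_bp, r.island.end_bp,
                  r.signal.window_start, r.signal.window_start + r.signal.window_bp,
                  r.overlap_bp) for r in recs],
                columns=["breed", "chrom", "island_start", "island_end",
                         "signal_start", "signal_end", "overlap_bp"],
            ),
            self._path("overlaps.tsv"),
        )
        self._record("overlap", z_crit=z_crit, overlap_mode="same-breed",
                     hotspot_unit="sweep-line constant-coverage regions")
        log.info("overlap: %d island x signal overlaps", len(recs))

    def stage_anova(self) -> None:
        if self.cfg.factors is None:
            log.info("anova: no factor table configured; skipping")
            return
        hs = gio.read_tsv(self._require("hotspots.tsv", "anova"))
        factor_table = gio.read_tsv(self.cfg.factors)
        from .overlap import HotSpot
        rows = []
        for feature in hs["feature"].unique():
            sub = hs[hs["feature"] == feature]
            regions = [HotSpot(str(r.chrom), int(r.start_bp), int(r.end_bp),
                               frozenset(str(r.breeds).split(",")), int(r.k),
                               float(r.z) if pd.notna(r.z) else float("nan"),
                               bool(r.significant))
                       for r in sub.itertuples()]
            for res in anova_by_factors(regions, factor_table):
                rows.append((feature, res.factor, res.F, res.p, res.r_squared,
                             res.n_groups, res.n))
        gio.write_tsv(
            pd.DataFrame(rows, columns=["feature", "factor", "F", "p", "r_squared",
                                        "n_groups", "n"]),
            self._path("anova.tsv"),
        )
        self._record("anova", response="region breed-sharing count per (breed, region) "
                     "incidence (interpretive coding)")

    def stage_fst(self) -> None:
        G = self._genotypes("qc2", "fst")
        M = pairwise_fst(G)
        M.to_frame().to_csv(self._path("fst.tsv"), sep="\t", na_rep=".")
        self._record("fst", estimator="Weir-Cockerham 1984, ratio of sums")
        log.info("fst: %d x %d matrix", len(M.breeds), len(M.breeds))

    STAGE_FN = {
        "simulate": stage_simulate, "qc": stage_qc, "runs": stage_runs,
        "hbd": stage_hbd, "islands": stage_islands, "tajima": stage_tajima,
        "overlap": stage_overlap, "anova": stage_anova, "fst": stage_fst,
    }

    def run(self, stages: list[str] | None = None) -> Path:
        stages = list(stages) if stages else list(ALL_STAGES)
        if self.cfg.simulate is None and "simulate" in stages:
            stages.remove("simulate")
        for st in ALL_STAGES:
            if st in stages:
                log.info("=== stage %s ===", st)
                self.STAGE_FN[st](self)
        return self.out


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> Path:
    return Pipeline(config).run(stages)
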