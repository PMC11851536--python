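"""PLINK PED/MAP and BED/BIM/FAM readers, plus interval/table writers.

Allele coding is deterministic: for text input, allele A is the first
non-missing allele encountered in file order at each marker; for binary
input, PLINK's A1 maps to code 0 and A2 to code 2.  The orientation is
immaterial downstream (every statistic here is symmetric in allele label)
but is fixed so that round trips are byte-stable.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    DataError,
    FormatError,
    GenomicInterval,
    GenotypeMatrix,
    make_marker_map,
    make_sample_table,
)

_BED_MAGIC = b"\x6c\x1b"


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Sort markers by (chrom, bp) with a stable natural-ish chromosome order."""

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    order = sorted(
        range(len(markers)),
        key=lambda i: (chrom_key(markers["chrom"].iat[i]), int(markers["bp"].iat[i])),
    )
    order = np.asarray(order, dtype=int)
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


def read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 MAP fields")
            rows.append((fields[0], fields[1], int(fields[3])))
    return make_marker_map(
        marker_id=[r[1] for r in rows],
        chrom=[r[0] for r in rows],
        bp=[r[2] for r in rows],
    )


def read_ped_map(ped_path: str | os.PathLike, map_path: str | os.PathLike) -> GenotypeMatrix:
    """Read text PLINK data; samples keep the PED FID as their breed label."""
    markers = read_map(map_path)
    m = len(markers)
    sample_ids: list[str] = []
    breeds: list[str] = []
    allele_a: list[str | None] = [None] * m
    allele_b: list[str | None] = [None] * m
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} markers), found {len(fields)}"
                )
            breeds.append(fields[0])
            sample_ids.append(fields[1])
            g = np.full(m, MISSING, dtype=np.int8)
            for j in range(m):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    continue
                code = 0
                for al in (a1, a2):
                    if allele_a[j] is None:
                        allele_a[j] = al
                    if al == allele_a[j]:
                        continue
                    if allele_b[j] is None:
                        allele_b[j] = al
                    if al != allele_b[j]:
                        raise DataError(
                            f"{ped_path}: line {lineno}: marker {markers['marker_id'].iat[j]} "
                            f"has >2 distinct alleles"
                        )
                    code += 1
                g[j] = code
            rows.append(g)
    markers = markers.assign(
        allele_a=[a if a is not None else "A" for a in allele_a],
        allele_b=[b if b is not None else "B" for b in allele_b],
    )
    calls = np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    markers, calls = _sort_markers(markers, calls)
    return GenotypeMatrix(make_sample_table(sample_ids, breeds), markers, calls)


# PLINK 1 BED: 2 bits per call, samples packed LSB-first within each byte.
_BED_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)  # 00, 01, 10, 11


def read_bed_bim_fam(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> GenotypeMatrix:
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        if header[:2] != _BED_MAGIC:
            raise FormatError(f"{bed_path}: not a PLINK 1 BED file (bad magic bytes)")
        if header[2] != 0x01:
            raise FormatError(f"{bed_path}: unsupported mode byte {header[2]:#04x} (need SNP-major 0x01)")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bpm = (n + 3) // 4  # bytes per marker
    if data.size != bpm * m:
        raise FormatError(
            f"{bed_path}: truncated: {data.size} data bytes, expected {bpm * m}"
        )
    mat = data.reshape(m, bpm)
    # expand each byte into 4 two-bit codes, LSB-first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (mat[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpm * 4)[:, :n]
    calls = _BED_CODE[codes].T.copy()  # -> (n_samples, n_markers)
    markers = make_marker_map(
        marker_id=bim["marker_id"],
        chrom=bim["chrom"],
        bp=bim["bp"].astype(int),
        allele_a=bim["a1"],
        allele_b=bim["a2"],
    )
    markers, calls = _sort_markers(markers, calls)
    return GenotypeMatrix(make_sample_table(fam["iid"], fam["fid"]), markers, calls)


def write_ped_map(
    G: GenotypeMatrix, ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> None:
    """Write text PLINK files (breed as FID); inverse of :func:`read_ped_map`."""
    mk = G.markers
    with open(map_path, "w") as fh:
        for _, r in mk.iterrows():
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.bp}\n")
    a = mk["allele_a"].to_numpy()
    b = mk["allele_b"].to_numpy()
    pair = {0: lambda j: (a[j], a[j]), 1: lambda j: (a[j], b[j]), 2: lambda j: (b[j], b[j])}
    with open(ped_path, "w") as fh:
        for i in range(G.n_samples):
            row = [G.samples["breed"].iat[i], G.samples["sample_id"].iat[i], "0", "0", "0", "-9"]
            g = G.calls[i]
            for j in range(G.n_markers):
                if g[j] == MISSING:
                    row += ["0", "0"]
                else:
                    row += list(pair[int(g[j])](j))
            fh.write(" ".join(row) + "\n")


def write_bed_bim_fam(
    G: GenotypeMatrix,
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> None:
    """Write PLINK 1 binary (SNP-major); inverse of :func:`read_bed_bim_fam`."""
    with open(bim_path, "w") as fh:
        for _, r in G.markers.iterrows():
            fh.write(f"{r.chrom}\t{r.marker_id}\t0\t{r.bp}\t{r.allele_a}\t{r.allele_b}\n")
    with open(fam_path, "w") as fh:
        for _, r in G.samples.iterrows():
            fh.write(f"{r.breed}\t{r.sample_id}\t0\t0\t0\t-9\n")
    n = G.n_samples
    bpm = (n + 3) // 4
    inv = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        for j in range(G.n_markers):
            buf = bytearray(bpm)
            for i in range(n):
                buf[i // 4] |= inv[int(G.calls[i, j])] << (2 * (i % 4))
            fh.write(bytes(buf))


def write_intervals_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED3+ (0-based half-open), sorted by (chrom, start)."""

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    ordered = sorted(intervals, key=lambda iv: (chrom_key(iv.chrom), iv.start_bp))
    with open(path, "w") as fh:
        for iv in ordered:
            line = f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}"
            if iv.label:
                line += f"\t{iv.label}"
            fh.write(line + "\n")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Result-table convention: tab-separated, header row, '.' for undefined."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str, "breed": str})
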