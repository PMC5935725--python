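"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open; BED/bedGraph are already
in that convention, GTF (1-based closed) is converted on input.  All readers
and writers are gzip-transparent (a ``.gz`` suffix triggers compression).

bedGraph is written with zero-coverage regions made explicit (no gaps), so a
re-read track has an unambiguous genome-wide mean; adjacent equal-value bins
are merged into one interval and values carry 6 significant digits.
"""

from __future__ import annotations

import gzip
import logging
import math
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd

from .model import (
    CalibrationTable,
    ExpressionTable,
    GenePartition,
    GeneRecord,
    GenomeModel,
    SignalTrack,
)

log = logging.getLogger("chipquant")

BEDGRAPH_SIGFIGS = 6


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if "w" in mode:
        path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


# ---------------------------------------------------------------------------
# annotation

def read_annotation(
    path: str | Path,
    fmt: str = "bed12",
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeModel:
    """Parse gene annotation (BED6/BED12 or minimal GTF) into a GenomeModel.

    BED may carry 6 or 12 columns; with 12, the exonic length is the sum of
    block sizes, otherwise the body length.  GTF needs ``gene`` features with a
    ``gene_id`` attribute; 1-based closed coordinates are converted to 0-based
    half-open.  If ``chrom_sizes`` is omitted it is inferred as each
    chromosome's maximum gene end.
    """
    if fmt == "bed12":
        genes = list(_parse_bed_genes(path))
    elif fmt == "gtf":
        genes = list(_parse_gtf_genes(path))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeModel(chrom_sizes=dict(chrom_sizes), genes=genes)


def _parse_bed_genes(path: str | Path) -> Iterator[GeneRecord]:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED gene line needs >= 6 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                if len(f) >= 12:
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    exonic = sum(sizes)
                else:
                    exonic = end - start
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            yield GeneRecord(name, chrom, strand, start, end, exonic)


def _parse_gtf_genes(path: str | Path) -> Iterator[GeneRecord]:
    bodies: dict[str, list] = {}
    exon_bp: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GTF line needs 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = f[:9]
            try:
                start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            if feature == "gene":
                bodies[gid] = [chrom, strand, start, end]
            elif feature == "exon":
                exon_bp[gid] = exon_bp.get(gid, 0) + (end - start)
    for gid, (chrom, strand, start, end) in bodies.items():
        yield GeneRecord(gid, chrom, strand, start, end, exon_bp.get(gid, end - start))


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part[len(key) :].strip().strip('"')
    return None


def write_annotation(genome: GenomeModel, path: str | Path) -> None:
    """Write genes as BED12 (single block spanning the body; thickStart=start)."""
    with _open_text(path, "wt") as fh:
        for g in genome.genes:
            blocks = f"1\t{g.end - g.start},\t0,"
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{g.start}\t{g.end}\t0\t{blocks}\n"
            )


# ---------------------------------------------------------------------------
# reads

def read_reads(
    path: str | Path,
    genome: GenomeModel | None = None,
    on_unknown_chrom: str = "error",
) -> pd.DataFrame:
    """Read a >= 3-column BED of read intervals into a (chrom, start, end) frame.

    With a genome given, intervals are validated against chromosome bounds;
    reads on unknown chromosomes either raise or are skipped with a warning
    (``on_unknown_chrom='skip'``).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"chrom": str, "start": np.int64, "end": np.int64}
        )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: intervals must satisfy 0 <= start < end")
    if genome is not None:
        known = df["chrom"].isin(genome.chrom_sizes)
        if not known.all():
            bad = sorted(df.loc[~known, "chrom"].unique())
            if on_unknown_chrom == "skip":
                log.warning("%s: skipping %d reads on unknown chromosomes %s",
                            path, int((~known).sum()), bad)
                df = df[known].reset_index(drop=True)
            else:
                raise ValueError(f"{path}: unknown chromosomes {bad}")
        sizes = df["chrom"].map(genome.chrom_sizes)
        if (df["end"] > sizes).any():
            raise ValueError(f"{path}: read interval beyond chromosome end")
    log.info("%s: %d read intervals", path, len(df))
    return df


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    """Write read intervals as 6-column BED (name '.', score 0, strand '+')."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end in reads[["chrom", "start", "end"]].itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t+\n")


# ---------------------------------------------------------------------------
# tracks (bedGraph)

def write_track(track: SignalTrack, path: str | Path) -> None:
    """Write a binned track as bedGraph, merging runs of equal value.

    Values are rounded to 6 significant digits; zero bins are written
    explicitly so the file covers every base of every chromosome.
    """
    with _open_text(path, "wt") as fh:
        fh.write(f"#bin_size={track.bin_size}\n")
        for chrom in track.values:
            v = track.values[chrom]
            rounded = np.array([_sigfig(x) for x in v])
            if v.size == 0:
                continue
            run_start = 0
            for i in range(1, v.size + 1):
                if i == v.size or rounded[i] != rounded[run_start]:
                    gstart = run_start * track.bin_size
                    gend = i * track.bin_size
                    fh.write(f"{chrom}\t{gstart}\t{gend}\t{rounded[run_start]:.6g}\n")
                    run_start = i


def _sigfig(x: float, n: int = BEDGRAPH_SIGFIGS) -> float:
    if x == 0 or not math.isfinite(x):
        return 0.0 if x == 0 else x
    return float(f"{x:.{n}g}")


def read_track(path: str | Path, chrom_sizes: dict[str, int] | None = None,
               bin_size: int | None = None) -> SignalTrack:
    """Read a bedGraph written by :func:`write_track` back into a SignalTrack.

    The bin size is taken from the ``#bin_size=`` header unless overridden.
    Interval bounds must align to the bin grid.
    """
    header_bin: int | None = None
    rows: list[tuple[str, int, int, float]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#bin_size="):
                    header_bin = int(line.split("=", 1)[1])
                continue
            if line.startswith(("track", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            rows.append((chrom, int(s), int(e), float(v)))
    bs = bin_size or header_bin
    if bs is None:
        raise ValueError(f"{path}: bin size unknown (no #bin_size header)")
    ends: dict[str, int] = {}
    for chrom, s, e, v in rows:
        ends[chrom] = max(ends.get(chrom, 0), e)
    if chrom_sizes is None:
        chrom_sizes = ends
    values = {
        c: np.zeros(-(-chrom_sizes[c] // bs), dtype=float) for c in chrom_sizes
    }
    for chrom, s, e, v in rows:
        if s % bs or (e % bs and e != chrom_sizes.get(chrom, e)):
            raise ValueError(f"{path}: interval [{s},{e}) not aligned to bin size {bs}")
        values[chrom][s // bs : -(-e // bs)] = v
    return SignalTrack(bin_size=bs, values=values)


# ---------------------------------------------------------------------------
# chromosome sizes

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, size), the UCSC chrom.sizes convention."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": np.int64})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# calibration

def read_calibration(path: str | Path) -> CalibrationTable:
    """Read the Western-blot global-level table (TSV: sample_id, mark, global_level)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "mark": str})
    return CalibrationTable(df)


def write_calibration(calib: CalibrationTable, path: str | Path) -> None:
    calib.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression tables and partitions

def read_expression(path: str | Path,
                    library_sizes: dict[str, int] | None = None) -> ExpressionTable:
    """Read a counts TSV (gene_id, exonic_length_bp, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return ExpressionTable(df, library_sizes)


def write_expression(expr: ExpressionTable, path: str | Path) -> None:
    expr.df.to_csv(path, sep="\t", index_label="gene_id")


def read_library_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "library_size": np.int64})
    return dict(zip(df["sample_id"], df["library_size"].astype(int)))


def write_library_sizes(sizes: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sizes), "library_size": list(sizes.values())}
    ).to_csv(path, sep="\t", index=False)


def write_partition(part: GenePartition, path: str | Path) -> None:
    """Serialize a partition as two-column TSV (gene_id, set), sorted for determinism."""
    with _open_text(path, "wt") as fh:
        fh.write("gene_id\tset\n")
        for name in part.sets:
            for gid in sorted(part.sets[name]):
                fh.write(f"{gid}\t{name}\n")


def read_partition(path: str | Path, scheme: str = "") -> GenePartition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets: dict[str, set[str]] = {}
    for gid, name in zip(df["gene_id"], df["set"]):
        sets.setdefault(name, set()).add(gid)
    return GenePartition(scheme=scheme or str(path), sets=sets)
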