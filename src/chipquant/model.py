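"""Shared data model for the quantitative ChIP-seq / RNA-seq pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)``.  The TSS of a
minus-strand gene is ``end - 1`` (the last base of the interval), so that the
TSS is always the first transcribed base.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GenomeModel",
    "SignalTrack",
    "CalibrationTable",
    "ExpressionTable",
    "GenePartition",
    "SelectivityRanking",
    "ProfileMatrix",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene: body interval, strand and exonic length."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int
    end: int
    exonic_length_bp: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.exonic_length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: exonic length must be positive")

    @property
    def tss(self) -> int:
        """First transcribed base: ``start`` on +, ``end - 1`` on - strand."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene annotation."""

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(
                    f"gene {g.gene_id}: end {g.end} beyond {g.chrom} length {size}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class SignalTrack:
    """Fixed-bin signal over a genome for one sample.

    ``values[chrom]`` has length ``ceil(chrom_size / bin_size)``; the last bin
    may cover a partial window.  Units are arbitrary for raw coverage and
    dimensionless "normalized intensity" after unit-mean scaling.

    ``reads_per_bin`` records the sequencing depth (mean mapped reads per bin)
    of the library the track came from; the Poisson input-subtraction step uses
    it to convert unit-mean intensities back into read-count units.
    """

    bin_size: int
    values: dict[str, np.ndarray]
    sample_id: str = ""
    mark: str = ""
    condition: str = ""
    units: str = "coverage"
    reads_per_bin: float | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if v.ndim != 1:
                raise ValueError(f"{c}: track values must be 1-D")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{c}: non-finite track values")

    @property
    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def mean(self) -> float:
        """Genome-wide mean intensity over all bins."""
        n = self.n_bins
        if n == 0:
            raise ValueError("empty track")
        return self.total() / n

    def same_grid(self, other: "SignalTrack") -> bool:
        return self.bin_size == other.bin_size and {
            c: v.size for c, v in self.values.items()
        } == {c: v.size for c, v in other.values.items()}

    def replace(self, **kw) -> "SignalTrack":
        return dataclasses.replace(self, **kw)


@dataclass
class CalibrationTable:
    """Per-sample global modification levels relative to a reference sample.

    This is the quantitative Western-blot measurement: for each histone mark,
    one sample is the reference (level 1.0) and every other sample's level is
    its global amount of the mark relative to that reference.
    """

    table: pd.DataFrame  # columns: sample_id, mark, global_level

    REQUIRED = ("sample_id", "mark", "global_level")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"calibration table missing columns: {missing}")
        if t.duplicated(["sample_id", "mark"]).any():
            raise ValueError("duplicate (sample_id, mark) rows in calibration table")
        if not (t["global_level"] > 0).all():
            raise ValueError("global_level must be > 0")
        for mark, grp in t.groupby("mark"):
            n_ref = int(np.isclose(grp["global_level"], 1.0).sum())
            if n_ref < 1:
                raise ValueError(
                    f"mark {mark!r}: needs a reference sample with global_level = 1"
                )

    def level(self, sample_id: str, mark: str) -> float:
        sel = self.table[
            (self.table["sample_id"] == sample_id) & (self.table["mark"] == mark)
        ]
        if sel.empty:
            raise KeyError(f"no calibration row for sample {sample_id!r}, mark {mark!r}")
        return float(sel["global_level"].iloc[0])


class ExpressionTable:
    """Gene-level counts with exonic lengths, library sizes and derived RPKM.

    Wraps a DataFrame indexed by gene_id with an ``exonic_length_bp`` column
    and one integer count column per sample.  ``library_sizes`` maps sample to
    total mapped reads; it must be at least the column sum of counts (mapped
    reads include reads outside annotated genes).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        library_sizes: Mapping[str, int] | None = None,
    ) -> None:
        if "exonic_length_bp" not in counts.columns:
            raise ValueError("expression table needs an exonic_length_bp column")
        if not (counts["exonic_length_bp"] > 0).all():
            raise ValueError("exonic lengths must be positive")
        samples = [c for c in counts.columns if c != "exonic_length_bp"]
        if not samples:
            raise ValueError("expression table has no sample columns")
        cnt = counts[samples]
        if (cnt.values < 0).any():
            raise ValueError("counts must be non-negative")
        if library_sizes is None:
            library_sizes = {s: int(cnt[s].sum()) for s in samples}
        for s in samples:
            lib = int(library_sizes[s])
            if lib <= 0:
                raise ValueError(f"sample {s}: library size must be positive")
            if lib < cnt[s].sum():
                raise ValueError(f"sample {s}: library size below the column count sum")
        self.df = counts.copy()
        self.samples = samples
        self.library_sizes = {s: int(library_sizes[s]) for s in samples}
        self._rpkm: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def lengths(self) -> pd.Series:
        return self.df["exonic_length_bp"]

    @property
    def counts(self) -> pd.DataFrame:
        return self.df[self.samples]

    @property
    def rpkm(self) -> pd.DataFrame:
        if self._rpkm is None:
            raise AttributeError("RPKM not computed yet; call compute_rpkm first")
        return self._rpkm

    def set_rpkm(self, rpkm: pd.DataFrame) -> None:
        self._rpkm = rpkm


@dataclass
class GenePartition:
    """Named disjoint gene sets produced by one classification rule."""

    scheme: str
    sets: dict[str, set[str]]
    params: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self.sets[a] & self.sets[b]
                if inter:
                    raise ValueError(
                        f"partition {self.scheme!r}: sets {a!r} and {b!r} overlap "
                        f"({len(inter)} genes)"
                    )

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


@dataclass
class SelectivityRanking:
    """Genes ranked by log2 fold change between two conditions.

    ``table`` columns: log2fc, rank (1 = most A-selective), selected
    ("A", "B" or "").  Ordering is strict: (log2fc desc, gene_id asc).
    """

    cond_a: str
    cond_b: str
    n_top: int
    table: pd.DataFrame

    def selected(self, direction: str) -> list[str]:
        if direction not in ("A", "B"):
            raise ValueError("direction must be 'A' or 'B'")
        sel = self.table[self.table["selected"] == direction]
        return list(sel.index)


@dataclass
class ProfileMatrix:
    """Per-gene signal around the TSS on a shared, strand-flipped offset axis.

    Offsets are profile-bin centers in bases relative to the TSS; positive is
    downstream in the direction of transcription, so +/- strand rows share one
    axis.  ``groups`` maps each retained gene to its group label.
    """

    offsets: np.ndarray
    gene_ids: list[str]
    matrix: np.ndarray  # genes x offsets
    groups: dict[str, str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), self.offsets.size):
            raise ValueError("profile matrix shape does not match genes x offsets")
        if not np.allclose(self.offsets, -self.offsets[::-1]):
            raise ValueError("offsets must be symmetric about 0")

    def group_curve(self, group: str) -> np.ndarray:
        rows = [i for i, g in enumerate(self.gene_ids) if self.groups.get(g) == group]
        if not rows:
            raise ValueError(f"empty group {group!r}")
        return self.matrix[rows].mean(axis=0)
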