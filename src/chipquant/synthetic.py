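"""Synthetic genomes, ChIP/input reads and expression tables with planted truth.

The generator emulates, at toy scale, the design of a quantitative
histone-methylation study of adipogenesis: two conditions (WT and a
dominant-negative mutant) with

* ChIP read sets for two histone marks where the mutant's mark is globally
  depleted by a known factor — the situation that defeats per-sample
  unit-mean normalization and motivates Western-blot calibration;
* gene-body enrichment domains and an optional TSS-proximal enrichment;
* a four-sample expression design (WT/MUT x D0/D2) with a planted fraction of
  induced genes, a planted subset of which fail to be induced in the mutant
  ("sensitive" genes).

Everything is driven by one integer seed through independent, label-keyed
substreams, so simulating one sample never perturbs another.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ExpressionTable, GenePartition, GeneRecord, GenomeModel

log = logging.getLogger("chipquant")

__all__ = [
    "SyntheticSpec",
    "ChipTruth",
    "make_genome",
    "simulate_chip_reads",
    "simulate_input_reads",
    "simulate_expression",
    "write_spec",
    "read_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Fractions are of the relevant parent set (``sensitive_fraction`` is a
    fraction of the induced genes).  ``global_depletion`` multiplies the
    mutant condition's expected ChIP rate for ``depleted_mark`` uniformly
    across the genome; 1.0 means no global change.  ``noise_sigma`` is the
    standard deviation of log-normal multiplicative noise on expression;
    0 gives the noiseless mode used for exact-recovery tests.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    bin_size: int = 200
    enrichment_domains: tuple[tuple[float, float], ...] = ((0.1, 4.0),)
    global_depletion: float = 0.3
    background_rate: float = 5.0
    n_induced_fraction: float = 0.2
    sensitive_fraction: float = 0.5
    seed: int = 0
    # free simulation choices (no values are dictated by the study design)
    read_length: int = 50
    gene_length_min: int = 3_000
    gene_length_max: int = 8_000
    depleted_mark: str = "H3K36me2"
    tss_fold: float = 1.0
    tss_halfwidth: int = 500
    induced_fold: float = 4.0
    mutant_fold: float = 1.0
    noise_sigma: float = 0.1
    library_size: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("n_induced_fraction", "sensitive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for frac, fold in self.enrichment_domains:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"enrichment domain fraction {frac} outside [0, 1]")
            if fold <= 0:
                raise ValueError(f"enrichment fold must be > 0, got {fold}")
        if self.global_depletion <= 0:
            raise ValueError("global_depletion must be > 0")
        if self.chrom_length % self.bin_size:
            raise ValueError("chrom_length must be divisible by bin_size")
        if self.n_chroms < 1 or self.n_genes < 0:
            raise ValueError("need n_chroms >= 1 and n_genes >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 0 < self.gene_length_min <= self.gene_length_max:
            raise ValueError("need 0 < gene_length_min <= gene_length_max")


def _rng(spec: SyntheticSpec, label: str) -> np.random.Generator:
    """Independent substream keyed by (seed, label) — stable across runs."""
    return np.random.default_rng([spec.seed, zlib.crc32(label.encode())])


@dataclass
class ChipTruth:
    """Ground truth accompanying one simulated ChIP read set."""

    mark: str
    condition: str
    global_factor: float
    enriched_genes: dict[float, list[str]]  # fold -> gene ids


# ---------------------------------------------------------------------------
# genome

def make_genome(spec: SyntheticSpec) -> GenomeModel:
    """Place non-overlapping genes on ``n_chroms`` equal-length chromosomes.

    Genes are dealt round-robin across chromosomes; within each chromosome
    their order along the sequence is random but overlap-free.  Strands
    alternate so both are always represented.  Raises if the requested genes
    cannot fit.
    """
    rng = _rng(spec, "genome")
    chrom_sizes = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chroms)}
    chroms = list(chrom_sizes)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(spec.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1

    genes: list[GeneRecord] = []
    idx = 0
    for chrom in chroms:
        n = per_chrom[chrom]
        if n == 0:
            continue
        lengths = rng.integers(spec.gene_length_min, spec.gene_length_max + 1, size=n)
        slack = spec.chrom_length - int(lengths.sum())
        if slack < n + 1:
            raise ValueError(
                f"{chrom}: cannot place {n} genes of total length {int(lengths.sum())} "
                f"in {spec.chrom_length} bp without overlap"
            )
        # random gap sizes summing to the slack, one gap before each gene
        cuts = np.sort(rng.choice(slack, size=n, replace=False))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 0
        for j in range(n):
            start = pos + int(gaps[j])
            end = start + int(lengths[j])
            strand = "+" if idx % 2 == 0 else "-"
            exonic = max(1, int(round((end - start) * rng.uniform(0.4, 0.9))))
            genes.append(GeneRecord(f"gene{idx:04d}", chrom, strand, start, end, exonic))
            pos = end
            idx += 1
    return GenomeModel(chrom_sizes=chrom_sizes, genes=genes)


# ---------------------------------------------------------------------------
# ChIP and input reads

def enriched_gene_sets(genome: GenomeModel, spec: SyntheticSpec,
                       mark: str) -> dict[float, list[str]]:
    """Assign enrichment domains to gene subsets, per mark, deterministically.

    The same genes are enriched in every condition so that the planted global
    depletion is the only between-condition difference.
    """
    rng = _rng(spec, f"domains:{mark}")
    ids = np.array(genome.gene_ids)
    free = np.arange(ids.size)
    out: dict[float, list[str]] = {}
    for frac, fold in spec.enrichment_domains:
        k = int(round(frac * ids.size))
        k = min(k, free.size)
        pick = rng.choice(free, size=k, replace=False) if k else np.array([], dtype=int)
        out[float(fold)] = sorted(ids[pick])
        free = np.setdiff1d(free, pick)
    return out


def _bin_rates(genome: GenomeModel, spec: SyntheticSpec,
               enriched: dict[float, list[str]]) -> dict[str, np.ndarray]:
    """Expected reads per bin before any global factor: background x plants."""
    n_bins = spec.chrom_length // spec.bin_size
    rates = {c: np.full(n_bins, spec.background_rate, dtype=float)
             for c in genome.chrom_sizes}
    by_id = {g.gene_id: g for g in genome.genes}
    for fold, gids in enriched.items():
        for gid in gids:
            g = by_id[gid]
            b0, b1 = g.start // spec.bin_size, -(-g.end // spec.bin_size)
            rates[g.chrom][b0:b1] *= fold
    if spec.tss_fold != 1.0:
        for g in genome.genes:
            lo = max(0, g.tss - spec.tss_halfwidth)
            hi = min(genome.chrom_sizes[g.chrom], g.tss + spec.tss_halfwidth + 1)
            b0, b1 = lo // spec.bin_size, -(-hi // spec.bin_size)
            rates[g.chrom][b0:b1] *= spec.tss_fold
    return rates


def _reads_from_rates(rates: dict[str, np.ndarray], spec: SyntheticSpec,
                      rng: np.random.Generator) -> pd.DataFrame:
    frames = []
    for chrom, lam in rates.items():
        counts = rng.poisson(lam)
        bins = np.repeat(np.arange(lam.size), counts)
        offsets = rng.integers(0, spec.bin_size, size=bins.size)
        starts = bins * spec.bin_size + offsets
        ends = np.minimum(starts + spec.read_length, lam.size * spec.bin_size)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def simulate_chip_reads(genome: GenomeModel, spec: SyntheticSpec,
                        mark: str, condition: str) -> tuple[pd.DataFrame, ChipTruth]:
    """Poisson reads for one (mark, condition) ChIP sample plus ground truth.

    The mutant condition (``condition == "MUT"``) of ``spec.depleted_mark``
    has every bin's expected rate multiplied by ``spec.global_depletion``;
    all other samples keep factor 1.  Returns the reads and a
    :class:`ChipTruth` holding the true global factor and enriched gene sets.
    """
    enriched = enriched_gene_sets(genome, spec, mark)
    rates = _bin_rates(genome, spec, enriched)
    factor = (spec.global_depletion
              if condition == "MUT" and mark == spec.depleted_mark else 1.0)
    rates = {c: v * factor for c, v in rates.items()}
    rng = _rng(spec, f"chip:{mark}:{condition}")
    reads = _reads_from_rates(rates, spec, rng)
    return reads, ChipTruth(mark, condition, factor, enriched)


def simulate_input_reads(genome: GenomeModel, spec: SyntheticSpec) -> pd.DataFrame:
    """Uniform Poisson background reads — the sequencing 'input' control."""
    n_bins = spec.chrom_length // spec.bin_size
    rates = {c: np.full(n_bins, spec.background_rate, dtype=float)
             for c in genome.chrom_sizes}
    return _reads_from_rates(rates, spec, _rng(spec, "input"))


# ---------------------------------------------------------------------------
# expression

EXPR_SAMPLES = ("WT_D0", "WT_D2", "MUT_D0", "MUT_D2")


def simulate_expression(genome: GenomeModel,
                        spec: SyntheticSpec) -> tuple[ExpressionTable, GenePartition]:
    """Four-sample expression with planted induced and sensitive genes.

    Induced genes rise ``induced_fold``-fold (>= 2) from D0 to D2 in WT; the
    sensitive subset instead changes only ``mutant_fold``-fold (< 2) in the
    mutant, while resistant induced genes rise as in WT.  Baseline abundance
    is log-uniform over 1-100 RPKM; with ``noise_sigma > 0`` each measurement
    gets independent log-normal noise.  Counts are rounded from expected RPKM
    at the spec's library size and exonic lengths.

    Returns the table and the truth partition with sets ``sensitive``,
    ``resistant`` and ``not_induced`` (induced = sensitive + resistant).
    """
    n = len(genome.genes)
    n_ind = int(round(spec.n_induced_fraction * n))
    if n and spec.n_induced_fraction > 0 and n_ind == 0:
        warnings.warn("n_induced_fraction * n_genes < 1: planting zero induced genes")
    n_sens = int(round(spec.sensitive_fraction * n_ind))
    rng = _rng(spec, "expression")
    ids = np.array(genome.gene_ids)
    induced_idx = np.sort(rng.choice(n, size=n_ind, replace=False)) if n_ind else np.array([], dtype=int)
    sens_idx = np.sort(rng.choice(induced_idx, size=n_sens, replace=False)) if n_sens else np.array([], dtype=int)
    induced = set(ids[induced_idx])
    sensitive = set(ids[sens_idx])
    resistant = induced - sensitive

    base = 10.0 ** rng.uniform(0.0, 2.0, size=n)  # baseline RPKM, 1-100
    fold_wt = np.where(np.isin(ids, list(induced)), spec.induced_fold, 1.0)
    fold_mut = np.where(np.isin(ids, list(sensitive)), spec.mutant_fold, fold_wt)
    expected = {
        "WT_D0": base,
        "WT_D2": base * fold_wt,
        "MUT_D0": base,
        "MUT_D2": base * fold_mut,
    }

    lengths = np.array([g.exonic_length_bp for g in genome.genes], dtype=np.int64)
    counts = {}
    for s in EXPR_SAMPLES:
        rpkm = expected[s]
        if spec.noise_sigma > 0:
            rpkm = rpkm * rng.lognormal(0.0, spec.noise_sigma, size=n)
        counts[s] = np.round(
            rpkm * (lengths / 1_000.0) * (spec.library_size / 1e6)
        ).astype(np.int64)

    df = pd.DataFrame({"exonic_length_bp": lengths, **counts},
                      index=pd.Index(ids, name="gene_id"))
    table = ExpressionTable(df, {s: spec.library_size for s in EXPR_SAMPLES})
    truth = GenePartition(
        scheme="truth",
        sets={
            "sensitive": sensitive,
            "resistant": resistant,
            "not_induced": set(ids) - induced,
        },
        params={
            "n_induced_fraction": spec.n_induced_fraction,
            "sensitive_fraction": spec.sensitive_fraction,
            "induced_fold": spec.induced_fold,
            "mutant_fold": spec.mutant_fold,
            "noise_sigma": spec.noise_sigma,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# spec round-trip

def write_spec(spec: SyntheticSpec, path: str | Path) -> None:
    d = asdict(spec)
    d["enrichment_domains"] = [list(t) for t in spec.enrichment_domains]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def read_spec(path: str | Path) -> SyntheticSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["enrichment_domains"] = tuple(tuple(t) for t in d["enrichment_domains"])
    return SyntheticSpec(**d)
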