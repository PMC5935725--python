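"""Quantitative ChIP-seq signal chain.

The chain runs in a fixed order on binned coverage tracks:

1. ``compute_coverage`` — per-bin mean read coverage (bin_size=1 reproduces
   per-nucleotide coverage);
2. ``scale_to_unit_mean`` — rescale so the genome-wide mean intensity is
   exactly 1, removing sequencing-depth differences (and, with it, any real
   global difference between samples);
3. ``subtract_input`` — remove background using a Poisson model of the input:
   per bin, the upper (1 - p_upper) Poisson quantile of the depth-matched
   input rate is subtracted and the result floored at 0;
4. ``apply_global_calibration`` — multiply by the sample's Western-blot global
   modification level, restoring true between-sample global differences: a
   calibrated track's genome-wide mean equals its global level.

Summaries: per-gene body means, strand-flipped TSS metagene profiles, and the
pointwise ratio of two marks' profile curves (H3K36me2/H3K27me3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CalibrationTable, GenePartition, GenomeModel, ProfileMatrix, SignalTrack

log = logging.getLogger("chipquant")

__all__ = [
    "SubtractionParams",
    "compute_coverage",
    "scale_to_unit_mean",
    "subtract_input",
    "apply_global_calibration",
    "gene_body_signal",
    "tss_profile",
    "ratio_profile",
]


@dataclass(frozen=True)
class SubtractionParams:
    """Poisson background-subtraction settings.

    ``p_upper`` is the tail probability of the Poisson bound: the subtracted
    background is the smallest integer k with CDF(k; lambda) >= 1 - p_upper.
    ``floor`` is the minimum output intensity (0: tracks stay non-negative).
    """

    p_upper: float = 0.001
    floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_upper < 1.0:
            raise ValueError("p_upper must be in (0, 1)")


def compute_coverage(reads: pd.DataFrame, genome: GenomeModel,
                     bin_size: int = 200) -> SignalTrack:
    """Bin read coverage: value of bin b = overlapping read bases / bin_size.

    Computed exactly via a per-base difference array, so aggregating the
    bin_size=1 track to size k equals computing at k directly.  The returned
    track records ``reads_per_bin`` (total reads / total bins) for later
    depth-matching in the Poisson subtraction.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    values: dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        n_bins = -(-size // bin_size)
        diff = np.zeros(size + 1, dtype=float)
        sel = reads[reads["chrom"] == chrom]
        if len(sel):
            starts = sel["start"].to_numpy()
            ends = np.minimum(sel["end"].to_numpy(), size)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
        per_base = np.cumsum(diff[:-1])
        padded = np.zeros(n_bins * bin_size)
        padded[:size] = per_base
        values[chrom] = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    unknown = set(reads["chrom"]) - set(genome.chrom_sizes)
    if unknown:
        raise ValueError(f"reads on chromosomes absent from genome: {sorted(unknown)}")
    n_bins_total = sum(v.size for v in values.values())
    return SignalTrack(
        bin_size=bin_size, values=values, units="coverage",
        reads_per_bin=len(reads) / n_bins_total if n_bins_total else None,
    )


def scale_to_unit_mean(track: SignalTrack) -> SignalTrack:
    """Rescale so the genome-wide mean intensity equals 1.

    Multiplies every bin by (number of bins / total signal); relative bin
    ratios are untouched.  An all-zero track has no defined scaling.
    """
    total = track.total()
    if total <= 0:
        raise ValueError("cannot unit-mean scale an all-zero track")
    factor = track.n_bins / total
    out = {c: v * factor for c, v in track.values.items()}
    log.info("scale_to_unit_mean[%s]: factor %.6g", track.sample_id or "-", factor)
    return track.replace(values=out, units="normalized intensity")


def subtract_input(chip: SignalTrack, input_: SignalTrack,
                   params: SubtractionParams = SubtractionParams(),
                   chip_depth: float | None = None) -> SignalTrack:
    """Subtract input background from a ChIP track under a Poisson model.

    Both tracks must be on the same bin grid and unit-mean scaled.  The input
    intensity is rescaled to the ChIP library's depth (``chip_depth`` reads
    per bin, default the chip track's recorded ``reads_per_bin``), giving a
    Poisson rate lambda per bin.  The background estimate is the upper
    (1 - p_upper) quantile u(lambda) — the smallest integer k whose Poisson
    CDF reaches 1 - p_upper — converted back to intensity units and
    subtracted; output is floored at ``params.floor``.
    """
    if not chip.same_grid(input_):
        raise ValueError("chip and input tracks are on different bin grids")
    for t, name in ((chip, "chip"), (input_, "input")):
        if any((v < 0).any() for v in t.values.values()):
            raise ValueError(f"{name} track has negative values")
    depth = chip_depth if chip_depth is not None else chip.reads_per_bin
    if depth is None or depth <= 0:
        raise ValueError("chip depth (reads per bin) unknown; pass chip_depth")
    if input_.total() == 0:
        warnings.warn("input track is all zero; treating background as lambda=0 "
                      "everywhere (no subtraction)")
    q = 1.0 - params.p_upper
    out: dict[str, np.ndarray] = {}
    for chrom, chip_v in chip.values.items():
        lam = input_.values[chrom] * depth
        u = stats.poisson.ppf(q, lam)  # 0 where lam == 0
        out[chrom] = np.maximum(chip_v - u / depth, params.floor)
    return chip.replace(values=out)


def apply_global_calibration(track: SignalTrack, calib: CalibrationTable,
                             sample_id: str | None = None,
                             mark: str | None = None) -> SignalTrack:
    """Multiply a unit-mean track by its Western-blot global level.

    After calibration the genome-wide mean equals the sample's global
    modification level, so between-sample comparisons reflect true global
    differences; the reference sample (level 1) is unchanged.
    """
    sid = sample_id if sample_id is not None else track.sample_id
    mk = mark if mark is not None else track.mark
    level = calib.level(sid, mk)
    out = {c: v * level for c, v in track.values.items()}
    log.info("apply_global_calibration[%s/%s]: level %.6g", sid, mk, level)
    return track.replace(values=out, units="calibrated intensity")


def gene_body_signal(track: SignalTrack, genome: GenomeModel) -> pd.Series:
    """Mean calibrated intensity over each gene body [start, end).

    Bins partially overlapping a body edge contribute proportionally to their
    overlap, so the result equals the per-base mean over the body.
    """
    bs = track.bin_size
    out = {}
    for g in genome.genes:
        if g.chrom not in track.values:
            raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom!r} not in track")
        v = track.values[g.chrom]
        b0, b1 = g.start // bs, -(-g.end // bs)
        bins = np.arange(b0, b1)
        ov = (np.minimum(g.end, (bins + 1) * bs)
              - np.maximum(g.start, bins * bs)).astype(float)
        out[g.gene_id] = float((v[b0:b1] * ov).sum() / (g.end - g.start))
    return pd.Series(out, name="mean_intensity")


def tss_profile(
    track: SignalTrack,
    genome: GenomeModel,
    window: int = 2_500,
    step: int = 50,
    groups: GenePartition | dict[str, str] | None = None,
) -> tuple[ProfileMatrix, dict[str, pd.Series]]:
    """Strand-flipped metagene profile around the TSS.

    Offsets are the centers of 2*window/step profile bins, symmetric about 0;
    positive offsets are downstream in the direction of transcription.  Each
    profile value is the track intensity of the genome bin containing the
    offset position.  Genes whose window crosses a chromosome boundary are
    dropped (their count is recorded on the matrix).  Returns the per-gene
    matrix and one mean curve per group; a named error is raised for a group
    with no retained genes.
    """
    if window % step:
        raise ValueError("window must be a multiple of step")
    if isinstance(groups, GenePartition):
        gmap = {gid: name for name, gids in groups.sets.items() for gid in gids}
        requested = set(groups.sets)
    elif groups is None:
        gmap = {g.gene_id: "all" for g in genome.genes}
        requested = {"all"}
    else:
        gmap = dict(groups)
        requested = set(gmap.values())

    offsets = np.arange(-window, window, step) + step / 2.0
    rows, kept = [], []
    n_dropped = 0
    for g in genome.genes:
        if g.gene_id not in gmap:
            continue
        direction = 1 if g.strand == "+" else -1
        pos = np.floor(g.tss + direction * offsets).astype(np.int64)
        size = genome.chrom_sizes[g.chrom]
        if pos.min() < 0 or pos.max() >= size:
            n_dropped += 1
            continue
        rows.append(track.values[g.chrom][pos // track.bin_size])
        kept.append(g.gene_id)
    if n_dropped:
        log.info("tss_profile: dropped %d genes with windows beyond chromosome ends",
                 n_dropped)
    matrix = np.array(rows) if rows else np.empty((0, offsets.size))
    pm = ProfileMatrix(offsets=offsets, gene_ids=kept, matrix=matrix,
                       groups={gid: gmap[gid] for gid in kept}, n_dropped=n_dropped)
    present = set(pm.groups.values())
    curves: dict[str, pd.Series] = {}
    for name in sorted(requested):
        if name not in present:
            raise ValueError(f"group {name!r} has no genes with a complete TSS window")
        curves[name] = pd.Series(pm.group_curve(name), index=offsets, name=name)
    return pm, curves


def ratio_profile(me2_curve: pd.Series, me3_curve: pd.Series,
                  epsilon: float = 0.01) -> pd.Series:
    """Pointwise ratio of two profile curves: me2 / (me3 + epsilon).

    ``epsilon`` guards near-zero denominators; with calibrated tracks whose
    genome mean is of order 1, the default 0.01 is 1% of a typical level.
    The curves must share the same offset axis.
    """
    if not me2_curve.index.equals(me3_curve.index):
        raise ValueError("profile curves have mismatched offsets")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    out = me2_curve / (me3_curve + epsilon)
    out.name = f"ratio(eps={epsilon:g})"
    return out
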