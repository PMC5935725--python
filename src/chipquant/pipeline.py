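"""End-to-end orchestration: config, staged runs, manifest, and the demo.

A run is driven by one YAML config (validated strictly — unknown keys are
errors so a typo in a threshold never passes silently).  Every numeric factor
applied to the data (scaling factors, calibration levels, p_upper, thresholds,
dropped-gene counts) is recorded in a JSON manifest, and outputs are written
atomically so a crashed run never leaves half-written files.  Reruns with the
same config and inputs are bit-identical.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import chip, expression as expr_mod, io as cq_io, synthetic
from .model import CalibrationTable, SignalTrack

log = logging.getLogger("chipquant")

__all__ = [
    "RunConfig",
    "StageError",
    "load_config",
    "save_config",
    "run_chip_pipeline",
    "run_expression_pipeline",
    "make_demo",
    "setup_logging",
]


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Console + optional file logging for pipeline runs."""
    log.setLevel(level)
    have = {getattr(h, "_cq_tag", None) for h in log.handlers}
    if "console" not in have:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        h._cq_tag = "console"  # type: ignore[attr-defined]
        log.addHandler(h)
    if logfile is not None:
        h = logging.FileHandler(logfile)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        h._cq_tag = "file"  # type: ignore[attr-defined]
        log.addHandler(h)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input provenance."""

    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


class ChipSampleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_id: str
    mark: str
    condition: str
    reads: str


class ExpressionDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control_from: str = "WT_D0"
    control_to: str = "WT_D2"
    mutant_from: str = "MUT_D0"
    mutant_to: str = "MUT_D2"


class SelectivityDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cond_a: str
    cond_b: str
    extra_contrasts: list[tuple[str, str]] = Field(default_factory=list)


class RunConfig(BaseModel):
    """Full run configuration; round-trips losslessly through YAML."""

    model_config = ConfigDict(extra="forbid")

    outdir: str
    seed: int = 0
    # ChIP parameters
    bin_size: int = Field(200, ge=1)
    p_upper: float = Field(0.001, gt=0, lt=1)
    window: int = Field(2_500, ge=1)
    step: int = Field(50, ge=1)
    # expression parameters
    threshold: float = Field(2.0, gt=1)
    pseudocount: float = Field(0.5, ge=0)
    top_n: int = Field(1_000, ge=1)
    sensitivity_rule: str = "mutant_fold"
    # inputs
    annotation: str | None = None
    annotation_format: str = "bed12"
    chrom_sizes: str | None = None
    chip_samples: list[ChipSampleConfig] = Field(default_factory=list)
    input_reads: str | None = None
    calibration: str | None = None
    ratio_marks: tuple[str, str] | None = None
    groups: str | None = None
    counts: str | None = None
    library_sizes: str | None = None
    expression_design: ExpressionDesign = Field(default_factory=ExpressionDesign)
    selectivity: SelectivityDesign | None = None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with _atomic(path) as tmp:
        with open(tmp, "w") as fh:
            yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)


class _atomic:
    """Write to <path>.tmp, then rename into place on success."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        self.tmp = self.path.with_name(self.path.name + ".tmp")

    def __enter__(self) -> Path:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        return self.tmp

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is None:
            os.replace(self.tmp, self.path)
        elif self.tmp.exists():
            self.tmp.unlink()


def _write_json(obj: Any, path: str | Path) -> None:
    with _atomic(path) as tmp:
        with open(tmp, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: str | Path, **kw) -> None:
    with _atomic(path) as tmp:
        df.to_csv(tmp, sep="\t", float_format="%.6g", **kw)


# ---------------------------------------------------------------------------
# ChIP pipeline

def run_chip_pipeline(config: RunConfig) -> dict[str, Any]:
    """coverage -> unit-mean scaling -> Poisson subtraction -> calibration.

    Writes calibrated bedGraph tracks, per-gene body means, grouped TSS
    profile curves, the me2/me3 ratio curves when both marks are present, and
    a manifest of every factor applied.
    """
    out = Path(config.outdir)
    manifest: dict[str, Any] = {
        "bin_size": config.bin_size, "p_upper": config.p_upper,
        "window": config.window, "step": config.step, "samples": {},
    }
    try:
        if config.annotation is None:
            raise ValueError("config.annotation is required")
        sizes = (cq_io.read_chrom_sizes(config.chrom_sizes)
                 if config.chrom_sizes else None)
        genome = cq_io.read_annotation(config.annotation, config.annotation_format,
                                       chrom_sizes=sizes)
    except Exception as exc:
        raise StageError("annotation", f"{config.annotation}: {exc}") from exc

    try:
        if config.input_reads is None:
            raise ValueError("config.input_reads is required")
        input_reads = cq_io.read_reads(config.input_reads, genome)
        input_track = chip.scale_to_unit_mean(
            chip.compute_coverage(input_reads, genome, config.bin_size))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", f"{config.input_reads}: {exc}") from exc

    try:
        if config.calibration is None:
            raise ValueError("config.calibration is required")
        calib = cq_io.read_calibration(config.calibration)
    except Exception as exc:
        raise StageError("calibrate", f"{config.calibration}: {exc}") from exc

    params = chip.SubtractionParams(p_upper=config.p_upper)
    groups = cq_io.read_partition(config.groups, "groups") if config.groups else None
    tracks: dict[str, SignalTrack] = {}
    curves_by_sample: dict[str, dict[str, pd.Series]] = {}
    genebody = pd.DataFrame(index=pd.Index(genome.gene_ids, name="gene_id"))
    for sc in config.chip_samples:
        stage = f"chip:{sc.sample_id}"
        try:
            reads = cq_io.read_reads(sc.reads, genome)
            cov = chip.compute_coverage(reads, genome, config.bin_size)
            scaled = chip.scale_to_unit_mean(cov).replace(
                sample_id=sc.sample_id, mark=sc.mark, condition=sc.condition)
            sub = chip.subtract_input(scaled, input_track, params)
            cal = chip.apply_global_calibration(sub, calib)
            tracks[sc.sample_id] = cal
            cq_io.write_track(cal, out / "tracks" / f"{sc.sample_id}.bedgraph")
            genebody[sc.sample_id] = chip.gene_body_signal(cal, genome)
            pm, curves = chip.tss_profile(cal, genome, config.window,
                                          config.step, groups)
            curves_by_sample[sc.sample_id] = curves
            _write_tsv(pd.DataFrame(curves),
                       out / "profiles" / f"{sc.sample_id}.tsv", index_label="offset")
            manifest["samples"][sc.sample_id] = {
                "mark": sc.mark, "condition": sc.condition,
                "n_reads": int(len(reads)),
                "reads_per_bin": cov.reads_per_bin,
                "scaling_factor": cov.n_bins / cov.total(),
                "calibration_level": calib.level(sc.sample_id, sc.mark),
                "p_upper": config.p_upper,
                "profile_genes_dropped": pm.n_dropped,
            }
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, f"{sc.reads}: {exc}") from exc

    _write_tsv(genebody, out / "genebody.tsv", index_label="gene_id")

    ratios: dict[str, pd.Series] = {}
    if config.ratio_marks is not None:
        num_mark, den_mark = config.ratio_marks
        by_cond: dict[str, dict[str, str]] = {}
        for sc in config.chip_samples:
            by_cond.setdefault(sc.condition, {})[sc.mark] = sc.sample_id
        for cond, marks in sorted(by_cond.items()):
            if num_mark in marks and den_mark in marks:
                try:
                    num = curves_by_sample[marks[num_mark]]
                    den = curves_by_sample[marks[den_mark]]
                    cols = {g: chip.ratio_profile(num[g], den[g]) for g in num}
                    ratios[cond] = cols[next(iter(cols))]
                    _write_tsv(pd.DataFrame(cols),
                               out / "profiles" / f"ratio_{cond}.tsv",
                               index_label="offset")
                except Exception as exc:
                    raise StageError(f"ratio:{cond}", str(exc)) from exc
    manifest["ratio_epsilon"] = 0.01 if ratios else None
    _write_json(manifest, out / "chip_manifest.json")
    return {"genome": genome, "tracks": tracks, "genebody": genebody,
            "profiles": curves_by_sample, "ratios": ratios, "manifest": manifest}


# ---------------------------------------------------------------------------
# expression pipeline

def run_expression_pipeline(config: RunConfig) -> dict[str, Any]:
    """RPKM -> twofold calls -> sensitivity partition -> overlap -> selectivity.

    Writes the RPKM table, regulation and sensitivity partitions, Venn counts
    for control-course vs mutant-course up-regulation, the selectivity ranking
    and log2 fold-change heatmap matrix, and a summary with the percentage of
    genes called up and down.
    """
    out = Path(config.outdir)
    d = config.expression_design
    try:
        if config.counts is None:
            raise ValueError("config.counts is required")
        libs = (cq_io.read_library_sizes(config.library_sizes)
                if config.library_sizes else None)
        table = cq_io.read_expression(config.counts, libs)
        if len(table.df) == 0:
            raise ValueError("expression table has no genes")
        expr_mod.compute_rpkm(table)
    except Exception as exc:
        raise StageError("expression-load", f"{config.counts}: {exc}") from exc
    _write_tsv(table.rpkm, out / "rpkm.tsv", index_label="gene_id")

    try:
        reg = expr_mod.call_regulated(table, d.control_from, d.control_to,
                                      config.threshold, config.pseudocount)
        sens = expr_mod.partition_sensitivity(
            reg["up"], table, d.mutant_from, d.mutant_to,
            config.threshold, config.pseudocount, rule=config.sensitivity_rule,
            control_to=d.control_to)
        reg_mut = expr_mod.call_regulated(table, d.mutant_from, d.mutant_to,
                                          config.threshold, config.pseudocount)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    cq_io.write_partition(reg, out / "regulation_control.tsv")
    cq_io.write_partition(reg_mut, out / "regulation_mutant.tsv")
    cq_io.write_partition(sens, out / "sensitivity.tsv")

    venn = expr_mod.overlap(reg["up"], reg_mut["up"])
    _write_json({"a": f"up:{d.control_from}->{d.control_to}",
                 "b": f"up:{d.mutant_from}->{d.mutant_to}",
                 **venn.counts}, out / "venn.json")

    ranking = None
    heat = None
    if config.selectivity is not None:
        s = config.selectivity
        try:
            ranking = expr_mod.rank_selectivity(table, s.cond_a, s.cond_b,
                                                config.top_n, config.pseudocount)
            contrasts = [(s.cond_a, s.cond_b)] + [tuple(c) for c in s.extra_contrasts]
            heat = expr_mod.heatmap_matrix(table, contrasts, ranking,
                                           config.pseudocount)
        except Exception as exc:
            raise StageError("selectivity", str(exc)) from exc
        _write_tsv(ranking.table, out / "selectivity_ranking.tsv",
                   index_label="gene_id")
        _write_tsv(heat, out / "heatmap_matrix.tsv", index_label="gene_id")

    total = len(table.df)
    summary = {
        "n_genes": total,
        "regulation_percent": expr_mod.summarize_fractions(reg, total),
        "regulation_counts": reg.sizes(),
        "sensitivity_counts": sens.sizes(),
        "venn": venn.counts,
        "threshold": config.threshold,
        "pseudocount": config.pseudocount,
        "top_n": config.top_n if config.selectivity else None,
    }
    _write_json(summary, out / "expression_summary.json")
    return {"table": table, "regulation": reg, "regulation_mutant": reg_mut,
            "sensitivity": sens, "venn": venn, "ranking": ranking,
            "heatmap": heat, "summary": summary}


# ---------------------------------------------------------------------------
# demo

DEMO_SPEC = dict(
    n_chroms=2, chrom_length=500_000, n_genes=100, bin_size=200,
    enrichment_domains=((0.1, 4.0),), global_depletion=0.3, background_rate=5.0,
    n_induced_fraction=0.2, sensitive_fraction=0.5,
    tss_fold=2.0, tss_halfwidth=500, noise_sigma=0.1,
)

MARKS = ("H3K36me2", "H3K27me3")
CONDITIONS = ("WT", "MUT")


def make_demo(seed: int = 0, outdir: str | Path = "demo",
              figures: bool = True) -> dict[str, Any]:
    """Generate a synthetic study, run both pipelines, and plot key outputs.

    The workspace is self-contained: synthetic inputs under ``data/``,
    pipeline outputs under ``results/``, figures under ``figures/``.  The
    whole run is a deterministic function of ``seed``.
    """
    outdir = Path(outdir)
    data = outdir / "data"
    data.mkdir(parents=True, exist_ok=True)
    spec = synthetic.SyntheticSpec(seed=seed, **DEMO_SPEC)
    synthetic.write_spec(spec, data / "spec.yaml")

    genome = synthetic.make_genome(spec)
    cq_io.write_annotation(genome, data / "genes.bed")
    cq_io.write_chrom_sizes(genome.chrom_sizes, data / "chrom.sizes")

    calib_rows = []
    truths = {}
    for mark in MARKS:
        for cond in CONDITIONS:
            reads, truth = synthetic.simulate_chip_reads(genome, spec, mark, cond)
            sid = f"{cond}_{mark}"
            cq_io.write_reads(reads, data / f"{sid}.bed")
            truths[sid] = truth
            # the calibration table plays the Western blot: it reports the
            # true global level of each sample relative to the WT reference
            calib_rows.append({"sample_id": sid, "mark": mark,
                               "global_level": truth.global_factor})
    cq_io.write_calibration(CalibrationTable(pd.DataFrame(calib_rows)),
                            data / "calibration.tsv")
    input_reads = synthetic.simulate_input_reads(genome, spec)
    cq_io.write_reads(input_reads, data / "input.bed")

    table, truth_part = synthetic.simulate_expression(genome, spec)
    cq_io.write_expression(table, data / "counts.tsv")
    cq_io.write_library_sizes(table.library_sizes, data / "library_sizes.tsv")
    cq_io.write_partition(truth_part, data / "truth.tsv")

    config = RunConfig(
        outdir=str(outdir / "results"), seed=seed,
        bin_size=spec.bin_size, window=2_000, step=100, top_n=10,
        annotation=str(data / "genes.bed"), chrom_sizes=str(data / "chrom.sizes"),
        chip_samples=[
            ChipSampleConfig(sample_id=f"{cond}_{mark}", mark=mark,
                             condition=cond, reads=str(data / f"{cond}_{mark}.bed"))
            for mark in MARKS for cond in CONDITIONS
        ],
        input_reads=str(data / "input.bed"),
        calibration=str(data / "calibration.tsv"),
        ratio_marks=("H3K36me2", "H3K27me3"),
        counts=str(data / "counts.tsv"),
        library_sizes=str(data / "library_sizes.tsv"),
        selectivity=SelectivityDesign(
            cond_a="WT_D2", cond_b="MUT_D2",
            extra_contrasts=[("WT_D2", "WT_D0"), ("MUT_D2", "MUT_D0")]),
    )
    save_config(config, outdir / "config.yaml")

    chip_out = run_chip_pipeline(config)
    expr_out = run_expression_pipeline(config)
    if figures:
        _demo_figures(outdir, chip_out, expr_out)
    return {"spec": spec, "config": config, "truth": truth_part,
            "chip_truth": truths, "chip": chip_out, "expression": expr_out}


def _demo_figures(outdir: Path, chip_out: dict, expr_out: dict) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)

    # regulation + sensitivity counts
    fig, ax = plt.subplots(figsize=(5, 3.2))
    counts = {**expr_out["summary"]["regulation_counts"],
              **expr_out["summary"]["sensitivity_counts"]}
    ax.bar(range(len(counts)), list(counts.values()), color="#4878a8")
    ax.set_xticks(range(len(counts)), list(counts), rotation=30, ha="right")
    ax.set_ylabel("genes")
    ax.set_title("Twofold regulation calls and mutant sensitivity")
    fig.tight_layout()
    fig.savefig(figdir / "classification_counts.png", dpi=120)
    plt.close(fig)

    # Venn counts
    venn = expr_out["summary"]["venn"]
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for x, c in ((0.35, "#c44e52"), (0.65, "#55a868")):
        ax.add_patch(plt.Circle((x, 0.5), 0.3, alpha=0.4, color=c))
    ax.text(0.2, 0.5, str(venn["a_only"]), ha="center")
    ax.text(0.5, 0.5, str(venn["shared"]), ha="center")
    ax.text(0.8, 0.5, str(venn["b_only"]), ha="center")
    ax.text(0.25, 0.88, "control up", ha="center")
    ax.text(0.75, 0.88, "mutant up", ha="center")
    ax.set_axis_off()
    fig.savefig(figdir / "venn_up_regulated.png", dpi=120)
    plt.close(fig)

    # selectivity heatmap
    heat = expr_out["heatmap"]
    if heat is not None and len(heat):
        fig, ax = plt.subplots(figsize=(4, 5))
        im = ax.imshow(heat.values, aspect="auto", cmap="RdBu_r",
                       vmin=-3, vmax=3, interpolation="nearest")
        ax.set_xticks(range(heat.shape[1]), list(heat.columns),
                      rotation=30, ha="right")
        ax.set_ylabel("genes (ranked)")
        fig.colorbar(im, label="log2 fold change")
        fig.tight_layout()
        fig.savefig(figdir / "selectivity_heatmap.png", dpi=120)
        plt.close(fig)

    # TSS ratio curves per condition
    if chip_out["ratios"]:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for cond, curve in sorted(chip_out["ratios"].items()):
            ax.plot(curve.index, curve.values, label=cond)
        ax.set_xlabel("distance from TSS (bp)")
        ax.set_ylabel("H3K36me2 / H3K27me3")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "tss_ratio.png", dpi=120)
        plt.close(fig)
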