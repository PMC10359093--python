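"""End-to-end orchestration: walk -> (sweep) -> map -> compartments -> evaluate.

Every artifact written by a run carries a provenance sidecar embedding the
full configuration and input checksums, so a run can be reproduced or
resumed per chromosome.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import compartments, contact_map, dda_core, evaluation, sequence_walk, trackio
from .sequence_walk import InputError

__all__ = ["RunConfig", "run_predict", "run_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one end-to-end run."""

    fasta: str
    out_dir: str
    chip_bed: str | None = None
    exclude_bed: str | None = None
    reference_matrix: str | None = None  # dense TSV, for evaluation only
    bin_size: int = 100_000
    model_id: str = dda_core.DEFAULT_MODEL_ID
    tau1: int | None = None
    tau2: int | None = None
    tau_min: int = 1
    tau_max: int = 50
    sweep_region: str | None = None  # "chrom:start-end", 1-based inclusive
    derivative_halfwidth: int = 1
    standardize: bool = True
    pc_index: int | None = None
    seed: int = 0
    mode: str = "dda"
    resume: bool = False  # skip chromosomes whose outputs already exist

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                import yaml

                data = yaml.safe_load(fh)
            else:
                data = json.load(fh)
        return cls(**data)


def _model_by_id(model_id: str) -> dda_core.DDAModel:
    if model_id == dda_core.DEFAULT_MODEL_ID:
        return dda_core.default_model()
    for m in dda_core.enumerate_models():
        if m.id == model_id:
            return m
    raise InputError(f"unknown model id {model_id!r}")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive region string into 0-based half-open coords."""
    try:
        chrom, span = region.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        return chrom, int(lo) - 1, int(hi)
    except ValueError as exc:
        raise InputError(f"malformed region {region!r} (want chrom:start-end)") from exc


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _provenance(config: RunConfig, extra: dict) -> dict:
    prov = {"config": dataclasses.asdict(config)}
    for key in ("fasta", "chip_bed", "exclude_bed", "reference_matrix"):
        p = getattr(config, key)
        if p and Path(p).exists():
            prov[f"sha256_{key}"] = _checksum(p)
    prov.update(extra)
    return prov


def run_predict(config: RunConfig) -> dict:
    """Run the pipeline described by ``config``; returns a result summary.

    Writes, under ``config.out_dir``: per-chromosome normalized matrices,
    pc bedGraph + compartment BED tracks, an optional sweep grid, metric
    reports against the reference (if given) and provenance JSON.
    """
    for key in ("fasta",):
        p = getattr(config, key)
        if not p or not Path(p).exists():
            raise InputError(f"missing required input {key}={p!r}")
    if config.chip_bed is None and config.pc_index is None:
        raise InputError(
            "no ChIP BED and no pc_index given: PC orientation is impossible. "
            "Provide --chip peaks.bed or an explicit --pc-index."
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sequences = sequence_walk.read_fasta(config.fasta)
    bins_by_chrom = sequence_walk.make_bins(
        {c: len(s) for c, s in sequences.items()}, config.bin_size
    )
    exclude = sequence_walk.read_bed(config.exclude_bed) if config.exclude_bed else []
    walks_by_chrom: dict[str, list] = {}
    for chrom, bins in bins_by_chrom.items():
        sequence_walk.apply_exclusion(bins, exclude)
        walks_by_chrom[chrom] = sequence_walk.bin_walks(sequences, bins)

    peaks = sequence_walk.read_bed(config.chip_bed) if config.chip_bed else []
    chip_by_chrom = {
        chrom: compartments.chip_profile(peaks, bins)
        for chrom, bins in bins_by_chrom.items()
    }

    template = _model_by_id(config.model_id)
    pair = (config.tau1, config.tau2) if config.tau1 and config.tau2 else None
    sweep_summary = None
    if pair is None:
        from . import structure_selection

        if config.sweep_region is None or config.reference_matrix is None:
            raise InputError(
                "no delay pair given: need sweep_region and reference_matrix "
                "to run structure selection"
            )
        chrom, lo, hi = parse_region(config.sweep_region)
        bins = bins_by_chrom[chrom]
        sel = (bins.starts >= lo) & (bins.starts + config.bin_size <= hi)
        idx = np.where(sel)[0]
        sub_bins = sequence_walk.GenomicBins(
            chrom, config.bin_size, bins.starts[idx] - bins.starts[idx[0]],
            bins.mask[idx].copy(), int(len(idx) * config.bin_size),
        )
        sub_walks = [walks_by_chrom[chrom][i] for i in idx]
        ref_m = contact_map.read_matrix(config.reference_matrix, "tsv", kind="hic")
        ref_track = compartments.call(ref_m, chip_by_chrom[chrom], mode="hic")
        sub_chip = compartments.ChipProfile(
            chip_by_chrom[chrom].counts[idx], chip_by_chrom[chrom].mark
        )
        result = structure_selection.sweep(
            sub_walks, sub_bins, ref_track.pc[idx], sub_chip,
            tau_range=(config.tau_min, config.tau_max),
            w=config.derivative_halfwidth, standardize=config.standardize,
            model_template=template, region=config.sweep_region,
        )
        pair = result.best_pair
        sweep_summary = {"best_pair": list(pair), "best_score": result.best_score}
        with open(out_dir / "sweep.tsv", "w") as fh:
            fh.write("tau1\ttau2\tr\n")
            for t1, t2, r in result.to_rows():
                fh.write(f"{t1}\t{t2}\t{r!r}\n")

    model = template.with_delays(*pair)
    summary: dict = {"pair": list(pair), "model": model.id, "chromosomes": {}}
    if sweep_summary:
        summary["sweep"] = sweep_summary
    for chrom in sorted(bins_by_chrom):
        bins = bins_by_chrom[chrom]
        outputs = [
            out_dir / f"{chrom}.dda.tsv",
            out_dir / f"{chrom}.pc.bedgraph",
            out_dir / f"{chrom}.compartments.bed",
        ]
        if bins.mask.all():
            logger.warning("chromosome %s fully masked; skipped", chrom)
            summary["chromosomes"][chrom] = {"skipped": "all bins masked"}
            continue
        if config.resume and all(p.exists() for p in outputs):
            logger.info("chromosome %s: outputs exist, resumed", chrom)
            summary["chromosomes"][chrom] = {
                "resumed": True,
                "checksums": {p.name: _checksum(p) for p in outputs},
            }
            continue
        D = contact_map.build_dda_matrix(
            walks_by_chrom[chrom], model, bins,
            w=config.derivative_halfwidth, standardize=config.standardize,
        )
        N = contact_map.postprocess(D)
        contact_map.write_matrix(N, out_dir / f"{chrom}.dda.tsv", "tsv")
        track = compartments.call(
            N, chip_by_chrom[chrom], mode=config.mode, pc_index=config.pc_index
        )
        trackio.write_bedgraph(track, N.bins, out_dir / f"{chrom}.pc.bedgraph")
        trackio.write_compartment_bed(track, N.bins, out_dir / f"{chrom}.compartments.bed")
        summary["chromosomes"][chrom] = {
            "pc_index": track.pc_index,
            "orientation_r": track.orientation_r,
            "n_masked": int(track.mask.sum()),
            "checksums": {p.name: _checksum(p) for p in outputs},
        }
    prov = _provenance(config, {"summary": summary})
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
    return summary


def run_report(metric_reports: dict[str, evaluation.MetricReport]) -> dict:
    """Aggregate per-chromosome metric reports into a summary table.

    Returns {"per_chromosome": {...}, "mean": {...}, "variance": {...}} with
    the mean and population variance across chromosomes per metric, the way
    genome-wide performance tables are shaped.
    """
    out: dict = {"per_chromosome": {}, "mean": {}, "variance": {}}
    if not metric_reports:
        return out
    metrics = ("r_pc", "auc", "acc", "f1")
    for chrom, rep in metric_reports.items():
        out["per_chromosome"][chrom] = rep.to_dict()
    for m in metrics:
        vals = np.array([getattr(rep, m) for rep in metric_reports.values()], dtype=float)
        vals = vals[np.isfinite(vals)]
        out["mean"][m] = float(vals.mean()) if len(vals) else float("nan")
        out["variance"][m] = float(vals.var()) if len(vals) else float("nan")
    return out
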