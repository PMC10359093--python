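"""Exhaustive delay-pair sweep (structure selection) and genome-wide apply.

Unlike iteratively trained models, the model structure is fixed and only
its delay pair is selected: every (tau1 < tau2) pair in the configured
range is scored by the absolute Pearson correlation between the
sequence-derived compartment track and a reference track on a training
region, and the argmax pair is applied to the rest of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import compartments, contact_map, dda_core
from .compartments import ChipProfile, CompartmentTrack
from .sequence_walk import GenomicBins, InputError

__all__ = ["SweepResult", "sweep", "apply_model", "score_pair"]

logger = logging.getLogger(__name__)

MIN_SWEEP_BINS = 10


@dataclass
class SweepResult:
    """Score grid over delay pairs plus the winning pair."""

    grid: dict[tuple[int, int], float]
    best_pair: tuple[int, int]
    best_score: float
    region: str = ""

    def to_rows(self) -> list[tuple[int, int, float]]:
        return [(t1, t2, r) for (t1, t2), r in sorted(self.grid.items())]


def _reference_values(reference_pc) -> np.ndarray:
    if isinstance(reference_pc, CompartmentTrack):
        return reference_pc.pc
    return np.asarray(reference_pc, dtype=float)


def score_pair(
    walks,
    bins: GenomicBins,
    tau1: int,
    tau2: int,
    reference_pc,
    chip: ChipProfile,
    w: int = 1,
    standardize: bool = True,
    model_template: dda_core.DDAModel | None = None,
) -> float:
    """|Pearson r| between the track called for one delay pair and the reference."""
    template = model_template if model_template is not None else dda_core.default_model()
    model = template.with_delays(tau1, tau2)
    D = contact_map.build_dda_matrix(walks, model, bins, w=w, standardize=standardize)
    N = contact_map.postprocess(D)
    track = compartments.call(N, chip, mode="dda")
    ref = _reference_values(reference_pc)
    both = np.isfinite(track.pc) & np.isfinite(ref)
    if both.sum() < 3 or track.pc[both].std() == 0 or ref[both].std() == 0:
        return float("nan")
    return float(abs(np.corrcoef(track.pc[both], ref[both])[0, 1]))


def sweep(
    walks,
    bins: GenomicBins,
    reference_pc,
    chip: ChipProfile,
    tau_range: tuple[int, int] = (1, 50),
    w: int = 1,
    standardize: bool = True,
    model_template: dda_core.DDAModel | None = None,
    region: str = "",
) -> SweepResult:
    """Score every unordered delay pair on the training region.

    The winner is the pair with the highest |r|; ties break to the smallest
    tau1, then tau2 (guaranteed by in-order iteration and strict >).
    """
    n_unmasked = int((~bins.mask).sum())
    if n_unmasked < MIN_SWEEP_BINS:
        raise InputError(
            f"training region has only {n_unmasked} unmasked bins "
            f"(need >= {MIN_SWEEP_BINS})"
        )
    pairs = dda_core.enumerate_delay_pairs(*tau_range)
    grid: dict[tuple[int, int], float] = {}
    best_pair = pairs[0]
    best_score = -np.inf
    for t1, t2 in pairs:
        score = score_pair(
            walks, bins, t1, t2, reference_pc, chip,
            w=w, standardize=standardize, model_template=model_template,
        )
        grid[(t1, t2)] = score
        if np.isfinite(score) and score > best_score:
            best_score = score
            best_pair = (t1, t2)
    if not np.isfinite(best_score):
        best_score = float("nan")
    logger.info("sweep best pair %s with |r|=%.4f", best_pair, best_score)
    return SweepResult(grid=grid, best_pair=best_pair, best_score=best_score, region=region)


def apply_model(
    walks_by_chrom: dict[str, list],
    bins_by_chrom: dict[str, GenomicBins],
    pair: tuple[int, int],
    chip_by_chrom: dict[str, ChipProfile],
    w: int = 1,
    standardize: bool = True,
    model_template: dda_core.DDAModel | None = None,
    pc_index: int | None = None,
) -> dict[str, CompartmentTrack]:
    """Run the full per-chromosome pipeline with a selected delay pair."""
    template = model_template if model_template is not None else dda_core.default_model()
    model = template.with_delays(*pair)
    tracks: dict[str, CompartmentTrack] = {}
    for chrom in sorted(walks_by_chrom):
        bins = bins_by_chrom[chrom]
        if bins.mask.all():
            logger.warning("chromosome %s: all bins masked; emitting empty track", chrom)
            tracks[chrom] = CompartmentTrack(
                pc=np.full(bins.n_bins, np.nan),
                label=np.array([""] * bins.n_bins),
                display=np.full(bins.n_bins, np.nan),
                pc_index=0,
                orientation_r=float("nan"),
                mask=np.ones(bins.n_bins, dtype=bool),
                bins=bins,
            )
            continue
        D = contact_map.build_dda_matrix(
            walks_by_chrom[chrom], model, bins, w=w, standardize=standardize
        )
        N = contact_map.postprocess(D)
        tracks[chrom] = compartments.call(
            N, chip_by_chrom[chrom], mode="dda", pc_index=pc_index
        )
    return tracks
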