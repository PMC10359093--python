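"""Agreement metrics, saddle-plot compartment strength and GC baseline.

The positive class throughout is the A compartment (reference pc > 0).
AUC uses the Mann-Whitney rank statistic with midrank tie handling;
accuracy and F1 threshold the prediction score at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .contact_map import ContactMatrix
from .compartments import CompartmentTrack
from .sequence_walk import InputError

__all__ = [
    "MetricReport",
    "SaddleResult",
    "track_metrics",
    "observed_expected",
    "saddle",
    "gc_baseline_metrics",
    "paired_wilcoxon",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    r_pc: float
    auc: float
    acc: float
    f1: float
    n_bins: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SaddleResult:
    n_quantiles: int
    strength: float
    sorted_oe: np.ndarray


def _mutual(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    both = np.isfinite(pred) & np.isfinite(ref)
    return pred[both], ref[both]


def auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum statistic with midranks."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # average (mid) ranks for ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def track_metrics(pred, ref) -> MetricReport:
    """Pearson r, AUC, accuracy and F1 of a predicted track against a reference.

    ``pred`` and ``ref`` may be CompartmentTrack objects or plain per-bin
    score arrays (NaN = masked). Reference labels come from the sign of the
    reference pc (A = positive); ACC/F1 threshold the prediction at zero.
    """
    p = pred.pc if isinstance(pred, CompartmentTrack) else np.asarray(pred, dtype=float)
    r = ref.pc if isinstance(ref, CompartmentTrack) else np.asarray(ref, dtype=float)
    if len(p) != len(r):
        raise InputError("prediction and reference must cover the same bins")
    ps, rs = _mutual(p, r)
    n = len(ps)
    if n < 2:
        raise InputError("need at least 2 mutually defined bins")
    labels = rs > 0
    pred_labels = ps > 0
    if ps.std() == 0 or rs.std() == 0:
        r_pc = float("nan")
    else:
        r_pc = float(np.corrcoef(ps, rs)[0, 1])
    auc = auc_midrank(ps, labels)
    acc = float((pred_labels == labels).mean())
    tp = int((pred_labels & labels).sum())
    fp = int((pred_labels & ~labels).sum())
    fn = int((~pred_labels & labels).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else float("nan")
    return MetricReport(r_pc=r_pc, auc=auc, acc=acc, f1=f1, n_bins=n)


def observed_expected(H: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of its diagonal (same genomic distance).

    Masked entries are excluded from both the diagonal sum and the element
    count; diagonals with zero expected value yield masked entries.
    """
    n = H.n_bins
    vals = H.values
    oe = np.full_like(vals, np.nan)
    for d in range(n):
        idx = (np.arange(n - d), np.arange(d, n))
        diag = vals[idx]
        finite = np.isfinite(diag)
        if not finite.any():
            continue
        expected = diag[finite].sum() / finite.sum()
        if expected == 0:
            continue
        row = np.full(n - d, np.nan)
        row[finite] = diag[finite] / expected
        oe[idx] = row
        oe[idx[1], idx[0]] = row
    return ContactMatrix(oe, H.bins.copy(), "observed-expected", H.mask.copy())


def saddle(
    M: ContactMatrix,
    pc: np.ndarray,
    n_quantiles: int = 30,
    extreme_fraction: float = 0.25,
    corner_definition: str = "value-quantile",
    aggregate: str = "mean",
) -> SaddleResult:
    """Saddle aggregation and compartment strength S = (AA+BB)/(AB+BA).

    The pc is scaled to [-1, 1] by its maximum absolute value; bins are
    ranked by pc and split into ``n_quantiles`` equal-count groups to form
    the reordered, group-aggregated matrix. Corner masses use bins in the
    top/bottom ``extreme_fraction`` of scaled pc values
    (``corner_definition="value-quantile"``; ``"group-index"`` uses the
    extreme quantile groups instead). ``aggregate`` is "mean" or "sum".
    """
    pc = np.asarray(pc, dtype=float)
    if len(pc) != M.n_bins:
        raise InputError("pc must be defined on the matrix bins")
    live = np.isfinite(pc) & ~M.mask
    idx = np.where(live)[0]
    if len(idx) < 2:
        raise InputError("too few defined bins for saddle analysis")
    vmax = np.abs(pc[live]).max()
    scaled = pc[live] / vmax if vmax > 0 else pc[live]
    order = np.argsort(scaled, kind="stable")
    sorted_idx = idx[order]
    k = min(n_quantiles, len(idx))
    if k < n_quantiles:
        logger.warning("only %d bins; using %d saddle groups", len(idx), k)
    groups = np.array_split(sorted_idx, k)
    agg = np.nanmean if aggregate == "mean" else np.nansum
    sorted_oe = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            block = M.values[np.ix_(groups[a], groups[b])]
            if np.isfinite(block).any():
                sorted_oe[a, b] = agg(block)
    if corner_definition == "value-quantile":
        lo_thr = np.quantile(scaled, extreme_fraction)
        hi_thr = np.quantile(scaled, 1 - extreme_fraction)
        top = idx[scaled >= hi_thr]
        bot = idx[scaled <= lo_thr]
    elif corner_definition == "group-index":
        n_corner = max(1, int(round(k * extreme_fraction)))
        bot = np.concatenate(groups[:n_corner])
        top = np.concatenate(groups[-n_corner:])
    else:
        raise InputError(f"unknown corner_definition {corner_definition!r}")

    def corner(rows, cols) -> float:
        block = M.values[np.ix_(rows, cols)]
        return float(agg(block)) if np.isfinite(block).any() else float("nan")

    aa, bb = corner(top, top), corner(bot, bot)
    ab, ba = corner(top, bot), corner(bot, top)
    cross = ab + ba
    strength = (aa + bb) / cross if cross and np.isfinite(cross) else float("nan")
    return SaddleResult(n_quantiles=k, strength=float(strength), sorted_oe=sorted_oe)


def gc_baseline_metrics(gc: np.ndarray, ref) -> MetricReport:
    """Metrics of the per-bin GC fraction used directly as prediction score.

    The GC track is z-scored over defined bins so that the zero threshold of
    ACC/F1 is meaningful.
    """
    gc = np.asarray(gc, dtype=float)
    finite = np.isfinite(gc)
    gz = gc.copy()
    sd = gc[finite].std()
    if sd > 0:
        gz[finite] = (gc[finite] - gc[finite].mean()) / sd
    else:
        gz[finite] = 0.0
    return track_metrics(gz, ref)


def paired_wilcoxon(xs, ys) -> float:
    """Wilcoxon signed-rank p-value for paired per-chromosome metrics."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) != len(ys) or len(xs) < 2:
        raise InputError("need two equal-length samples with >= 2 pairs")
    if np.all(xs == ys):
        return 1.0
    return float(stats.wilcoxon(xs, ys).pvalue)
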