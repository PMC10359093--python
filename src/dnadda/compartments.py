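"""A/B compartment calling from a contact matrix.

The caller follows the classic eigenvector route: Pearson correlation
matrix of the contact map, PCA over bins, per-PC outlier replacement
(scaled-MAD rule), selection and orientation of the compartment PC by its
correlation with a ChIP-seq open-chromatin profile, and optional smoothing
for sequence-derived maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_map import ContactMatrix
from .sequence_walk import GenomicBins, InputError

__all__ = [
    "ChipProfile",
    "CompartmentTrack",
    "pearson_matrix",
    "pca_tracks",
    "filter_outliers",
    "chip_profile",
    "select_and_orient",
    "call",
    "OrientationError",
]

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency constant for the scaled MAD
SMOOTH_WINDOW = 5


class OrientationError(ValueError):
    """Raised when no PC can be oriented against the ChIP profile."""


@dataclass
class ChipProfile:
    """Per-bin ChIP-seq peak counts used for PC selection and orientation."""

    counts: np.ndarray
    mark: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)


@dataclass
class CompartmentTrack:
    """Per-bin signed PC value, A/B label and display-scaled value.

    ``pc`` has zero mean and unit variance over unmasked bins; label is A
    exactly where pc > 0. ``display`` maps A into [0, 0.5] and B into
    [0.5, 1] for plotting only.
    """

    pc: np.ndarray
    label: np.ndarray
    display: np.ndarray
    pc_index: int
    orientation_r: float
    mask: np.ndarray
    bins: GenomicBins | None = None

    @property
    def n_bins(self) -> int:
        return len(self.pc)


def pearson_matrix(M: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of matrix rows over unmasked columns.

    Rows with zero variance are masked. Diagonal is exactly 1.
    """
    mask = M.mask.copy()
    keep = ~mask
    if keep.sum() < 3:
        raise InputError("need at least 3 unmasked bins for a correlation matrix")
    sub = M.values[np.ix_(keep, keep)]
    sd = sub.std(axis=1)
    zero_var = sd == 0
    if zero_var.any():
        idx = np.where(keep)[0][zero_var]
        logger.warning("masking %d zero-variance bins", len(idx))
        mask[idx] = True
        keep = ~mask
        sub = M.values[np.ix_(keep, keep)]
    n = M.n_bins
    corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    out = np.full((n, n), np.nan)
    out[np.ix_(keep, keep)] = corr
    bins = M.bins.copy()
    bins.mask |= mask
    return ContactMatrix(out, bins, "pearson", mask)


def pca_tracks(C: ContactMatrix, n_pcs: int = 4) -> list[np.ndarray]:
    """Principal-component score series of the correlation matrix.

    Bins are observations (rows), columns are centered before the SVD.
    Sign convention: the largest-magnitude loading of each component is made
    positive. Masked bins are reinserted as NaN. Fewer unmasked bins than
    ``n_pcs`` yields fewer components.
    """
    keep = ~C.mask
    sub = C.values[np.ix_(keep, keep)]
    n_obs = sub.shape[0]
    k = min(n_pcs, n_obs)
    if k < n_pcs:
        logger.warning("only %d unmasked bins; returning %d PCs", n_obs, k)
    X = sub - sub.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tracks: list[np.ndarray] = []
    for c in range(k):
        scores = U[:, c] * s[c]
        loading = Vt[c]
        j = int(np.argmax(np.abs(loading)))
        if loading[j] < 0:
            scores = -scores
        full = np.full(C.n_bins, np.nan)
        full[keep] = scores
        tracks.append(full)
    return tracks


def filter_outliers(pc: np.ndarray, n_mads: float = 3.0) -> np.ndarray:
    """Replace extreme values by the nearest non-outlier, then z-normalize.

    A value is an outlier when |v - median| exceeds ``n_mads`` scaled MADs
    (MAD * 1.4826). Replacement is by the numerically nearest non-outlier
    value. NaN entries (masked bins) pass through untouched. With MAD = 0 no
    replacement happens; a zero-variance series is returned unchanged.
    """
    pc = np.asarray(pc, dtype=float)
    out = pc.copy()
    finite = np.isfinite(pc)
    vals = pc[finite]
    if len(vals) < 3:
        raise InputError("need at least 3 finite values")
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad > 0:
        cutoff = n_mads * MAD_SCALE * mad
        is_out = np.abs(vals - med) > cutoff
        if is_out.any() and not is_out.all():
            good = np.sort(vals[~is_out])
            pos = np.searchsorted(good, vals[is_out])
            pos = np.clip(pos, 1, len(good) - 1) if len(good) > 1 else np.zeros_like(pos)
            lo = good[np.maximum(pos - 1, 0)]
            hi = good[np.minimum(pos, len(good) - 1)]
            nearest = np.where(np.abs(vals[is_out] - lo) <= np.abs(vals[is_out] - hi), lo, hi)
            vals = vals.copy()
            vals[is_out] = nearest
    sd = vals.std()
    if sd == 0:
        logger.warning("zero-variance PC; skipping z-normalization")
        out[finite] = vals
        return out
    out[finite] = (vals - vals.mean()) / sd
    return out


def chip_profile(
    peaks: Sequence[tuple[str, int, int]],
    bins: GenomicBins,
    mark: str = "",
    assignment: str = "midpoint",
) -> ChipProfile:
    """Count called peaks per bin (+1 per peak).

    With ``assignment="midpoint"`` (default) each peak increments the single
    bin containing its midpoint; ``"overlap"`` increments every overlapped
    bin. Peaks on other sequences are skipped with a warning count.
    """
    counts = np.zeros(bins.n_bins)
    skipped = 0
    for chrom, start, end in peaks:
        if chrom != bins.chrom:
            skipped += 1
            continue
        if assignment == "midpoint":
            mid = (start + end) // 2
            idx = mid // bins.bin_size
            if 0 <= idx < bins.n_bins:
                counts[idx] += 1
            else:
                skipped += 1
        elif assignment == "overlap":
            lo = max(0, start // bins.bin_size)
            hi = min(bins.n_bins, -(-end // bins.bin_size))
            counts[lo:hi] += 1
        else:
            raise InputError(f"unknown peak assignment {assignment!r}")
    if skipped:
        logger.warning("skipped %d peaks outside %s bins", skipped, bins.chrom)
    counts[bins.mask] = np.nan
    return ChipProfile(counts=counts, mark=mark)


def _moving_mean(x: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    # centered window, shrinking at the edges; NaN (masked) entries ignored
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    finite = np.isfinite(x)
    vals = x[finite]
    sd = vals.std()
    if sd > 0:
        out[finite] = (vals - vals.mean()) / sd
    else:
        out[finite] = vals - vals.mean()
    return out


def _display_scale(pc: np.ndarray) -> np.ndarray:
    """Map A (pc > 0) into [0, 0.5] and B (pc <= 0) into [0.5, 1]."""
    disp = np.full_like(pc, np.nan)
    pos = np.isfinite(pc) & (pc > 0)
    neg = np.isfinite(pc) & (pc <= 0)
    if pos.any():
        pmax = pc[pos].max()
        disp[pos] = 0.5 * (1.0 - pc[pos] / pmax) if pmax > 0 else 0.5
    if neg.any():
        pmin = pc[neg].min()
        disp[neg] = 0.5 * (1.0 + pc[neg] / pmin) if pmin < 0 else 0.5
    return disp


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    both = np.isfinite(x) & np.isfinite(y)
    if both.sum() < 3:
        return float("nan")
    xs, ys = x[both], y[both]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def select_and_orient(
    pcs: Sequence[np.ndarray],
    chip: ChipProfile,
    smooth: bool = False,
    pc_index: int | None = None,
    bins: GenomicBins | None = None,
) -> CompartmentTrack:
    """Choose and orient the compartment PC against a ChIP profile.

    Each candidate is optionally moving-averaged (window 5, centered,
    shrinking at the edges) before correlation; the candidate with the
    largest |Pearson r| to the ChIP profile among the first four is chosen
    (ties go to the lowest index) and sign-flipped so that r >= 0. An
    explicit 1-based ``pc_index`` overrides the automatic selection.
    """
    if not pcs:
        raise InputError("no candidate PCs")
    candidates = [ _zscore(_moving_mean(pc)) if smooth else pc for pc in pcs ]
    rs = [_safe_corr(c, chip.counts) for c in candidates]
    if pc_index is not None:
        if not 1 <= pc_index <= len(candidates):
            raise InputError(f"pc_index {pc_index} out of range 1..{len(candidates)}")
        chosen = pc_index - 1
    else:
        finite_rs = [(abs(r), -i) for i, r in enumerate(rs) if np.isfinite(r)]
        if not finite_rs:
            raise OrientationError(
                "all PC/ChIP correlations are undefined (constant profile?); "
                "pass an explicit pc_index"
            )
        best = max(finite_rs)
        if sum(1 for v, _ in finite_rs if v == best[0]) > 1:
            logger.info("tie in |r| among PCs; choosing the lowest index")
        chosen = -best[1]
    pc = candidates[chosen].copy()
    r = rs[chosen]
    if np.isfinite(r) and r < 0:
        pc = -pc
        r = -r
    mask = ~np.isfinite(pc)
    label = np.where(mask, "", np.where(pc > 0, "A", "B"))
    return CompartmentTrack(
        pc=pc,
        label=label,
        display=_display_scale(pc),
        pc_index=chosen + 1,
        orientation_r=float(r) if np.isfinite(r) else float("nan"),
        mask=mask,
        bins=bins,
    )


def call(
    M: ContactMatrix,
    chip: ChipProfile,
    mode: str = "hic",
    n_pcs: int = 4,
    pc_index: int | None = None,
) -> CompartmentTrack:
    """Full compartment call: correlation -> PCA -> outlier filter -> orient.

    ``mode="dda"`` additionally smooths each candidate PC (window 5) before
    the ChIP correlation, as done for sequence-derived maps.
    """
    if mode not in ("hic", "dda"):
        raise InputError(f"mode must be 'hic' or 'dda', got {mode!r}")
    C = pearson_matrix(M)
    pcs = pca_tracks(C, n_pcs=n_pcs)
    filtered = [filter_outliers(pc) for pc in pcs]
    return select_and_orient(
        filtered, chip, smooth=(mode == "dda"), pc_index=pc_index, bins=C.bins
    )
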