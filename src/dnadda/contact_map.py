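"""Pairwise ergodicity matrices and contact-matrix post-processing / I/O.

The raw sequence-only contact estimate for a chromosome is the symmetric
matrix of dynamical-ergodicity scores over all bin pairs. Post-processing
turns it into a normalized contact map: high ergodicity (dissimilar
dynamics) maps to low contact via a linear flip, non-zero values are
log-transformed, and the result is rescaled to [0, 1].

Supported interchange formats: HOMER interaction-matrix text, dense TSV
with bin labels, and a single-resolution cooler-layout HDF5 container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import dda_core
from .sequence_walk import GenomicBins, InputError
from .dda_core import DDAModel, FitError

__all__ = [
    "ContactMatrix",
    "build_dda_matrix",
    "feature_table",
    "postprocess",
    "normalize_range",
    "mask_low_coverage",
    "read_matrix",
    "write_matrix",
    "FormatError",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on malformed contact-matrix files."""


class NormalizationError(ValueError):
    """Raised when a matrix has zero range and cannot be rescaled."""


@dataclass
class ContactMatrix:
    """Square symmetric matrix of contact scores over genomic bins.

    Masked bins carry NaN in their rows and columns. ``kind`` is one of
    raw-dda | normalized | hic | pearson | observed-expected.
    """

    values: np.ndarray
    bins: GenomicBins
    kind: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise InputError("contact matrix must be square")
        if n != self.bins.n_bins:
            raise InputError("matrix size must match bin count")
        if self.mask is None:
            self.mask = self.bins.mask.copy()
        self.mask = np.asarray(self.mask, dtype=bool)
        self._apply_mask()

    def _apply_mask(self) -> None:
        self.values[self.mask, :] = np.nan
        self.values[:, self.mask] = np.nan

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def unmasked_values(self) -> np.ndarray:
        keep = ~self.mask
        return self.values[np.ix_(keep, keep)]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.values.copy(), self.bins.copy(), self.kind, self.mask.copy())


def build_dda_matrix(
    walks: Sequence,
    model: DDAModel,
    bins: GenomicBins,
    w: int = 1,
    standardize: bool = True,
) -> ContactMatrix:
    """Ergodicity score matrix over all unmasked bin pairs.

    ST errors are computed once per bin (n single-trial fits) and reused for
    the n(n-1)/2 cross-trial fits. Bins whose fit degenerates or errors are
    masked and the event logged. The result is exactly symmetric with a zero
    diagonal.
    """
    if model.delays is None:
        raise FitError("model delays must be set")
    bins = bins.copy()
    n = bins.n_bins
    if len(walks) != n:
        raise InputError("need one walk slot per bin")
    factors: dict[int, dda_core.BinFactor] = {}
    rho_s = np.full(n, np.nan)
    for i in range(n):
        if bins.mask[i] or walks[i] is None:
            bins.mask[i] = True
            continue
        label = f"{bins.chrom}-{bins.starts[i]}"
        try:
            feats = dda_core.fit_st(walks[i], model, w=w, standardize=standardize, label=label)
        except FitError as exc:
            logger.warning("masking bin %s: %s", label, exc)
            bins.mask[i] = True
            continue
        if feats.degenerate:
            logger.warning("masking degenerate bin %s", label)
            bins.mask[i] = True
            continue
        rho_s[i] = feats.rho
        factors[i] = dda_core.bin_factor(
            walks[i], model, w=w, standardize=standardize, label=label
        )
    live = [i for i in range(n) if not bins.mask[i]]
    if len(live) < 2:
        raise FitError("need at least 2 unmasked bins to build a contact matrix")
    E = np.zeros((n, n))
    for ai, i in enumerate(live):
        for j in live[ai + 1 :]:
            ct = dda_core.fit_ct(factors=(factors[i], factors[j]))
            e = dda_core.ergodicity(rho_s[i], rho_s[j], ct.rho)
            E[i, j] = E[j, i] = e
    return ContactMatrix(E, bins, "raw-dda")


def feature_table(
    walks: Sequence,
    model: DDAModel,
    bins: GenomicBins,
    w: int = 1,
    standardize: bool = True,
):
    """Per-pair ST/CT feature table as a pandas DataFrame.

    Columns: bin_i, bin_j, a1..aK (cross-trial coefficients), rho_s_i,
    rho_s_j, rho_c, E. Writable as TSV via ``df.to_csv(path, sep="\\t")``.
    """
    import pandas as pd

    labels = bins.labels()
    live = [
        i for i in range(bins.n_bins) if not bins.mask[i] and walks[i] is not None
    ]
    st = {
        i: dda_core.fit_st(walks[i], model, w=w, standardize=standardize, label=labels[i])
        for i in live
    }
    factors = {
        i: dda_core.bin_factor(walks[i], model, w=w, standardize=standardize)
        for i in live
    }
    rows = []
    for ai, i in enumerate(live):
        for j in live[ai + 1 :]:
            ct = dda_core.fit_ct(factors=(factors[i], factors[j]))
            row = {"bin_i": labels[i], "bin_j": labels[j]}
            row.update({f"a{k + 1}": ct.a[k] for k in range(len(ct.a))})
            row["rho_s_i"] = st[i].rho
            row["rho_s_j"] = st[j].rho
            row["rho_c"] = ct.rho
            row["E"] = dda_core.ergodicity(st[i].rho, st[j].rho, ct.rho)
            rows.append(row)
    return pd.DataFrame(rows)


def normalize_range(M: ContactMatrix) -> ContactMatrix:
    """Min-max rescale of unmasked entries to [0, 1]."""
    out = M.copy()
    finite = np.isfinite(out.values)
    if not finite.any():
        raise NormalizationError("matrix has no unmasked entries")
    vmin = out.values[finite].min()
    vmax = out.values[finite].max()
    if vmax == vmin:
        raise NormalizationError("matrix has zero range; cannot normalize")
    out.values[finite] = (out.values[finite] - vmin) / (vmax - vmin)
    out.kind = "normalized"
    return out


def postprocess(D: ContactMatrix, hic_mask: np.ndarray | None = None) -> ContactMatrix:
    """Turn a raw ergodicity matrix into a normalized contact map.

    Steps, in order: (1) linear flip d' = max + min - d over unmasked
    entries, so the highest ergodicity (most dissimilar pair) maps to the
    lowest contact; (2) natural log of each non-zero entry, zeros left
    untouched; (3) min-max rescale to [0, 1]; (4) bins excluded in the
    reference Hi-C map (if given) are masked here too.
    """
    if D.kind != "raw-dda":
        raise InputError(f"postprocess expects a raw-dda matrix, got {D.kind!r}")
    out = D.copy()
    if hic_mask is not None:
        out.mask = out.mask | np.asarray(hic_mask, dtype=bool)
        out._apply_mask()
    finite = np.isfinite(out.values)
    if not finite.any():
        raise NormalizationError("matrix has no unmasked entries")
    vals = out.values[finite]
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        raise NormalizationError("constant matrix; cannot post-process")
    flipped = vmax + vmin - vals
    nz = flipped != 0
    flipped[nz] = np.log(flipped[nz])
    out.values[finite] = flipped
    out.kind = "raw-dda"  # rescale step below sets the final kind
    out = normalize_range(out)
    return out


def mask_low_coverage(
    H: ContactMatrix, fraction: float = 0.10, relative_to: str = "mean-row-sum"
) -> np.ndarray:
    """Mask bins with low total contact; returns the updated mask.

    With ``relative_to="mean-row-sum"`` (default) a bin is masked when its
    row sum falls below ``fraction`` times the mean row sum over currently
    unmasked bins; with ``"total"`` the threshold is ``fraction`` times the
    bin's share of total contact mass, i.e. rows below ``fraction`` times
    ``total / n_unmasked``.
    """
    vals = np.where(np.isfinite(H.values), H.values, 0.0)
    if np.any(vals < 0):
        raise InputError("mask_low_coverage expects a nonnegative matrix")
    row_sums = vals.sum(axis=1)
    live = ~H.mask
    if not live.any() or fraction <= 0:
        return H.mask
    if relative_to == "mean-row-sum":
        ref = row_sums[live].mean()
    elif relative_to == "total":
        ref = row_sums[live].sum() / live.sum()
    else:
        raise InputError(f"unknown relative_to {relative_to!r}")
    new_mask = H.mask | (live & (row_sums < fraction * ref))
    H.mask = new_mask
    H._apply_mask()
    H.bins.mask |= new_mask
    return new_mask


# ---------------------------------------------------------------------------
# matrix I/O

_NAN_TOKEN = "nan"


def write_matrix(M: ContactMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a contact matrix as HOMER text, labeled dense TSV, or cooler HDF5."""
    path = Path(path)
    if format == "tsv":
        _write_dense(M, path)
    elif format == "homer":
        _write_homer(M, path)
    elif format == "cool":
        _write_cool(M, path)
    else:
        raise FormatError(f"unknown matrix format {format!r}")


def read_matrix(path: str | Path, format: str = "tsv", kind: str = "hic") -> ContactMatrix:
    path = Path(path)
    if format == "tsv":
        return _read_dense(path, kind)
    if format == "homer":
        return _read_homer(path, kind)
    if format == "cool":
        return _read_cool(path, kind)
    raise FormatError(f"unknown matrix format {format!r}")


def _fmt(v: float) -> str:
    return _NAN_TOKEN if not np.isfinite(v) else repr(float(v))


def _bins_from_labels(labels: list[str], seq_length: int | None = None) -> GenomicBins:
    chroms = {lab.rsplit("-", 1)[0] for lab in labels}
    if len(chroms) != 1:
        raise FormatError(f"matrix spans multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    starts = np.array([int(lab.rsplit("-", 1)[1]) for lab in labels], dtype=np.int64)
    if len(starts) > 1:
        sizes = np.unique(np.diff(starts))
        if len(sizes) != 1:
            raise FormatError("bin starts are not evenly spaced")
        bin_size = int(sizes[0])
    else:
        bin_size = int(starts[0]) if starts[0] > 0 else 1
    length = seq_length if seq_length is not None else int(starts[-1] + bin_size)
    return GenomicBins(chrom, bin_size, starts, np.zeros(len(starts), dtype=bool), length)


def _write_dense(M: ContactMatrix, path: Path) -> None:
    labels = M.bins.labels()
    with open(path, "w") as fh:
        fh.write("bin\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, M.values):
            fh.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def _read_dense(path: Path, kind: str) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "bin":
            raise FormatError(f"{path}:1: expected 'bin' header column")
        labels = header[1:]
        n = len(labels)
        values = np.empty((n, n))
        row_labels = []
        for r in range(n):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: expected {n} data rows, got {r}")
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 1:
                raise FormatError(f"{path}:{r + 2}: expected {n + 1} columns, got {len(parts)}")
            row_labels.append(parts[0])
            values[r] = [float(p) for p in parts[1:]]
    if row_labels != labels:
        raise FormatError(f"{path}: row labels do not match header labels")
    bins = _bins_from_labels(labels)
    mask = ~np.isfinite(values).any(axis=1)
    bins.mask |= mask
    return ContactMatrix(values, bins, kind, mask)


def _write_homer(M: ContactMatrix, path: Path) -> None:
    labels = M.bins.labels()
    with open(path, "w") as fh:
        fh.write("HiCMatrix (directory=.)\tRegions\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, M.values):
            fh.write(lab + "\t" + lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def _read_homer(path: Path, kind: str) -> ContactMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[1] != "Regions":
            raise FormatError(f"{path}:1: not a HOMER interaction-matrix header")
        labels = header[2:]
        n = len(labels)
        values = np.empty((n, n))
        row_labels = []
        for r in range(n):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: expected {n} data rows, got {r}")
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n + 2:
                raise FormatError(
                    f"{path}:{r + 2}: header names {n} bins but row has {len(parts) - 2}"
                )
            row_labels.append(parts[0])
            values[r] = [float(p) for p in parts[2:]]
    if row_labels != labels:
        raise FormatError(f"{path}: row labels do not match header labels")
    bins = _bins_from_labels(labels)
    mask = ~np.isfinite(values).any(axis=1)
    bins.mask |= mask
    return ContactMatrix(values, bins, kind, mask)


def _write_cool(M: ContactMatrix, path: Path) -> None:
    # single-resolution cooler v3 layout subset, written natively (no cooler dep)
    import h5py

    n = M.n_bins
    iu = np.triu_indices(n)
    counts = M.values[iu]
    keep = np.isfinite(counts)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-size"] = M.bins.bin_size
        f.attrs["kind"] = M.kind
        chroms = f.create_group("chroms")
        chroms.create_dataset("name", data=[M.bins.chrom.encode()])
        chroms.create_dataset("length", data=np.array([M.bins.seq_length], dtype=np.int64))
        bins = f.create_group("bins")
        bins.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        bins.create_dataset("start", data=M.bins.starts)
        bins.create_dataset("end", data=M.bins.ends)
        bins.create_dataset("mask", data=M.mask.astype(np.int8))
        pixels = f.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu[0][keep].astype(np.int64))
        pixels.create_dataset("bin2_id", data=iu[1][keep].astype(np.int64))
        pixels.create_dataset("count", data=counts[keep].astype(np.float64))


def _read_cool(path: Path, kind: str) -> ContactMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        chrom = f["chroms/name"][0].decode()
        length = int(f["chroms/length"][0])
        starts = f["bins/start"][:]
        mask = f["bins/mask"][:].astype(bool)
        bin_size = int(f.attrs["bin-size"])
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
        stored_kind = f.attrs.get("kind", kind)
    n = len(starts)
    values = np.full((n, n), np.nan)
    values[b1, b2] = cnt
    values[b2, b1] = cnt
    bins = GenomicBins(chrom, bin_size, starts, mask, length)
    return ContactMatrix(values, bins, str(stored_kind), mask)
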