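"""Fixed-width genomic binning and DNA-walk encoding.

A DNA walk represents a nucleotide sequence as a one-dimensional series
following the hydrogen-bond (SW) rule: the walker starts at zero and steps
up for strongly bonded bases (C/G) and down for weakly bonded bases (A/T).
Each genomic bin is encoded independently, so walks restart at zero at every
bin boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GenomicBins",
    "DNAWalk",
    "make_bins",
    "encode_walk",
    "bin_walks",
    "gc_fraction",
    "read_fasta",
    "read_bed",
    "apply_exclusion",
    "InputError",
]

# minimum fraction of unambiguous (A/C/G/T) calls for a bin to stay unmasked
MIN_INFORMATIVE_FRACTION = 0.5

_STEP = np.zeros(256, dtype=np.int8)
for _b in b"CGcg":
    _STEP[_b] = 1
for _b in b"ATat":
    _STEP[_b] = -1
_INFORMATIVE = _STEP != 0


class InputError(ValueError):
    """Raised for malformed user input (sequences, bins, regions)."""


@dataclass
class GenomicBins:
    """Ordered, contiguous, non-overlapping fixed-width windows on one sequence.

    Coordinates are 0-based half-open. The trailing bin may be shorter than
    ``bin_size``; it is masked by default because downstream model fits
    assume equal length across bins.
    """

    chrom: str
    bin_size: int
    starts: np.ndarray
    mask: np.ndarray
    seq_length: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.starts.shape:
            raise InputError("mask must have one entry per bin")
        if np.any(np.diff(self.starts) != self.bin_size):
            raise InputError("bins must be contiguous and sorted")

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.bin_size, self.seq_length)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def labels(self) -> list[str]:
        """HOMER-style ``chrom-start`` labels, one per bin."""
        return [f"{self.chrom}-{s}" for s in self.starts]

    def copy(self) -> "GenomicBins":
        return GenomicBins(
            self.chrom, self.bin_size, self.starts.copy(), self.mask.copy(), self.seq_length
        )


@dataclass
class DNAWalk:
    """Cumulative +/-1 series encoding one bin's sequence.

    ``values[0] == 0`` always; ambiguous bases contribute a zero step and are
    excluded from ``n_informative``.
    """

    values: np.ndarray
    n_informative: int

    @property
    def L(self) -> int:
        return len(self.values)


def make_bins(seq_lengths: Mapping[str, int], bin_size: int = 100_000) -> dict[str, GenomicBins]:
    """Tile each sequence with fixed-width bins.

    The trailing partial bin (if any) is retained but masked.
    """
    if bin_size < 2:
        raise InputError(f"bin_size must be >= 2, got {bin_size}")
    out: dict[str, GenomicBins] = {}
    for chrom, length in seq_lengths.items():
        if length < 1:
            raise InputError(f"sequence {chrom!r} has non-positive length {length}")
        n_full, rem = divmod(length, bin_size)
        n = n_full + (1 if rem else 0)
        starts = np.arange(n, dtype=np.int64) * bin_size
        mask = np.zeros(n, dtype=bool)
        if rem:
            mask[-1] = True  # partial trailing bin
        out[chrom] = GenomicBins(chrom, bin_size, starts, mask, length)
    return out


def encode_walk(seq: str) -> DNAWalk:
    """Encode a sequence as a DNA walk under the SW (hydrogen bond) rule.

    The walk starts at zero and the base at position t+1 drives the step
    from x(t) to x(t+1), so the first base never contributes a step.
    Ambiguous bases (anything outside A/C/G/T, case-insensitive) give a
    zero step.
    """
    if not seq:
        raise InputError("cannot encode an empty sequence")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    steps = _STEP[raw]
    values = np.empty(len(raw), dtype=np.int64)
    values[0] = 0
    np.cumsum(steps[1:], out=values[1:])
    n_informative = int(_INFORMATIVE[raw].sum())
    return DNAWalk(values=values, n_informative=n_informative)


def gc_fraction(seq: str) -> float:
    """(#C + #G) / (#A + #C + #G + #T); NaN when no unambiguous base exists."""
    if not seq:
        raise InputError("cannot compute GC fraction of an empty sequence")
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    steps = _STEP[raw]
    n_inf = int((steps != 0).sum())
    if n_inf == 0:
        return float("nan")
    return float((steps == 1).sum() / n_inf)


def bin_walks(
    sequences: Mapping[str, str],
    bins: GenomicBins,
    min_informative_fraction: float = MIN_INFORMATIVE_FRACTION,
) -> list[DNAWalk | None]:
    """Encode every unmasked bin of one chromosome as an independent walk.

    Returns a list aligned with ``bins`` holding ``None`` for masked bins.
    Bins whose fraction of unambiguous bases falls below the occupancy
    threshold are masked in place (this covers the all-ambiguous "empty
    bins").
    """
    try:
        seq = sequences[bins.chrom]
    except KeyError as exc:
        raise InputError(f"sequence {bins.chrom!r} not found") from exc
    if bins.starts[-1] + bins.widths[-1] > len(seq):
        raise InputError(
            f"bins extend past the end of {bins.chrom!r} "
            f"({bins.starts[-1] + bins.widths[-1]} > {len(seq)})"
        )
    walks: list[DNAWalk | None] = []
    for i, (start, end) in enumerate(zip(bins.starts, bins.ends)):
        if bins.mask[i]:
            walks.append(None)
            continue
        walk = encode_walk(seq[start:end])
        if walk.n_informative < min_informative_fraction * bins.bin_size:
            bins.mask[i] = True
            walks.append(None)
        else:
            walks.append(walk)
    return walks


# ---------------------------------------------------------------------------
# file I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into name -> sequence."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seqs: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in seqs:
                raise InputError(f"duplicate FASTA record {record.id!r}")
            seqs[record.id] = str(record.seq)
    if not seqs:
        raise InputError(f"FASTA {path} contains no records")
    return seqs


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three columns of a BED file."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{ln}: expected at least 3 BED columns")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def apply_exclusion(bins: GenomicBins, regions: Iterable[tuple[str, int, int]]) -> GenomicBins:
    """Mask every bin overlapping any exclusion region (in place; returns bins)."""
    for chrom, start, end in regions:
        if chrom != bins.chrom:
            continue
        lo = max(0, start // bins.bin_size)
        hi = min(bins.n_bins, -(-end // bins.bin_size))
        bins.mask[lo:hi] = True
    return bins
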