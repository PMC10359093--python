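"""Text I/O for per-bin tracks and walk directories.

Tracks travel as bedGraph (signed pc values; masked bins omitted) and BED
(A/B labels). A "walk directory" holds one bins.tsv plus one single-column
text file per unmasked bin, which keeps every intermediate inspectable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .compartments import CompartmentTrack
from .sequence_walk import DNAWalk, GenomicBins, InputError

__all__ = [
    "write_bedgraph",
    "read_bedgraph",
    "write_compartment_bed",
    "write_walk_dir",
    "read_walk_dir",
]


def write_bedgraph(track, bins: GenomicBins, path: str | Path) -> None:
    values = track.pc if isinstance(track, CompartmentTrack) else np.asarray(track, float)
    with open(path, "w") as fh:
        for start, end, v in zip(bins.starts, bins.ends, values):
            if np.isfinite(v):
                fh.write(f"{bins.chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_bedgraph(path: str | Path) -> dict[tuple[str, int], float]:
    """Map (chrom, start) -> value; intervals keep their file order semantics."""
    out: dict[tuple[str, int], float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}:{ln}: expected 4 bedGraph columns")
            out[(parts[0], int(parts[1]))] = float(parts[3])
    return out


def bedgraph_to_array(values: dict[tuple[str, int], float], bins: GenomicBins) -> np.ndarray:
    arr = np.full(bins.n_bins, np.nan)
    for i, start in enumerate(bins.starts):
        v = values.get((bins.chrom, int(start)))
        if v is not None:
            arr[i] = v
    return arr


def write_compartment_bed(track: CompartmentTrack, bins: GenomicBins, path: str | Path) -> None:
    with open(path, "w") as fh:
        for start, end, lab in zip(bins.starts, bins.ends, track.label):
            if lab:
                fh.write(f"{bins.chrom}\t{start}\t{end}\t{lab}\n")


def write_walk_dir(
    out_dir: str | Path,
    bins_by_chrom: dict[str, GenomicBins],
    walks_by_chrom: dict[str, list],
    gc_by_chrom: dict[str, np.ndarray] | None = None,
) -> None:
    out_dir = Path(out_dir)
    (out_dir / "walks").mkdir(parents=True, exist_ok=True)
    with open(out_dir / "bins.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tbin_size\tseq_length\tmask\tgc\n")
        for chrom, bins in bins_by_chrom.items():
            gc = gc_by_chrom.get(chrom) if gc_by_chrom else None
            for i, (s, e) in enumerate(zip(bins.starts, bins.ends)):
                g = "nan" if gc is None or not np.isfinite(gc[i]) else repr(float(gc[i]))
                fh.write(
                    f"{chrom}\t{s}\t{e}\t{bins.bin_size}\t{bins.seq_length}"
                    f"\t{int(bins.mask[i])}\t{g}\n"
                )
    for chrom, walks in walks_by_chrom.items():
        bins = bins_by_chrom[chrom]
        for i, walk in enumerate(walks):
            if walk is None:
                continue
            p = out_dir / "walks" / f"{chrom}-{bins.starts[i]}.txt"
            np.savetxt(p, walk.values, fmt="%d", header=f"n_informative={walk.n_informative}")


def read_walk_dir(out_dir: str | Path):
    """Inverse of :func:`write_walk_dir`.

    Returns (bins_by_chrom, walks_by_chrom, gc_by_chrom).
    """
    out_dir = Path(out_dir)
    rows: dict[str, list] = {}
    with open(out_dir / "bins.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["chrom", "start", "end"]:
            raise InputError(f"{out_dir}/bins.tsv: unexpected header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.setdefault(parts[0], []).append(parts)
    bins_by_chrom: dict[str, GenomicBins] = {}
    walks_by_chrom: dict[str, list] = {}
    gc_by_chrom: dict[str, np.ndarray] = {}
    for chrom, rr in rows.items():
        starts = np.array([int(r[1]) for r in rr], dtype=np.int64)
        bin_size = int(rr[0][3])
        seq_length = int(rr[0][4])
        mask = np.array([bool(int(r[5])) for r in rr])
        gc_by_chrom[chrom] = np.array([float(r[6]) for r in rr])
        bins = GenomicBins(chrom, bin_size, starts, mask, seq_length)
        walks: list[DNAWalk | None] = []
        for i, start in enumerate(starts):
            p = out_dir / "walks" / f"{chrom}-{start}.txt"
            if mask[i] or not p.exists():
                walks.append(None)
                continue
            n_inf = 0
            with open(p) as fh:
                first = fh.readline()
                if first.startswith("#"):
                    n_inf = int(first.split("=", 1)[1])
            values = np.loadtxt(p, dtype=np.int64, comments="#")
            walks.append(DNAWalk(values=values, n_informative=n_inf))
        bins_by_chrom[chrom] = bins
        walks_by_chrom[chrom] = walks
    return bins_by_chrom, walks_by_chrom, gc_by_chrom
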