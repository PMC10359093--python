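"""Self-contained synthetic inputs with planted ground truth.

Three generators emulate the structures the real pipeline consumes:
sequences whose bins come from class-specific base-composition processes,
plaid contact maps with distance decay, and peak calls enriched in one
class. Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_walk import GenomicBins, InputError, make_bins

__all__ = ["FixtureSpec", "planted_labels", "gen_sequences", "gen_plaid_hic", "gen_peaks"]

BASES = np.array(list("ACGT"))
_GC = np.array([0.0, 1.0, 1.0, 0.0])  # per-base GC indicator over ACGT


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic data set (defaults sized for CI)."""

    n_bins: int = 200
    bin_size: int = 10_000
    seed: int = 0
    chrom: str = "chrS"
    block_size: int = 25  # planted labels alternate in blocks of this many bins
    labels: tuple[str, ...] | None = None  # explicit planted labels override blocks
    # sequence regime parameters
    gc_by_class: dict = field(default_factory=lambda: {"A": 0.60, "B": 0.40})
    period_by_class: dict = field(default_factory=dict)  # class -> lag tau*
    period_amplitude: float = 0.25
    markov_by_class: dict = field(default_factory=dict)  # class -> 4x4 transition matrix
    # plaid contact-map parameters
    intra_mean: float = 2.0
    inter_mean: float = 0.5
    decay_alpha: float = 0.0
    noise_dispersion: float = 0.0
    # peak rates per class (expected peaks per bin)
    peak_rate: dict = field(default_factory=lambda: {"A": 5.0, "B": 0.5})

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.bin_size < 2:
            raise InputError("n_bins and bin_size must be positive")
        if self.intra_mean <= 0 or self.inter_mean <= 0:
            raise InputError("plaid means must be positive")
        if self.labels is not None and len(self.labels) != self.n_bins:
            raise InputError("labels must have one entry per bin")
        for cls, T in self.markov_by_class.items():
            T = np.asarray(T, dtype=float)
            if T.shape != (4, 4) or np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0):
                raise InputError(f"invalid transition matrix for class {cls!r}")


def planted_labels(spec: FixtureSpec) -> np.ndarray:
    """Planted A/B label per bin (alternating blocks unless given explicitly)."""
    if spec.labels is not None:
        return np.asarray(spec.labels)
    blocks = np.arange(spec.n_bins) // spec.block_size
    return np.where(blocks % 2 == 0, "A", "B")


def planted_signal(spec: FixtureSpec) -> np.ndarray:
    """Planted +/-1 signal (A = +1), the analogue of a reference pc track."""
    return np.where(planted_labels(spec) == "A", 1.0, -1.0)


def _class_transition(spec: FixtureSpec, cls: str) -> np.ndarray:
    if cls in spec.markov_by_class:
        return np.asarray(spec.markov_by_class[cls], dtype=float)
    gc = spec.gc_by_class.get(cls, 0.5)
    row = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return np.tile(row, (4, 1))  # iid rows: first-order chain with no memory


def _markov_bin(spec: FixtureSpec, cls: str, gc_mod: np.ndarray, rng) -> np.ndarray:
    """Sample one bin from a first-order chain with optional GC modulation."""
    T = _class_transition(spec, cls)
    L = len(gc_mod)
    u = rng.random(L)
    seq_idx = np.empty(L, dtype=np.int64)
    prev = int(rng.integers(0, 4))
    sign = np.where(_GC == 1.0, 1.0, -1.0)
    for t in range(L):
        p = T[prev]
        if gc_mod[t]:
            p = np.clip(p * (1.0 + gc_mod[t] * sign), 1e-9, None)
            p = p / p.sum()
        prev = min(int(np.searchsorted(np.cumsum(p), u[t], side="right")), 3)
        seq_idx[t] = prev
    return seq_idx


def gen_sequences(spec: FixtureSpec) -> tuple[dict[str, str], GenomicBins, np.ndarray]:
    """One chromosome whose bins come from class-specific base processes.

    Each bin's sequence is drawn from its class's first-order Markov chain
    over ACGT. A class listed in ``period_by_class`` gets a sinusoidal
    GC-probability modulation of amplitude ``period_amplitude`` at its lag,
    which imprints a periodic component on the implied DNA walk.

    Returns (sequences dict, bins, labels).
    """
    rng = np.random.default_rng(spec.seed)
    labels = planted_labels(spec)
    parts: list[str] = []
    for b in range(spec.n_bins):
        cls = str(labels[b])
        L = spec.bin_size
        period = spec.period_by_class.get(cls)
        if period:
            t = np.arange(L)
            gc_mod = spec.period_amplitude * np.sin(2 * np.pi * t / period)
        else:
            gc_mod = np.zeros(L)
        if cls in spec.markov_by_class:
            seq_idx = _markov_bin(spec, cls, gc_mod, rng)
        else:
            # memoryless composition: sample the GC/AT group, then the base
            gc = spec.gc_by_class.get(cls, 0.5)
            at = 1.0 - gc
            num = gc * (1.0 + gc_mod)
            p_gc = np.clip(num / (num + at * (1.0 - gc_mod)), 0.0, 1.0)
            is_gc = rng.random(L) < p_gc
            coin = rng.random(L) < 0.5
            # A=0 C=1 G=2 T=3 in index space of BASES
            seq_idx = np.where(is_gc, np.where(coin, 1, 2), np.where(coin, 0, 3))
        parts.append("".join(BASES[seq_idx]))
    seq = "".join(parts)
    bins = make_bins({spec.chrom: len(seq)}, spec.bin_size)[spec.chrom]
    return {spec.chrom: seq}, bins, labels


def gen_plaid_hic(spec: FixtureSpec):
    """Plaid contact matrix with optional distance decay and noise.

    Entry (i, j) is intra_mean (same planted label) or inter_mean
    (different), times (1 + |i-j|)^(-decay_alpha), times lognormal noise
    with the configured dispersion. Output is symmetric and nonnegative.

    Returns (ContactMatrix of kind "hic", labels).
    """
    from .contact_map import ContactMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    labels = planted_labels(spec)
    same = labels[:, None] == labels[None, :]
    base = np.where(same, spec.intra_mean, spec.inter_mean).astype(float)
    if spec.decay_alpha > 0:
        d = np.abs(np.subtract.outer(np.arange(spec.n_bins), np.arange(spec.n_bins)))
        base = base * (1.0 + d) ** (-spec.decay_alpha)
    if spec.noise_dispersion > 0:
        noise = rng.lognormal(0.0, spec.noise_dispersion, size=base.shape)
        base = base * noise
    vals = (base + base.T) / 2.0
    bins = make_bins({spec.chrom: spec.n_bins * spec.bin_size}, spec.bin_size)[spec.chrom]
    return ContactMatrix(vals, bins, "hic"), labels


def gen_peaks(spec: FixtureSpec, labels: np.ndarray | None = None) -> list[tuple[str, int, int]]:
    """Peak intervals with Poisson counts per bin at the class rate.

    Positions are uniform within the bin; peaks are 200 bp wide (clipped to
    the bin). Deterministic under the spec seed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if labels is None:
        labels = planted_labels(spec)
    peaks: list[tuple[str, int, int]] = []
    width = min(200, spec.bin_size // 2)
    for b in range(spec.n_bins):
        rate = spec.peak_rate.get(str(labels[b]), 0.0)
        if rate <= 0:
            continue
        k = int(rng.poisson(rate))
        if k == 0:
            continue
        starts = rng.integers(0, max(1, spec.bin_size - width), size=k)
        off = b * spec.bin_size
        for s in sorted(int(x) for x in starts):
            peaks.append((spec.chrom, off + s, off + s + width))
    return peaks
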