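"""Delay-differential model machinery.

A model relates the center derivative of a series to products of its
delayed values,

    xdot(t) = sum_k a_k * prod_n x(t - tau_n)^m_{n,k},

and is fitted by minimum-norm least squares (SVD). The fitting coefficients
``a`` and the root-mean-square residual ``rho`` form the classifying feature
set. Two series can be fitted individually (single trial, ST) or jointly on
the row-stacked system (cross trial, CT); combining the ST and CT residuals
yields the dynamical-ergodicity score used as a sequence-only contact
estimate.

Delays are shifts in genomic coordinates (nucleotide steps).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .sequence_walk import DNAWalk

__all__ = [
    "DDAModel",
    "DDAFeatures",
    "FitWindow",
    "default_model",
    "enumerate_models",
    "enumerate_delay_pairs",
    "center_derivative",
    "build_design",
    "fit_st",
    "fit_ct",
    "ergodicity",
    "BinFactor",
    "bin_factor",
    "FitError",
    "FIT_COUNTS",
    "reset_fit_counts",
]

# relative singular-value cutoff for the minimum-norm solution
SVD_RCOND = 1e-12

# call-count instrumentation (used by contact-map tests)
FIT_COUNTS = {"st": 0, "ct": 0}


def reset_fit_counts() -> None:
    FIT_COUNTS["st"] = 0
    FIT_COUNTS["ct"] = 0


class FitError(ValueError):
    """Raised when a model cannot be fitted to a series (e.g. empty window)."""


Monomial = tuple[tuple[int, int], ...]  # ((delay_index, order), ...), delay_index is 1-based


@dataclass(frozen=True)
class DDAModel:
    """Monomial structure plus (optionally) a concrete delay pair.

    ``monomials`` is a tuple of K terms; each term is a tuple of
    (delay_index, order) factors with 1-based delay indices and positive
    integer orders.
    """

    monomials: tuple[Monomial, ...]
    n_delays: int
    delays: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for mono in self.monomials:
            for idx, order in mono:
                if not 1 <= idx <= self.n_delays:
                    raise ValueError(f"delay index {idx} out of range 1..{self.n_delays}")
                if order < 1:
                    raise ValueError("orders must be positive integers")
        if self.delays is not None:
            if len(self.delays) != self.n_delays:
                raise ValueError("need one delay per delay index")
            if any(d < 1 for d in self.delays):
                raise ValueError("delays must be strictly positive")

    @property
    def n_terms(self) -> int:
        return len(self.monomials)

    @property
    def max_delay(self) -> int:
        if self.delays is None:
            raise ValueError("model has no delays set")
        return max(self.delays)

    @property
    def id(self) -> str:
        """Stable human-readable identifier, e.g. ``x1+x2+x1x2``."""
        parts = []
        for mono in self.monomials:
            parts.append(
                "".join(f"x{i}" if m == 1 else f"x{i}^{m}" for i, m in mono)
            )
        return "+".join(parts)

    def with_delays(self, *delays: int) -> "DDAModel":
        return replace(self, delays=tuple(int(d) for d in delays))


def default_model(tau1: int | None = None, tau2: int | None = None) -> DDAModel:
    """The simple symmetric model with quadratic nonlinearity:

    xdot = a1*x_tau1 + a2*x_tau2 + a3*x_tau1*x_tau2
    """
    delays = None if tau1 is None else (int(tau1), int(tau2))
    return DDAModel(
        monomials=(((1, 1),), ((2, 1),), ((1, 1), (2, 1))),
        n_delays=2,
        delays=delays,
    )


DEFAULT_MODEL_ID = default_model().id  # "x1+x2+x1x2"


def _all_monomials(n_delays: int, max_order: int) -> list[Monomial]:
    """All monomials over the delay indices with total degree in 1..max_order."""
    monos: list[Monomial] = []
    for orders in itertools.product(range(max_order + 1), repeat=n_delays):
        deg = sum(orders)
        if 1 <= deg <= max_order:
            monos.append(tuple((i + 1, m) for i, m in enumerate(orders) if m > 0))
    return monos


def _canonical(monomials: Iterable[Monomial], n_delays: int) -> tuple[Monomial, ...]:
    """Canonical representative under permutation of delay indices.

    Delays are free parameters, so relabeling tau1 <-> tau2 gives the same
    model family; the lexicographically smallest relabeled, sorted monomial
    tuple is used as the representative.
    """
    def mono_key(mono: Monomial):
        return (sum(order for _, order in mono), mono)

    best = None
    for perm in itertools.permutations(range(1, n_delays + 1)):
        relabeled = tuple(
            sorted(
                (
                    tuple(sorted((perm[idx - 1], order) for idx, order in mono))
                    for mono in monomials
                ),
                key=mono_key,
            )
        )
        if best is None or relabeled < best:
            best = relabeled
    assert best is not None
    return best


def enumerate_models(
    max_terms: int = 3, max_order: int = 3, n_delays: int = 2
) -> list[DDAModel]:
    """Enumerate all model structures up to the given size (delays unset).

    Models are deduplicated both as monomial sets and under permutation of
    delay indices, and returned in a deterministic canonical order. The
    default symmetric model is always present when the bounds admit it.
    """
    monos = _all_monomials(n_delays, max_order)
    seen: set[tuple[Monomial, ...]] = set()
    models: list[DDAModel] = []
    for k in range(1, max_terms + 1):
        for combo in itertools.combinations(monos, k):
            canon = _canonical(combo, n_delays)
            if canon in seen:
                continue
            seen.add(canon)
            models.append(DDAModel(monomials=canon, n_delays=n_delays))
    models.sort(key=lambda m: (m.n_terms, m.monomials))
    return models


def enumerate_delay_pairs(tau_min: int, tau_max: int) -> list[tuple[int, int]]:
    """All unordered delay pairs tau1 < tau2 in [tau_min, tau_max].

    The symmetric default model makes (tau1, tau2) and (tau2, tau1)
    equivalent, so only the strict upper triangle is enumerated.
    """
    if tau_min < 1 or tau_max < tau_min:
        raise ValueError("need 1 <= tau_min <= tau_max")
    return [
        (t1, t2)
        for t1 in range(tau_min, tau_max + 1)
        for t2 in range(t1 + 1, tau_max + 1)
    ]


@dataclass(frozen=True)
class FitWindow:
    """First/last usable 1-based index given delays and the derivative stencil."""

    t_lo: int
    t_hi: int

    @property
    def n_points(self) -> int:
        return max(0, self.t_hi - self.t_lo + 1)


def fit_window(L: int, model: DDAModel, w: int = 1) -> FitWindow:
    return FitWindow(t_lo=model.max_delay + w + 1, t_hi=L - w)


@dataclass
class DDAFeatures:
    """Fitting coefficients and least-square error of one ST or CT fit."""

    a: np.ndarray
    rho: float
    n_points: int
    kind: str  # "single-trial" | "cross-trial"
    degenerate: bool = False


def center_derivative(x: Sequence[float] | np.ndarray, w: int = 1) -> np.ndarray:
    """Center derivative with half-width ``w`` and unit spacing.

    Returns the series over the interior points only (length ``len(x) - 2w``);
    the ``w`` boundary points on each side are undefined.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * w + 1:
        raise FitError(f"series of length {len(x)} too short for w={w}")
    return (x[2 * w :] - x[: -2 * w]) / (2.0 * w)


def _walk_values(x) -> np.ndarray:
    if isinstance(x, DNAWalk):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def build_design(
    x,
    model: DDAModel,
    w: int = 1,
    standardize: bool = True,
    label: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Derivative vector and design matrix of the over-determined system.

    Row l corresponds to 1-based index t = t_lo + l within the fit window;
    column k holds the k-th monomial evaluated on the delayed series. When
    ``standardize`` is on (default), the series is centered and scaled to
    unit variance before embedding.
    """
    if model.delays is None:
        raise FitError("model delays must be set before fitting")
    xv = _walk_values(x)
    if standardize:
        xv = _standardize(xv)
    L = len(xv)
    win = fit_window(L, model, w)
    if win.n_points < 1:
        raise FitError(
            f"empty fit window for bin {label or '<series>'}: "
            f"L={L}, delays={model.delays}, w={w}"
        )
    # 0-based slice of usable t values: [t_lo-1, t_hi-1]
    lo, hi = win.t_lo - 1, win.t_hi - 1
    xdot = (xv[lo + w : hi + w + 1] - xv[lo - w : hi - w + 1]) / (2.0 * w)
    cols = []
    for mono in model.monomials:
        col = np.ones(win.n_points)
        for idx, order in mono:
            tau = model.delays[idx - 1]
            delayed = xv[lo - tau : hi - tau + 1]
            col = col * (delayed if order == 1 else delayed**order)
        cols.append(col)
    M = np.column_stack(cols)
    return xdot, M


@dataclass
class BinFactor:
    """Compact QR factor of one bin's augmented design ``[M | xdot]``.

    ``R`` is the (K+1)x(K+1) triangular factor; least-squares solutions and
    residual norms computed from it equal those of the full system exactly
    (orthogonal invariance), which makes CT fits over many bin pairs cheap.
    """

    R: np.ndarray
    n_points: int


def bin_factor(
    x, model: DDAModel, w: int = 1, standardize: bool = True, label: str = ""
) -> BinFactor:
    xdot, M = build_design(x, model, w=w, standardize=standardize, label=label)
    aug = np.column_stack([M, xdot])
    R = np.linalg.qr(aug, mode="r")
    return BinFactor(R=R, n_points=len(xdot))


def _solve_min_norm(B: np.ndarray, b: np.ndarray, n_points: int) -> tuple[np.ndarray, float, bool]:
    """Minimum-norm least squares of ``B a = b`` via SVD with rho = RMS residual."""
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    if s[0] == 0.0:
        degenerate = bool(np.all(b == 0))
        a = np.zeros(B.shape[1])
        rho = float(np.sqrt(np.sum(b**2) / n_points))
        return a, rho, degenerate
    keep = s > SVD_RCOND * s[0]
    a = Vt[keep].T @ ((U[:, keep].T @ b) / s[keep])
    r = B @ a - b
    rho = float(np.sqrt(np.sum(r**2) / n_points))
    return a, rho, False


def _features_from_factor(
    factors: Sequence[BinFactor], kind: str
) -> DDAFeatures:
    K = factors[0].R.shape[1] - 1
    B = np.vstack([f.R[:, :K] for f in factors])
    b = np.concatenate([f.R[:, K] for f in factors])
    n = sum(f.n_points for f in factors)
    a, rho, degenerate = _solve_min_norm(B, b, n)
    return DDAFeatures(a=a, rho=rho, n_points=n, kind=kind, degenerate=degenerate)


def fit_st(
    x, model: DDAModel, w: int = 1, standardize: bool = True, label: str = ""
) -> DDAFeatures:
    """Single-trial fit: minimum-norm SVD solution of ``xdot = M a``.

    ``rho`` is the root mean square residual over the rows actually fitted.
    """
    FIT_COUNTS["st"] += 1
    f = bin_factor(x, model, w=w, standardize=standardize, label=label)
    return _features_from_factor([f], "single-trial")


def fit_ct(
    xi=None,
    xj=None,
    model: DDAModel | None = None,
    w: int = 1,
    standardize: bool = True,
    factors: tuple[BinFactor, BinFactor] | None = None,
) -> DDAFeatures:
    """Cross-trial fit of two series on the row-stacked system.

    A single coefficient vector is fitted to ``[xdot_i; xdot_j] =
    [M_i; M_j] a``; ``rho`` runs over all stacked rows. Precomputed
    ``factors`` (from :func:`bin_factor`) may be supplied to avoid
    re-embedding the same bins across many pairs; the result is identical.
    """
    FIT_COUNTS["ct"] += 1
    if factors is None:
        if model is None:
            raise FitError("fit_ct needs a model when factors are not given")
        factors = (
            bin_factor(xi, model, w=w, standardize=standardize, label="i"),
            bin_factor(xj, model, w=w, standardize=standardize, label="j"),
        )
    return _features_from_factor(list(factors), "cross-trial")


def ergodicity(rho_si: float, rho_sj: float, rho_c: float) -> float:
    """Dynamical-ergodicity score E = |mean(ST errors)/CT error - 1|.

    Near zero when the two series are dynamically similar. Undefined (NaN)
    when the CT error is zero while the ST errors are not; the caller masks
    such bin pairs.
    """
    if rho_c == 0.0:
        if rho_si == 0.0 and rho_sj == 0.0:
            return 0.0
        return float("nan")
    return float(abs((rho_si + rho_sj) / 2.0 / rho_c - 1.0))
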