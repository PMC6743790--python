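"""Saturating Michaelis-Menten cleavage kinetics.

The observable is the fraction of a peptide substrate that remains
uncleaved, ``S`` in [0, 1] with ``S(0) = 1``.  One protease at
concentration ``alpha`` cleaves it at

    dS/dt = -alpha * V * (S - beta)^n / ((S - beta)^n + K^n)

where ``V`` is the maximal cleavage rate (fraction per minute), ``K`` the
half-saturation level, ``n`` the reaction order, and ``beta`` the
saturation floor: the fraction-uncleaved level at which the reaction
stops (the rate vanishes at ``S = beta``).  For a mixture of N proteases
acting on substrate i, the per-protease rates add (no synergy or
antagonism), each term carrying its own (V_ij, K_ij, n_ij, beta_ij) and
deactivating at its own floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._integrate import DEFAULT_ATOL, DEFAULT_RTOL, integrate_grid

__all__ = [
    "ParameterError",
    "DomainError",
    "ShapeError",
    "KineticParams",
    "KineticMatrix",
    "Timecourse",
    "MixingCoefficients",
    "cleavage_rate",
    "integrate_single",
    "integrate_mixture",
]


class ParameterError(ValueError):
    """A kinetic parameter or concentration violates its constraints."""


class DomainError(ValueError):
    """A substrate level lies outside the model's valid domain."""


class ShapeError(ValueError):
    """Dimensions of related containers do not match."""


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters (V, K, n, beta) of one protease-substrate reaction.

    V : maximal cleavage rate, fraction uncleaved per minute (> 0)
    K : half-saturation level in fraction-uncleaved units (> 0)
    n : reaction order, a positive real (not restricted to integers)
    beta : saturation floor, fraction-uncleaved at which cleavage stops
        (0 <= beta < 1)
    """

    V: float
    K: float
    n: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.V > 0 and self.K > 0 and self.n > 0):
            raise ParameterError(
                f"V, K, n must be positive; got V={self.V}, K={self.K}, n={self.n}"
            )
        if not (0.0 <= self.beta < 1.0):
            raise ParameterError(f"beta must lie in [0, 1); got {self.beta}")

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.K, self.n, self.beta], dtype=float)


@dataclass(frozen=True)
class Timecourse:
    """Fraction-uncleaved observations y_z at sampling times t_z (minutes)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ShapeError("times and values must be 1-D of equal length")
        if t.size < 1:
            raise ShapeError("a timecourse needs at least one observation")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DomainError("times must be non-negative and strictly increasing")
        if np.any(y < 0) or np.any(y > 1):
            raise DomainError("fraction-uncleaved values must lie in [0, 1]")

    @property
    def Q(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class MixingCoefficients:
    """Nonnegative protease concentrations alpha_j in a mixture."""

    alphas: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        object.__setattr__(self, "alphas", a)
        if a.ndim != 1:
            raise ShapeError("alphas must be a 1-D vector")
        if np.any(a < 0):
            raise ParameterError("mixing coefficients must be nonnegative")

    def __len__(self) -> int:
        return self.alphas.size

    def __iter__(self):
        return iter(self.alphas)


def _unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(x) for x in ids)
    if len(set(ids)) != len(ids):
        raise ShapeError(f"{what} identifiers must be unique")
    return ids


@dataclass(frozen=True)
class KineticMatrix:
    """M x N grid of kinetic parameters for M substrates against N proteases.

    Stored as four (M, N) arrays V, K, n, beta; cell (i, j) holds the
    parameters of substrate i reacting with protease j.
    """

    substrates: tuple[str, ...]
    proteases: tuple[str, ...]
    V: np.ndarray
    K: np.ndarray
    n: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        subs = _unique(self.substrates, "substrate")
        prots = _unique(self.proteases, "protease")
        object.__setattr__(self, "substrates", subs)
        object.__setattr__(self, "proteases", prots)
        shape = (len(subs), len(prots))
        for name in ("V", "K", "n", "beta"):
            arr = np.ascontiguousarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ShapeError(
                    f"{name} has shape {arr.shape}, expected {shape} from identifiers"
                )
            object.__setattr__(self, name, arr)
        if not (np.all(self.V > 0) and np.all(self.K > 0) and np.all(self.n > 0)):
            raise ParameterError("V, K, n must be positive in every cell")
        if np.any(self.beta < 0) or np.any(self.beta >= 1):
            raise ParameterError("beta must lie in [0, 1) in every cell")

    @property
    def M(self) -> int:
        return len(self.substrates)

    @property
    def N(self) -> int:
        return len(self.proteases)

    @classmethod
    def from_grid(
        cls,
        substrates: Sequence[str],
        proteases: Sequence[str],
        grid: Sequence[Sequence[KineticParams]],
    ) -> "KineticMatrix":
        M, N = len(substrates), len(proteases)
        if len(grid) != M or any(len(row) != N for row in grid):
            raise ShapeError("grid dimensions must match identifier lists")
        V = np.array([[p.V for p in row] for row in grid])
        K = np.array([[p.K for p in row] for row in grid])
        n = np.array([[p.n for p in row] for row in grid])
        b = np.array([[p.beta for p in row] for row in grid])
        return cls(tuple(substrates), tuple(proteases), V, K, n, b)

    @classmethod
    def from_columns(
        cls,
        substrates: Sequence[str],
        proteases: Sequence[str],
        columns: Sequence[Sequence[KineticParams]],
    ) -> "KineticMatrix":
        """Build from per-protease columns (each a length-M parameter list)."""
        grid = [[col[i] for col in columns] for i in range(len(substrates))]
        return cls.from_grid(substrates, proteases, grid)

    def param(self, i: int, j: int) -> KineticParams:
        return KineticParams(
            V=float(self.V[i, j]),
            K=float(self.K[i, j]),
            n=float(self.n[i, j]),
            beta=float(self.beta[i, j]),
        )

    def column(self, j: int) -> list[KineticParams]:
        return [self.param(i, j) for i in range(self.M)]

    def _take(self, rows: np.ndarray, cols: np.ndarray) -> "KineticMatrix":
        return KineticMatrix(
            tuple(self.substrates[i] for i in rows),
            tuple(self.proteases[j] for j in cols),
            self.V[np.ix_(rows, cols)],
            self.K[np.ix_(rows, cols)],
            self.n[np.ix_(rows, cols)],
            self.beta[np.ix_(rows, cols)],
        )

    def select_substrates(self, names: Iterable[str]) -> "KineticMatrix":
        idx = []
        for name in names:
            if name not in self.substrates:
                raise ShapeError(f"unknown substrate {name!r}")
            idx.append(self.substrates.index(name))
        return self._take(np.array(idx, dtype=int), np.arange(self.N))

    def select_proteases(self, names: Iterable[str]) -> "KineticMatrix":
        idx = []
        for name in names:
            if name not in self.proteases:
                raise ShapeError(f"unknown protease {name!r}")
            idx.append(self.proteases.index(name))
        return self._take(np.arange(self.M), np.array(idx, dtype=int))


def cleavage_rate(s: float, params: KineticParams, alpha: float) -> float:
    """Instantaneous rate dS/dt at fraction-uncleaved ``s`` (always <= 0).

    Zero exactly when ``s`` sits at the saturation floor or the protease
    concentration is zero; half-maximal (-alpha*V/2) at ``s = beta + K``.
    """
    if alpha < 0:
        raise ParameterError(f"alpha must be nonnegative; got {alpha}")
    if s < params.beta - 1e-12 or s > 1.0 + 1e-12:
        raise DomainError(
            f"s={s} outside [beta, 1] = [{params.beta}, 1] for this reaction"
        )
    d = max(s - params.beta, 0.0)
    if d == 0.0 or alpha == 0.0:
        return 0.0
    dn = d**params.n
    return -alpha * params.V * dn / (dn + params.K**params.n)


def _as_times(times) -> np.ndarray:
    t = np.ascontiguousarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ShapeError("times must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise DomainError("times must be non-negative and strictly increasing")
    return t


def integrate_single(
    params: KineticParams,
    alpha: float,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Timecourse:
    """Solve the single-protease rate law from S(0) = 1 at the given times.

    The trajectory is monotone non-increasing and clipped so it never
    undershoots the saturation floor ``beta``.
    """
    if alpha < 0:
        raise ParameterError(f"alpha must be nonnegative; got {alpha}")
    t = _as_times(times)
    shape = (1, 1)
    y = integrate_grid(
        np.full(shape, params.V),
        np.full(shape, params.K),
        np.full(shape, params.n),
        np.full(shape, params.beta),
        np.array([float(alpha)]),
        t,
        rtol,
        atol,
    )[0]
    return Timecourse(times=t, values=np.clip(y, params.beta, 1.0))


def integrate_mixture(
    km: KineticMatrix,
    alphas,
    times,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Solve the summed rate law for every substrate against a mixture.

    Returns an (M, Q) array; row i starts at 1, is monotone non-increasing
    and stays at or above min_j beta_ij — each protease's term switches
    off at its own floor, so no term can drive the substrate below the
    smallest applicable floor (and none regenerates substrate).
    """
    if isinstance(alphas, MixingCoefficients):
        a = alphas.alphas
    else:
        a = np.ascontiguousarray(alphas, dtype=float)
    if a.ndim != 1 or a.size != km.N:
        raise ShapeError(f"alphas has length {a.size}, expected N={km.N}")
    if np.any(a < 0):
        raise ParameterError("mixing coefficients must be nonnegative")
    t = _as_times(times)
    y = integrate_grid(km.V, km.K, km.n, km.beta, a, t, rtol, atol)
    active = a > 0
    if np.any(active):
        floors = km.beta[:, active].min(axis=1)
    else:
        floors = np.zeros(km.M)
    return np.clip(y, floors[:, None], 1.0)
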