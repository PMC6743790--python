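"""Synthetic cleavage-assay generation with known ground truth.

Emulates the structure of real multiplexed protease activity assays: a
library of ~7 peptide substrates observed as fraction-uncleaved over a
0-400 minute window at a handful of time points, each trace decaying
monotonically from 1 toward a pair-specific saturation floor.  Ground
truth (kinetic parameters, mixing coefficients, family structure) is
always available to the caller, which is what makes parameter-recovery
experiments possible.

Parameter distributions are uniform over configurable ranges.  The
defaults (V in [0.005, 0.05] min^-1, K in [0.1, 0.9], n in [0.5, 3],
beta in [0, 0.4], mixing coefficients in [0.2, 2]) produce visible but
incomplete decay with nonzero floors over the observation window, the
qualitative shape of real recombinant-protease assay traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .kinetics import (
    KineticMatrix,
    KineticParams,
    MixingCoefficients,
    ParameterError,
    ShapeError,
    Timecourse,
    integrate_mixture,
    integrate_single,
)

__all__ = [
    "ParamRanges",
    "SimConfig",
    "SingleAssay",
    "MixtureAssay",
    "sample_kinetic_matrix",
    "interpolate_protease",
    "make_family",
    "sample_family_panel",
    "simulate_single_assays",
    "sample_mixing_coefficients",
    "simulate_mixture_assay",
]


def _check_range(lohi, what: str, lo_min=None, hi_max=None) -> tuple[float, float]:
    lo, hi = float(lohi[0]), float(lohi[1])
    if lo > hi:
        raise ParameterError(f"{what} range must satisfy low <= high; got {lohi}")
    if lo_min is not None and lo < lo_min:
        raise ParameterError(f"{what} range must start at or above {lo_min}")
    if hi_max is not None and hi >= hi_max:
        raise ParameterError(f"{what} range must stay below {hi_max}")
    return lo, hi


@dataclass(frozen=True)
class ParamRanges:
    """Uniform sampling ranges (low, high) for each kinetic parameter."""

    V: tuple[float, float] = (0.005, 0.05)
    K: tuple[float, float] = (0.1, 0.9)
    n: tuple[float, float] = (0.5, 3.0)
    beta: tuple[float, float] = (0.0, 0.4)

    def __post_init__(self) -> None:
        _check_range(self.V, "V", lo_min=0.0)
        _check_range(self.K, "K", lo_min=0.0)
        _check_range(self.n, "n", lo_min=0.0)
        _check_range(self.beta, "beta", lo_min=0.0, hi_max=1.0)
        if self.V[0] <= 0 or self.K[0] <= 0 or self.n[0] <= 0:
            raise ParameterError("V, K, n ranges must be strictly positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    ``times`` are the Q sampling times of *mixture* assays in minutes.
    The default is Q = 2 points {0, 60}: the baseline anchor at t = 0
    (every substrate starts fully uncleaved) plus one informative
    mid-transient read-out, so each substrate contributes one effective
    equation per mixture and a library of M substrates can resolve at
    most M proteases — the identifiability threshold that substrate-
    selection experiments probe.  ``calibration_times`` are the sampling
    times of the single-protease calibration assays, denser by default
    (six points spanning the 0-400 min window, emulating the sampling of
    real recombinant-protease traces): the single-protease rate law has
    four parameters, so calibration data must carry more than two points
    for the fitted kinetics to transfer to mixtures.  ``P`` is the
    number of repeated mixtures per condition; ``lam`` the interpolation
    weight used when constructing correlated proteases; ``noise_sd`` the
    SD of additive Gaussian observation noise on fraction-uncleaved (0
    by default: variability comes from random parameter/coefficient
    draws).
    """

    M: int = 7
    N: int = 7
    times: tuple[float, ...] = (0.0, 60.0)
    calibration_times: tuple[float, ...] = (10.0, 30.0, 60.0, 120.0, 240.0, 400.0)
    P: int = 200
    lam: float = 0.9
    noise_sd: float = 0.0
    seed: int | None = None
    param_ranges: ParamRanges = field(default_factory=ParamRanges)
    alpha_range: tuple[float, float] = (0.2, 2.0)

    def __post_init__(self) -> None:
        if self.M < 1 or self.N < 1:
            raise ParameterError("M and N must be at least 1")
        if self.P < 1:
            raise ParameterError("P must be at least 1")
        if not (0.0 <= self.lam <= 1.0):
            raise ParameterError(f"lambda must lie in [0, 1]; got {self.lam}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be nonnegative")
        for name in ("times", "calibration_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
                raise ParameterError(
                    f"{name} must be non-negative and strictly increasing"
                )
        _check_range(self.alpha_range, "alpha", lo_min=0.0)

    @property
    def Q(self) -> int:
        return len(self.times)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SingleAssay:
    """One protease against one substrate: a Q-point timecourse."""

    protease: str
    substrate: str
    timecourse: Timecourse

    def __post_init__(self) -> None:
        if not self.protease or not self.substrate:
            raise ShapeError("protease and substrate identifiers must be non-empty")


@dataclass(frozen=True)
class MixtureAssay:
    """M x Q fraction-uncleaved matrix for a library exposed to a mixture."""

    substrates: tuple[str, ...]
    times: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "substrates", tuple(self.substrates))
        if Y.shape != (len(self.substrates), t.size):
            raise ShapeError(
                f"Y has shape {Y.shape}, expected ({len(self.substrates)}, {t.size})"
            )
        if np.any(Y < 0) or np.any(Y > 1):
            raise ParameterError("fraction-uncleaved entries must lie in [0, 1]")


def sample_kinetic_matrix(
    config: SimConfig, rng: np.random.Generator | None = None
) -> KineticMatrix:
    """Draw an M x N kinetic panel, each parameter uniform over its range."""
    rng = config.rng() if rng is None else rng
    pr = config.param_ranges
    shape = (config.M, config.N)
    return KineticMatrix(
        substrates=tuple(f"S{i + 1}" for i in range(config.M)),
        proteases=tuple(f"E{j + 1}" for j in range(config.N)),
        V=rng.uniform(*pr.V, shape),
        K=rng.uniform(*pr.K, shape),
        n=rng.uniform(*pr.n, shape),
        beta=rng.uniform(*pr.beta, shape),
    )


def interpolate_protease(
    col1: Sequence[KineticParams], col2: Sequence[KineticParams], lam: float
) -> list[KineticParams]:
    """Convex combination lam*p1 + (1-lam)*p2 of two parameter columns.

    lam = 1 copies col1, lam = 0 copies col2; intermediate values make a
    protease whose cleavage dynamics correlate with col1 increasingly as
    lam grows — the knob that tunes deconvolution difficulty.
    """
    if len(col1) != len(col2):
        raise ShapeError("columns must have the same number of substrates")
    if not (0.0 <= lam <= 1.0):
        raise ParameterError(f"lambda must lie in [0, 1]; got {lam}")
    out = []
    for p1, p2 in zip(col1, col2):
        out.append(
            KineticParams(
                V=lam * p1.V + (1 - lam) * p2.V,
                K=lam * p1.K + (1 - lam) * p2.K,
                n=lam * p1.n + (1 - lam) * p2.n,
                beta=lam * p1.beta + (1 - lam) * p2.beta,
            )
        )
    return out


def make_family(
    base_cols: Sequence[Sequence[KineticParams]], lam: float
) -> tuple[list[KineticParams], list[KineticParams], list[KineticParams]]:
    """Build a 3-member family (p1, p4, p5) from independent bases (p1, p2, p3).

    p4 = lam*p1 + (1-lam)*p2 and p5 = lam*p1 + (1-lam)*p3, so in
    concatenated-parameter Euclidean distance d(p1, p4) = (1-lam) d(p1, p2)
    exactly; lam close to 1 gives a tightly correlated family.
    """
    if len(base_cols) != 3:
        raise ShapeError("make_family needs exactly three base columns")
    p1, p2, p3 = (list(c) for c in base_cols)
    if not (len(p1) == len(p2) == len(p3)):
        raise ShapeError("base columns must have equal length")
    p4 = interpolate_protease(p1, p2, lam)
    p5 = interpolate_protease(p1, p3, lam)
    return p1, p4, p5


def sample_family_panel(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_families: int = 3,
    members: int = 3,
) -> tuple[KineticMatrix, dict[str, str]]:
    """Draw a panel of ``n_families`` independent 3-member protease families.

    For each family, three independent parameter columns are drawn and
    collapsed to (p1, p4, p5) via :func:`make_family` at ``config.lam``.
    Returns the M x (3*n_families) kinetic matrix and the true
    protease -> family assignment.
    """
    if members != 3:
        raise ShapeError("family construction is defined for 3 members (p1, p4, p5)")
    rng = config.rng() if rng is None else rng
    base_cfg = config.with_(N=3)
    columns: list[list[KineticParams]] = []
    proteases: list[str] = []
    labels: dict[str, str] = {}
    for f in range(n_families):
        base = sample_kinetic_matrix(base_cfg, rng)
        fam_cols = make_family([base.column(j) for j in range(3)], config.lam)
        for k, col in enumerate(fam_cols):
            name = f"F{f + 1}m{k + 1}"
            proteases.append(name)
            labels[name] = f"F{f + 1}"
            columns.append(col)
    substrates = tuple(f"S{i + 1}" for i in range(config.M))
    km = KineticMatrix.from_columns(substrates, tuple(proteases), columns)
    return km, labels


def _add_noise(y: np.ndarray, noise_sd: float, rng: np.random.Generator | None):
    if noise_sd == 0.0:
        return y
    if rng is None:
        raise ParameterError("an rng is required when noise_sd > 0")
    return np.clip(y + rng.normal(0.0, noise_sd, size=y.shape), 0.0, 1.0)


def simulate_single_assays(
    km: KineticMatrix,
    times,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[SingleAssay]:
    """Simulate every protease-substrate pair at unit concentration (alpha=1)."""
    assays = []
    t = np.asarray(times, dtype=float)
    for i, sub in enumerate(km.substrates):
        for j, prot in enumerate(km.proteases):
            tc = integrate_single(km.param(i, j), 1.0, t)
            y = _add_noise(tc.values, noise_sd, rng)
            assays.append(
                SingleAssay(protease=prot, substrate=sub, timecourse=Timecourse(t, y))
            )
    return assays


def sample_mixing_coefficients(
    rng: np.random.Generator, N: int, alpha_range=(0.2, 2.0)
) -> MixingCoefficients:
    """Draw N independent uniform mixing coefficients from ``alpha_range``."""
    lo, hi = _check_range(alpha_range, "alpha", lo_min=0.0)
    return MixingCoefficients(rng.uniform(lo, hi, size=N))


def simulate_mixture_assay(
    km: KineticMatrix,
    alphas,
    times,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> MixtureAssay:
    """Simulate the substrate library against a protease mixture."""
    t = np.asarray(times, dtype=float)
    Y = integrate_mixture(km, alphas, t)
    Y = _add_noise(Y, noise_sd, rng)
    return MixtureAssay(substrates=km.substrates, times=t, Y=Y)
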