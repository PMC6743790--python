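"""Bound-constrained nonlinear least-squares estimation.

Two fitting problems, both solved with scipy's trust-region-reflective
least-squares (an active-set-equivalent bound-constrained method), with
seeded multi-start because the kinetic objective is nonconvex in (K, n):

1. kinetic parameters (V, K, n, beta) of one protease-substrate pair
   from a Q-point fraction-uncleaved timecourse, minimising
   sum_z (y_z - S(t_z; V, K, n, beta))^2 subject to V, K, n > 0 and
   beta in [0, 1);

2. nonnegative mixing coefficients alpha of a protease mixture from an
   M x Q mixture assay, minimising the double sum of squared residuals
   between the data and the re-integrated mixture model, subject to
   alpha_j >= 0.

Each residual evaluation re-integrates the rate law; integration
tolerances (1e-8/1e-10) sit well below the optimizer tolerances (1e-8)
so finite-difference gradients are not dominated by integrator noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from ._integrate import DEFAULT_ATOL, DEFAULT_RTOL, integrate_grid
from .kinetics import (
    KineticMatrix,
    KineticParams,
    MixingCoefficients,
    ShapeError,
    integrate_single,
)
from .simulate import MixtureAssay, ParamRanges, SingleAssay

__all__ = [
    "FitOptions",
    "FitResult",
    "MissingAssayError",
    "predict_single",
    "fit_kinetics",
    "fit_kinetics_matrix",
    "fit_family_kinetics",
    "estimate_mixing",
]


class MissingAssayError(ShapeError):
    """A required protease-substrate pair is absent from the assay grid."""


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the multi-start bounded least-squares fits.

    ``n_restarts`` random initialisations are tried and the best residual
    kept (first encountered wins ties).  Kinetic starts are drawn
    uniformly from ``init_ranges``; mixing-coefficient starts are the
    all-ones vector followed by 1 + N(0, 0.5) perturbations.  Upper
    bounds keep the solver's box finite: V is capped at 10x the steepest
    rate implied by the data, K at ``k_upper``, n at ``n_bounds[1]``,
    alpha at ``alpha_upper``.

    ``diff_step`` (relative finite-difference step) must sit well above
    the integrator's ~1e-8 error floor or gradients degenerate into
    integration noise; 1e-4 balances truncation against that floor.
    """

    n_restarts: int = 5
    seed: int | None = None
    init_ranges: ParamRanges = field(default_factory=ParamRanges)
    k_upper: float = 10.0
    n_bounds: tuple[float, float] = (0.05, 5.0)
    v_upper: float | None = None
    alpha_upper: float = 100.0
    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    diff_step: float = 1e-4


@dataclass(frozen=True)
class FitResult:
    """Outcome of one fit: the estimate, its SSE, and convergence info."""

    estimate: KineticParams | MixingCoefficients
    residual: float
    converged: bool
    n_restarts_used: int


def _rng_from(opts: FitOptions, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(opts.seed)


def predict_single(params: KineticParams, alpha: float, times) -> np.ndarray:
    """Model prediction for a single-pair assay.

    The 1 - cumulative-cleavage form of the fitting objective is the
    trajectory of the rate law itself, so this is just the integrated
    solution evaluated at the sampling times.
    """
    return integrate_single(params, alpha, times).values


def _predict_arrays(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    V, K, n, beta = x
    shape = (1, 1)
    return integrate_grid(
        np.full(shape, V),
        np.full(shape, K),
        np.full(shape, n),
        np.full(shape, beta),
        np.ones(1),
        t,
        DEFAULT_RTOL,
        DEFAULT_ATOL,
    )[0]


def _implied_max_rate(timecourses) -> float:
    """Steepest fraction-per-minute drop implied by any observed segment."""
    best = 0.0
    for t, y in timecourses:
        tt = np.concatenate(([0.0], t)) if t[0] > 0 else t
        yy = np.concatenate(([1.0], y)) if t[0] > 0 else y
        if tt.size >= 2:
            rates = -np.diff(yy) / np.diff(tt)
            if rates.size:
                best = max(best, float(rates.max()))
    return best


def _fit_kinetics_pooled(
    timecourses: list[tuple[np.ndarray, np.ndarray]],
    opts: FitOptions,
    rng: np.random.Generator | None,
) -> FitResult:
    rng = _rng_from(opts, rng)
    pr = opts.init_ranges
    v_upper = opts.v_upper
    if v_upper is None:
        v_upper = max(10.0 * _implied_max_rate(timecourses), pr.V[1], 1e-3)
    lower = np.array([1e-8, 1e-6, opts.n_bounds[0], 0.0])
    upper = np.array([v_upper, opts.k_upper, opts.n_bounds[1], 1.0 - 1e-6])

    def residuals(x: np.ndarray) -> np.ndarray:
        parts = [_predict_arrays(x, t) - y for t, y in timecourses]
        return np.concatenate(parts)

    best = None
    x_scale = np.array([max(pr.V[1], 1e-3), max(pr.K[1], 0.1), 1.0, 0.2])
    for _ in range(opts.n_restarts):
        x0 = np.array(
            [
                rng.uniform(*pr.V),
                rng.uniform(*pr.K),
                rng.uniform(*pr.n),
                rng.uniform(*pr.beta),
            ]
        )
        x0 = np.clip(x0, lower, upper)
        res = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            x_scale=x_scale,
            diff_step=opts.diff_step,
            ftol=opts.ftol,
            xtol=opts.xtol,
            gtol=opts.gtol,
        )
        if best is None or res.cost < best.cost:
            best = res
    params = KineticParams(
        V=float(best.x[0]), K=float(best.x[1]), n=float(best.x[2]), beta=float(best.x[3])
    )
    return FitResult(
        estimate=params,
        residual=float(2.0 * best.cost),
        converged=bool(best.success),
        n_restarts_used=opts.n_restarts,
    )


def fit_kinetics(
    assay: SingleAssay,
    opts: FitOptions | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit (V, K, n, beta) to one single-protease-single-substrate assay."""
    opts = opts or FitOptions()
    tc = assay.timecourse
    return _fit_kinetics_pooled([(tc.times, tc.values)], opts, rng)


def fit_family_kinetics(
    member_assays: Sequence[SingleAssay],
    opts: FitOptions | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one representative parameter set to a family of member assays.

    Member timecourses (same substrate, different proteases of one
    activity family) are treated as replicates: the pooled sum of squared
    errors over all members' observations is minimised by a single
    (V, K, n, beta).
    """
    opts = opts or FitOptions()
    if len(member_assays) == 0:
        raise ShapeError("at least one member assay is required")
    substrates = {a.substrate for a in member_assays}
    if len(substrates) != 1:
        raise ShapeError(
            f"family members must share one substrate; got {sorted(substrates)}"
        )
    tcs = [(a.timecourse.times, a.timecourse.values) for a in member_assays]
    return _fit_kinetics_pooled(tcs, opts, rng)


def fit_kinetics_matrix(
    assays: Sequence[SingleAssay],
    opts: FitOptions | None = None,
) -> KineticMatrix:
    """Fit every cell of a complete M x N single-assay grid independently.

    Substrate/protease order follows first appearance in ``assays``.
    Per-cell RNGs are spawned from ``opts.seed`` so results do not depend
    on fitting order.
    """
    opts = opts or FitOptions()
    substrates: list[str] = []
    proteases: list[str] = []
    table: dict[tuple[str, str], SingleAssay] = {}
    for a in assays:
        if a.substrate not in substrates:
            substrates.append(a.substrate)
        if a.protease not in proteases:
            proteases.append(a.protease)
        key = (a.substrate, a.protease)
        if key in table:
            raise ShapeError(f"duplicate assay for pair {key}")
        table[key] = a
    M, N = len(substrates), len(proteases)
    missing = [
        (s, p) for s in substrates for p in proteases if (s, p) not in table
    ]
    if missing:
        raise MissingAssayError(f"missing assays for pairs: {missing}")
    ss = np.random.SeedSequence(opts.seed)
    children = ss.spawn(M * N)
    V = np.empty((M, N))
    K = np.empty((M, N))
    n = np.empty((M, N))
    beta = np.empty((M, N))
    for i, s in enumerate(substrates):
        for j, p in enumerate(proteases):
            rng = np.random.default_rng(children[i * N + j])
            fit = fit_kinetics(table[(s, p)], opts, rng)
            est = fit.estimate
            V[i, j], K[i, j], n[i, j], beta[i, j] = est.V, est.K, est.n, est.beta
    return KineticMatrix(tuple(substrates), tuple(proteases), V, K, n, beta)


def estimate_mixing(
    mix: MixtureAssay,
    km: KineticMatrix,
    opts: FitOptions | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Estimate nonnegative mixing coefficients from a mixture assay.

    Every candidate alpha re-integrates the full mixture rate law with
    the supplied kinetic matrix (typically itself fitted from single
    assays) and the M x Q squared-residual objective is minimised over
    alpha >= 0.
    """
    opts = opts or FitOptions()
    rng = _rng_from(opts, rng)
    km = km.select_substrates(mix.substrates)
    t = np.ascontiguousarray(mix.times, dtype=float)
    Y = mix.Y
    N = km.N

    def residuals(a: np.ndarray) -> np.ndarray:
        pred = integrate_grid(
            km.V, km.K, km.n, km.beta, np.ascontiguousarray(a), t,
            DEFAULT_RTOL, DEFAULT_ATOL,
        )
        return (pred - Y).ravel()

    lower = np.zeros(N)
    upper = np.full(N, opts.alpha_upper)
    best = None
    for r in range(opts.n_restarts):
        if r == 0:
            x0 = np.ones(N)
        else:
            x0 = np.clip(1.0 + rng.normal(0.0, 0.5, size=N), 1e-3, opts.alpha_upper)
        res = least_squares(
            residuals,
            x0,
            bounds=(lower, upper),
            method="trf",
            diff_step=opts.diff_step,
            ftol=opts.ftol,
            xtol=opts.xtol,
            gtol=opts.gtol,
        )
        if best is None or res.cost < best.cost:
            best = res
    alphas = MixingCoefficients(np.maximum(best.x, 0.0))
    return FitResult(
        estimate=alphas,
        residual=float(2.0 * best.cost),
        converged=bool(best.success),
        n_restarts_used=opts.n_restarts,
    )
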