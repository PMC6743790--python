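"""Experiment drivers: difficulty sweeps, substrate selection, families.

These orchestrate the full two-step pipeline the way it would be used to
plan a real assay: simulate single-protease calibration data, fit
kinetics from it (never from the unobservable truth), simulate P repeated
mixtures with random coefficients, deconvolve them with the fitted
kinetics, and score with RMSE.  On top of that pipeline sit three study
designs:

* a lambda sweep that tunes protease correlation to map how RMSE tracks
  deconvolution difficulty;
* greedy backward substrate elimination, dropping at each round the
  substrate whose removal hurts RMSE least, down to two substrates;
* protease-family analysis, clustering proteases with correlated
  cleavage signatures (single-linkage, Euclidean) and deconvolving the
  families instead of the individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .estimate import FitOptions, estimate_mixing, fit_family_kinetics, fit_kinetics_matrix
from .evaluate import RmseReport, family_rmse, family_true_sums, rmse_report
from .kinetics import KineticMatrix, ShapeError
from .simulate import (
    SimConfig,
    SingleAssay,
    interpolate_protease,
    sample_kinetic_matrix,
    simulate_mixture_assay,
    simulate_single_assays,
)

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "FamilyAssignment",
    "FamilyDeconvResult",
    "evaluate_panel",
    "greedy_substrate_reduction",
    "lambda_difficulty_sweep",
    "cluster_proteases",
    "family_deconvolution_experiment",
]

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class SelectionStep:
    substrate_set: tuple[str, ...]
    removed: str | None
    rmse: float


@dataclass(frozen=True)
class SelectionTrace:
    """Record of a greedy backward elimination run, largest set first."""

    steps: tuple[SelectionStep, ...]

    def __post_init__(self) -> None:
        steps = tuple(self.steps)
        object.__setattr__(self, "steps", steps)
        for prev, cur in zip(steps, steps[1:]):
            if cur.removed is None:
                raise ShapeError("only the first step may have no removed substrate")
            expect = tuple(s for s in prev.substrate_set if s != cur.removed)
            if expect != cur.substrate_set:
                raise ShapeError("each step must be the previous set minus its removal")
        if steps and len(steps[-1].substrate_set) < 2:
            raise ShapeError("elimination must stop at two substrates")

    @property
    def terminal_size(self) -> int:
        return len(self.steps[-1].substrate_set)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "n_substrates": [len(s.substrate_set) for s in self.steps],
                "removed": [s.removed for s in self.steps],
                "remaining_set": [",".join(s.substrate_set) for s in self.steps],
                "rmse": [s.rmse for s in self.steps],
            }
        )


@dataclass(frozen=True)
class FamilyAssignment:
    """Flat protease -> family labelling from a dendrogram cut."""

    labels: dict[str, str]
    cutoff: float
    linkage_heights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "linkage_heights", np.asarray(self.linkage_heights, dtype=float)
        )
        if not self.labels:
            raise ShapeError("assignment must label at least one protease")

    @property
    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, f in self.labels.items():
            out.setdefault(f, []).append(p)
        return out

    @property
    def n_families(self) -> int:
        return len(set(self.labels.values()))


@dataclass(frozen=True)
class FamilyDeconvResult:
    """Paired (true member-sum, estimated family coefficient) table."""

    table: pd.DataFrame
    family_report: RmseReport
    protease_report: RmseReport | None

    @property
    def pearson_r(self) -> float:
        return float(
            np.corrcoef(self.table["true_sum"], self.table["estimated"])[0, 1]
        )


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(_SEED_MAX))


def _deconvolve(
    km_sim: KineticMatrix,
    km_fit: KineticMatrix,
    config: SimConfig,
    true_alphas: np.ndarray,
    seed: int,
    fit_opts: FitOptions,
) -> np.ndarray:
    """Simulate and deconvolve P mixtures; returns the P x N estimate matrix."""
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_est = (np.random.default_rng(c) for c in ss.spawn(2))
    P = true_alphas.shape[0]
    est = np.empty_like(true_alphas)
    for k in range(P):
        mix = simulate_mixture_assay(
            km_sim, true_alphas[k], config.times, config.noise_sd, rng_noise
        )
        fit = estimate_mixing(mix, km_fit, fit_opts, rng_est)
        est[k] = fit.estimate.alphas
    return est


def evaluate_panel(
    km_true: KineticMatrix,
    substrate_subset: Sequence[str],
    config: SimConfig,
    fit_opts: FitOptions | None = None,
    rng: np.random.Generator | None = None,
) -> RmseReport:
    """Full-pipeline deconvolution accuracy for one substrate subset.

    Simulates single assays for the subset, fits kinetics from them,
    simulates ``config.P`` mixtures with random coefficients, estimates
    the coefficients using the *fitted* kinetics, and reports RMSE.
    Returns an :class:`RmseReport`; its ``overall`` attribute is the
    headline number.
    """
    subset = list(substrate_subset)
    if not subset:
        raise ShapeError("substrate subset must be non-empty")
    fit_opts = fit_opts or FitOptions()
    rng = config.rng() if rng is None else rng
    km_sub = km_true.select_substrates(subset)
    assays = simulate_single_assays(
        km_sub, config.calibration_times, config.noise_sd, rng
    )
    km_fit = fit_kinetics_matrix(assays, replace(fit_opts, seed=_spawn_seed(rng)))
    true_alphas = rng.uniform(*config.alpha_range, size=(config.P, km_true.N))
    est = _deconvolve(km_sub, km_fit, config, true_alphas, _spawn_seed(rng), fit_opts)
    return rmse_report(true_alphas, est, km_true.proteases)


def greedy_substrate_reduction(
    km_true: KineticMatrix,
    config: SimConfig,
    fit_opts: FitOptions | None = None,
) -> SelectionTrace:
    """Backward elimination of substrates by deconvolution RMSE.

    Kinetics are fitted once per cell from the full panel's simulated
    single assays and re-restricted to each candidate subset.  At each
    round every leave-one-out subset of the current set is evaluated on
    a shared draw of true coefficients (paired comparison); the
    substrate whose removal gives the lowest RMSE is dropped, ties going
    to the lowest substrate index.  Stops at two substrates.
    """
    if km_true.M < 3:
        raise ShapeError("greedy reduction needs at least three substrates")
    fit_opts = fit_opts or FitOptions()
    rng = config.rng()
    assays = simulate_single_assays(
        km_true, config.calibration_times, config.noise_sd, rng
    )
    km_fit = fit_kinetics_matrix(assays, replace(fit_opts, seed=_spawn_seed(rng)))

    def subset_rmse(subset: list[str], alphas: np.ndarray, seed: int) -> float:
        est = _deconvolve(
            km_true.select_substrates(subset),
            km_fit.select_substrates(subset),
            config,
            alphas,
            seed,
            fit_opts,
        )
        return rmse_report(alphas, est, km_true.proteases).overall

    def draw_alphas() -> np.ndarray:
        return rng.uniform(*config.alpha_range, size=(config.P, km_true.N))

    current = list(km_true.substrates)
    steps = [
        SelectionStep(tuple(current), None, subset_rmse(current, draw_alphas(), _spawn_seed(rng)))
    ]
    while len(current) > 2:
        alphas = draw_alphas()
        seed = _spawn_seed(rng)
        best_rmse, best_idx = np.inf, -1
        for idx, sub in enumerate(current):
            candidate = [s for s in current if s != sub]
            r = subset_rmse(candidate, alphas, seed)
            if r < best_rmse:
                best_rmse, best_idx = r, idx
        removed = current.pop(best_idx)
        steps.append(SelectionStep(tuple(current), removed, best_rmse))
    return SelectionTrace(tuple(steps))


def lambda_difficulty_sweep(
    config: SimConfig,
    lambdas: Sequence[float] | None = None,
    substrate_counts: Sequence[int] | None = None,
    fit_opts: FitOptions | None = None,
) -> pd.DataFrame:
    """RMSE of two-protease deconvolution vs. protease correlation.

    One independent pair (p1, p2) is drawn once; for each lambda on the
    grid a correlated protease p3 = lambda*p1 + (1-lambda)*p2 is built
    and mixtures of p1 and p3 are deconvolved with ``substrate_counts``
    substrates (prefixes of the panel).  Returns a tidy frame with
    columns (lam, n_substrates, rmse).
    """
    fit_opts = fit_opts or FitOptions()
    if lambdas is None:
        lambdas = np.round(np.arange(0.0, 1.0001, 0.05), 4)
    if substrate_counts is None:
        substrate_counts = range(2, config.M + 1)
    substrate_counts = [int(m) for m in substrate_counts]
    if any(m < 1 or m > config.M for m in substrate_counts):
        raise ShapeError("substrate counts must lie in [1, M]")
    rng = config.rng()
    km_base = sample_kinetic_matrix(config.with_(N=2), rng)
    p1 = km_base.column(0)
    p2 = km_base.column(1)
    rows = []
    for lam in lambdas:
        p3 = interpolate_protease(p1, p2, float(lam))
        km_pair = KineticMatrix.from_columns(
            km_base.substrates, ("p1", "p3"), [p1, p3]
        )
        cond_rng = np.random.default_rng(_spawn_seed(rng))
        assays = simulate_single_assays(
            km_pair, config.calibration_times, config.noise_sd, cond_rng
        )
        km_fit = fit_kinetics_matrix(
            assays, replace(fit_opts, seed=_spawn_seed(cond_rng))
        )
        for mcount in substrate_counts:
            subset = list(km_base.substrates[:mcount])
            alphas = cond_rng.uniform(*config.alpha_range, size=(config.P, 2))
            est = _deconvolve(
                km_pair.select_substrates(subset),
                km_fit.select_substrates(subset),
                config,
                alphas,
                _spawn_seed(cond_rng),
                fit_opts,
            )
            rows.append(
                {
                    "lam": float(lam),
                    "n_substrates": mcount,
                    "rmse": rmse_report(alphas, est, km_pair.proteases).overall,
                }
            )
    return pd.DataFrame(rows)


def cluster_proteases(
    single_assays: Sequence[SingleAssay], cutoff: float = 0.6
) -> FamilyAssignment:
    """Group proteases into activity families by hierarchical clustering.

    Each protease is represented by the concatenation of all its
    fraction-uncleaved observations (substrate-major, time ascending; no
    rescaling — values are already on [0, 1]).  Agglomerative clustering
    with single linkage and Euclidean distance is cut at ``cutoff`` to
    give flat families.
    """
    if cutoff <= 0:
        raise ShapeError("cutoff must be positive")
    proteases: list[str] = []
    substrates: list[str] = []
    table: dict[tuple[str, str], SingleAssay] = {}
    for a in single_assays:
        if a.protease not in proteases:
            proteases.append(a.protease)
        if a.substrate not in substrates:
            substrates.append(a.substrate)
        table[(a.substrate, a.protease)] = a
    missing = [(s, p) for s in substrates for p in proteases if (s, p) not in table]
    if missing:
        raise ShapeError(f"incomplete assay grid; missing pairs: {missing}")
    features = []
    for p in proteases:
        vec = np.concatenate(
            [table[(s, p)].timecourse.values for s in substrates]
        )
        features.append(vec)
    lengths = {v.size for v in features}
    if len(lengths) != 1:
        raise ShapeError("all proteases must share one observation layout")
    X = np.vstack(features)
    if len(proteases) == 1:
        return FamilyAssignment(
            labels={proteases[0]: "F1"}, cutoff=cutoff, linkage_heights=np.array([])
        )
    Z = linkage(X, method="single", metric="euclidean")
    raw = fcluster(Z, t=cutoff, criterion="distance")
    relabel: dict[int, str] = {}
    labels: dict[str, str] = {}
    for p, c in zip(proteases, raw):
        if c not in relabel:
            relabel[c] = f"F{len(relabel) + 1}"
        labels[p] = relabel[c]
    return FamilyAssignment(labels=labels, cutoff=cutoff, linkage_heights=Z[:, 2])


def family_deconvolution_experiment(
    km_true: KineticMatrix,
    assignment: FamilyAssignment | Mapping[str, str],
    config: SimConfig,
    fit_opts: FitOptions | None = None,
    rng: np.random.Generator | None = None,
    include_protease_level: bool = True,
) -> FamilyDeconvResult:
    """Deconvolve simulated mixtures at family resolution.

    A representative kinetic parameter set is fitted per (substrate,
    family) by pooling the members' single assays as replicates; the
    family-level kinetic matrix then deconvolves ``config.P`` mixtures
    that were simulated at *protease* level with random per-protease
    coefficients.  Each family estimate is paired with the true sum of
    its members' coefficients.  With ``include_protease_level`` the same
    mixtures are also deconvolved protease-by-protease for comparison.
    """
    fit_opts = fit_opts or FitOptions()
    rng = config.rng() if rng is None else rng
    labels = getattr(assignment, "labels", assignment)
    missing = [p for p in km_true.proteases if p not in labels]
    if missing:
        raise ShapeError(f"assignment does not cover proteases: {missing}")
    family_ids = list(dict.fromkeys(labels[p] for p in km_true.proteases))

    assays = simulate_single_assays(
        km_true, config.calibration_times, config.noise_sd, rng
    )
    by_pair = {(a.substrate, a.protease): a for a in assays}

    M, F = km_true.M, len(family_ids)
    ss = np.random.SeedSequence(_spawn_seed(rng))
    children = iter(ss.spawn(M * F))
    V = np.empty((M, F))
    K = np.empty((M, F))
    n = np.empty((M, F))
    beta = np.empty((M, F))
    for i, s in enumerate(km_true.substrates):
        for f, fam in enumerate(family_ids):
            members = [
                by_pair[(s, p)] for p in km_true.proteases if labels[p] == fam
            ]
            fit = fit_family_kinetics(
                members, fit_opts, np.random.default_rng(next(children))
            )
            est = fit.estimate
            V[i, f], K[i, f], n[i, f], beta[i, f] = est.V, est.K, est.n, est.beta
    km_family = KineticMatrix(km_true.substrates, tuple(family_ids), V, K, n, beta)

    km_fit_prot = None
    if include_protease_level:
        km_fit_prot = fit_kinetics_matrix(
            assays, replace(fit_opts, seed=_spawn_seed(rng))
        )

    true_alphas = rng.uniform(*config.alpha_range, size=(config.P, km_true.N))
    ss2 = np.random.SeedSequence(_spawn_seed(rng))
    rng_noise, rng_fam, rng_prot = (np.random.default_rng(c) for c in ss2.spawn(3))
    est_fam = np.empty((config.P, F))
    est_prot = np.empty((config.P, km_true.N)) if include_protease_level else None
    for k in range(config.P):
        mix = simulate_mixture_assay(
            km_true, true_alphas[k], config.times, config.noise_sd, rng_noise
        )
        est_fam[k] = estimate_mixing(mix, km_family, fit_opts, rng_fam).estimate.alphas
        if include_protease_level:
            est_prot[k] = estimate_mixing(
                mix, km_fit_prot, fit_opts, rng_prot
            ).estimate.alphas

    fam_ids, true_sums = family_true_sums(
        true_alphas, km_true.proteases, labels, family_ids
    )
    fam_report = family_rmse(
        true_alphas, est_fam, labels, km_true.proteases, family_ids
    )
    prot_report = (
        rmse_report(true_alphas, est_prot, km_true.proteases)
        if include_protease_level
        else None
    )
    records = []
    for k in range(config.P):
        for f, fam in enumerate(fam_ids):
            records.append(
                {
                    "rep": k,
                    "family": fam,
                    "true_sum": true_sums[k, f],
                    "estimated": est_fam[k, f],
                }
            )
    return FamilyDeconvResult(
        table=pd.DataFrame(records),
        family_report=fam_report,
        protease_report=prot_report,
    )
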