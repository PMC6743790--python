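"""RMSE accounting for repeated deconvolution experiments.

For P repeated mixtures of N proteases, the per-protease error is

    R_j = sqrt( (1/P) * sum_k (alpha_hat_jk - alpha_jk)^2 )

and the overall error is the arithmetic mean of the R_j.  At the family
level, the "true" coefficient of a family is the sum of its members'
true coefficients in each repetition, because a family's estimated
coefficient should account for the total activity of its members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .kinetics import ShapeError

__all__ = [
    "RmseReport",
    "rmse_per_protease",
    "rmse_overall",
    "rmse_report",
    "family_true_sums",
    "family_rmse",
]


@dataclass(frozen=True)
class RmseReport:
    ids: tuple[str, ...]
    per_protease: np.ndarray
    P: int

    def __post_init__(self) -> None:
        r = np.asarray(self.per_protease, dtype=float)
        object.__setattr__(self, "per_protease", r)
        object.__setattr__(self, "ids", tuple(self.ids))
        if r.ndim != 1 or r.size != len(self.ids):
            raise ShapeError("per-protease RMSE vector must match the id list")
        if np.any(r < 0):
            raise ValueError("RMSE values cannot be negative")

    @property
    def overall(self) -> float:
        return rmse_overall(self.per_protease)


def _as_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ShapeError(f"{name} must be a P x N matrix")
    return a


def rmse_per_protease(true_alphas, est_alphas, relative: bool = False) -> np.ndarray:
    """Root-mean-square coefficient error per protease over P repetitions.

    With ``relative=True`` each error is divided by the true coefficient
    before squaring (not the default; headline results use raw errors).
    """
    t = _as_matrix(true_alphas, "true_alphas")
    e = _as_matrix(est_alphas, "est_alphas")
    if t.shape != e.shape:
        raise ShapeError(f"shape mismatch: true {t.shape} vs estimated {e.shape}")
    err = e - t
    if relative:
        err = err / t
    return np.sqrt(np.mean(err**2, axis=0))


def rmse_overall(per_protease) -> float:
    """Mean of the per-protease RMSEs."""
    r = np.asarray(per_protease, dtype=float)
    if r.size == 0:
        raise ShapeError("cannot average an empty RMSE vector")
    return float(np.mean(r))


def rmse_report(true_alphas, est_alphas, ids: Sequence[str]) -> RmseReport:
    t = _as_matrix(true_alphas, "true_alphas")
    r = rmse_per_protease(t, est_alphas)
    if len(ids) != r.size:
        raise ShapeError("id list does not match coefficient columns")
    return RmseReport(ids=tuple(ids), per_protease=r, P=t.shape[0])


def _labels_of(assignment) -> Mapping[str, str]:
    return getattr(assignment, "labels", assignment)


def family_true_sums(
    true_alphas,
    protease_ids: Sequence[str],
    assignment,
    family_ids: Sequence[str] | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Per-repetition sums of member coefficients for each family.

    ``assignment`` maps protease id -> family id (a mapping or a
    FamilyAssignment).  Family order defaults to first appearance along
    ``protease_ids``.  Every protease must be assigned.
    """
    labels = _labels_of(assignment)
    t = _as_matrix(true_alphas, "true_alphas")
    if t.shape[1] != len(protease_ids):
        raise ShapeError("true_alphas columns must match protease_ids")
    missing = [p for p in protease_ids if p not in labels]
    if missing:
        raise ShapeError(f"unassigned proteases: {missing}")
    if family_ids is None:
        family_ids = list(dict.fromkeys(labels[p] for p in protease_ids))
    sums = np.zeros((t.shape[0], len(family_ids)))
    fidx = {f: k for k, f in enumerate(family_ids)}
    for j, p in enumerate(protease_ids):
        f = labels[p]
        if f not in fidx:
            raise ShapeError(f"protease {p!r} assigned to unknown family {f!r}")
        sums[:, fidx[f]] += t[:, j]
    return tuple(family_ids), sums


def family_rmse(
    true_alphas,
    est_family_alphas,
    assignment,
    protease_ids: Sequence[str],
    family_ids: Sequence[str] | None = None,
) -> RmseReport:
    """RMSE at family resolution: estimates vs. true member sums."""
    e = _as_matrix(est_family_alphas, "est_family_alphas")
    fam_ids, sums = family_true_sums(true_alphas, protease_ids, assignment, family_ids)
    if e.shape != sums.shape:
        raise ShapeError(
            f"estimated family matrix {e.shape} does not match {sums.shape}"
        )
    return rmse_report(sums, e, fam_ids)
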