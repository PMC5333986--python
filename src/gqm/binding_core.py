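"""Mass-action antibody–epitope binding equilibria.

The model treats [Ab] as free paratope concentration and [Ag] as free
epitope concentration, both in molar, with the equilibrium dissociation
constant

    K_D = [Ab]_free [Ag]_free / [AbAg]

so that an epitope is half saturated exactly when the free antibody
concentration equals K_D.  This module provides the scalar identities
(K_D, fractional saturation, antigen-binding capacity), the closed-form
solution for a single antibody/epitope pair with mass conservation, and a
competitive multi-clone, multi-epitope equilibrium solver.

Absent interactions are represented by ``K_D = +inf`` ("no binding") and
are excluded from all sums rather than pushed through large-float
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, sparse

from .errors import (
    ConsistencyError,
    DomainError,
    SolverError,
    UndefinedKdError,
)

__all__ = [
    "BindingPair",
    "EquilibriumState",
    "kd_from_equilibrium",
    "fractional_saturation",
    "binding_capacity",
    "solve_pair_equilibrium",
    "solve_system_equilibrium",
]

# Relative residual above which the system solver refuses to return a state.
_RESIDUAL_FAIL = 1e-9


def kd_from_equilibrium(ab_free: float, ag_free: float, complex_conc: float) -> float:
    """Equilibrium dissociation constant from free and bound concentrations.

    Parameters are molar concentrations of free paratope, free epitope and
    the antibody–epitope complex.  Returns ``ab_free * ag_free /
    complex_conc`` in molar.
    """
    if ab_free < 0 or ag_free < 0 or complex_conc < 0:
        raise DomainError("concentrations must be non-negative")
    if complex_conc == 0:
        raise UndefinedKdError("K_D is undefined at zero complex concentration")
    return ab_free * ag_free / complex_conc


def fractional_saturation(ab_free, kd):
    """Occupancy of an epitope by antibody at equilibrium.

    ``ab_free / (ab_free + kd)``; equals 0.5 exactly when the free antibody
    concentration equals K_D.  Accepts scalars or numpy arrays
    (broadcasting); returns a value in [0, 1].
    """
    ab_free = np.asarray(ab_free, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(ab_free < 0):
        raise DomainError("ab_free must be non-negative")
    if np.any(kd <= 0):
        raise DomainError("kd must be positive")
    out = ab_free / (ab_free + kd)
    return float(out) if out.ndim == 0 else out


def binding_capacity(ab_free: float, kd: float) -> float:
    """Antigen-binding capacity [Ab]_free / K_D (dimensionless).

    This is the quantity drawn as the node radius in the antibody network.
    """
    if ab_free < 0:
        raise DomainError("ab_free must be non-negative")
    if kd <= 0:
        raise DomainError("kd must be positive")
    return ab_free / kd


@dataclass(frozen=True)
class BindingPair:
    """A single antibody–epitope pair: total concentrations and K_D (molar).

    ``kd = +inf`` is the no-binding sentinel.
    """

    ab_total: float
    ag_total: float
    kd: float

    def __post_init__(self):
        if self.ab_total < 0 or self.ag_total < 0:
            raise DomainError("total concentrations must be non-negative")
        if not self.kd > 0:
            raise DomainError("kd must be positive (+inf means no binding)")


def solve_pair_equilibrium(pair: BindingPair) -> tuple[float, float, float]:
    """Closed-form equilibrium of one antibody clone binding one epitope.

    Solves the conservation quadratic

        c^2 - (A + G + K) c + A G = 0

    for the complex concentration ``c`` (the physically meaningful smaller
    root), where ``A``/``G`` are total paratope/epitope and ``K`` the
    dissociation constant.  Returns ``(ab_free, ag_free, complex)``.

    The root is evaluated as ``2AG / (S + sqrt(S^2 - 4AG))`` with
    ``S = A + G + K``, which is numerically stable both in the weak-binding
    limit (K >> totals, c -> AG/K) and the stoichiometric limit (K -> 0,
    c -> min(A, G)).
    """
    a, g, k = pair.ab_total, pair.ag_total, pair.kd
    if not math.isfinite(k) or a == 0.0 or g == 0.0:
        return a, g, 0.0
    s = a + g + k
    disc = s * s - 4.0 * a * g
    c = 2.0 * a * g / (s + math.sqrt(max(disc, 0.0)))
    return max(a - c, 0.0), max(g - c, 0.0), c


@dataclass
class EquilibriumState:
    """Free and bound concentrations of a competitive binding system.

    ``complexes`` is a sparse clone × epitope matrix of complex
    concentrations; its sparsity pattern matches the finite entries of the
    affinity matrix that produced it.  ``clone_ids`` / ``epitope_ids`` are
    optional labels aligned with the vector axes.
    """

    ab_free: np.ndarray
    ag_free: np.ndarray
    complexes: sparse.csr_array
    clone_ids: tuple[str, ...] | None = None
    epitope_ids: tuple[str, ...] | None = None
    residual: float = 0.0
    n_iter: int = 0
    _clone_index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.clone_ids is not None:
            self._clone_index = {c: i for i, c in enumerate(self.clone_ids)}

    def ab_free_of(self, clone_id: str) -> float:
        """Free paratope concentration of one clone, by id."""
        return float(self.ab_free[self._clone_index[clone_id]])

    def ag_free_of(self, epitope_id: str) -> float:
        return float(self.ag_free[self.epitope_ids.index(epitope_id)])

    def validate(self, ab_total, ag_total, kd, rtol: float = 1e-8) -> None:
        """Check conservation and mass-action closure; raise on violation."""
        ab_total = np.asarray(ab_total, dtype=float)
        ag_total = np.asarray(ag_total, dtype=float)
        kd = np.asarray(kd, dtype=float)
        bound_ab = np.asarray(self.complexes.sum(axis=1)).ravel()
        bound_ag = np.asarray(self.complexes.sum(axis=0)).ravel()
        scale_a = np.maximum(ab_total, np.finfo(float).tiny)
        scale_g = np.maximum(ag_total, np.finfo(float).tiny)
        res_a = np.abs(ab_total - self.ab_free - bound_ab) / scale_a
        res_g = np.abs(ag_total - self.ag_free - bound_ag) / scale_g
        if res_a.size and res_a.max() > rtol:
            raise ConsistencyError(
                f"antibody conservation violated (max rel. residual {res_a.max():.3e})"
            )
        if res_g.size and res_g.max() > rtol:
            raise ConsistencyError(
                f"epitope conservation violated (max rel. residual {res_g.max():.3e})"
            )
        coo = self.complexes.tocoo()
        for i, j, c in zip(coo.row, coo.col, coo.data):
            lhs = kd[i, j] * c
            rhs = self.ab_free[i] * self.ag_free[j]
            scale = max(abs(rhs), np.finfo(float).tiny)
            if abs(lhs - rhs) / scale > rtol:
                raise ConsistencyError(
                    f"mass-action closure violated at ({i},{j})"
                )
        if np.any(self.ab_free < 0) or np.any(self.ag_free < 0) or np.any(coo.data < 0):
            raise ConsistencyError("negative concentration in equilibrium state")


def _as_kd_array(kd_matrix, clone_ids, epitope_ids):
    """Accept a dense ndarray (inf = absent) or an AffinityMatrix-like
    object exposing ``to_dense``; return (kd, clone_ids, epitope_ids)."""
    if hasattr(kd_matrix, "to_dense"):
        cids = tuple(kd_matrix.clones) if clone_ids is None else tuple(clone_ids)
        eids = tuple(kd_matrix.epitopes) if epitope_ids is None else tuple(epitope_ids)
        return kd_matrix.to_dense(cids, eids), cids, eids
    kd = np.asarray(kd_matrix, dtype=float)
    return kd, clone_ids, epitope_ids


def _residual(ab_total, ag_total, aff, ab, ag) -> float:
    tiny = np.finfo(float).tiny
    ra = np.abs(ab_total - ab * (1.0 + aff @ ag)) / np.maximum(ab_total, tiny)
    rg = np.abs(ag_total - ag * (1.0 + aff.T @ ab)) / np.maximum(ag_total, tiny)
    res = 0.0
    if ra.size:
        res = max(res, float(ra.max()))
    if rg.size:
        res = max(res, float(rg.max()))
    return res


def _newton_polish(ab_total, ag_total, aff, ab, ag):
    """Refine a fixed-point iterate by root-finding on log-concentrations.

    Returns a (possibly improved) pair (ab, ag); never raises.
    """
    n, m = aff.shape
    ia = np.flatnonzero(ab_total > 0)
    ja = np.flatnonzero(ag_total > 0)
    if ia.size + ja.size == 0 or not aff.any():
        return ab, ag
    k = ia.size

    def func(z):
        a = np.zeros(n)
        g = np.zeros(m)
        a[ia] = np.exp(z[:k])
        g[ja] = np.exp(z[k:])
        fa = z[:k] - (np.log(ab_total[ia]) - np.log1p((aff @ g)[ia]))
        fg = z[k:] - (np.log(ag_total[ja]) - np.log1p((aff.T @ a)[ja]))
        return np.concatenate([fa, fg])

    with np.errstate(all="ignore"):
        z0 = np.concatenate([np.log(ab[ia]), np.log(ag[ja])])
        if not np.all(np.isfinite(z0)):
            return ab, ag
        try:
            sol = optimize.root(func, z0, method="hybr", tol=1e-13)
        except Exception:
            return ab, ag
    if not np.all(np.isfinite(sol.x)):
        return ab, ag
    ab2 = np.zeros(n)
    ag2 = np.zeros(m)
    ab2[ia] = np.exp(sol.x[:k])
    ag2[ja] = np.exp(sol.x[k:])
    if _residual(ab_total, ag_total, aff, ab2, ag2) < _residual(
        ab_total, ag_total, aff, ab, ag
    ):
        return ab2, ag2
    return ab, ag


def solve_system_equilibrium(
    ab_total: Sequence[float],
    ag_total: Sequence[float],
    kd_matrix,
    *,
    clone_ids: Sequence[str] | None = None,
    epitope_ids: Sequence[str] | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumState:
    """Competitive equilibrium of many clones against many epitopes.

    Solves the coupled conservation relations

        ab_free_i = ab_total_i / (1 + sum_j ag_free_j / kd_ij)
        ag_free_j = ag_total_j / (1 + sum_i ab_free_i / kd_ij)

    by damped fixed-point iteration (geometric-mean damping, i.e. factor
    0.5 in log space), with a Newton refinement on the log-concentration
    residuals after the iteration settles or hits the cap.  ``kd_matrix``
    may be a dense ndarray with ``+inf`` marking absent interactions, or
    any object exposing ``to_dense(clone_ids, epitope_ids)``.

    Deterministic for fixed input.  Raises :class:`SolverError` carrying
    the final residual if neither stage reaches a relative conservation
    residual below 1e-9.
    """
    kd, clone_ids, epitope_ids = _as_kd_array(kd_matrix, clone_ids, epitope_ids)
    ab_total = np.asarray(ab_total, dtype=float).copy()
    ag_total = np.asarray(ag_total, dtype=float).copy()
    n, m = kd.shape
    if ab_total.shape != (n,) or ag_total.shape != (m,):
        raise DomainError("total-concentration vectors do not match kd matrix shape")
    if np.any(ab_total < 0) or np.any(ag_total < 0):
        raise DomainError("total concentrations must be non-negative")
    if np.any(np.isnan(kd)) or np.any(kd <= 0):
        raise DomainError("kd entries must be positive (+inf = no binding)")

    finite = np.isfinite(kd)
    with np.errstate(divide="ignore"):
        aff = np.where(finite, 1.0 / np.where(finite, kd, 1.0), 0.0)

    ab = ab_total.copy()
    ag = ag_total.copy()
    tiny = np.finfo(float).tiny
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ab_new = ab_total / (1.0 + aff @ ag)
        ag_new = ag_total / (1.0 + aff.T @ ab)
        ab_next = np.sqrt(ab * ab_new)
        ag_next = np.sqrt(ag * ag_new)
        rel = 0.0
        if n:
            rel = max(rel, float(np.max(np.abs(ab_next - ab) / np.maximum(ab, tiny))))
        if m:
            rel = max(rel, float(np.max(np.abs(ag_next - ag) / np.maximum(ag, tiny))))
        ab, ag = ab_next, ag_next
        if rel < tol:
            converged = True
            break

    ab, ag = _newton_polish(ab_total, ag_total, aff, ab, ag)
    res = _residual(ab_total, ag_total, aff, ab, ag)
    if not converged and res > _RESIDUAL_FAIL:
        raise SolverError(
            f"equilibrium solver did not converge in {max_iter} iterations "
            f"(residual {res:.3e})",
            residual=res,
        )

    ii, jj = np.nonzero(aff)
    data = ab[ii] * ag[jj] * aff[ii, jj]
    complexes = sparse.csr_array((data, (ii, jj)), shape=(n, m))
    return EquilibriumState(
        ab_free=ab,
        ag_free=ag,
        complexes=complexes,
        clone_ids=tuple(clone_ids) if clone_ids is not None else None,
        epitope_ids=tuple(epitope_ids) if epitope_ids is not None else None,
        residual=res,
        n_iter=it,
    )
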