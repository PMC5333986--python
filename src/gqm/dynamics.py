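"""Response dynamics on the antibody network.

Three update rules drive the model:

* **TI** (thymus-independent) responses multiply a clone's total antibody
  concentration without touching any K_D — the node grows but does not
  move.
* **TD** (thymus-dependent) responses mature affinity: the cognate K_D
  falls by ``delta_pkd`` decades while every other interaction weakens by
  ``polyreactivity_decay`` decades (interactions pushed past the binding
  cutoff are dropped).  The node moves in epitope space and, with enough
  maturation, is extruded from the giant component.
* **Regulation** steers a clone's total antibody until its free
  concentration matches its cognate K_D — the 50%-saturation set point at
  which antigen concentration is best controlled.

Long-lived plasma-cell clones are fix posts: their affinities and
regulated level are hardwired (TD and regulation are rejected), though TI
boosting of secretion is still allowed.  Time is event-ordered; after each
event the mass-action equilibrium is re-solved and the network rebuilt.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .binding_core import EquilibriumState
from .errors import (
    DomainError,
    FrozenCloneError,
    RegulationWarning,
    SimulationError,
    UnknownCloneError,
)
from .epitope_network import (
    DEFAULT_BINDING_CUTOFF,
    DEFAULT_DISTANCE_CUTOFF,
    build_network,
    giant_component,
)
from .repertoire import (
    TI_CELL_TYPES,
    AffinityMatrix,
    CellType,
    Epitope,
    Repertoire,
    cognate_epitope,
    solve_equilibrium,
)

__all__ = [
    "EventKind",
    "ResponseEvent",
    "Snapshot",
    "Trajectory",
    "apply_ti",
    "apply_td",
    "regulate",
    "check_ti_sharing",
    "simulate",
    "KD_FLOOR",
]

#: Affinity-maturation floor (molar): maturation cannot push K_D below this.
KD_FLOOR = 1e-11


class EventKind(str, enum.Enum):
    TI = "TI"
    TD = "TD"
    REGULATE = "REGULATE"
    ANTIGEN_CHALLENGE = "ANTIGEN_CHALLENGE"


@dataclass(frozen=True)
class ResponseEvent:
    """One perturbation of the system.

    TI: ``clone_id`` + ``fold`` (> 1).  TD: ``clone_id`` + ``delta_pkd``
    (> 0) and ``polyreactivity_decay`` (>= 0).  REGULATE: ``clone_id`` +
    ``tolerance`` (log10 units).  ANTIGEN_CHALLENGE: ``epitope_id`` plus
    either ``scale`` (multiply an existing epitope's concentration) or
    ``ag_total`` and per-clone ``affinities`` for a new epitope.
    """

    kind: EventKind
    clone_id: str | None = None
    fold: float | None = None
    delta_pkd: float | None = None
    polyreactivity_decay: float = 0.5
    tolerance: float = 0.01
    epitope_id: str | None = None
    ag_total: float | None = None
    affinities: Mapping[str, float] | None = None
    scale: float | None = None

    def __post_init__(self):
        kind = EventKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (EventKind.TI, EventKind.TD, EventKind.REGULATE):
            if self.clone_id is None:
                raise DomainError(f"{kind.value} event needs a clone_id")
        if kind is EventKind.TI and (self.fold is None or self.fold <= 1):
            raise DomainError("TI fold must be > 1")
        if kind is EventKind.TD:
            if self.delta_pkd is None or self.delta_pkd <= 0:
                raise DomainError("TD delta_pkd must be > 0")
            if self.polyreactivity_decay < 0:
                raise DomainError("TD polyreactivity_decay must be >= 0")
        if kind is EventKind.REGULATE and self.tolerance <= 0:
            raise DomainError("REGULATE tolerance must be > 0")
        if kind is EventKind.ANTIGEN_CHALLENGE:
            if self.epitope_id is None:
                raise DomainError("ANTIGEN_CHALLENGE needs an epitope_id")
            if self.scale is None and self.ag_total is None:
                raise DomainError(
                    "ANTIGEN_CHALLENGE needs either scale or ag_total"
                )


def apply_ti(
    repertoire: Repertoire,
    matrix: AffinityMatrix,
    clone_id: str,
    fold: float,
    **solver_kwargs,
) -> tuple[Repertoire, AffinityMatrix, EquilibriumState]:
    """Thymus-independent boost: multiply a clone's total antibody by ``fold``.

    K_D values are untouched (the affinity matrix object is returned
    as-is), so no internodal distance can change; the equilibrium is
    re-solved.  Long-lived plasma cells may be TI-boosted.
    """
    if fold <= 1:
        raise DomainError("TI fold must be > 1")
    if clone_id not in repertoire.clones:
        raise UnknownCloneError(clone_id)
    new_rep = repertoire.with_clone_ab(
        clone_id, repertoire.clones[clone_id].ab_total * fold
    )
    return new_rep, matrix, solve_equilibrium(new_rep, matrix, **solver_kwargs)


def apply_td(
    repertoire: Repertoire,
    matrix: AffinityMatrix,
    clone_id: str,
    delta_pkd: float = 1.0,
    polyreactivity_decay: float = 0.5,
    *,
    binding_cutoff: float = DEFAULT_BINDING_CUTOFF,
    kd_floor: float = KD_FLOOR,
    **solver_kwargs,
) -> tuple[Repertoire, AffinityMatrix, EquilibriumState]:
    """One affinity-maturation step.

    The cognate K_D falls by ``delta_pkd`` decades (floored at
    ``kd_floor``); every other stored interaction weakens by
    ``polyreactivity_decay`` decades, and interactions pushed above
    ``binding_cutoff`` are dropped entirely.  The cognate entry is always
    retained, and cognate identity should be re-evaluated on the returned
    matrix.  Long-lived plasma cells are frozen and reject maturation.
    """
    if clone_id not in repertoire.clones:
        raise UnknownCloneError(clone_id)
    if repertoire.clones[clone_id].long_lived:
        raise FrozenCloneError(
            f"clone {clone_id} is a long-lived plasma cell; its affinities are hardwired"
        )
    if delta_pkd <= 0:
        raise DomainError("delta_pkd must be > 0")
    if polyreactivity_decay < 0:
        raise DomainError("polyreactivity_decay must be >= 0")

    cog = cognate_epitope(clone_id, matrix)
    new_matrix = matrix.copy()
    for eid, kd in matrix.row(clone_id).items():
        if eid == cog:
            new_matrix.set(clone_id, eid, max(kd * 10.0 ** (-delta_pkd), kd_floor))
        else:
            weakened = kd * 10.0**polyreactivity_decay
            if weakened > binding_cutoff:
                new_matrix.remove(clone_id, eid)
            else:
                new_matrix.set(clone_id, eid, weakened)
    state = solve_equilibrium(repertoire, new_matrix, **solver_kwargs)
    return repertoire, new_matrix, state


def regulate(
    repertoire: Repertoire,
    matrix: AffinityMatrix,
    clone_id: str,
    tolerance: float = 0.01,
    *,
    max_iter: int = 200,
    **solver_kwargs,
) -> tuple[Repertoire, AffinityMatrix, EquilibriumState, float]:
    """Homeostatic regulation: drive [Ab]_free to the cognate K_D.

    Adjusts the clone's total antibody by bisection in log10 space until
    ``|log10(ab_free / K_D_cognate)| < tolerance`` or ``max_iter``
    iterations.  Returns ``(repertoire, matrix, state, achieved
    residual)``; an unreachable target yields a best-effort state with a
    :class:`RegulationWarning`.  At the set point the clone's free
    antibody half-saturates its cognate epitope.
    """
    if clone_id not in repertoire.clones:
        raise UnknownCloneError(clone_id)
    if repertoire.clones[clone_id].long_lived:
        raise FrozenCloneError(
            f"clone {clone_id} is a long-lived plasma cell; its secretion is unregulated"
        )
    if tolerance <= 0:
        raise DomainError("tolerance must be > 0")

    cog = cognate_epitope(clone_id, matrix)
    kd_cog = matrix.kd(clone_id, cog)

    def residual_at(rep: Repertoire):
        st = solve_equilibrium(rep, matrix, **solver_kwargs)
        free = st.ab_free_of(clone_id)
        if free <= 0:
            return -math.inf, st
        return math.log10(free / kd_cog), st

    res, state = residual_at(repertoire)
    if abs(res) < tolerance:
        return repertoire, matrix, state, res

    # Analytic bracket: at ab_total = kd the free concentration cannot
    # exceed kd; at ab_total = kd * (1 + sum_e ag_total_e / kd_e) it cannot
    # fall below kd.
    row = matrix.row(clone_id)
    load = sum(
        repertoire.epitopes[e].ag_total / kd for e, kd in row.items()
        if e in repertoire.epitopes
    )
    lo = math.log10(kd_cog)
    hi = math.log10(kd_cog * (1.0 + load)) + 1e-12
    best = (abs(res), repertoire, state, res)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        rep_mid = repertoire.with_clone_ab(clone_id, 10.0**mid)
        res, state = residual_at(rep_mid)
        if abs(res) < best[0]:
            best = (abs(res), rep_mid, state, res)
        if abs(res) < tolerance:
            return rep_mid, matrix, state, res
        if res < 0:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"regulation of clone {clone_id} did not reach |log10 residual| < "
        f"{tolerance} (achieved {best[3]:.3g}); returning best-effort state",
        RegulationWarning,
    )
    return best[1], matrix, best[2], best[3]


def check_ti_sharing(net: nx.Graph) -> list[str]:
    """Diagnose violations of the shared-production rule for TI clones.

    Because TI responses are polyclonal, antibody production against any
    epitope region is shared and each B1/MZ node's binding capacity
    [Ab]_free / K_D stays below 1.  Returns the member clone ids of B1/MZ
    nodes whose radius reaches 1 (oligoclonal TD nodes may legitimately
    exceed 1 and are not flagged).
    """
    violations: list[str] = []
    ti_values = {t.value for t in TI_CELL_TYPES}
    for rep, data in net.nodes(data=True):
        if data.get("cell_type") in ti_values and data.get("radius", 0.0) >= 1.0:
            violations.extend(data.get("members", (rep,)))
    return sorted(violations)


@dataclass(frozen=True)
class Snapshot:
    """System state after one event (or the initial state at time 0)."""

    time: int
    event: ResponseEvent | None
    repertoire: Repertoire
    matrix: AffinityMatrix
    state: EquilibriumState
    network: nx.Graph


@dataclass
class Trajectory:
    """Ordered snapshots of a simulated event sequence."""

    snapshots: list[Snapshot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snapshots)

    def __getitem__(self, idx: int) -> Snapshot:
        return self.snapshots[idx]

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]

    def summary_frame(self) -> pd.DataFrame:
        """Per-snapshot, per-clone summary table."""
        rows = []
        for snap in self.snapshots:
            giant = giant_component(snap.network)
            for cid in snap.repertoire.clone_ids:
                row = snap.matrix.row(cid)
                cog = cognate_epitope(cid, snap.matrix) if row else None
                kd_cog = row[cog] if cog else math.inf
                free = snap.state.ab_free_of(cid)
                rows.append(
                    {
                        "time": snap.time,
                        "event": snap.event.kind.value if snap.event else "INIT",
                        "clone_id": cid,
                        "ab_total_molar": snap.repertoire.clones[cid].ab_total,
                        "ab_free_molar": free,
                        "cognate_epitope": cog,
                        "cognate_kd_molar": kd_cog,
                        "radius": free / kd_cog if cog else 0.0,
                        "in_giant_component": cid in giant,
                    }
                )
        return pd.DataFrame(rows)


def _apply_challenge(
    repertoire: Repertoire, matrix: AffinityMatrix, event: ResponseEvent, **solver_kwargs
):
    eid = event.epitope_id
    if eid in repertoire.epitopes:
        current = repertoire.epitopes[eid]
        ag = (
            current.ag_total * event.scale
            if event.scale is not None
            else event.ag_total
        )
        new_rep = repertoire.with_epitope(
            Epitope(id=eid, ag_total=ag, is_self=current.is_self)
        )
        new_matrix = matrix
    else:
        if event.ag_total is None:
            raise DomainError(f"new epitope {eid} needs an ag_total")
        new_rep = repertoire.with_epitope(
            Epitope(id=eid, ag_total=event.ag_total, is_self=False)
        )
        new_matrix = matrix.copy()
        for cid, kd in (event.affinities or {}).items():
            new_matrix.set(cid, eid, kd)
    return new_rep, new_matrix, solve_equilibrium(new_rep, new_matrix, **solver_kwargs)


def simulate(
    repertoire: Repertoire,
    matrix: AffinityMatrix,
    events: Sequence[ResponseEvent],
    *,
    binding_cutoff: float = DEFAULT_BINDING_CUTOFF,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    **solver_kwargs,
) -> Trajectory:
    """Run an ordered event sequence, re-solving and rebuilding after each.

    Snapshot 0 is the untouched initial system.  Failures inside an event
    are re-raised as :class:`SimulationError` carrying the event index.
    Deterministic.
    """

    def snap(t, event, rep, mat, state):
        net = build_network(
            rep,
            mat,
            state,
            binding_cutoff=binding_cutoff,
            distance_cutoff=distance_cutoff,
            validate=False,
        )
        return Snapshot(
            time=t, event=event, repertoire=rep, matrix=mat, state=state, network=net
        )

    state = solve_equilibrium(repertoire, matrix, **solver_kwargs)
    traj = Trajectory([snap(0, None, repertoire, matrix, state)])
    rep, mat = repertoire, matrix
    for idx, event in enumerate(events):
        try:
            if event.kind is EventKind.TI:
                rep, mat, state = apply_ti(
                    rep, mat, event.clone_id, event.fold, **solver_kwargs
                )
            elif event.kind is EventKind.TD:
                rep, mat, state = apply_td(
                    rep,
                    mat,
                    event.clone_id,
                    event.delta_pkd,
                    event.polyreactivity_decay,
                    binding_cutoff=binding_cutoff,
                    **solver_kwargs,
                )
            elif event.kind is EventKind.REGULATE:
                rep, mat, state, _ = regulate(
                    rep, mat, event.clone_id, event.tolerance, **solver_kwargs
                )
            elif event.kind is EventKind.ANTIGEN_CHALLENGE:
                rep, mat, state = _apply_challenge(rep, mat, event, **solver_kwargs)
            else:  # pragma: no cover - enum is exhaustive
                raise DomainError(f"unknown event kind {event.kind}")
        except Exception as exc:
            raise SimulationError(
                f"event {idx} ({event.kind.value}) failed: {exc}", event_index=idx
            ) from exc
        traj.snapshots.append(snap(idx + 1, event, rep, mat, state))
    return traj
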