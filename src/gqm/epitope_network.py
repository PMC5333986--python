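"""The antibody–epitope interaction network.

Clones are nodes placed in epitope space; a node's radius is its
antigen-binding capacity at its cognate epitope, ``[Ab]_free / K_D``, and
the distance between two nodes is the mean absolute difference of their
pK_D values over the epitopes both bind (the log-scale averaged
cross-reactivity distance).  Clones with identical binding profiles
collapse into a single node — the network counts B cells with *distinct*
antigen-binding properties — and an edge joins two nodes when they share
at least one bound epitope and their distance does not exceed a cutoff.
The giant connected component of this graph is the model's rendering of
immunological self; nodes outside it are "extruded".

A linear-scale distance (mean |K_Di − K_Dj| in molar) is available behind
``method="linear"`` for comparison, but across six decades of affinity it
is dominated by the strongest binder, so the log form is canonical.
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx

from .binding_core import EquilibriumState
from .errors import ConsistencyError, DomainError, UnknownCloneError
from .repertoire import AffinityMatrix, Repertoire, cognate_epitope

__all__ = [
    "internodal_distance",
    "node_radius",
    "build_network",
    "giant_component",
    "extruded_nodes",
    "DEFAULT_BINDING_CUTOFF",
    "DEFAULT_DISTANCE_CUTOFF",
]

#: Weakest interaction counted as binding (molar); the weakest printed
#: natural-antibody affinity.
DEFAULT_BINDING_CUTOFF = 1e-4
#: Largest internodal distance (pK_D units) still drawn as an edge.
DEFAULT_DISTANCE_CUTOFF = 3.0


def internodal_distance(
    i: str,
    j: str,
    matrix: AffinityMatrix,
    *,
    binding_cutoff: float = DEFAULT_BINDING_CUTOFF,
    method: str = "log",
) -> float:
    """Cross-reactivity distance between clones ``i`` and ``j``.

    Over the set S of epitopes both clones bind (finite K_D at or below
    ``binding_cutoff``), returns the mean of |pK_D_i(e) − pK_D_j(e)|
    (``method="log"``, pK_D units) or of |K_D_i(e) − K_D_j(e)|
    (``method="linear"``, molar).  Returns ``+inf`` when S is empty;
    symmetric; d(i, i) = 0.
    """
    if method not in ("log", "linear"):
        raise DomainError(f"unknown distance method {method!r}")
    row_i = matrix.row(i)
    row_j = matrix.row(j)
    if i == j:
        return 0.0
    shared = [
        e
        for e in row_i
        if e in row_j and row_i[e] <= binding_cutoff and row_j[e] <= binding_cutoff
    ]
    if not shared:
        return math.inf
    if method == "log":
        diffs = [abs(math.log10(row_i[e]) - math.log10(row_j[e])) for e in shared]
    else:
        diffs = [abs(row_i[e] - row_j[e]) for e in shared]
    return sum(diffs) / len(diffs)


def node_radius(
    clone_id: str, state: EquilibriumState, matrix: AffinityMatrix
) -> float:
    """Antigen-binding capacity [Ab]_free / K_D at the cognate epitope."""
    cog = cognate_epitope(clone_id, matrix)
    return state.ab_free_of(clone_id) / matrix.kd(clone_id, cog)


def _binding_profile(matrix: AffinityMatrix, clone_id: str):
    return frozenset(matrix.row(clone_id).items())


def build_network(
    repertoire: Repertoire,
    matrix: AffinityMatrix,
    state: EquilibriumState,
    *,
    binding_cutoff: float = DEFAULT_BINDING_CUTOFF,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
    method: str = "log",
    merge_identical: bool = True,
    validate: bool = True,
) -> nx.Graph:
    """Build the weighted antibody interaction network.

    One node per distinct binding profile (``merge_identical=True``, the
    default) or per clone; the node id is the lexicographically smallest
    member clone id and the ``members`` attribute lists all merged clones.
    A merged node's radius sums the members' free antibody over the shared
    cognate K_D.  Edges carry the internodal distance as ``weight`` and
    exist when the distance is finite (a shared bound epitope) and at most
    ``distance_cutoff``.  The construction is a pure function of its
    inputs.
    """
    cids = repertoire.clone_ids
    if validate:
        if state.clone_ids is not None and list(state.clone_ids) != cids:
            raise ConsistencyError("equilibrium state does not match repertoire")
        kd = matrix.to_dense(cids, repertoire.epitope_ids)
        state.validate(
            repertoire.ab_total_vector(cids),
            repertoire.ag_total_vector(repertoire.epitope_ids),
            kd,
            rtol=1e-6,
        )

    groups: dict = {}
    if merge_identical:
        for c in cids:
            groups.setdefault(_binding_profile(matrix, c), []).append(c)
        members_by_rep = {min(g): sorted(g) for g in groups.values()}
    else:
        members_by_rep = {c: [c] for c in cids}

    net = nx.Graph(
        binding_cutoff=binding_cutoff,
        distance_cutoff=distance_cutoff,
        distance_method=method,
    )
    for rep, members in sorted(members_by_rep.items()):
        row = matrix.row(rep)
        radius = 0.0
        if row:
            cog = cognate_epitope(rep, matrix)
            kd_cog = row[cog]
            radius = sum(state.ab_free_of(c) for c in members) / kd_cog
        net.add_node(
            rep,
            radius=radius,
            cell_type=repertoire.clones[rep].cell_type.value,
            members=tuple(members),
        )

    reps = sorted(members_by_rep)
    for a_idx, a in enumerate(reps):
        for b in reps[a_idx + 1 :]:
            d = internodal_distance(
                a, b, matrix, binding_cutoff=binding_cutoff, method=method
            )
            if d <= distance_cutoff:
                net.add_edge(a, b, weight=d)

    giant = giant_component(net)
    for rep in net.nodes:
        net.nodes[rep]["in_giant_component"] = all(
            m in giant for m in net.nodes[rep]["members"]
        )
    return net


def _component_members(net: nx.Graph, comp: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for rep in comp:
        out.update(net.nodes[rep]["members"])
    return out


def giant_component(net: nx.Graph) -> set[str]:
    """Clone ids in the largest connected component (immunological self).

    Size is measured in node count; ties go to the component containing
    the lexicographically smallest clone id.  Returns the union of member
    clone ids; an empty graph yields an empty set.
    """
    comps = list(nx.connected_components(net))
    if not comps:
        return set()
    best = min(comps, key=lambda comp: (-len(comp), min(_component_members(net, comp))))
    return _component_members(net, best)


def extruded_nodes(net: nx.Graph) -> set[str]:
    """Clone ids outside the giant component — extruded from the network."""
    giant = giant_component(net)
    everyone: set[str] = set()
    for rep in net.nodes:
        everyone.update(net.nodes[rep]["members"])
    return everyone - giant
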