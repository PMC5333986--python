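"""Table and graph round-tripping.

All numeric TSV fields are written in scientific notation with 17
significant digits, which round-trips IEEE doubles exactly.  Writers
prepend ``#``-prefixed provenance lines (version, seed, parameters —
never timestamps, so identical runs produce byte-identical files);
readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .binding_core import EquilibriumState
from .landscape import LandscapeGrid
from .repertoire import AffinityMatrix, CellType, Clone, Epitope, Isotype, Repertoire

__all__ = [
    "write_table",
    "read_table",
    "write_repertoire",
    "read_repertoire",
    "write_affinity",
    "read_affinity",
    "write_equilibrium",
    "write_network",
    "read_network",
    "write_landscape",
]

FLOAT_FORMAT = "%.17g"


def _provenance_lines(provenance: Mapping | None) -> str:
    lines = [f"# gqm {__version__}"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key} = {value}")
    return "".join(line + "\n" for line in lines)


def write_table(df: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write a DataFrame as TSV with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path, **kwargs) -> pd.DataFrame:
    # round_trip parsing: %.17g output must come back bit-identical
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_repertoire(
    repertoire: Repertoire, clones_path, epitopes_path, provenance=None
) -> None:
    clones = pd.DataFrame(
        [
            {
                "clone_id": c.id,
                "ab_total_molar": c.ab_total,
                "cell_type": c.cell_type.value,
                "isotype": c.isotype.value,
                "long_lived": c.long_lived,
            }
            for c in (repertoire.clones[cid] for cid in repertoire.clone_ids)
        ]
    )
    epitopes = pd.DataFrame(
        [
            {
                "epitope_id": e.id,
                "ag_total_molar": e.ag_total,
                "is_self": e.is_self,
            }
            for e in (repertoire.epitopes[eid] for eid in repertoire.epitope_ids)
        ]
    )
    write_table(clones, clones_path, provenance)
    write_table(epitopes, epitopes_path, provenance)


def read_repertoire(clones_path, epitopes_path) -> Repertoire:
    cdf = read_table(clones_path)
    edf = read_table(epitopes_path)
    clones = {
        str(r.clone_id): Clone(
            id=str(r.clone_id),
            ab_total=float(r.ab_total_molar),
            cell_type=CellType(r.cell_type),
            isotype=Isotype(r.isotype),
            long_lived=bool(r.long_lived),
        )
        for r in cdf.itertuples()
    }
    epitopes = {
        str(r.epitope_id): Epitope(
            id=str(r.epitope_id),
            ag_total=float(r.ag_total_molar),
            is_self=bool(r.is_self),
        )
        for r in edf.itertuples()
    }
    return Repertoire(clones=clones, epitopes=epitopes)


def write_affinity(matrix: AffinityMatrix, path, provenance=None) -> None:
    """Long-format sparse affinity table; absent pairs mean no binding."""
    write_table(matrix.to_frame(), path, provenance)


def read_affinity(path) -> AffinityMatrix:
    return AffinityMatrix.from_frame(read_table(path))


def write_equilibrium(state: EquilibriumState, out_dir, provenance=None) -> None:
    """Write free-concentration and complex tables for a solved state."""
    out_dir = Path(out_dir)
    cids = state.clone_ids or tuple(str(i) for i in range(state.ab_free.size))
    eids = state.epitope_ids or tuple(str(j) for j in range(state.ag_free.size))
    write_table(
        pd.DataFrame({"clone_id": cids, "ab_free_molar": state.ab_free}),
        out_dir / "equilibrium_clones.tsv",
        provenance,
    )
    write_table(
        pd.DataFrame({"epitope_id": eids, "ag_free_molar": state.ag_free}),
        out_dir / "equilibrium_epitopes.tsv",
        provenance,
    )
    coo = state.complexes.tocoo()
    write_table(
        pd.DataFrame(
            {
                "clone_id": [cids[i] for i in coo.row],
                "epitope_id": [eids[j] for j in coo.col],
                "complex_molar": coo.data,
            }
        ),
        out_dir / "equilibrium_complexes.tsv",
        provenance,
    )


def write_network(net: nx.Graph, graphml_path, edges_path=None) -> None:
    """Export a network as GraphML (plus an optional edge-list TSV).

    The tuple-valued ``members`` node attribute is flattened to a
    comma-separated string for GraphML; :func:`read_network` restores it.
    """
    out = net.copy()
    for n in out.nodes:
        out.nodes[n]["members"] = ",".join(out.nodes[n]["members"])
    Path(graphml_path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(out, graphml_path)
    if edges_path is not None:
        rows = [
            {"clone_i": a, "clone_j": b, "distance_pkd": d["weight"]}
            for a, b, d in sorted(net.edges(data=True))
        ]
        write_table(
            pd.DataFrame(rows, columns=["clone_i", "clone_j", "distance_pkd"]),
            edges_path,
        )


def read_network(graphml_path) -> nx.Graph:
    net = nx.read_graphml(graphml_path)
    net = nx.relabel_nodes(net, str)
    for n in net.nodes:
        net.nodes[n]["members"] = tuple(net.nodes[n]["members"].split(","))
    return net


def write_landscape(grid: LandscapeGrid, saturation_path, zone_path, provenance=None):
    """Write saturation and zone matrices (rows = [Ab], cols = K_D)."""
    kd_labels = [FLOAT_FORMAT % k for k in grid.kd_axis]
    sat = pd.DataFrame(grid.saturation, columns=kd_labels)
    sat.insert(0, "ab_free_molar", grid.ab_axis)
    write_table(sat, saturation_path, provenance)
    zone = pd.DataFrame(
        np.vectorize(lambda z: z.value)(grid.zone), columns=kd_labels
    )
    zone.insert(0, "ab_free_molar", grid.ab_axis)
    write_table(zone, zone_path, provenance)


def component_report(net: nx.Graph) -> pd.DataFrame:
    """Per-clone giant-component membership table."""
    from .epitope_network import giant_component

    giant = giant_component(net)
    rows = []
    for rep, data in sorted(net.nodes(data=True)):
        for member in data["members"]:
            rows.append(
                {
                    "clone_id": member,
                    "node": rep,
                    "radius": data["radius"],
                    "cell_type": data["cell_type"],
                    "in_giant_component": member in giant,
                }
            )
    return pd.DataFrame(
        rows, columns=["clone_id", "node", "radius", "cell_type", "in_giant_component"]
    )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
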