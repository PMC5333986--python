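"""Clones, epitopes, the sparse affinity matrix and a synthetic repertoire
generator.

The generator places antibody clones and epitopes in a latent Euclidean
"shape space": clones of one cluster (the progeny of a common precursor,
sharing a heavy chain) scatter around a common centroid, and a clone's
affinity for an epitope decays exponentially (in K_D decades) with latent
distance.  Cognate affinities live in a configurable range — by default
the natural-antibody range of K_D = 1e-6..1e-4 M — with cluster mates
sharing a cluster-level base affinity up to a per-clone jitter, since
clonally related cells carry the same heavy chain.  Interactions weaker
than ``kd_cap`` are dropped
entirely (no binding).  The latent coordinates exist only inside the
generator; everything downstream sees concentrations and K_D values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import binding_core
from .errors import ConfigError, DomainError, NoCognateError, UnknownCloneError

__all__ = [
    "CellType",
    "Isotype",
    "Clone",
    "Epitope",
    "Repertoire",
    "AffinityMatrix",
    "GeneratorConfig",
    "cognate_epitope",
    "estimate_b1_count",
    "generate_repertoire",
    "solve_equilibrium",
]


class CellType(str, enum.Enum):
    B1 = "B1"
    MZ = "MZ"
    NAIVE = "naive"
    ASC = "ASC"
    MEMORY = "memory"
    LONG_LIVED_PLASMA = "long_lived_plasma"


class Isotype(str, enum.Enum):
    IgM = "IgM"
    IgG = "IgG"
    IgA = "IgA"
    IgE = "IgE"


#: Cell types that secrete in thymus-independent (polyclonal) responses.
TI_CELL_TYPES = frozenset({CellType.B1, CellType.MZ})


@dataclass(frozen=True)
class Clone:
    """One antibody clone: id, total paratope concentration (molar), cell
    biology annotations.  ``long_lived`` marks constitutive, unregulated
    secretion by a long-lived plasma cell."""

    id: str
    ab_total: float
    cell_type: CellType = CellType.B1
    isotype: Isotype = Isotype.IgM
    long_lived: bool = False

    def __post_init__(self):
        if self.ab_total < 0:
            raise DomainError(f"clone {self.id}: ab_total must be non-negative")
        if self.long_lived and self.cell_type is not CellType.LONG_LIVED_PLASMA:
            raise DomainError(
                f"clone {self.id}: long_lived requires cell_type long_lived_plasma"
            )


@dataclass(frozen=True)
class Epitope:
    """One epitope: id, total concentration (molar) and self/foreign flag."""

    id: str
    ag_total: float
    is_self: bool = True

    def __post_init__(self):
        if self.ag_total < 0:
            raise DomainError(f"epitope {self.id}: ag_total must be non-negative")


class AffinityMatrix:
    """Sparse clone × epitope map of dissociation constants (molar).

    Absent pairs mean "no binding" (K_D = +inf).  Clone and epitope ids may
    be registered without entries while a matrix is being built, but a
    valid repertoire matrix gives every clone at least one finite entry
    (its cognate epitope).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], float] | None = None,
        clone_ids: Iterable[str] = (),
        epitope_ids: Iterable[str] = (),
    ):
        self._kd: dict[str, dict[str, float]] = {}
        self._clones: set[str] = set(clone_ids)
        self._epitopes: set[str] = set(epitope_ids)
        if entries:
            for (c, e), kd in entries.items():
                self.set(c, e, kd)

    # -- mutation -----------------------------------------------------
    def set(self, clone_id: str, epitope_id: str, kd: float) -> None:
        if not kd > 0 or not math.isfinite(kd):
            raise DomainError("stored kd must be positive and finite")
        self._kd.setdefault(clone_id, {})[epitope_id] = float(kd)
        self._clones.add(clone_id)
        self._epitopes.add(epitope_id)

    def remove(self, clone_id: str, epitope_id: str) -> None:
        """Drop an interaction (the pair reverts to no binding)."""
        row = self._kd.get(clone_id, {})
        row.pop(epitope_id, None)

    # -- queries ------------------------------------------------------
    def kd(self, clone_id: str, epitope_id: str) -> float:
        if clone_id not in self._clones:
            raise UnknownCloneError(clone_id)
        return self._kd.get(clone_id, {}).get(epitope_id, math.inf)

    def row(self, clone_id: str) -> dict[str, float]:
        if clone_id not in self._clones:
            raise UnknownCloneError(clone_id)
        return dict(self._kd.get(clone_id, {}))

    @property
    def clones(self) -> list[str]:
        return sorted(self._clones)

    @property
    def epitopes(self) -> list[str]:
        return sorted(self._epitopes)

    @property
    def n_entries(self) -> int:
        return sum(len(r) for r in self._kd.values())

    def items(self):
        for c in sorted(self._kd):
            for e in sorted(self._kd[c]):
                yield c, e, self._kd[c][e]

    def copy(self) -> "AffinityMatrix":
        new = AffinityMatrix(clone_ids=self._clones, epitope_ids=self._epitopes)
        new._kd = {c: dict(r) for c, r in self._kd.items()}
        return new

    def __eq__(self, other) -> bool:
        # equality is over stored interactions; the id registries are
        # construction bookkeeping and need not round-trip through tables
        if not isinstance(other, AffinityMatrix):
            return NotImplemented
        mine = {(c, e): kd for c, e, kd in self.items()}
        theirs = {(c, e): kd for c, e, kd in other.items()}
        return mine == theirs

    def to_dense(
        self,
        clone_order: Iterable[str] | None = None,
        epitope_order: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Dense K_D array with +inf in absent cells."""
        cids = list(clone_order) if clone_order is not None else self.clones
        eids = list(epitope_order) if epitope_order is not None else self.epitopes
        eidx = {e: j for j, e in enumerate(eids)}
        out = np.full((len(cids), len(eids)), np.inf)
        for i, c in enumerate(cids):
            for e, kd in self._kd.get(c, {}).items():
                j = eidx.get(e)
                if j is not None:
                    out[i, j] = kd
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (clone_id, epitope_id, kd_molar)."""
        rows = list(self.items())
        return pd.DataFrame(rows, columns=["clone_id", "epitope_id", "kd_molar"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AffinityMatrix":
        mat = cls()
        for c, e, kd in zip(df["clone_id"], df["epitope_id"], df["kd_molar"]):
            mat.set(str(c), str(e), float(kd))
        return mat


@dataclass
class Repertoire:
    """The immune system's state variables: clones and the epitopes they face."""

    clones: dict[str, Clone] = field(default_factory=dict)
    epitopes: dict[str, Epitope] = field(default_factory=dict)

    @property
    def clone_ids(self) -> list[str]:
        return sorted(self.clones)

    @property
    def epitope_ids(self) -> list[str]:
        return sorted(self.epitopes)

    def ab_total_vector(self, order: Iterable[str]) -> np.ndarray:
        return np.array([self.clones[c].ab_total for c in order])

    def ag_total_vector(self, order: Iterable[str]) -> np.ndarray:
        return np.array([self.epitopes[e].ag_total for e in order])

    def with_clone_ab(self, clone_id: str, ab_total: float) -> "Repertoire":
        """Copy of the repertoire with one clone's total antibody replaced."""
        if clone_id not in self.clones:
            raise UnknownCloneError(clone_id)
        clones = dict(self.clones)
        clones[clone_id] = replace(clones[clone_id], ab_total=ab_total)
        return Repertoire(clones=clones, epitopes=dict(self.epitopes))

    def with_epitope(self, epitope: Epitope) -> "Repertoire":
        epitopes = dict(self.epitopes)
        epitopes[epitope.id] = epitope
        return Repertoire(clones=dict(self.clones), epitopes=epitopes)


def cognate_epitope(clone_id: str, matrix: AffinityMatrix) -> str:
    """The epitope a clone binds with highest affinity (lowest K_D).

    Ties are broken toward the lexicographically smallest epitope id.  The
    cognate identity is not fixed: adding a higher-affinity interaction
    (a newly encountered antigen) changes the result.
    """
    row = matrix.row(clone_id)
    if not row:
        raise NoCognateError(clone_id)
    return min(row, key=lambda e: (row[e], e))


def estimate_b1_count(
    wbc_per_liter: float,
    frac_b_of_wbc: float,
    frac_b1_of_b: float,
    blood_volume: float,
) -> float:
    """Circulating B1-cell count from white-blood-cell arithmetic.

    With 4e9 white blood cells per liter, 5% B cells among them, 5% B1
    among B cells and 5 L of blood this yields 5e7 B1 cells — enough to
    dominate the natural (IgM) plasma antibody pool.
    """
    args = (wbc_per_liter, frac_b_of_wbc, frac_b1_of_b, blood_volume)
    if any(a < 0 for a in args):
        raise DomainError("all arguments must be non-negative")
    if frac_b_of_wbc > 1 or frac_b1_of_b > 1:
        raise DomainError("fractions must be at most 1")
    return wbc_per_liter * frac_b_of_wbc * frac_b1_of_b * blood_volume


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic repertoire generator.

    Defaults describe a natural (B1/MZ, IgM-dominated) repertoire:
    cognate affinities log-uniform in the natural-antibody range
    1e-6..1e-4 M, abundant self epitopes, per-clone antibody pools well
    below saturating any single target.  ``affinity_decay`` is in pK_D
    units lost per unit of latent distance; ``kd_cap`` is the weakest
    interaction still stored.
    """

    n_clusters: int = 5
    clones_per_cluster: int = 8
    n_epitopes: int = 40
    latent_dim: int = 2
    affinity_decay: float = 2.0
    kd_cognate_range: tuple[float, float] = (1e-6, 1e-4)
    kd_cap: float = 1e-4
    ab_total_range: tuple[float, float] = (1e-12, 1e-8)
    ag_total_range: tuple[float, float] = (1e-6, 1e-4)
    cluster_spread: float = 0.05
    cognate_jitter: float = 0.25
    mz_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1 or self.clones_per_cluster < 1:
            raise ConfigError("need at least one cluster with one clone")
        if self.n_epitopes < 1:
            raise ConfigError("need at least one epitope")
        if self.latent_dim < 1:
            raise ConfigError("latent_dim must be at least 1")
        if self.affinity_decay <= 0:
            raise ConfigError("affinity_decay must be positive")
        for name in ("kd_cognate_range", "ab_total_range", "ag_total_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi")
        if self.kd_cap < self.kd_cognate_range[1]:
            raise ConfigError("kd_cap must be at least the largest cognate kd")
        if not 0 <= self.mz_fraction <= 1:
            raise ConfigError("mz_fraction must be a fraction")
        if self.cognate_jitter < 0:
            raise ConfigError("cognate_jitter must be non-negative")
        lo, hi = self.kd_cognate_range
        if 2 * self.cognate_jitter > math.log10(hi / lo):
            raise ConfigError(
                "cognate_jitter must fit inside kd_cognate_range "
                "(2 * jitter <= width of the range in decades)"
            )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=size)


def generate_repertoire(
    config: GeneratorConfig,
) -> tuple[Repertoire, AffinityMatrix]:
    """Draw a synthetic repertoire, epitope panel and affinity matrix.

    Deterministic for a fixed ``config.seed``.  Cluster centroids and
    epitope positions are uniform in the unit hypercube; clone positions
    scatter normally (sd ``cluster_spread``) around their centroid.  Each
    cluster draws a base cognate K_D log-uniformly from the jitter-shrunk
    cognate range and each clone jitters it by up to ``cognate_jitter``
    decades, so every cognate K_D stays inside ``kd_cognate_range`` while
    cluster mates remain close on the affinity axis.  For a clone at
    latent distance ``d_e`` from epitope ``e`` with nearest epitope at
    distance ``d_min``,

        K_D(e) = K_D_cognate * 10 ** (affinity_decay * (d_e - d_min)),

    and entries above ``kd_cap`` are dropped, so every stored affinity
    lies in [cognate K_D, kd_cap] and each clone keeps its cognate entry.
    """
    rng = np.random.default_rng(config.seed)
    dim = config.latent_dim

    epitope_pos = rng.uniform(size=(config.n_epitopes, dim))
    epitopes = {}
    ag_totals = _log_uniform(rng, *config.ag_total_range, size=config.n_epitopes)
    for j in range(config.n_epitopes):
        eid = f"e{j:03d}"
        epitopes[eid] = Epitope(id=eid, ag_total=float(ag_totals[j]), is_self=True)
    epitope_ids = sorted(epitopes)

    centroids = rng.uniform(size=(config.n_clusters, dim))
    jit = config.cognate_jitter
    base_lo = config.kd_cognate_range[0] * 10.0**jit
    base_hi = config.kd_cognate_range[1] * 10.0**-jit
    cluster_kd = _log_uniform(rng, base_lo, base_hi, size=config.n_clusters)
    clones: dict[str, Clone] = {}
    matrix = AffinityMatrix(epitope_ids=epitope_ids)
    for k in range(config.n_clusters):
        for c in range(config.clones_per_cluster):
            cid = f"c{k:02d}_{c:02d}"
            pos = centroids[k] + rng.normal(scale=config.cluster_spread, size=dim)
            dists = np.linalg.norm(epitope_pos - pos, axis=1)
            d_min = float(dists.min())
            kd_cog = float(cluster_kd[k] * 10.0 ** rng.uniform(-jit, jit))
            cell_type = (
                CellType.MZ if rng.uniform() < config.mz_fraction else CellType.B1
            )
            ab_total = float(_log_uniform(rng, *config.ab_total_range))
            clones[cid] = Clone(
                id=cid, ab_total=ab_total, cell_type=cell_type, isotype=Isotype.IgM
            )
            # compare in log space: keeps kd <= kd_cap without overflow at
            # extreme affinity_decay
            span = math.log10(config.kd_cap / kd_cog)
            for j, eid in enumerate(f"e{j:03d}" for j in range(config.n_epitopes)):
                excess = config.affinity_decay * (dists[j] - d_min)
                if excess <= span:
                    matrix.set(cid, eid, kd_cog * 10.0**excess)

    return Repertoire(clones=clones, epitopes=epitopes), matrix


def solve_equilibrium(
    repertoire: Repertoire, matrix: AffinityMatrix, **solver_kwargs
) -> binding_core.EquilibriumState:
    """Solve the competitive mass-action equilibrium of a repertoire.

    Clone/epitope ordering is the sorted id order; the returned state
    carries the ids for lookup by clone.
    """
    cids = repertoire.clone_ids
    eids = repertoire.epitope_ids
    kd = matrix.to_dense(cids, eids)
    return binding_core.solve_system_equilibrium(
        repertoire.ab_total_vector(cids),
        repertoire.ag_total_vector(eids),
        kd,
        clone_ids=cids,
        epitope_ids=eids,
        **solver_kwargs,
    )
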