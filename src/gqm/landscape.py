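"""The [Ab] × K_D interaction landscape.

Over a log-spaced grid of free antibody concentration and dissociation
constant, each cell carries the equilibrium fractional saturation of the
epitope and a zone label: at low saturation antigen is *released*, around
50% saturation (the [Ab] = K_D diagonal) its concentration is best
*controlled*, and pushing saturation further *eliminates* it.  The zone
thresholds are exposed parameters (defaults 0.1 and 0.9) since the model
fixes only the 50% set point, not the zone borders.

Response types occupy characteristic bands of the landscape: natural/TI
antibodies at K_D = 1e-4..1e-6 M, affinity-matured TD antibodies at
K_D = 1e-8..1e-10 M.  ``place_response_types`` annotates such rectangles
on a grid by pure containment, clipping regions that overhang it.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .binding_core import fractional_saturation
from .errors import DomainError

__all__ = [
    "Zone",
    "LandscapeGrid",
    "Region",
    "classify_zone",
    "build_landscape",
    "place_response_types",
    "DEFAULT_THRESHOLDS",
    "DEFAULT_REGIONS",
]

DEFAULT_THRESHOLDS = (0.1, 0.9)
#: Default axis span (molar): covers the printed 1e-4..1e-10 M affinity
#: range with margin on both sides.
DEFAULT_AXIS_RANGE = (1e-12, 1e-4)


class Zone(str, enum.Enum):
    RELEASE = "release"
    CONTROL = "control"
    ELIMINATE = "eliminate"


def _check_thresholds(thresholds):
    low, high = thresholds
    if not (0 < low < high < 1):
        raise DomainError("thresholds must satisfy 0 < low < high < 1")
    return low, high


def classify_zone(
    ab_free: float, kd: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> Zone:
    """Zone of one (free antibody, K_D) point by fractional saturation."""
    low, high = _check_thresholds(thresholds)
    sat = fractional_saturation(ab_free, kd)
    if sat < low:
        return Zone.RELEASE
    if sat > high:
        return Zone.ELIMINATE
    return Zone.CONTROL


@dataclass(frozen=True)
class Region:
    """A rectangular annotation on the landscape (molar ranges)."""

    name: str
    ab_range: tuple[float, float]
    kd_range: tuple[float, float]


#: Characteristic response-type bands.  The antibody-concentration spans
#: are schematic defaults (single-clone output up to high serum levels);
#: the K_D bands are the printed natural and matured affinity ranges.
DEFAULT_REGIONS = (
    Region("natural_TI", ab_range=(1e-12, 1e-5), kd_range=(1e-6, 1e-4)),
    Region("TD", ab_range=(1e-12, 1e-5), kd_range=(1e-10, 1e-8)),
)


@dataclass
class LandscapeGrid:
    """Saturation and zone matrices over log-spaced [Ab] and K_D axes.

    Rows follow ``ab_axis``, columns follow ``kd_axis``.
    """

    ab_axis: np.ndarray
    kd_axis: np.ndarray
    saturation: np.ndarray
    zone: np.ndarray
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    annotations: list = field(default_factory=list)

    def diagonal(self) -> np.ndarray:
        """Saturation values where the two axes carry the same value."""
        shared = [
            (i, j)
            for i, a in enumerate(self.ab_axis)
            for j, k in enumerate(self.kd_axis)
            if a == k
        ]
        return np.array([self.saturation[i, j] for i, j in shared])

    def plot(self, ax=None):
        """Convenience heatmap of the saturation landscape."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(
            self.kd_axis, self.ab_axis, self.saturation, shading="nearest"
        )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("$K_D$ (M)")
        ax.set_ylabel("[Ab] free (M)")
        ax.figure.colorbar(mesh, ax=ax, label="fractional saturation")
        return ax


def build_landscape(
    ab_range: tuple[float, float] = DEFAULT_AXIS_RANGE,
    kd_range: tuple[float, float] = DEFAULT_AXIS_RANGE,
    n_points: int = 49,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> LandscapeGrid:
    """Fill a log-spaced grid with saturation and zone labels.

    Cells on the [Ab] = K_D diagonal carry saturation exactly 0.5 and are
    classified ``control``.
    """
    low, high = _check_thresholds(thresholds)
    for name, rng in (("ab_range", ab_range), ("kd_range", kd_range)):
        if not (0 < rng[0] < rng[1]):
            raise DomainError(f"{name} must be ordered and positive")
    if n_points < 2:
        raise DomainError("n_points must be at least 2")
    ab_axis = np.logspace(np.log10(ab_range[0]), np.log10(ab_range[1]), n_points)
    kd_axis = np.logspace(np.log10(kd_range[0]), np.log10(kd_range[1]), n_points)
    sat = fractional_saturation(ab_axis[:, None], kd_axis[None, :])
    zone = np.empty(sat.shape, dtype=object)
    zone[:] = Zone.CONTROL
    zone[sat < low] = Zone.RELEASE
    zone[sat > high] = Zone.ELIMINATE
    return LandscapeGrid(
        ab_axis=ab_axis,
        kd_axis=kd_axis,
        saturation=sat,
        zone=zone,
        thresholds=(low, high),
    )


def place_response_types(
    grid: LandscapeGrid, regions: tuple[Region, ...] = DEFAULT_REGIONS
) -> list[Region]:
    """Clip response-type rectangles to the grid and attach them to it.

    Annotation only — no computation beyond containment.  Regions
    entirely outside the grid are dropped; partially overhanging ones are
    clipped, both with a warning.
    """
    ab_lo, ab_hi = grid.ab_axis[0], grid.ab_axis[-1]
    kd_lo, kd_hi = grid.kd_axis[0], grid.kd_axis[-1]
    placed: list[Region] = []
    for region in regions:
        a0, a1 = region.ab_range
        k0, k1 = region.kd_range
        c0, c1 = max(a0, ab_lo), min(a1, ab_hi)
        d0, d1 = max(k0, kd_lo), min(k1, kd_hi)
        if c0 > c1 or d0 > d1:
            warnings.warn(f"region {region.name!r} lies outside the grid; dropped")
            continue
        if (c0, c1) != (a0, a1) or (d0, d1) != (k0, k1):
            warnings.warn(f"region {region.name!r} clipped to the grid")
        placed.append(Region(region.name, (c0, c1), (d0, d1)))
    grid.annotations = placed
    return placed
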