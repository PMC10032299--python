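"""Tunnel geometry: the discretized sinusoidal gallery and its surface irregularities.

The tunnel is a 1-D lattice of sites x = 0..L along the gallery axis, following
y = A*sin(pi*x/(L/2)) in the plane (the y profile is metadata only; all dynamics
depend on the arc position x).  One end (x = 0) opens into the nest, the other
(x = L) into an inexhaustible food site.  Two short high-curvature sections slow
agents down stochastically, and a set of surface-irregularity sites makes them
pause for Poisson-distributed times.

Irregularity placement is controlled by two integer levels:

* ``k3`` (distribution / patchiness): sites are only eligible where the gating
  sine ``sin(2*pi*f*x/L)`` with ``f = (k3-1)*2`` cycles is strictly positive, so
  larger ``k3`` breaks the eligible region into more, narrower patches.
* ``k4`` (density): ``(k4-1)*30`` distinct sites are drawn uniformly without
  replacement from the eligible set.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: default geometry constants
DEFAULT_LENGTH_CELLS = 1001          # sites x = 0 .. 1000
DEFAULT_AMPLITUDE = 20.0             # lattice units of the sinusoid
DEFAULT_CURVATURE_ZONES = ((235, 265), (735, 765))
IRREGULARITIES_PER_LEVEL = 30        # count = (k4 - 1) * 30
CYCLES_PER_LEVEL = 2                 # f = (k3 - 1) * 2
LEVELS = tuple(range(1, 12))         # admissible k levels


class ConfigurationError(ValueError):
    """Raised when a tunnel/simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class TunnelSpec:
    """The discretized tunnel path with curvature zones and endpoint roles.

    Parameters
    ----------
    length_cells:
        Number of lattice sites; site indices run 0 .. length_cells - 1.
    amplitude:
        Amplitude of the sinusoidal profile (metadata; used for plotting).
    curvature_zones:
        Inclusive integer intervals of high curvature.
    nest_x, food_x:
        Endpoint site indices (deposit and pickup points).
    """

    length_cells: int = DEFAULT_LENGTH_CELLS
    amplitude: float = DEFAULT_AMPLITUDE
    curvature_zones: tuple[tuple[int, int], ...] = DEFAULT_CURVATURE_ZONES
    nest_x: int = 0
    food_x: int = DEFAULT_LENGTH_CELLS - 1

    def __post_init__(self) -> None:
        if self.length_cells < 3:
            raise ConfigurationError("length_cells must be at least 3")
        last = self.length_cells - 1
        if {self.nest_x, self.food_x} != {0, last}:
            raise ConfigurationError(
                f"nest_x/food_x must be the endpoint sites 0 and {last}"
            )
        prev_hi = -1
        for lo, hi in sorted(self.curvature_zones):
            if not (0 <= lo <= hi <= last):
                raise ConfigurationError(f"curvature zone [{lo},{hi}] outside tunnel")
            if lo <= prev_hi:
                raise ConfigurationError("curvature zones must be disjoint")
            prev_hi = hi

    @property
    def axis_length(self) -> int:
        """L, the tunnel length along x (distance between the endpoint sites)."""
        return self.length_cells - 1

    def y_profile(self) -> np.ndarray:
        """Transverse profile A*sin(pi*x/(L/2)) at every site (for plotting)."""
        x = np.arange(self.length_cells)
        return self.amplitude * np.sin(np.pi * x / (self.axis_length / 2.0))

    def curvature_mask(self) -> np.ndarray:
        """Boolean array over sites: True inside a high-curvature zone."""
        mask = np.zeros(self.length_cells, dtype=bool)
        for lo, hi in self.curvature_zones:
            mask[lo : hi + 1] = True
        return mask


def build_tunnel(
    length_cells: int = DEFAULT_LENGTH_CELLS,
    amplitude: float = DEFAULT_AMPLITUDE,
    curvature_zones: tuple[tuple[int, int], ...] = DEFAULT_CURVATURE_ZONES,
) -> TunnelSpec:
    """Build a TunnelSpec; defaults reproduce the standard 1001-site gallery."""
    zones = tuple((int(lo), int(hi)) for lo, hi in curvature_zones)
    return TunnelSpec(
        length_cells=int(length_cells),
        amplitude=float(amplitude),
        curvature_zones=zones,
        nest_x=0,
        food_x=int(length_cells) - 1,
    )


def in_curvature_zone(spec: TunnelSpec, x: int) -> bool:
    """True iff site ``x`` lies in a high-curvature zone (inclusive bounds)."""
    if not 0 <= x <= spec.length_cells - 1:
        raise ValueError(f"site index {x} outside [0, {spec.length_cells - 1}]")
    return any(lo <= x <= hi for lo, hi in spec.curvature_zones)


def eligible_sites(spec: TunnelSpec, k3: int) -> np.ndarray:
    """Interior sites where an irregularity may be placed for distribution level k3.

    For f = (k3-1)*2 > 0 these are exactly the sites with sin(2*pi*f*x/L) > 0
    (strict).  k3 = 1 gives f = 0, i.e. no spatial gating: every interior site is
    eligible.  Endpoints are never eligible, so pickup/deposit is never delayed
    by a pause at the terminus.

    Returns a sorted integer array of site indices.
    """
    _check_level(k3, "k3")
    L = spec.axis_length
    interior = np.arange(1, spec.length_cells - 1)
    f = (k3 - 1) * CYCLES_PER_LEVEL
    if f == 0:
        return interior
    # sin(2*pi*f*x/L) > 0  <=>  (f*x mod L) in (0, L/2); integer arithmetic
    # avoids float noise at the exact zeros of the gating sine
    m = (f * interior) % L
    return interior[(2 * m > 0) & (2 * m < L)]


@dataclass(frozen=True)
class IrregularityLayout:
    """Set of tunnel sites carrying a surface irregularity for given (k3, k4)."""

    sites: frozenset[int]
    k3: int
    k4: int

    @property
    def f(self) -> int:
        """Cycles of the gating sine."""
        return (self.k3 - 1) * CYCLES_PER_LEVEL

    @property
    def count(self) -> int:
        """Nominal irregularity count (k4 - 1) * 30."""
        return (self.k4 - 1) * IRREGULARITIES_PER_LEVEL

    def site_mask(self, spec: TunnelSpec) -> np.ndarray:
        """Boolean array over tunnel sites: True where an irregularity sits."""
        mask = np.zeros(spec.length_cells, dtype=bool)
        if self.sites:
            mask[np.fromiter(self.sites, dtype=np.int64)] = True
        return mask

    def to_json(self, seed: int | None = None) -> str:
        """Serialize (k3, k4, seed, sorted site list) for reproducibility."""
        return json.dumps(
            {"k3": self.k3, "k4": self.k4, "seed": seed, "sites": sorted(self.sites)}
        )

    def to_csv(self, spec: TunnelSpec) -> str:
        """Two-column CSV (site_index, is_irregular) over all tunnel sites."""
        mask = self.site_mask(spec)
        lines = ["site_index,is_irregular"]
        lines += [f"{x},{int(mask[x])}" for x in range(spec.length_cells)]
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_json(text: str) -> "IrregularityLayout":
        d = json.loads(text)
        return IrregularityLayout(sites=frozenset(d["sites"]), k3=d["k3"], k4=d["k4"])


def place_irregularities(
    spec: TunnelSpec, k3: int, k4: int, rng: np.random.Generator
) -> IrregularityLayout:
    """Sample (k4-1)*30 distinct irregularity sites from the k3-eligible set.

    Sampling is uniform without replacement and deterministic given the
    generator state.  If the nominal count exceeds the eligible-set size, the
    layout is truncated to the whole eligible set and a warning is logged.
    """
    _check_level(k3, "k3")
    _check_level(k4, "k4")
    pool = eligible_sites(spec, k3)
    n = (k4 - 1) * IRREGULARITIES_PER_LEVEL
    if n > pool.size:
        logger.warning(
            "requested %d irregularities but only %d eligible sites for k3=%d; "
            "truncating",
            n,
            pool.size,
            k3,
        )
        n = pool.size
    chosen = rng.choice(pool, size=n, replace=False) if n else np.empty(0, dtype=int)
    return IrregularityLayout(sites=frozenset(int(s) for s in chosen), k3=k3, k4=k4)


def _check_level(k: int, name: str) -> None:
    if k not in LEVELS:
        raise ConfigurationError(f"{name} must be an integer level in 1..11, got {k!r}")
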