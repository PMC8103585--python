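"""Deterministic laser-spot layouts on the flattened equal-area retina.

Spots are equal circles (default diameter 0.4 mm, i.e. a 400 um burn) placed
one spot width apart on concentric rings inside a treatment annulus: scatter
PRP fills the annulus between the PRP-free radius (5.14 mm) and the equator
(15.6 mm); full-scatter PRP extends to the ora serrata (18.6 mm).  A spot is
kept only if its closed disc lies entirely inside the closed annulus —
crossing a boundary excludes it, touching does not.

Ring construction: centers of the first ring sit at ``inner + d/2`` (tangent
to the inner boundary); ring radii advance by the radial pitch of the chosen
mode (``square``: one center pitch; ``hex``: sqrt(3)/2 of it, the hexagonal
row spacing; ``count_match``: hex rings with per-ring counts adjusted to hit
a target total exactly).  Each ring holds ``floor(2 pi R / pitch)`` evenly
spaced spots; alternate rings are rotated by half an angular step so spots
do not align radially.  Everything is deterministic — identical configs give
identical layouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import EquivalentDisc

__all__ = [
    "Spot",
    "LayoutConfig",
    "SpotLayout",
    "LayoutValidationError",
    "generate_annulus_layout",
    "generate_single_ring",
    "photocoagulation_index",
    "load_layout",
    "save_layout",
    "read_layout_csv",
    "write_layout_csv",
]

_TOL = 1e-9

#: Standard PRP burn: 400 um spot, one spot width apart.
SPOT_DIAMETER_MM = 0.4
SPOT_SPACING_MM = 0.4


@dataclass(frozen=True)
class Spot:
    """One laser burn: a disc of ``diameter`` mm centered at (x, y) mm."""

    x: float
    y: float
    diameter: float = SPOT_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"spot diameter must be > 0, got {self.diameter}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def center_eccentricity(self) -> float:
        return math.hypot(self.x, self.y)

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class LayoutConfig:
    """Parameters of an annular spot layout.

    ``spacing`` is edge-to-edge, so the center-to-center circumferential
    pitch is ``spot_diameter + spacing``.  ``radial_pitch_mode`` selects the
    ring spacing; ``count_match`` additionally requires ``target_count`` and
    adjusts per-ring spot counts to reach it exactly.
    """

    inner_radius: float
    outer_radius: float
    spot_diameter: float = SPOT_DIAMETER_MM
    spacing: float = SPOT_SPACING_MM
    radial_pitch_mode: str = "hex"
    target_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.spot_diameter <= 0:
            raise ValueError("spot_diameter must be > 0")
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")
        if not self.inner_radius < self.outer_radius:
            raise ValueError(
                f"inner_radius ({self.inner_radius}) must be < outer_radius "
                f"({self.outer_radius})"
            )
        if self.radial_pitch_mode not in ("square", "hex", "count_match"):
            raise ValueError(
                f"radial_pitch_mode must be square|hex|count_match, "
                f"got {self.radial_pitch_mode!r}"
            )
        if self.radial_pitch_mode == "count_match" and self.target_count is None:
            raise ValueError("count_match mode requires target_count")

    @property
    def circumferential_pitch(self) -> float:
        return self.spot_diameter + self.spacing

    @property
    def radial_pitch(self) -> float:
        p = self.circumferential_pitch
        if self.radial_pitch_mode == "square":
            return p
        return p * math.sqrt(3.0) / 2.0  # hex row spacing; count_match starts from hex


class LayoutValidationError(ValueError):
    """A layout violates non-overlap or annulus containment; carries indices."""

    def __init__(self, message: str, indices: Sequence[int]):
        super().__init__(message)
        self.indices = list(indices)


@dataclass(frozen=True)
class SpotLayout:
    """An immutable list of non-overlapping spots plus its generating config."""

    spots: tuple[Spot, ...]
    config: LayoutConfig
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))
        if self.validate:
            _validate_spots(self.spots, self.config)

    def __len__(self) -> int:
        return len(self.spots)

    def __iter__(self):
        return iter(self.spots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def total_spot_area(self) -> float:
        """Summed burn area, mm^2 (spots never overlap)."""
        return sum(s.area for s in self.spots)


def _validate_spots(spots: Sequence[Spot], config: LayoutConfig) -> None:
    if not spots:
        return
    xy = np.array([(s.x, s.y) for s in spots])
    d = np.array([s.diameter for s in spots])
    r = np.hypot(xy[:, 0], xy[:, 1])
    # inner_radius == 0 means no hole: only the outer boundary constrains
    inner_bad = (
        r - d / 2 < config.inner_radius - _TOL
        if config.inner_radius > _TOL
        else np.zeros_like(r, dtype=bool)
    )
    bad_out = np.flatnonzero(inner_bad | (r + d / 2 > config.outer_radius + _TOL))
    if bad_out.size:
        raise LayoutValidationError(
            f"{bad_out.size} spot(s) outside the annulus "
            f"[{config.inner_radius}, {config.outer_radius}]: "
            f"indices {bad_out.tolist()[:10]}",
            bad_out.tolist(),
        )
    dist = np.hypot(
        xy[:, 0, None] - xy[None, :, 0], xy[:, 1, None] - xy[None, :, 1]
    )
    min_sep = (d[:, None] + d[None, :]) / 2.0
    np.fill_diagonal(dist, np.inf)
    bad = np.flatnonzero((dist < min_sep - _TOL).any(axis=1))
    if bad.size:
        raise LayoutValidationError(
            f"{bad.size} spot(s) overlap a neighbour: indices {bad.tolist()[:10]}",
            bad.tolist(),
        )


def _ring_spots(radius: float, n: int, angle_offset: float, diameter: float) -> list[Spot]:
    angles = angle_offset + 2.0 * math.pi * np.arange(n) / n
    return [
        Spot(radius * math.cos(a), radius * math.sin(a), diameter) for a in angles
    ]


def _ring_radii(config: LayoutConfig) -> list[float]:
    """Ring center radii tangent to the inner boundary, fitting the annulus."""
    first = config.inner_radius + config.spot_diameter / 2.0
    last_allowed = config.outer_radius - config.spot_diameter / 2.0
    radii = []
    k = 0
    while True:
        radius = first + k * config.radial_pitch
        if radius > last_allowed + _TOL:
            break
        radii.append(radius)
        k += 1
    return radii


def _ring_capacity(radius: float, pitch: float) -> int:
    """Spots of one circumferential pitch fitting on a ring of this radius."""
    if 2.0 * math.pi * radius < pitch:
        return 1
    return int(math.floor(2.0 * math.pi * radius / pitch + _TOL))


def _max_ring_count(radius: float, diameter: float) -> int:
    """Hard cap from the chord length: n spots on the ring must not touch."""
    if diameter >= 2.0 * radius:
        return 1
    return int(math.floor(math.pi / math.asin(diameter / (2.0 * radius)) + _TOL))


def generate_annulus_layout(config: LayoutConfig) -> SpotLayout:
    """Fill the treatment annulus with concentric rings of spots.

    An annulus too narrow for any spot yields an empty layout.  In
    ``count_match`` mode the hex ring structure is kept but per-ring counts
    are nudged (largest fractional ring capacity first) until the total
    equals ``config.target_count``; see the module docstring for the rules.
    """
    radii = _ring_radii(config)
    pitch = config.circumferential_pitch
    # the chord between ring neighbours, not the arc, must reach one diameter
    counts = [
        min(_ring_capacity(radius, pitch), _max_ring_count(radius, config.spot_diameter))
        for radius in radii
    ]

    if config.radial_pitch_mode == "count_match":
        counts = _match_counts(radii, counts, pitch, config)

    spots: list[Spot] = []
    prev_ring: list[Spot] = []
    n_dropped = 0
    for k, (radius, n) in enumerate(zip(radii, counts)):
        if n <= 0:
            continue
        offset = (k % 2) * math.pi / n  # alternate half of the angular step
        ring = _ring_spots(radius, n, offset, config.spot_diameter)
        if prev_ring and radius - prev_ring[0].center_eccentricity < config.spot_diameter:
            # tight radial pitch: drop spots colliding with the previous ring
            px = np.array([s.x for s in prev_ring])
            py = np.array([s.y for s in prev_ring])
            kept = [
                s
                for s in ring
                if np.hypot(px - s.x, py - s.y).min() >= config.spot_diameter - _TOL
            ]
            n_dropped += len(ring) - len(kept)
            ring = kept
        spots.extend(ring)
        prev_ring = ring
    if config.radial_pitch_mode == "count_match" and n_dropped:
        raise ValueError(
            f"count_match cannot reach target_count={config.target_count}: "
            f"{n_dropped} spot(s) collide between rings at this spacing"
        )
    return SpotLayout(spots=tuple(spots), config=config)


def _match_counts(
    radii: list[float], counts: list[int], pitch: float, config: LayoutConfig
) -> list[int]:
    target = config.target_count
    assert target is not None
    counts = list(counts)
    caps = [_max_ring_count(radius, config.spot_diameter) for radius in radii]
    if not radii and target > 0:
        raise ValueError(f"annulus fits no rings; cannot match target_count={target}")

    def slack(i: int) -> float:
        # remaining fractional capacity at the nominal pitch; rings with the
        # most unused circumference absorb extra spots first
        return 2.0 * math.pi * radii[i] / pitch - counts[i]

    deficit = target - sum(counts)
    while deficit > 0:
        candidates = [i for i in range(len(radii)) if counts[i] < caps[i]]
        if not candidates:
            raise ValueError(
                f"target_count={target} exceeds the annulus capacity "
                f"{sum(caps)} for diameter {config.spot_diameter}"
            )
        i = max(candidates, key=lambda i: (slack(i), -i))
        counts[i] += 1
        deficit -= 1
    while deficit < 0:
        candidates = [i for i in range(len(radii)) if counts[i] > 0]
        if not candidates:
            break
        i = min(candidates, key=lambda i: (slack(i), i))
        counts[i] -= 1
        deficit += 1
    return counts


def generate_single_ring(ring_radius: float, config: LayoutConfig) -> SpotLayout:
    """One ring of evenly spaced spots at ``ring_radius``.

    Used for the "one extra row inside the vascular arcade" scenario: a ring
    tangent to the inside of the PRP-free boundary.  The stored config gets
    a tight annulus around the ring so layout invariants stay meaningful.
    """
    if ring_radius <= config.spot_diameter / 2.0:
        raise ValueError("ring_radius must exceed the spot radius")
    n = _ring_capacity(ring_radius, config.circumferential_pitch)
    ring_config = replace(
        config,
        inner_radius=ring_radius - config.spot_diameter / 2.0,
        outer_radius=ring_radius + config.spot_diameter / 2.0,
    )
    spots = _ring_spots(ring_radius, n, 0.0, config.spot_diameter)
    return SpotLayout(spots=tuple(spots), config=ring_config)


def photocoagulation_index(layout: SpotLayout, disc: EquivalentDisc) -> float:
    """Percent of the whole retinal area covered by burns.

    ``100 * sum_i pi (d_i/2)^2 / (pi R_total^2)`` — for uniform spots this is
    ``100 n (d/2)^2 / R_total^2``.
    """
    return 100.0 * layout.total_spot_area / disc.area_total


# ---------------------------------------------------------------------------
# Tabular round trip: columns x_mm, y_mm, diameter_mm.

_LAYOUT_COLUMNS = ["x_mm", "y_mm", "diameter_mm"]


def load_layout(table: pd.DataFrame, config: Optional[LayoutConfig] = None) -> SpotLayout:
    """Build a validated layout from a table of spot centers and diameters.

    Without an explicit config, the annulus bounds are inferred as the
    tightest annulus containing all spots; overlapping spots are always
    rejected with the offending row indices.
    """
    if list(table.columns) != _LAYOUT_COLUMNS:
        raise ValueError(f"expected columns {_LAYOUT_COLUMNS}, got {list(table.columns)}")
    spots = tuple(
        Spot(float(r.x_mm), float(r.y_mm), float(r.diameter_mm))
        for r in table.itertuples(index=False)
    )
    if config is None:
        if spots:
            inner = min(s.center_eccentricity - s.radius for s in spots)
            outer = max(s.center_eccentricity + s.radius for s in spots)
        else:
            inner, outer = 0.0, 1.0
        config = LayoutConfig(
            inner_radius=max(inner, 0.0) - _TOL,
            outer_radius=outer + _TOL,
            spot_diameter=spots[0].diameter if spots else SPOT_DIAMETER_MM,
        )
    return SpotLayout(spots=spots, config=config)


def save_layout(layout: SpotLayout) -> pd.DataFrame:
    """Layout as a table with columns x_mm, y_mm, diameter_mm."""
    return pd.DataFrame(
        [(s.x, s.y, s.diameter) for s in layout.spots], columns=_LAYOUT_COLUMNS
    )


def read_layout_csv(path: str | Path, config: Optional[LayoutConfig] = None) -> SpotLayout:
    return load_layout(
        pd.read_csv(path, comment="#", float_precision="round_trip"), config=config
    )


def write_layout_csv(layout: SpotLayout, path: str | Path) -> None:
    save_layout(layout).to_csv(path, index=False, float_format="%.17g")
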