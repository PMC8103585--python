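"""Rotationally averaged photoreceptor density and the island-shaped solid.

The photoreceptor distribution is modelled as a rotationally symmetric
surface density ``rho(e)`` (cells/mm^2) over the flattened equal-area disc,
where ``e`` is eccentricity in mm from the foveal center.  Revolving the
eccentricity--density curve about the vertical axis produces the
"island-shaped" solid of revolution whose volume encodes the total
photoreceptor count: with the density axis scaled so that 1 mm of solid
height corresponds to 1e4 cells/mm^2, the solid volume in mm^3 times 1e4
is the photoreceptor count exactly.

The optic disc, which contains no photoreceptors, is represented by a
cylinder hollowed out of the solid at its eccentricity.

Counts over regions are area integrals of ``rho``:

* :func:`total_count` integrates ``2 pi e rho(e)`` over the whole disc —
  exact for the piecewise-linear profile (per-segment closed form).
* :func:`count_in_spot` integrates ``rho`` over one laser-spot disc by a
  midpoint rule on a Cartesian grid clipped to the disc (default step
  10 um), with :func:`count_in_spot_converged` providing a step-halving
  convergence check and :func:`mc_count_in_spot` an independent
  Monte-Carlo oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import EquivalentDisc
from .layout import Spot

__all__ = [
    "CELLS_PER_MM3",
    "DensityProfile",
    "OpticDiscSpec",
    "density_at",
    "total_count",
    "count_in_spot",
    "count_in_spot_converged",
    "mc_count_in_spot",
    "calibrate",
    "volume_from_count",
    "count_from_volume",
    "read_profile_csv",
    "write_profile_csv",
]

#: Photoreceptors per mm^3 of island-solid volume (1 mm height == 1e4 cells/mm^2).
CELLS_PER_MM3 = 1.0e4

#: Default quadrature step for spot integrals, mm (10 um).
DEFAULT_QUADRATURE_STEP_MM = 0.01

#: Optic-disc defaults: a 1.5 mm diameter disc centered 3.4 mm from the fovea.
OPTIC_DISC_RADIUS_MM = 0.75
OPTIC_DISC_ECCENTRICITY_MM = 3.4


@dataclass(frozen=True)
class OpticDiscSpec:
    """Photoreceptor-free cylinder hollowed out of the island solid.

    ``center_eccentricity`` is the distance of the disc center from the
    fovea on the flattened retina (mm); ``radius`` its radius (mm).
    """

    center_eccentricity: float = OPTIC_DISC_ECCENTRICITY_MM
    radius: float = OPTIC_DISC_RADIUS_MM

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"optic disc radius must be > 0, got {self.radius}")
        if self.center_eccentricity < 0:
            raise ValueError("optic disc eccentricity must be >= 0")

    @classmethod
    def from_config(cls, config: dict) -> "OpticDiscSpec | None":
        """Build from optic_disc_* config keys; None when disabled."""
        if not config.get("optic_disc_enabled", True):
            return None
        return cls(
            center_eccentricity=float(
                config.get("optic_disc_eccentricity_mm", OPTIC_DISC_ECCENTRICITY_MM)
            ),
            radius=float(config.get("optic_disc_radius_mm", OPTIC_DISC_RADIUS_MM)),
        )


@dataclass(frozen=True)
class DensityProfile:
    """Tabulated rotationally symmetric density vs planar eccentricity.

    ``eccentricity_grid`` is strictly increasing, starts at 0, in mm;
    ``density_values`` are cells/mm^2, non-negative, same length.  Between
    nodes the density is piecewise linear; beyond the last node it is 0
    (the island solid ends at the retinal edge).
    """

    eccentricity_grid: np.ndarray
    density_values: np.ndarray
    optic_disc: Optional[OpticDiscSpec] = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.eccentricity_grid, dtype=float)
        dens = np.asarray(self.density_values, dtype=float)
        if grid.ndim != 1 or dens.ndim != 1 or grid.size != dens.size:
            raise ValueError("grid and densities must be 1-D arrays of equal length")
        if grid.size < 2:
            raise ValueError("profile needs at least two grid nodes")
        if grid[0] != 0.0:
            raise ValueError("eccentricity grid must start at 0")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("eccentricity grid must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "eccentricity_grid", grid)
        object.__setattr__(self, "density_values", dens)

    @property
    def max_eccentricity(self) -> float:
        return float(self.eccentricity_grid[-1])

    def __call__(self, e):
        """Vectorised density lookup (cells/mm^2); 0 beyond the last node."""
        e = np.asarray(e, dtype=float)
        if np.any(e < 0):
            raise ValueError("eccentricity must be non-negative")
        return np.interp(e, self.eccentricity_grid, self.density_values, right=0.0)

    def scaled(self, factor: float) -> "DensityProfile":
        """Profile with every density multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, density_values=self.density_values * factor)


def density_at(profile: DensityProfile, e: float) -> float:
    """Piecewise-linear density at eccentricity ``e`` (mm), cells/mm^2."""
    return float(profile(e))


def _annular_integral(profile: DensityProfile) -> float:
    """Exact ``2 pi * int_0^inf rho(e) e de`` for the piecewise-linear profile."""
    e = profile.eccentricity_grid
    rho = profile.density_values
    e0, e1 = e[:-1], e[1:]
    r0, r1 = rho[:-1], rho[1:]
    b = (r1 - r0) / (e1 - e0)
    a = r0 - b * e0
    # int e (a + b e) de over each segment
    seg = a * (e1**2 - e0**2) / 2.0 + b * (e1**3 - e0**3) / 3.0
    return float(2.0 * math.pi * seg.sum())


def total_count(profile: DensityProfile, disc: Optional[EquivalentDisc] = None) -> float:
    """Total photoreceptor count of the island solid.

    Integrates the density over the whole flattened retina (exact composite
    quadrature for the piecewise-linear profile) and subtracts the
    optic-disc cylinder ``pi r^2 rho(e_disc)`` when the profile carries one.
    ``disc``, when given, only asserts that the profile does not extend
    beyond the retina.
    """
    if disc is not None and profile.max_eccentricity > disc.radius_total * (1 + 1e-9):
        raise ValueError(
            f"profile extends to {profile.max_eccentricity} mm, beyond the "
            f"retinal radius {disc.radius_total} mm"
        )
    count = _annular_integral(profile)
    od = profile.optic_disc
    if od is not None:
        count -= math.pi * od.radius**2 * density_at(profile, od.center_eccentricity)
    return count


def _spot_grid(spot: Spot, step: float):
    """Cell centers of a midpoint grid clipped to the spot disc."""
    radius = spot.diameter / 2.0
    k = int(math.ceil(radius / step))
    offsets = (np.arange(-k, k, dtype=float) + 0.5) * step
    dx, dy = np.meshgrid(offsets, offsets, indexing="ij")
    inside = dx * dx + dy * dy <= radius * radius
    return spot.x + dx[inside], spot.y + dy[inside]


def count_in_spot(
    profile: DensityProfile,
    spot: Spot,
    step: float = DEFAULT_QUADRATURE_STEP_MM,
    disc: Optional[EquivalentDisc] = None,
) -> float:
    """Photoreceptors inside one laser spot: ``iint_spot rho(|p|) dA``.

    Midpoint rule on a Cartesian grid of pitch ``step`` (mm) clipped to the
    spot disc.  The burn is a right-angle punch through the island solid, so
    the destroyed count is exactly this area integral of the surface density.
    With ``disc`` given, a spot not fully inside the retina is a domain error.
    """
    if step <= 0:
        raise ValueError("quadrature step must be > 0")
    if disc is not None:
        r_center = math.hypot(spot.x, spot.y)
        if r_center + spot.diameter / 2.0 > disc.radius_total * (1 + 1e-9):
            raise ValueError(
                f"spot at ({spot.x:.3f}, {spot.y:.3f}) with diameter "
                f"{spot.diameter} extends beyond the retina (radius {disc.radius_total})"
            )
    xs, ys = _spot_grid(spot, step)
    if xs.size == 0:
        return 0.0
    rho = profile(np.hypot(xs, ys))
    # exact spot area x lattice-mean density: cancels the O(step) error from
    # cells straddling the disc boundary, leaving only the smooth-field bias
    area = math.pi * (spot.diameter / 2.0) ** 2
    return float(area * rho.mean())


def count_in_spot_converged(
    profile: DensityProfile,
    spot: Spot,
    step: float = DEFAULT_QUADRATURE_STEP_MM,
    rel_tol: float = 1e-3,
) -> tuple[float, float]:
    """Spot integral with an automatic step-halving convergence check.

    Returns ``(value_at_step/2, relative_change)`` where ``relative_change``
    is ``|I(step/2) - I(step)| / max(I(step/2), tiny)``.  A change above
    ``rel_tol`` raises, flagging a profile too rough for the step.
    """
    coarse = count_in_spot(profile, spot, step)
    fine = count_in_spot(profile, spot, step / 2.0)
    rel = abs(fine - coarse) / max(abs(fine), 1e-300)
    if rel > rel_tol:
        raise RuntimeError(
            f"spot quadrature not converged: step {step} -> {step / 2} changed "
            f"the integral by {rel:.2e} (> {rel_tol:.0e})"
        )
    return fine, rel


def mc_count_in_spot(
    profile: DensityProfile,
    spot: Spot,
    n_samples: int,
    seed: int,
) -> tuple[float, float]:
    """Monte-Carlo oracle for :func:`count_in_spot`.

    Draws ``n_samples`` points uniformly on the spot disc by rejection
    sampling from the bounding square; the estimate is the spot area times
    the mean sampled density, returned with its standard error.
    Deterministic for a fixed seed.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    radius = spot.diameter / 2.0
    samples = np.empty(0)
    need = n_samples
    collected = []
    while need > 0:
        # accept ~pi/4 of the square; oversample to finish in few rounds
        m = int(need / 0.7) + 16
        pts = rng.uniform(-radius, radius, size=(m, 2))
        keep = pts[pts[:, 0] ** 2 + pts[:, 1] ** 2 <= radius * radius]
        collected.append(keep)
        need -= len(keep)
    pts = np.concatenate(collected)[:n_samples]
    rho = profile(np.hypot(spot.x + pts[:, 0], spot.y + pts[:, 1]))
    area = math.pi * radius * radius
    estimate = area * float(rho.mean())
    stderr = area * float(rho.std(ddof=1)) / math.sqrt(n_samples)
    return estimate, stderr


def calibrate(
    profile: DensityProfile,
    disc: EquivalentDisc,
    target_total: float,
) -> DensityProfile:
    """Scale the profile so its total count equals ``target_total``.

    Counts are linear in density, so a single multiplicative factor is
    exact; the calibrated total matches the target to float precision.
    """
    if target_total <= 0:
        raise ValueError("target total must be > 0")
    current = total_count(profile, disc)
    if current <= 0:
        raise ValueError("cannot calibrate a profile with zero total count")
    return profile.scaled(target_total / current)


def volume_from_count(count: float) -> float:
    """Island-solid volume (mm^3) equivalent to a photoreceptor count."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / CELLS_PER_MM3


def count_from_volume(volume_mm3: float) -> float:
    """Photoreceptor count encoded by an island-solid volume (mm^3)."""
    if volume_mm3 < 0:
        raise ValueError("volume must be non-negative")
    return volume_mm3 * CELLS_PER_MM3


# ---------------------------------------------------------------------------
# CSV round trip: two columns, '#' comments allowed, eccentricities ascending.

def read_profile_csv(
    path: str | Path,
    optic_disc: Optional[OpticDiscSpec] = None,
) -> DensityProfile:
    """Load a density profile from ``eccentricity_mm,density_cells_per_mm2`` CSV."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["eccentricity_mm", "density_cells_per_mm2"]
    if list(df.columns) != expected:
        raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
    return DensityProfile(
        eccentricity_grid=df["eccentricity_mm"].to_numpy(float),
        density_values=df["density_cells_per_mm2"].to_numpy(float),
        optic_disc=optic_disc,
    )


def write_profile_csv(profile: DensityProfile, path: str | Path) -> None:
    """Write the profile table; full float precision, stable round trip."""
    df = pd.DataFrame(
        {
            "eccentricity_mm": profile.eccentricity_grid,
            "density_cells_per_mm2": profile.density_values,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
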