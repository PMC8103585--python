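"""Parametric rod-density profiles and the packaged calibrated fixture.

Human rod density is roughly rotationally symmetric: near zero at the
foveal center (where cones dominate), rising to a ridge of peak density a
few mm out (~20 degrees eccentricity), then declining toward the ora
serrata.  The generator emulates that shape with three terms:

    rho(e) = A_cone * exp(-e^2 / (2 w_cone^2))                 (foveal peak)
           + A_rod  * exp(-(e - e_r)^2 / (2 w_rod^2))   e <= e_r (inner flank)
           + A_rod  * exp(-(e - e_r) / L)                e >  e_r (peripheral decay)

a Gaussian ridge at ``e_r`` whose outer flank is an exponential decay of
length ``L``.  The shape parameters are frozen so that, after calibrating
the total to the published 96,571,900 photoreceptors, the area-mean density
over the scatter annulus is about 1e5 cells/mm^2 — the level implied by
dividing the published destroyed counts by the burn areas — with the
published peripheral fall-off between equator and ora serrata.  The true
averaged curve was never published as a table; this parametric stand-in is
synthetic and claims only that qualitative shape.

:func:`packaged_fixture` returns the frozen, optic-disc-hollowed,
calibrated profile used everywhere a "standard eye" is needed; the same
table ships in ``data/fixture_profile.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .density import (
    CELLS_PER_MM3,
    DensityProfile,
    OpticDiscSpec,
    calibrate,
)
from .geometry import RADIUS_TOTAL_MM, EquivalentDisc

__all__ = [
    "SyntheticDensityParams",
    "TOTAL_PHOTORECEPTORS",
    "parametric_profile",
    "perturbed_profile",
    "packaged_fixture",
    "FIXTURE_PARAMS",
]

#: Published standard-eye total the fixture is calibrated to (= 9657.19 mm^3).
TOTAL_PHOTORECEPTORS = 96_571_900

#: Default grid step for generated profiles, mm.
DEFAULT_GRID_STEP_MM = 0.1


@dataclass(frozen=True)
class SyntheticDensityParams:
    """Shape parameters of the parametric rod-density generator.

    Amplitudes in cells/mm^2, lengths in mm.  ``noise_sd_fraction`` is the
    relative standard deviation of the per-node lognormal perturbation used
    by :func:`perturbed_profile` (0 = smooth deterministic curve).
    """

    cone_peak_amplitude: float = 150_000.0
    cone_peak_width: float = 0.3
    rod_ridge_amplitude: float = 160_000.0
    rod_ridge_eccentricity: float = 4.0
    rod_ridge_width: float = 2.0
    peripheral_decay_length: float = 9.0
    noise_sd_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cone_peak_amplitude",
            "cone_peak_width",
            "rod_ridge_amplitude",
            "rod_ridge_eccentricity",
            "rod_ridge_width",
            "peripheral_decay_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.noise_sd_fraction < 0.5:
            raise ValueError("noise_sd_fraction must lie in [0, 0.5)")


#: Frozen parameters behind the packaged fixture.
FIXTURE_PARAMS = SyntheticDensityParams()


def _evaluate(params: SyntheticDensityParams, e: np.ndarray) -> np.ndarray:
    rho = np.zeros_like(e)
    if params.cone_peak_amplitude > 0 and params.cone_peak_width > 0:
        rho += params.cone_peak_amplitude * np.exp(
            -(e**2) / (2.0 * params.cone_peak_width**2)
        )
    if params.rod_ridge_amplitude > 0:
        e_r = params.rod_ridge_eccentricity
        inner = e <= e_r
        ridge = np.empty_like(e)
        if params.rod_ridge_width > 0:
            ridge[inner] = np.exp(
                -((e[inner] - e_r) ** 2) / (2.0 * params.rod_ridge_width**2)
            )
        else:
            ridge[inner] = np.where(e[inner] == e_r, 1.0, 0.0)
        if params.peripheral_decay_length > 0:
            ridge[~inner] = np.exp(-(e[~inner] - e_r) / params.peripheral_decay_length)
        else:
            ridge[~inner] = 0.0
        rho += params.rod_ridge_amplitude * ridge
    return np.maximum(rho, 0.0)


def parametric_profile(
    params: SyntheticDensityParams,
    grid_step: float = DEFAULT_GRID_STEP_MM,
    max_eccentricity: float = RADIUS_TOTAL_MM,
    optic_disc: OpticDiscSpec | None = None,
) -> DensityProfile:
    """Evaluate the parametric curve on a regular eccentricity grid."""
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    if max_eccentricity <= 0:
        raise ValueError("max_eccentricity must be > 0")
    n = int(round(max_eccentricity / grid_step)) + 1
    grid = np.linspace(0.0, max_eccentricity, n)
    return DensityProfile(
        eccentricity_grid=grid,
        density_values=_evaluate(params, grid),
        optic_disc=optic_disc,
    )


def perturbed_profile(
    params: SyntheticDensityParams,
    seed: int | None = None,
    grid_step: float = DEFAULT_GRID_STEP_MM,
    max_eccentricity: float = RADIUS_TOTAL_MM,
    optic_disc: OpticDiscSpec | None = None,
) -> DensityProfile:
    """Smooth profile with per-node multiplicative lognormal noise.

    Emulates inter-eye variability: each grid value is multiplied by a
    unit-mean lognormal factor with relative standard deviation
    ``params.noise_sd_fraction``.  Reproducible for a fixed seed.
    """
    if params.noise_sd_fraction <= 0:
        raise ValueError("perturbed_profile requires noise_sd_fraction > 0")
    base = parametric_profile(params, grid_step, max_eccentricity, optic_disc)
    rng = np.random.default_rng(params.seed if seed is None else seed)
    f = params.noise_sd_fraction
    sigma = np.sqrt(np.log1p(f * f))
    factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=base.density_values.size)
    noisy = np.maximum(base.density_values * factors, 0.0)
    return replace(base, density_values=noisy)


def packaged_fixture(disc: EquivalentDisc | None = None) -> DensityProfile:
    """The frozen standard-eye profile, optic disc hollowed, calibrated.

    Total count equals :data:`TOTAL_PHOTORECEPTORS` (island-solid volume
    9657.19 mm^3) to float precision.  Identical to the versioned table in
    ``data/fixture_profile.csv``.
    """
    disc = disc or EquivalentDisc()
    raw = parametric_profile(
        FIXTURE_PARAMS,
        grid_step=DEFAULT_GRID_STEP_MM,
        max_eccentricity=disc.radius_total,
        optic_disc=OpticDiscSpec(),
    )
    return calibrate(raw, disc, TOTAL_PHOTORECEPTORS)


def fixture_csv_path():
    """Path to the shipped fixture table (a context-manager-free accessor)."""
    return resources.files("prpsim").joinpath("data/fixture_profile.csv")
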