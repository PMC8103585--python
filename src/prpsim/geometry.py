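"""Equal-area flattening of the retina via the spherical-dome surface formula.

The retina is treated as the curved surface of a spherical dome (a sphere cut
by a plane).  With dome radius ``r``, height ``h`` and base radius ``c``, the
curved surface area is

    S = 2 pi r h = pi (c^2 + h^2),

so the curved region has exactly the area of a flat disc of radius
``sqrt(c^2 + h^2)``.  All downstream geometry lives on that flat equal-area
disc: the whole retina maps to a disc of radius 18.6 mm, the retina up to the
equator to 15.6 mm, and the central never-photocoagulated region (vascular
arcades, macula, optic disc) to 5.14 mm.  Those three equivalent radii are
standard-eye constants; override them via :class:`EquivalentDisc` if needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DomeGeometry",
    "EquivalentDisc",
    "dome_surface_area",
    "equivalent_radius",
]

#: Equal-area radius of the whole retina (ora serrata), mm.
RADIUS_TOTAL_MM = 18.6
#: Equal-area radius of the retina up to the equator, mm.
RADIUS_EQUATOR_MM = 15.6
#: Equal-area radius of the central PRP-free region, mm.
RADIUS_FREE_MM = 5.14


def dome_surface_area(c: float, h: float) -> float:
    """Curved surface area ``S = pi (c^2 + h^2)`` of a spherical dome.

    Parameters
    ----------
    c : float
        Base radius of the dome in mm (``c >= 0``).
    h : float
        Height of the dome in mm (``h >= 0``).

    Returns
    -------
    float
        Curved surface area in mm^2 (the base disc is not included).
        For ``h == 0`` this degenerates to the area of the base circle.
    """
    if c < 0 or h < 0:
        raise ValueError(f"dome dimensions must be non-negative, got c={c}, h={h}")
    if c == 0 and h == 0:
        raise ValueError("degenerate dome: c and h cannot both be zero")
    return math.pi * (c * c + h * h)


def equivalent_radius(c: float, h: float) -> float:
    """Radius of the flat disc whose area equals the dome's curved surface.

    ``sqrt(c^2 + h^2)``; satisfies ``pi * equivalent_radius(c, h)**2 ==
    dome_surface_area(c, h)`` exactly.
    """
    if c < 0 or h < 0:
        raise ValueError(f"dome dimensions must be non-negative, got c={c}, h={h}")
    return math.hypot(c, h)


@dataclass(frozen=True)
class DomeGeometry:
    """Spherical-dome parameters (all mm / mm^2).

    ``r`` sphere radius, ``h`` dome height, ``c`` base radius, ``B`` base
    area, ``S`` curved surface area.  Checks ``S = 2 pi r h = pi (c^2 + h^2)``
    and ``B = pi c^2`` on construction.
    """

    r: float
    h: float
    c: float
    B: float
    S: float

    _RTOL = 1e-9

    def __post_init__(self) -> None:
        if self.r < 0 or self.h < 0 or self.c < 0:
            raise ValueError("dome dimensions must be non-negative")
        expected_B = math.pi * self.c**2
        if not math.isclose(self.B, expected_B, rel_tol=self._RTOL, abs_tol=1e-12):
            raise ValueError(f"B={self.B} inconsistent with pi*c^2={expected_B}")
        s_from_ch = math.pi * (self.c**2 + self.h**2)
        s_from_rh = 2.0 * math.pi * self.r * self.h
        if not math.isclose(self.S, s_from_ch, rel_tol=self._RTOL, abs_tol=1e-12):
            raise ValueError(f"S={self.S} inconsistent with pi*(c^2+h^2)={s_from_ch}")
        if self.h > 0 and not math.isclose(
            self.S, s_from_rh, rel_tol=self._RTOL, abs_tol=1e-12
        ):
            raise ValueError(f"S={self.S} inconsistent with 2*pi*r*h={s_from_rh}")

    @classmethod
    def from_ch(cls, c: float, h: float) -> "DomeGeometry":
        """Build a consistent dome from base radius and height alone."""
        S = dome_surface_area(c, h)
        # S = 2 pi r h  =>  r = (c^2 + h^2) / (2 h); undefined for a flat disc
        r = (c * c + h * h) / (2.0 * h) if h > 0 else math.inf
        return cls(r=r, h=h, c=c, B=math.pi * c * c, S=S)

    @property
    def equivalent_radius(self) -> float:
        return math.hypot(self.c, self.h)


@dataclass(frozen=True)
class EquivalentDisc:
    """The three concentric equal-area radii of the flattened standard eye.

    ``radius_total`` is the whole retina, ``radius_equator`` the customary
    outer limit of scatter PRP, and ``radius_free`` the central region that
    is never photocoagulated.  Units mm.
    """

    radius_total: float = RADIUS_TOTAL_MM
    radius_equator: float = RADIUS_EQUATOR_MM
    radius_free: float = RADIUS_FREE_MM

    def __post_init__(self) -> None:
        if not (0.0 < self.radius_free < self.radius_equator < self.radius_total):
            raise ValueError(
                "require 0 < radius_free < radius_equator < radius_total, got "
                f"{self.radius_free}, {self.radius_equator}, {self.radius_total}"
            )

    @property
    def area_total(self) -> float:
        """Area of the whole flattened retina, mm^2."""
        return math.pi * self.radius_total**2

    @classmethod
    def from_config(cls, config: dict) -> "EquivalentDisc":
        """Build from config keys radius_total_mm / radius_equator_mm / radius_free_mm."""
        return cls(
            radius_total=float(config.get("radius_total_mm", RADIUS_TOTAL_MM)),
            radius_equator=float(config.get("radius_equator_mm", RADIUS_EQUATOR_MM)),
            radius_free=float(config.get("radius_free_mm", RADIUS_FREE_MM)),
        )
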