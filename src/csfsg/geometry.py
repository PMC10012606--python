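"""Microvillar geometry of the choroid plexus luminal surface.

The luminal membrane is idealized as a flat sheet carrying a homogeneous lawn
of cylindrical microvilli (radius ``r_mv``, length ``l_mv``) at surface
density ``sigma``.  The repeating inter-microvillar space between four
neighbours — the functional unit (FU) — is reduced to a straight cylindrical
channel of equivalent hydraulic diameter ``d`` (4 x cross-section / wetted
perimeter of the true FU cross-section).  The number of FUs tiling the
apparent (unfolded, microvilli-free) luminal area ``A_app`` is
``N = sigma * A_app``.

Units follow the measurement literature: lengths in µm, densities in 1/µm²,
apparent area in cm².  CGS accessors (``*_cm``) are provided for the
transport model, which works in cm/s/g/Osm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import GeometryInfeasibleError, InvalidParameterError

#: µm per cm
UM_PER_CM = 1.0e4
#: µm² per cm²
UM2_PER_CM2 = 1.0e8


def microvillar_spacing(sigma: float) -> float:
    """Center-to-center microvillar spacing p = 1/sqrt(sigma), in µm.

    Parameters
    ----------
    sigma : float
        Microvilli surface density in 1/µm²; must be strictly positive.
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma!r}")
    return 1.0 / math.sqrt(sigma)


def fu_count(sigma: float, A_app: float) -> float:
    """Number of functional units N = sigma * A_app (dimensionless, real).

    ``sigma`` is in 1/µm², ``A_app`` in cm²; the area is converted to µm²
    internally.  N is a density product, not a census, and is deliberately
    not rounded to an integer — it only ever scales per-FU fluxes.
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma!r}")
    if A_app < 0:
        raise InvalidParameterError(f"A_app must be >= 0, got {A_app!r}")
    return sigma * A_app * UM2_PER_CM2


def hydraulic_diameter(p: float, r_mv: float) -> float:
    """Equivalent hydraulic diameter of the inter-microvillar channel, in µm.

    d = (p² − π r_mv²) / (p + (π/2 − 2) r_mv)

    i.e. 4 A_CS / P_CS for the square unit cell of side ``p`` minus the four
    quarter-cylinders of radius ``r_mv`` at its corners.

    Raises
    ------
    GeometryInfeasibleError
        If ``p² <= π r_mv²`` (microvilli fill or exceed the unit cell).
    """
    if r_mv < 0:
        raise InvalidParameterError(f"r_mv must be >= 0, got {r_mv!r}")
    if not p > 0:
        raise InvalidParameterError(f"p must be > 0, got {p!r}")
    area = p * p - math.pi * r_mv * r_mv
    if area <= 0:
        raise GeometryInfeasibleError(
            f"microvilli overlap: p²={p * p:.4g} <= π r_mv²={math.pi * r_mv**2:.4g}"
        )
    return area / (p + (math.pi / 2.0 - 2.0) * r_mv)


@dataclass(frozen=True)
class MicrovilliGeometry:
    """Anatomic inputs and derived functional-unit geometry.

    Attributes
    ----------
    r_mv, l_mv : float
        Microvillus radius and length, µm.
    sigma : float
        Microvilli surface density, 1/µm².
    A_app : float
        Apparent luminal area of the whole choroid plexus, cm².
    p : float
        Derived microvillar spacing 1/sqrt(sigma), µm.
    d : float
        Derived hydraulic diameter of the FU channel, µm.
    A_CS : float
        Derived 1D-channel cross-section π d²/4, µm².
    N : float
        Derived number of FUs, sigma * A_app (real-valued).
    """

    r_mv: float
    l_mv: float
    sigma: float
    A_app: float
    p: float = field(init=False)
    d: float = field(init=False)
    A_CS: float = field(init=False)
    N: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("r_mv", "l_mv", "sigma", "A_app"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
        p = microvillar_spacing(self.sigma)
        d = hydraulic_diameter(p, self.r_mv)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "A_CS", math.pi * d * d / 4.0)
        object.__setattr__(self, "N", fu_count(self.sigma, self.A_app))

    # --- CGS accessors used by the transport model ---

    @property
    def d_cm(self) -> float:
        """Hydraulic diameter in cm."""
        return self.d / UM_PER_CM

    @property
    def l_mv_cm(self) -> float:
        """Microvillus (channel) length in cm."""
        return self.l_mv / UM_PER_CM

    @property
    def A_CS_cm2(self) -> float:
        """Channel cross-section in cm²."""
        return self.A_CS / UM2_PER_CM2
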