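"""Parallel-plate flow-chamber arithmetic.

The perfusion chamber is a shallow rectangular slit (default 50 µm high,
3.0 mm wide, 30 mm long).  For fully developed laminar Poiseuille flow
between parallel plates the wall-shear rate is

    gamma = 6 Q / (w h^2)

with volumetric flow ``Q``, chamber width ``w`` and height ``h``.  Blood is
recalcified in situ by co-perfusing it with a CaCl2/MgCl2 medium at a fixed
volume ratio (default 10 parts blood : 1 part medium), which dilutes the
medium solutes accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class InvalidGeometryError(ValueError):
    """A chamber dimension or flow rate is non-positive or inconsistent."""


@dataclass(frozen=True)
class FlowGeometry:
    """Parallel-plate chamber geometry and operating flow.

    Parameters
    ----------
    height_um : float
        Slit height in micrometres (default 50).
    width_mm : float
        Chamber width in millimetres (default 3.0).
    length_mm : float
        Chamber length in millimetres (default 30).
    volumetric_flow_ul_min : float
        Perfusion rate in µL/min.  75 µL/min yields 1000 s^-1 in the
        default chamber.
    """

    height_um: float = 50.0
    width_mm: float = 3.0
    length_mm: float = 30.0
    volumetric_flow_ul_min: float = 75.0

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_mm <= 0 or self.length_mm <= 0:
            raise InvalidGeometryError(
                f"chamber dimensions must be positive, got "
                f"h={self.height_um} µm, w={self.width_mm} mm, l={self.length_mm} mm"
            )
        if self.volumetric_flow_ul_min < 0:
            raise InvalidGeometryError(
                f"volumetric flow must be non-negative, got {self.volumetric_flow_ul_min}"
            )
        # parallel-plate assumption: the slit must be much wider than high
        if self.height_um >= self.width_mm * 1000.0:
            raise InvalidGeometryError("parallel-plate assumption requires height < width")


def wall_shear_rate(geometry: FlowGeometry) -> float:
    """Wall-shear rate gamma = 6Q/(w h^2) in s^-1.

    Unit bookkeeping: Q [µL/min] -> m^3/s via 1e-9/60, w [mm] -> m via 1e-3,
    h [µm] -> m via 1e-6.
    """
    q = geometry.volumetric_flow_ul_min * 1e-9 / 60.0  # m^3/s
    w = geometry.width_mm * 1e-3  # m
    h = geometry.height_um * 1e-6  # m
    return 6.0 * q / (w * h * h)


def flow_rate_for_shear(target_shear_s1: float, geometry: FlowGeometry) -> float:
    """Volumetric flow (µL/min) producing ``target_shear_s1`` in this chamber."""
    if target_shear_s1 < 0:
        raise InvalidGeometryError("target shear rate must be non-negative")
    w = geometry.width_mm * 1e-3
    h = geometry.height_um * 1e-6
    q = target_shear_s1 * w * h * h / 6.0  # m^3/s
    return q * 60.0 / 1e-9


@dataclass(frozen=True)
class MixingSpec:
    """Blood/recalcification-medium mixing ratio and medium composition.

    Defaults: 10 parts blood to 1 part medium; the medium carries 63 mM
    CaCl2 and 32 mM MgCl2, so the final (post-mixing) concentrations are
    63/11 and 32/11 mM.
    """

    blood_parts: int = 10
    medium_parts: int = 1
    medium_solutes_mm: dict[str, float] = field(
        default_factory=lambda: {"CaCl2": 63.0, "MgCl2": 32.0}
    )

    def __post_init__(self) -> None:
        if self.blood_parts < 0 or self.medium_parts <= 0:
            raise ValueError(
                "mixing parts must be positive (blood_parts may be 0 for pure medium)"
            )
        for species, conc in self.medium_solutes_mm.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {species}: {conc}")


def final_concentration(mix: MixingSpec, species: str) -> float:
    """Concentration (mM) of a medium solute after mixing with blood.

    stock * medium_parts / (blood_parts + medium_parts); raises ``KeyError``
    for a species the medium does not contain.
    """
    stock = mix.medium_solutes_mm[species]
    return stock * mix.medium_parts / (mix.blood_parts + mix.medium_parts)
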