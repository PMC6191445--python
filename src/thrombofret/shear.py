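"""Parallel-plate flow-chamber hydrodynamics.

Converts volumetric flow rate and chamber geometry to wall shear rate and
shear stress, and back.  For an ideal parallel-plate chamber of width ``w``
and gap height ``h`` perfused at volumetric rate ``Q`` the wall shear rate is

    gamma_dot = 6 Q / (w h^2)

and for a Newtonian fluid of dynamic viscosity ``eta`` the wall shear stress
is ``tau = eta * gamma_dot``.  Units follow the conventions of the flow-chamber
literature: geometry in mm, flow in mL/min, shear rate in 1/s, viscosity in
dyn*s/cm^2 (0.01 dyn*s/cm^2 = 1 cP, aqueous buffer at room temperature) and
shear stress in dyn/cm^2.  Commercial slides apply small slide-specific
correction factors to the ideal formula; an optional multiplicative
``correction`` is exposed for that purpose (default 1.0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "ChamberSpec",
    "ShearResult",
    "shear_rate_from_flow",
    "shear_stress",
    "flow_for_target_shear",
    "convert",
]

#: dynamic viscosity of aqueous buffer at room temperature, dyn*s/cm^2 (= 1 cP)
WATER_VISCOSITY = 0.01


@dataclass(frozen=True)
class ChamberSpec:
    """Geometry and fluid of a parallel-plate flow chamber.

    Parameters
    ----------
    width_mm : float
        Channel width (mm), transverse to flow.
    height_mm : float
        Channel gap height (mm).  The parallel-plate approximation assumes
        ``width >= 10 * height``; a narrower chamber triggers a warning, not
        an error.
    viscosity : float
        Dynamic viscosity in dyn*s/cm^2.  Default 0.01 (1 cP).
    correction : float
        Multiplicative slide-specific correction to the ideal formula.
    """

    width_mm: float
    height_mm: float
    viscosity: float = WATER_VISCOSITY
    correction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("width_mm", "height_mm", "viscosity", "correction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ChamberSpec.{name} must be > 0")
        if self.width_mm < 10 * self.height_mm:
            warnings.warn(
                "width < 10 x height: parallel-plate approximation is inaccurate "
                "for this aspect ratio",
                stacklevel=2,
            )

    @property
    def parallel_plate_valid(self) -> bool:
        return self.width_mm >= 10 * self.height_mm


@dataclass(frozen=True)
class ShearResult:
    """Shear state of a chamber at a given flow rate (Newtonian fluid)."""

    shear_rate: float  # 1/s
    shear_stress: float  # dyn/cm^2
    flow_rate: float  # mL/min


def shear_rate_from_flow(q_ml_min: float, chamber: ChamberSpec) -> float:
    """Wall shear rate (1/s) for flow rate ``q_ml_min`` (mL/min)."""
    if q_ml_min < 0:
        raise ValueError("flow rate must be >= 0")
    q_cm3_s = q_ml_min / 60.0
    w_cm = chamber.width_mm / 10.0
    h_cm = chamber.height_mm / 10.0
    return chamber.correction * 6.0 * q_cm3_s / (w_cm * h_cm**2)


def shear_stress(shear_rate: float, viscosity: float = WATER_VISCOSITY) -> float:
    """Wall shear stress tau = eta * gamma_dot (dyn/cm^2)."""
    if shear_rate < 0 or viscosity < 0:
        raise ValueError("shear rate and viscosity must be >= 0")
    return viscosity * shear_rate


def flow_for_target_shear(target_rate: float, chamber: ChamberSpec) -> float:
    """Flow rate (mL/min) producing wall shear rate ``target_rate`` (1/s)."""
    if target_rate < 0:
        raise ValueError("target shear rate must be >= 0")
    w_cm = chamber.width_mm / 10.0
    h_cm = chamber.height_mm / 10.0
    q_cm3_s = target_rate * w_cm * h_cm**2 / (6.0 * chamber.correction)
    return q_cm3_s * 60.0


def convert(q_ml_min: float, chamber: ChamberSpec) -> ShearResult:
    """Full conversion of a flow rate to shear rate and stress."""
    rate = shear_rate_from_flow(q_ml_min, chamber)
    return ShearResult(
        shear_rate=rate,
        shear_stress=shear_stress(rate, chamber.viscosity),
        flow_rate=q_ml_min,
    )
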