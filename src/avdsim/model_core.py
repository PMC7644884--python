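"""Constants, parameter sets, and quasi-steady-state closed forms.

The model describes a cell of volume ``V`` (cm^3) bathed in a medium of
osmolarity ``C0`` (mol/cm^3) whose actomyosin cortex exerts an excess
hydrostatic (intracellular) pressure ``S``.  Expressed in equivalent
concentration units (pressure divided by RT), ``S`` competes with the
osmotic gradient ``dC = Ci - C0`` to drive water across a membrane of
water permeability ``Pw`` (cm/s), while the same pressure and gradient
push a generic membrane-permeant osmolyte out through channels of
cumulative permeability ``Pi`` (cm/s).

When osmolyte efflux balances the concentration-raising effect of water
efflux, ``dC`` settles at a quasi-steady value and the cell shrinks at a
constant rate.  This module evaluates those closed forms:

* ``qss_delta_c``            -- the quasi-steady osmotic gradient,
* ``qss_volume_rate``        -- dV/dt at quasi-steady state (cm^3/s),
* ``qss_relative_rate``      -- (1/V0) dV/dt in h^-1 for a spherical cell,
* ``qss_relative_rate_high_pw`` -- the high-water-permeability limit in
  which ion permeability is the only limiting factor.

All internal computation uses cm / mol / s units; shrinkage rates are
signed (negative = volume decrease).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from scipy.constants import R as _R_SI  # J mol^-1 K^-1 == Pa m^3 ... / 1000 -> Pa L

__all__ = [
    "GAS_CONSTANT_PA_L",
    "RT_ROUNDED_PA_L",
    "SECONDS_PER_HOUR",
    "PhysicalConstants",
    "ModelParameters",
    "QssResult",
    "RegimeWarning",
    "pressure_to_equivalent_concentration",
    "equivalent_concentration_to_pressure",
    "sphere_geometry",
    "qss_delta_c",
    "qss_volume_rate",
    "qss_relative_rate",
    "qss_relative_rate_high_pw",
    "qss",
]

#: Gas constant in Pa·L·mol⁻¹·K⁻¹ (1 J = 10³ Pa·L).
GAS_CONSTANT_PA_L: float = _R_SI * 1.0e3

#: Rounded RT at 300 K used in the worked examples, Pa·L·mol⁻¹.
RT_ROUNDED_PA_L: float = 2.5e6

SECONDS_PER_HOUR: float = 3600.0

#: Fraction S/C0 above which the C0 >> S assumption behind the
#: quasi-steady closed forms starts to look shaky.
REGIME_S_OVER_C0_MAX: float = 0.05


class RegimeWarning(UserWarning):
    """The parameter set leaves the regime the closed forms assume."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic constants used to convert pressure to concentration.

    Parameters
    ----------
    temperature : float
        Absolute temperature in K.
    gas_constant : float
        Gas constant in Pa·L·mol⁻¹·K⁻¹.
    water_molar_volume : float
        Molar volume of water ρ in cm³/mol (18 cm³/mol).
    rt_mode : {"paper_rounded", "exact"}
        ``paper_rounded`` uses RT = 2.5·10⁶ Pa·L/mol (the rounded value at
        300 K, so worked-example numbers reproduce digit for digit);
        ``exact`` uses ``gas_constant * temperature`` (≈0.23 % smaller at
        300 K).
    """

    temperature: float = 300.0
    gas_constant: float = GAS_CONSTANT_PA_L
    water_molar_volume: float = 18.0
    rt_mode: str = "paper_rounded"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.gas_constant <= 0:
            raise ValueError(f"gas_constant must be positive, got {self.gas_constant}")
        if self.water_molar_volume <= 0:
            raise ValueError(
                f"water_molar_volume must be positive, got {self.water_molar_volume}"
            )
        if self.rt_mode not in ("paper_rounded", "exact"):
            raise ValueError(
                f"rt_mode must be 'paper_rounded' or 'exact', got {self.rt_mode!r}"
            )

    @property
    def rt(self) -> float:
        """RT in Pa·L·mol⁻¹ under the selected mode."""
        if self.rt_mode == "paper_rounded":
            return RT_ROUNDED_PA_L
        return self.gas_constant * self.temperature


def pressure_to_equivalent_concentration(
    pressure_pa: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Convert a hydrostatic pressure (Pa) to equivalent concentration (mol/cm³).

    Dividing pressure by RT yields mol/L; a further factor 10³ converts to
    mol/cm³, putting hydrostatic and osmotic driving forces in shared
    units.  1000 Pa at RT = 2.5·10⁶ Pa·L/mol gives 4·10⁻⁷ mol/cm³.
    """
    if pressure_pa < 0:
        raise ValueError(
            f"pressure must be non-negative (the cortex compresses, it does not "
            f"suck); got {pressure_pa} Pa"
        )
    return pressure_pa / constants.rt / 1.0e3


def equivalent_concentration_to_pressure(
    concentration: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Inverse of :func:`pressure_to_equivalent_concentration` (mol/cm³ → Pa)."""
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration}")
    return concentration * constants.rt * 1.0e3


def sphere_geometry(radius_cm: float) -> tuple[float, float]:
    """Volume (cm³) and surface area (cm²) of a sphere; A/V = 3/r."""
    if radius_cm <= 0:
        raise ValueError(f"radius must be positive, got {radius_cm} cm")
    volume = 4.0 / 3.0 * math.pi * radius_cm**3
    area = 4.0 * math.pi * radius_cm**2
    return volume, area


@dataclass(frozen=True)
class ModelParameters:
    """One cell's parameter set.

    Defaults reproduce the worked example: an MDCK-sized cell of radius
    5 µm in a 100 mOsm/L medium with literature permeabilities and a
    cortical pressure of 1000 Pa.

    Parameters
    ----------
    radius : float
        Cell radius r in cm.
    external_osmolarity : float
        Medium osmolarity C0 in mol/cm³ (10⁻⁴ mol/cm³ = 100 mOsm/L).
    pressure : float
        Excess intracellular (cytoskeletal) pressure S in Pa; ≥ 0.
    ion_permeability : float
        Cumulative membrane permeability for the osmolyte, Pi, in cm/s.
    water_permeability : float
        Membrane permeability for water, Pw, in cm/s.
    area_mode : {"constant", "sphere_coupled"}
        ``constant`` keeps A fixed at its initial value during dynamics
        (the closed forms assume this); ``sphere_coupled`` re-derives
        A = (36π)^⅓ V^⅔ from the instantaneous volume.
    constants : PhysicalConstants
        Unit-conversion constants (temperature, RT mode, ρ).
    initial_volume, initial_area : float, optional
        Override the sphere-derived V0 and A0.
    """

    radius: float = 5.0e-4
    external_osmolarity: float = 1.0e-4
    pressure: float = 1000.0
    ion_permeability: float = 1.0e-5
    water_permeability: float = 2.0e-3
    area_mode: str = "constant"
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    initial_volume: float | None = None
    initial_area: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius} cm")
        for name in ("external_osmolarity", "ion_permeability", "water_permeability"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.pressure < 0:
            raise ValueError(f"pressure must be non-negative, got {self.pressure} Pa")
        if self.area_mode not in ("constant", "sphere_coupled"):
            raise ValueError(
                f"area_mode must be 'constant' or 'sphere_coupled', got {self.area_mode!r}"
            )
        volume, area = sphere_geometry(self.radius)
        if self.initial_volume is None:
            object.__setattr__(self, "initial_volume", volume)
        elif self.initial_volume <= 0:
            raise ValueError(f"initial_volume must be positive, got {self.initial_volume}")
        if self.initial_area is None:
            object.__setattr__(self, "initial_area", area)
        elif self.initial_area <= 0:
            raise ValueError(f"initial_area must be positive, got {self.initial_area}")
        if not self.regime_ok:
            warnings.warn(
                f"S/C0 = {self.pressure_equivalent / self.external_osmolarity:.3g} "
                f"> {REGIME_S_OVER_C0_MAX}: the quasi-steady closed forms assume "
                "C0 >> S and become first-order approximations only.",
                RegimeWarning,
                stacklevel=2,
            )

    @property
    def pressure_equivalent(self) -> float:
        """Pressure S in equivalent concentration units (mol/cm³)."""
        return pressure_to_equivalent_concentration(self.pressure, self.constants)

    @property
    def regime_ok(self) -> bool:
        """True when S/C0 ≤ 0.05, the regime the closed forms assume."""
        if self.external_osmolarity == 0:
            return self.pressure == 0
        return (
            self.pressure_equivalent / self.external_osmolarity <= REGIME_S_OVER_C0_MAX
        )

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (validation re-runs)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class QssResult:
    """Quasi-steady-state summary for one parameter set.

    ``volume_rate`` and the relative rates are signed: negative values
    mean shrinkage.  ``relative_rate`` is a fraction of V0 per hour.
    """

    delta_c: float
    volume_rate: float
    relative_rate: float
    high_pw_relative_rate: float
    regime_notes: str


def _qss_denominator(params: ModelParameters) -> float:
    rho = params.constants.water_molar_volume
    den = (
        params.external_osmolarity * rho * params.water_permeability
        + params.ion_permeability
    )
    if den <= 0:
        raise ValueError(
            "quasi-steady state undefined: C0*rho*Pw + Pi must be positive "
            "(both permeability pathways are closed)"
        )
    return den


def qss_delta_c(params: ModelParameters) -> float:
    """Quasi-steady osmotic gradient dC = S (C0 ρ Pw − Pi) / (C0 ρ Pw + Pi).

    For an impermeant membrane (Pi = 0) this collapses to dC = S: the
    gradient grows until it exactly opposes the pressure and water efflux
    stops.  When Pi > C0 ρ Pw the returned value is *negative* — solute
    leaves faster than water concentrates it, and the quasi-steady
    intracellular osmolarity sits slightly below the medium.  The value is
    reported as-is; the sign flip is physical within the model, not an
    error.
    """
    rho = params.constants.water_molar_volume
    den = _qss_denominator(params)
    num = params.external_osmolarity * rho * params.water_permeability - params.ion_permeability
    return params.pressure_equivalent * num / den


def qss_volume_rate(params: ModelParameters) -> float:
    """Quasi-steady dV/dt in cm³/s, signed (negative = shrinkage).

    Magnitude 2 ρ A Pi Pw S / (C0 ρ Pw + Pi); exactly linear in S.
    """
    rho = params.constants.water_molar_volume
    den = _qss_denominator(params)
    magnitude = (
        2.0
        * rho
        * params.initial_area
        * params.ion_permeability
        * params.water_permeability
        * params.pressure_equivalent
        / den
    )
    return -magnitude


def qss_relative_rate(params: ModelParameters) -> float:
    """Quasi-steady (1/V0) dV/dt in h⁻¹, signed.

    For a sphere A0/V0 = 3/r, giving magnitude
    6 ρ Pi Pw S / (r (C0 ρ Pw + Pi)) — 0.457 h⁻¹ (>40 %/h) at the default
    parameter set.
    """
    return qss_volume_rate(params) / params.initial_volume * SECONDS_PER_HOUR


def qss_relative_rate_high_pw(params: ModelParameters) -> float:
    """High-Pw limit of the relative rate: −6 Pi S / (r C0) per hour.

    When C0 ρ Pw ≫ Pi water follows instantly and ion permeability is the
    only limiting factor; the limit is independent of Pw and ρ.
    """
    if params.external_osmolarity <= 0:
        raise ValueError("external_osmolarity must be positive for the high-Pw limit")
    magnitude = (
        6.0
        * params.ion_permeability
        * params.pressure_equivalent
        / (params.radius * params.external_osmolarity)
    )
    return -magnitude * SECONDS_PER_HOUR


def qss(params: ModelParameters) -> QssResult:
    """Evaluate all quasi-steady-state quantities for one parameter set."""
    delta_c = qss_delta_c(params)
    notes = []
    if not params.regime_ok:
        notes.append(
            f"S/C0 = {params.pressure_equivalent / params.external_osmolarity:.3g} "
            "violates C0 >> S; closed forms are first-order only."
        )
    rho = params.constants.water_molar_volume
    if params.ion_permeability > params.external_osmolarity * rho * params.water_permeability:
        notes.append(
            "Pi > C0*rho*Pw: quasi-steady dC is negative (intracellular "
            "osmolarity slightly below the medium)."
        )
    return QssResult(
        delta_c=delta_c,
        volume_rate=qss_volume_rate(params),
        relative_rate=qss_relative_rate(params),
        high_pw_relative_rate=qss_relative_rate_high_pw(params),
        regime_notes=" ".join(notes) or "within the C0 >> S regime",
    )
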