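"""Translocation kinetics and interfacial electrostatics.

Converts a measured SH intensity decay time into ion-transport quantities:

* the number of Ca2+ ions initially bound to the outer leaflet, from the
  headgroup charge density sigma and the GUV area 4*pi*R^2;
* the average translocation time per ion, tau_eff / N;
* the permeability coefficient P = (N / tau_eff) / (4*pi*R^2 * c * N_A),
  i.e. flux per unit area per unit concentration, reported in cm/s;
* the single-pore permeability p = flux / (c * N_A), flux per concentration
  through one open pore, in cm^3/s.

Two valence conventions are supported and recorded with every result: Ca2+
carries 2e (``divalent_2e``, the default) or one bound ion neutralizes one
monovalent headgroup site (``monovalent_site_e``).  The companion
electrostatics helpers solve the Grahame relation for the surface potential
and coupled 1:1 binding equilibria for indicator-dye competition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy import constants as const
from scipy.optimize import brentq

from shgflux.errors import InvalidParameterError, NumericalError

#: Default relative permittivity of water at the default temperature.
DEFAULT_EPS_R = 78.4
DEFAULT_TEMPERATURE_K = 298.15


class ValenceConvention(str, Enum):
    divalent_2e = "divalent_2e"
    monovalent_site_e = "monovalent_site_e"

    @property
    def charge_per_ion(self) -> float:
        return 2.0 * const.e if self is ValenceConvention.divalent_2e else const.e


@dataclass(frozen=True)
class KineticsInputs:
    """Physical inputs of the translocation-rate calculation (SI units)."""

    sigma: float = 1e-3  # headgroup charge density magnitude, C/m^2
    radius_m: float = 10e-6  # GUV radius, m
    c_bulk_molar: float = 5e-3  # Ca2+ bulk concentration, mol/L
    tau_eff_s: float = math.nan  # effective intensity decay time, s
    valence_convention: ValenceConvention = ValenceConvention.divalent_2e

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.radius_m <= 0:
            raise InvalidParameterError("radius must be positive")
        if self.c_bulk_molar <= 0:
            raise InvalidParameterError("concentration must be positive")

    @property
    def area_m2(self) -> float:
        return 4.0 * math.pi * self.radius_m**2


@dataclass(frozen=True)
class TranslocationResult:
    n_ions: float
    t_ion_s: float  # per-ion translocation time
    permeability_cm_per_s: float
    single_pore_permeability_cm3_per_s: float | None
    provenance: dict


@dataclass(frozen=True)
class ElectrostaticState:
    psi0_V: float
    ionic_composition: tuple  # ((valence, mol/L), ...)
    temperature_K: float


@dataclass(frozen=True)
class BindingSystem:
    """1:1 Ca2+ binding competition between species (e.g. membrane vs dye).

    ``species`` is a list of (name, K_D mol/L, total site concentration
    mol/L); ``ca_total`` the total Ca2+ concentration in mol/L.
    """

    species: tuple
    ca_total: float

    def __post_init__(self) -> None:
        for name, kd, total in self.species:
            if kd <= 0:
                raise InvalidParameterError(f"K_D of {name} must be positive")
            if total < 0:
                raise InvalidParameterError(f"site total of {name} must be >= 0")
        if self.ca_total < 0:
            raise InvalidParameterError("ca_total must be >= 0")


# ---------------------------------------------------------------------------
# translocation arithmetic
# ---------------------------------------------------------------------------

def bound_ion_count(inputs: KineticsInputs) -> float:
    """Ca2+ ions bound to the outer leaflet: N = sigma * 4*pi*R^2 / q."""
    return inputs.sigma * inputs.area_m2 / inputs.valence_convention.charge_per_ion


def per_ion_translocation_time(inputs: KineticsInputs, n_ions: float) -> float:
    """Average translocation time per ion, tau_eff / N."""
    if n_ions <= 0:
        raise InvalidParameterError("n_ions must be positive")
    if not (inputs.tau_eff_s > 0):
        raise InvalidParameterError("tau_eff must be positive")
    return inputs.tau_eff_s / n_ions


def permeability_coefficient(inputs: KineticsInputs, n_ions: float) -> float:
    """Permeability coefficient P = (N/tau) / (A * c * N_A), in cm/s."""
    if n_ions < 0:
        raise InvalidParameterError("n_ions must be >= 0")
    if math.isinf(inputs.tau_eff_s):
        return 0.0
    if not (inputs.tau_eff_s > 0):
        raise InvalidParameterError("tau_eff must be positive")
    flux = n_ions / inputs.tau_eff_s  # ions / s
    area_cm2 = inputs.area_m2 * 1e4
    conc_per_cm3 = inputs.c_bulk_molar * const.N_A / 1000.0
    return flux / (area_cm2 * conc_per_cm3)


def single_pore_permeability(flux_per_s: float, c_molar: float) -> float:
    """Single-pore permeability p = flux / (c * N_A), in cm^3/s."""
    if flux_per_s < 0:
        raise InvalidParameterError("flux must be >= 0")
    if c_molar <= 0:
        raise InvalidParameterError("concentration must be positive")
    conc_per_cm3 = c_molar * const.N_A / 1000.0
    return flux_per_s / conc_per_cm3


def translocation_summary(
    inputs: KineticsInputs,
    amplitude_time: bool = False,
) -> TranslocationResult:
    """Full per-GUV kinetics record from one effective decay time.

    ``amplitude_time=True`` converts the intensity decay time to the
    oriented-water amplitude time (2 * tau_intensity), since SH intensity is
    the square of the amplitude; the default reports intensity-time kinetics.
    """
    eff = inputs
    if amplitude_time and math.isfinite(inputs.tau_eff_s):
        eff = KineticsInputs(
            sigma=inputs.sigma,
            radius_m=inputs.radius_m,
            c_bulk_molar=inputs.c_bulk_molar,
            tau_eff_s=2.0 * inputs.tau_eff_s,
            valence_convention=inputs.valence_convention,
        )
    n = bound_ion_count(eff)
    if math.isinf(eff.tau_eff_s):
        t_ion = math.inf
        perm = 0.0
    else:
        t_ion = per_ion_translocation_time(eff, n)
        perm = permeability_coefficient(eff, n)
    return TranslocationResult(
        n_ions=n,
        t_ion_s=t_ion,
        permeability_cm_per_s=perm,
        single_pore_permeability_cm3_per_s=None,
        provenance={
            "sigma_C_per_m2": eff.sigma,
            "radius_m": eff.radius_m,
            "c_bulk_molar": eff.c_bulk_molar,
            "tau_eff_s": eff.tau_eff_s,
            "valence_convention": eff.valence_convention.value,
            "amplitude_time": amplitude_time,
            "activity_coefficients": "none (concentrations used as activities)",
        },
    )


# ---------------------------------------------------------------------------
# electrostatics
# ---------------------------------------------------------------------------

def _check_electroneutral(composition) -> None:
    net = sum(z * c for z, c in composition)
    scale = sum(abs(z) * c for z, c in composition) or 1.0
    if abs(net) > 1e-9 * scale:
        raise InvalidParameterError("ionic composition must be electroneutral")


def _grahame_sigma(psi: float, composition, temperature: float,
                   eps_r: float) -> float:
    """Signed surface charge density for a given surface potential."""
    rt = const.R * temperature
    s = 0.0
    for z, c_molar in composition:
        c = c_molar * 1000.0  # mol/m^3
        s += c * (math.exp(-z * const.physical_constants["Faraday constant"][0]
                           * psi / rt) - 1.0)
    s = max(s, 0.0)
    mag = math.sqrt(2.0 * eps_r * const.epsilon_0 * rt * s)
    return math.copysign(mag, psi) if psi != 0.0 else 0.0


def debye_length(composition, temperature: float = DEFAULT_TEMPERATURE_K,
                 eps_r: float = DEFAULT_EPS_R) -> float:
    """Debye screening length (m) of the electrolyte."""
    ionic = sum(c * 1000.0 * z**2 for z, c in composition)  # mol/m^3 weighted
    kappa_sq = (const.e**2 * const.N_A * ionic) / (
        eps_r * const.epsilon_0 * const.k * temperature
    )
    return 1.0 / math.sqrt(kappa_sq)


def grahame_potential(
    sigma_signed: float,
    composition,
    temperature: float = DEFAULT_TEMPERATURE_K,
    eps_r: float = DEFAULT_EPS_R,
    psi_tol: float = 1e-9,
) -> ElectrostaticState:
    """Solve the Grahame relation for the surface potential psi0.

    sigma = sign(psi) * sqrt(2 eps eps0 R T * sum_i c_i (exp(-z_i F psi / RT)
    - 1)); the left side is strictly increasing in psi, so a bracketing root
    find (Brent) converges to ``psi_tol`` volts.
    """
    composition = tuple((float(z), float(c)) for z, c in composition)
    _check_electroneutral(composition)
    if sigma_signed == 0.0:
        return ElectrostaticState(psi0_V=0.0, ionic_composition=composition,
                                  temperature_K=temperature)

    def f(psi):
        return _grahame_sigma(psi, composition, temperature, eps_r) - sigma_signed

    lo, hi = -0.5, 0.5
    for _ in range(16):
        if f(lo) < 0.0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
        if hi > 50.0:
            raise NumericalError("Grahame root not bracketed (ill-posed composition)")
    psi = brentq(f, lo, hi, xtol=psi_tol)
    return ElectrostaticState(psi0_V=float(psi), ionic_composition=composition,
                              temperature_K=temperature)


def dye_competition(system: BindingSystem) -> dict:
    """Equilibrium partition of Ca2+ over competing 1:1 binding species.

    Solves the coupled mass-action/mass-balance system for free Ca2+ by
    monotone bracketing root-finding and returns the fraction of total Ca2+
    bound to each species plus the free fraction (key ``"free"``); fractions
    sum to 1.
    """
    if system.ca_total == 0.0:
        out = {name: 0.0 for name, _, _ in system.species}
        out["free"] = 0.0
        return out

    def total_at(x):
        return x + sum(tot * x / (kd + x) for _, kd, tot in system.species)

    x = brentq(lambda x: total_at(x) - system.ca_total, 0.0, system.ca_total,
               xtol=1e-30, rtol=1e-14)
    out = {}
    for name, kd, tot in system.species:
        out[name] = (tot * x / (kd + x)) / system.ca_total
    out["free"] = x / system.ca_total
    return out
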