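"""Biological source-sink terms of the four-compartment NPZD nitrogen model.

The model tracks dissolved inorganic nitrogen (N, nitrate), phytoplankton (P),
zooplankton (Z) and detritus (D), all in mmol N m^-3.  Every function here is a
pure, local closure: growth is limited by nitrate (Michaelis-Menten) and light
(saturating exponential with self-shading attenuation), zooplankton graze on
phytoplankton and detritus with a shared-saturation preference response,
zooplankton mortality is quadratic (an implicit higher-predator closure), and
detritus remineralizes and sinks at a concentration-dependent speed.

Nitrogen accounting is exact by construction: all transfers are computed as
explicit inter-compartment fluxes, so the tendencies sum to the single
permanent loss term -(1-beta)*m_Z*Z^2 (the fraction of the quadratic mortality
exported to unresolved predators) to rounding error.

All rates are per day; concentrations mmol N m^-3; irradiance W m^-2.
Functions broadcast over numpy arrays, so the same code serves the 0-D box
model and full 3-D fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable

import numpy as np

__all__ = [
    "BioParams",
    "BioState",
    "Tendencies",
    "BioFluxes",
    "nutrient_limitation",
    "light_limitation",
    "light_profile",
    "grazing",
    "sinking_velocity",
    "bio_fluxes",
    "source_terms",
]


@dataclass(frozen=True)
class BioParams:
    """The biological constants of the NPZD closures (defaults are the
    calibrated winter Alboran values).

    Units: rates in day^-1, concentrations mmol N m^-3, light in W m^-2.
    """

    r_P: float = 1.3       #: max phytoplankton growth rate (day^-1)
    m_P: float = 0.06      #: phytoplankton linear mortality (day^-1)
    m_Z: float = 0.10      #: quadratic zooplankton mortality (day^-1 (mmol N m^-3)^-1)
    mu_Z: float = 0.05     #: zooplankton excretion (day^-1)
    gamma: float = 0.7     #: grazing assimilation efficiency (-)
    beta: float = 0.5      #: recycled fraction of quadratic mortality (-)
    eps: float = 0.25      #: detritus remineralization rate (day^-1)
    K_N: float = 0.5       #: nitrate uptake half-saturation (mmol N m^-3)
    alpha_I: float = 0.03  #: initial slope of the light curve ((W m^-2)^-1)
    k_w: float = 0.05      #: background light extinction (m^-1)
    k_b: float = 0.04      #: biogenic extinction (mmol N^-1 m^2)
    I_s: float = 40.0      #: surface photosynthetically available radiation (W m^-2)
    r_Z: float = 0.5       #: max zooplankton grazing rate (day^-1)
    K_Z: float = 0.5       #: grazing half-saturation (mmol N m^-3)
    a1: float = 1.0        #: food preference for phytoplankton (-)
    a2: float = 0.5        #: food preference for detritus (-)
    S_D: float = 0.2       #: sinking half-saturation (mmol N m^-3)
    w_Dmax: float = 8.0    #: maximum detritus sinking speed (m day^-1)

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"BioParams.{f.name} must be finite and >= 0, got {v}")
        for name in ("gamma", "beta", "a1", "a2"):
            v = getattr(self, name)
            if v > 1.0:
                raise ValueError(f"BioParams.{name} must be in [0, 1], got {v}")


@dataclass
class BioState:
    """Concentrations of the four compartments (scalar or per grid cell)."""

    N: np.ndarray | float
    P: np.ndarray | float
    Z: np.ndarray | float
    D: np.ndarray | float


@dataclass
class Tendencies:
    """Local rates of change (mmol N m^-3 day^-1); their sum is the closure
    loss -(1-beta)*m_Z*Z^2 (sinking is a transport, not a local, process)."""

    dN: np.ndarray | float
    dP: np.ndarray | float
    dZ: np.ndarray | float
    dD: np.ndarray | float


@dataclass
class BioFluxes:
    """The individual inter-compartment transfers (mmol N m^-3 day^-1).

    uptake: N->P; graze_P: out of P; graze_D: out of D; of the total grazing,
    gamma goes to Z and (1-gamma) to D; mort_P: P->D; excretion: Z->N;
    mort_Z: out of Z, beta of it to D and (1-beta) permanently lost;
    remin: D->N.
    """

    uptake: np.ndarray | float
    graze_P: np.ndarray | float
    graze_D: np.ndarray | float
    mort_P: np.ndarray | float
    excretion: np.ndarray | float
    mort_Z: np.ndarray | float
    remin: np.ndarray | float

    @property
    def closure_loss(self):
        """Permanent nitrogen loss rate (1-beta fraction applied by caller)."""
        return self.mort_Z


def _check_nonneg(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    return x


def nutrient_limitation(N, p: BioParams):
    """Michaelis-Menten nitrate limitation f(N) = N/(K_N + N) in [0, 1)."""
    N = _check_nonneg(N, "N")
    return N / (p.K_N + N)


def light_limitation(I, p: BioParams):
    """Saturating-exponential light limitation f(I) = 1 - exp(-alpha_I * I)."""
    I = _check_nonneg(I, "I")
    return -np.expm1(-p.alpha_I * I)


def light_profile(P_column, layer_thickness, p: BioParams):
    """Irradiance at layer midpoints under self-shading attenuation.

    I(z) = I_s * exp(-int_0^z (k_w + k_b * P) dz'), with the integral
    accumulated layer by layer (midpoint rule: full overlying layers plus half
    the current one).  The first array axis is depth, surface first; extra
    trailing axes broadcast (columns of a 3-D field).

    Parameters
    ----------
    P_column : array (nz, ...)
        Phytoplankton, surface layer first.
    layer_thickness : array (nz,)
        Layer thicknesses in metres, all positive.
    """
    P_column = np.asarray(P_column, dtype=float)
    dz = np.asarray(layer_thickness, dtype=float)
    if np.any(dz <= 0):
        raise ValueError("layer thicknesses must be positive")
    kappa = p.k_w + p.k_b * np.maximum(P_column, 0.0)
    dz_b = dz.reshape((-1,) + (1,) * (P_column.ndim - 1))
    tau_layer = kappa * dz_b
    # optical depth down to each layer midpoint
    tau = np.cumsum(tau_layer, axis=0) - 0.5 * tau_layer
    return p.I_s * np.exp(-tau)


def grazing(P, D, Z, p: BioParams):
    """Zooplankton grazing on phytoplankton and detritus (shared saturation).

    G_P = r_Z * Z * a1*P / (K_Z + a1*P + a2*D), and analogously for G_D, so
    the total specific grazing (G_P+G_D)/Z saturates at r_Z and the two food
    sources compete for the same saturating response.

    Returns (G_P, G_D) in mmol N m^-3 day^-1.
    """
    P = _check_nonneg(P, "P")
    D = _check_nonneg(D, "D")
    Z = _check_nonneg(Z, "Z")
    food = p.K_Z + p.a1 * P + p.a2 * D
    G_P = p.r_Z * Z * p.a1 * P / food
    G_D = p.r_Z * Z * p.a2 * D / food
    return G_P, G_D


def sinking_velocity(D, p: BioParams):
    """Concentration-dependent detritus sinking speed w_D = w_Dmax*D/(S_D+D)
    (m day^-1): faster sinking of denser aggregates, saturating at w_Dmax."""
    D = _check_nonneg(D, "D")
    return p.w_Dmax * D / (p.S_D + D)


def bio_fluxes(
    s: BioState,
    I,
    p: BioParams,
    light_fn: Callable = light_limitation,
    grazing_fn: Callable = grazing,
) -> BioFluxes:
    """All inter-compartment transfer rates at the given state and irradiance.

    ``light_fn`` and ``grazing_fn`` are injectable so alternative closure
    shapes can replace the defaults without touching any caller.
    """
    G_P, G_D = grazing_fn(s.P, s.D, s.Z, p)
    uptake = p.r_P * nutrient_limitation(s.N, p) * light_fn(I, p) * np.asarray(s.P, float)
    Z = np.asarray(s.Z, dtype=float)
    return BioFluxes(
        uptake=uptake,
        graze_P=G_P,
        graze_D=G_D,
        mort_P=p.m_P * np.asarray(s.P, float),
        excretion=p.mu_Z * Z,
        mort_Z=p.m_Z * Z * Z,
        remin=p.eps * np.asarray(s.D, float),
    )


def source_terms(
    s: BioState,
    I,
    p: BioParams,
    light_fn: Callable = light_limitation,
    grazing_fn: Callable = grazing,
) -> Tendencies:
    """The biological tendencies B_X of the four compartments.

    dP = uptake - G_P - m_P*P
    dZ = gamma*(G_P+G_D) - mu_Z*Z - m_Z*Z^2
    dN = -uptake + mu_Z*Z + eps*D
    dD = m_P*P + (1-gamma)*(G_P+G_D) + beta*m_Z*Z^2 - G_D - eps*D

    Summing: dN+dP+dZ+dD = -(1-beta)*m_Z*Z^2, the permanent closure loss.
    """
    f = bio_fluxes(s, I, p, light_fn=light_fn, grazing_fn=grazing_fn)
    graze_tot = f.graze_P + f.graze_D
    dP = f.uptake - f.graze_P - f.mort_P
    dZ = p.gamma * graze_tot - f.excretion - f.mort_Z
    dN = -f.uptake + f.excretion + f.remin
    dD = f.mort_P + (1.0 - p.gamma) * graze_tot + p.beta * f.mort_Z - f.graze_D - f.remin
    return Tendencies(dN=dN, dP=dP, dZ=dZ, dD=dD)
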