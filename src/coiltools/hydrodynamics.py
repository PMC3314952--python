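"""Sedimentation-velocity hydrodynamics: the Svedberg -> Stokes -> Rh chain.

An observed sedimentation coefficient is first standardised to water at 20 C
(s20,w). The Svedberg equation then yields the translational friction
coefficient

    f = M (1 - vbar * rho_20,w) / (N_A * s20,w)

which is compared with the friction of the smooth sphere of equal anhydrous
volume, f0 = 6 pi eta_20,w R0 with R0 = (3 M vbar / (4 pi N_A))^(1/3). The
frictional ratio f/f0 measures departure from a compact sphere (1 for a
sphere, larger for expanded or asymmetric particles), and the hydrodynamic
radius follows as Rh = (f/f0) * R0.

All internal arithmetic is in cgs units: M in g/mol, s in seconds
(1 Svedberg = 1e-13 s), density in g/mL, viscosity in poise, lengths in cm
(reported in Angstrom). Empirical correlations for the density and viscosity
of water versus temperature are packaged; buffer density and viscosity are
user inputs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

from .errors import FlotationError

AVOGADRO = 6.02214076e23
SVEDBERG_S = 1e-13  # seconds per Svedberg unit

#: Density (g/mL) and viscosity (mPa s) of pure water at 20 C.
RHO_20W = 0.998207
ETA_20W_MPAS = 1.002

CM_PER_ANGSTROM = 1e-8


def water_density(temperature_k: float) -> float:
    """Density of air-free water (g/mL) from the Kell (1975) correlation.

    Valid 0-100 C; 0.998207 g/mL at 20 C.
    """
    t = temperature_k - 273.15
    if not 0.0 <= t <= 100.0:
        raise ValueError("water density correlation valid for 0-100 C")
    numerator = (999.83952 + 16.945176 * t - 7.9870401e-3 * t ** 2
                 - 46.170461e-6 * t ** 3 + 105.56302e-9 * t ** 4
                 - 280.54253e-12 * t ** 5)
    return numerator / (1.0 + 16.879850e-3 * t) / 1000.0


def water_viscosity(temperature_k: float) -> float:
    """Viscosity of water (mPa s) from standard empirical correlations.

    Below 20 C the Hardy-Cottington form is used; above, the relative
    correlation anchored at eta(20 C) = 1.002 mPa s.
    """
    t = temperature_k - 273.15
    if not 0.0 <= t <= 100.0:
        raise ValueError("water viscosity correlation valid for 0-100 C")
    if t < 20.0:
        exponent = 1301.0 / (998.333 + 8.1855 * (t - 20.0)
                             + 0.00585 * (t - 20.0) ** 2) - 3.30233
        return 10.0 ** exponent * 100.0  # poise -> mPa s
    exponent = (1.3272 * (20.0 - t) - 0.001053 * (t - 20.0) ** 2) / (t + 105.0)
    return ETA_20W_MPAS * 10.0 ** exponent


def _buoyancy(vbar: float, rho: float) -> float:
    b = 1.0 - vbar * rho
    if b <= 0:
        raise FlotationError(
            f"buoyancy term 1 - vbar*rho = {b:.4g} <= 0: particle floats")
    return b


def standardize_s20w(s_obs: float, temperature_k: float, buffer_density: float,
                     buffer_viscosity_mpas: float, vbar: float) -> float:
    """Correct an observed sedimentation coefficient to water at 20 C.

    s20,w = s_obs * (eta_T,buffer / eta_20,w) * (1 - vbar rho)_20,w
            / (1 - vbar rho)_T,buffer

    Parameters are in Svedberg units, K, g/mL, mPa s and mL/g respectively.
    """
    if s_obs <= 0:
        raise ValueError("sedimentation coefficient must be positive")
    if not 0.5 < vbar < 0.9:
        raise ValueError("partial specific volume outside the physical range")
    factor = ((buffer_viscosity_mpas / ETA_20W_MPAS)
              * _buoyancy(vbar, RHO_20W) / _buoyancy(vbar, buffer_density))
    return s_obs * factor


def svedberg_friction(s20w: float, molar_mass: float, vbar: float) -> float:
    """Translational friction coefficient f (g/s) from the Svedberg equation.

    f = M (1 - vbar rho_20,w) / (N_A * s20,w), with s20,w in Svedberg units.
    """
    if s20w <= 0:
        raise ValueError("sedimentation coefficient must be positive")
    buoyancy = _buoyancy(vbar, RHO_20W)
    return molar_mass * buoyancy / (AVOGADRO * s20w * SVEDBERG_S)


def stokes_sphere(molar_mass: float, vbar: float, hydration: float = 0.0
                  ) -> tuple[float, float]:
    """Radius (Angstrom) and friction (g/s) of the equal-volume rigid sphere.

    R0 = (3 M vbar / (4 pi N_A))^(1/3); f0 = 6 pi eta_20,w R0. The anhydrous
    volume from M*vbar is used by default so that the chain
    f -> f/f0 -> Rh closes exactly on Rh = (f/f0) R0; an optional hydration
    parameter (g water per g protein) adds the bound-water volume for users
    who want a hydrated reference sphere.
    """
    if molar_mass <= 0 or vbar <= 0:
        raise ValueError("molar mass and vbar must be positive")
    specific_volume = vbar + hydration / RHO_20W  # mL/g
    volume_cm3 = molar_mass * specific_volume / AVOGADRO
    r0_cm = (3.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    eta_poise = ETA_20W_MPAS * 1e-2  # mPa s -> poise (g cm^-1 s^-1)
    f0 = 6.0 * math.pi * eta_poise * r0_cm
    return r0_cm / CM_PER_ANGSTROM, f0


def hydrodynamic_radius(f: float, f0: float, r0: float) -> tuple[float, float]:
    """Frictional ratio and hydrodynamic radius Rh = (f/f0) * R0 (Angstrom)."""
    if f <= 0 or f0 <= 0:
        raise ValueError("friction coefficients must be positive")
    f_ratio = f / f0
    if f_ratio < 1.0:
        warnings.warn(
            f"frictional ratio {f_ratio:.3f} < 1 is unphysical for a rigid "
            "particle; check M, vbar or s20,w", stacklevel=2)
    return f_ratio, f_ratio * r0


WILKINS_COEFFICIENTS = {"folded": (4.75, 0.29), "denatured": (2.21, 0.57)}


def wilkins_rh(n_residues: int, state: str) -> float:
    """Empirical hydrodynamic radius (Angstrom) of an N-residue chain.

    Power laws from sedimentation/diffusion surveys of folded proteins and
    chemically denatured chains: folded Rh = 4.75 N^0.29, denatured
    Rh = 2.21 N^0.57.
    """
    if n_residues < 1:
        raise ValueError("chain length must be >= 1")
    try:
        coefficient, exponent = WILKINS_COEFFICIENTS[state]
    except KeyError:
        raise ValueError(
            f"state must be one of {sorted(WILKINS_COEFFICIENTS)}, got "
            f"{state!r}") from None
    return coefficient * n_residues ** exponent


def compaction_metrics(rh_a: float, rh_b: float) -> tuple[float, float]:
    """Compaction of radius a relative to radius b.

    Returns (ratio a/b, percent more compact = 100*(1 - a/b)). Ratios above 1
    (expansion) are allowed and yield a negative percentage.
    """
    if rh_b <= 0:
        raise ValueError("reference radius must be positive")
    ratio = rh_a / rh_b
    return ratio, 100.0 * (1.0 - ratio)


@dataclass
class SedimentationRecord:
    """One sedimentation-velocity measurement and its derived chain.

    Raw fields are user inputs (buffer density/viscosity and vbar come from
    the user's buffer tables); calling :meth:`analyze` fills the derived
    fields s20w, f, f0, f_ratio, r0 and rh.
    """

    s_obs: float
    temperature_k: float
    buffer_density: float
    buffer_viscosity_mpas: float
    vbar: float
    molar_mass: float
    label: str = ""
    hydration: float = 0.0
    s20w: float | None = None
    f: float | None = None
    f0: float | None = None
    f_ratio: float | None = None
    r0: float | None = None
    rh: float | None = None

    def analyze(self) -> "SedimentationRecord":
        self.s20w = standardize_s20w(self.s_obs, self.temperature_k,
                                     self.buffer_density,
                                     self.buffer_viscosity_mpas, self.vbar)
        self.f = svedberg_friction(self.s20w, self.molar_mass, self.vbar)
        self.r0, self.f0 = stokes_sphere(self.molar_mass, self.vbar,
                                         self.hydration)
        self.f_ratio, self.rh = hydrodynamic_radius(self.f, self.f0, self.r0)
        return self

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as handle:
                handle.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SedimentationRecord":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(**payload)
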