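"""Three-bond HN-HA scalar couplings from HNHA intensity ratios.

In a quantitative HNHA experiment the cross-peak to diagonal-peak intensity
ratio encodes the coupling through

    I_cross / I_diag = -tan^2(2 pi J delta)

where ``delta`` is the evolution delay in the pulse sequence (half the mixing
time). Inverting gives J = atan(sqrt(-ratio)) / (2 pi delta), which is only
defined for non-positive ratios and bounded above by the tangent singularity
at J = 1/(4 delta). 3J(HNHA) reports on the backbone phi angle: values at or
below 6 Hz indicate helical conformations, at or above 8 Hz extended ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import CouplingError

#: Default evolution delay (s); the mixing time 2*delta is 25.08 ms.
DEFAULT_DELTA = 0.01254

#: Conformational-class boundaries (Hz).
HELICAL_MAX_HZ = 6.0
EXTENDED_MIN_HZ = 8.0


@dataclass(frozen=True)
class JCouplingRecord:
    """One residue's HNHA-derived coupling and its classification."""

    residue: int
    i_cross: float
    i_diag: float
    delta: float
    j: float
    sigma_j: float
    conformation: str


def j_max(delta: float = DEFAULT_DELTA) -> float:
    """Upper bound of the observable J window, 1/(4 delta) Hz."""
    return 1.0 / (4.0 * delta)


def hnha_ratio(j: float, delta: float = DEFAULT_DELTA) -> float:
    """Forward model: the intensity ratio -tan^2(2 pi J delta) for a coupling.

    Valid for 0 <= J < 1/(4 delta); raises at or beyond the singularity.
    """
    if j < 0:
        raise CouplingError("coupling must be non-negative")
    if j >= j_max(delta):
        raise CouplingError(
            f"J = {j} Hz at or above the tangent singularity 1/(4 delta) = "
            f"{j_max(delta):.3f} Hz")
    return -math.tan(2.0 * math.pi * j * delta) ** 2


def classify_j(j: float, helical_max: float = HELICAL_MAX_HZ,
               extended_min: float = EXTENDED_MIN_HZ) -> str:
    """'helical' if J <= 6 Hz, 'extended' if J >= 8 Hz, else 'intermediate'."""
    if j < 0:
        raise CouplingError("coupling must be non-negative")
    if j <= helical_max:
        return "helical"
    if j >= extended_min:
        return "extended"
    return "intermediate"


def j_from_hnha(i_cross: float, i_diag: float, delta: float = DEFAULT_DELTA,
                noise: float = 0.0, residue: int = 0) -> JCouplingRecord:
    """Invert the HNHA ratio to a coupling with propagated uncertainty.

    J = atan(sqrt(-I_cross/I_diag)) / (2 pi delta). A positive ratio cannot
    arise from the coupling evolution (it signals a phase or assignment
    artefact) and is an explicit error rather than being clipped. The
    uncertainty is first-order propagation of independent intensity noise on
    both peaks through the inverse formula; at ratio 0 the derivative
    diverges, so sigma_j is reported as infinity when noise is non-zero.
    """
    if i_diag == 0:
        raise CouplingError("diagonal intensity must be non-zero")
    ratio = i_cross / i_diag
    if ratio > 0:
        raise CouplingError(
            f"positive intensity ratio {ratio:.4g}: cross and diagonal peaks "
            "must have opposite sign (phase or assignment artefact)")
    u = math.sqrt(-ratio)
    j = math.atan(u) / (2.0 * math.pi * delta)

    if noise == 0:
        sigma_j = 0.0
    else:
        sigma_ratio = math.hypot(noise / i_diag, ratio * noise / i_diag)
        if u == 0:
            sigma_j = math.inf
        else:
            # dJ/dr = -1 / (4 pi delta u (1 + u^2))
            djdr = 1.0 / (4.0 * math.pi * delta * u * (1.0 + u * u))
            sigma_j = abs(djdr) * sigma_ratio
    return JCouplingRecord(
        residue=residue, i_cross=i_cross, i_diag=i_diag, delta=delta,
        j=j, sigma_j=sigma_j, conformation=classify_j(j))
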