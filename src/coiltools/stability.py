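"""Equilibrium stability and spectroscopic probes of folding.

* CD helicity: percent helix of a variant from its 222 nm mean residue
  ellipticity relative to the wild-type value, scaled by 50 because half of
  the wild-type residues are helical in the crystal structure.
* Two-state urea denaturation: the titration signal is a population-weighted
  average of linear folded and unfolded baselines,

      Signal = ((a[urea]+b) K + (c[urea]+d)) / (1 + K),
      K = exp((dG_UF - m [urea]) / RT)

  with dG_UF the unfolding free energy (positive for a stable fold; the
  folding free energy quoted for stability comparisons is -dG_UF), m the
  denaturant dependence and a,b / c,d the folded / unfolded baselines. A
  flat titration — no cooperative transition — is detected by an F-test
  against a straight line before any parameters are reported.
* Fluorescence lambda-max via parabolic interpolation, for blue-shift
  detection between conditions.
* The gamma statistic of the luminescence protection assay:
  gamma = (L_sample - L_control) / L_control on density-corrected
  luminescence, higher values meaning more colicin activity (less
  protection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, NoTransitionError
from .io import read_tsv, write_tsv

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Percent of wild-type residues in helical conformation (the CD scaling factor).
WT_HELIX_PERCENT = 50.0


def helical_content(mre_variant_222: float, mre_wt_222: float) -> float:
    """Percent helix from 222 nm mean residue ellipticities.

    (MRE_variant / MRE_wt) x 50; both MREs are negative at 222 nm for helical
    proteins, so the ratio is positive for a partly helical variant.
    """
    if mre_wt_222 == 0:
        raise ValueError("wild-type reference MRE must be non-zero")
    return (mre_variant_222 / mre_wt_222) * WT_HELIX_PERCENT


def two_state_signal(urea, dg: float, m: float, a: float, b: float,
                     c: float, d: float, temperature_k: float = 283.15):
    """Two-state titration model evaluated at urea concentration(s)."""
    urea = np.asarray(urea, dtype=float)
    k = np.exp((dg - m * urea) / (R_KJ * temperature_k))
    return ((a * urea + b) * k + (c * urea + d)) / (1.0 + k)


@dataclass
class DenaturationCurve:
    """Titration signal versus denaturant concentration."""

    urea: np.ndarray
    signal: np.ndarray
    probe: str = ""
    temperature_k: float = 283.15

    def __post_init__(self) -> None:
        self.urea = np.asarray(self.urea, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if len(self.urea) < 8:
            raise InsufficientDataError("titration needs >= 8 points")
        if len(np.unique(self.urea)) != len(self.urea):
            raise ValueError("urea concentrations must be unique")
        if np.any(self.urea < 0) or np.any(self.urea > 10):
            raise ValueError("urea concentrations must lie within [0, 10] M")
        order = np.argsort(self.urea)
        self.urea = self.urea[order]
        self.signal = self.signal[order]

    def normalized_to_endpoint(self) -> "DenaturationCurve":
        """Signal divided by the value at the highest urea concentration."""
        endpoint = self.signal[-1]
        if endpoint == 0:
            raise ValueError("cannot normalise: endpoint signal is zero")
        return DenaturationCurve(self.urea, self.signal / endpoint,
                                 self.probe, self.temperature_k)

    def to_tsv(self, path) -> None:
        import pandas as pd

        write_tsv(path, pd.DataFrame({"urea_M": self.urea,
                                      "signal": self.signal}),
                  {"probe": self.probe, "temperature_K": self.temperature_k})

    @classmethod
    def from_tsv(cls, path) -> "DenaturationCurve":
        frame, metadata = read_tsv(path)
        return cls(frame["urea_M"].to_numpy(), frame["signal"].to_numpy(),
                   probe=metadata.get("probe", ""),
                   temperature_k=float(metadata.get("temperature_K", 283.15)))


@dataclass
class TwoStateFit:
    """Fitted two-state parameters; unfolding convention (dG > 0 = stable)."""

    dg: float
    m_value: float
    a: float
    b: float
    c: float
    d: float
    temperature_k: float
    errors: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def dg_fold(self) -> float:
        """Folding free energy (negative of the unfolding dG)."""
        return -self.dg

    @property
    def midpoint(self) -> float:
        """Denaturation midpoint dG/m (M urea)."""
        return self.dg / self.m_value


def fit_two_state(curve: DenaturationCurve, temperature_k: float | None = None,
                  normalize: bool = False, gate_alpha: float = 0.01,
                  m_guess: float = 5.0) -> TwoStateFit:
    """Nonlinear least-squares fit of the two-state titration model.

    Initial guesses: baselines from linear fits to the first and last three
    points, m from ``m_guess`` (kJ/mol/M) and dG from the midpoint crossing of
    the half-signal level. Before parameters are reported, an F-test compares
    the six-parameter model against a straight line at ``gate_alpha``; a
    titration indistinguishable from a line raises :class:`NoTransitionError`,
    mirroring the absence of a detectable cooperative unfolding event.
    """
    if normalize:
        curve = curve.normalized_to_endpoint()
    temperature_k = temperature_k or curve.temperature_k
    u, y = curve.urea, curve.signal

    a0, b0 = np.polyfit(u[:3], y[:3], 1)
    c0, d0 = np.polyfit(u[-3:], y[-3:], 1)
    half = 0.5 * (y[:3].mean() + y[-3:].mean())
    crossing = u[np.argmin(np.abs(y - half))]
    dg0 = max(m_guess * crossing, 1.0)

    def model(urea, dg, m, a, b, c, d):
        return two_state_signal(urea, dg, m, a, b, c, d, temperature_k)

    try:
        popt, pcov = curve_fit(model, u, y,
                               p0=(dg0, m_guess, a0, b0, c0, d0), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"two-state fit failed to converge: {exc}") from exc

    rss_model = float(np.sum((y - model(u, *popt)) ** 2))
    slope, intercept = np.polyfit(u, y, 1)
    rss_line = float(np.sum((y - (slope * u + intercept)) ** 2))
    df_model = len(u) - 6
    if df_model <= 0:
        raise InsufficientDataError("too few points for a six-parameter fit")
    if rss_model <= 0:
        p_value = 0.0  # numerically perfect fit of a genuine transition
    else:
        f_statistic = ((rss_line - rss_model) / 4) / (rss_model / df_model)
        p_value = float(stats.f.sf(max(f_statistic, 0.0), 4, df_model))
    if p_value >= gate_alpha:
        raise NoTransitionError(
            f"no detectable cooperative unfolding transition "
            f"(F-test p = {p_value:.3g} >= {gate_alpha})")

    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.inf] * 6
    names = ("dg", "m_value", "a", "b", "c", "d")
    return TwoStateFit(dg=float(popt[0]), m_value=float(popt[1]),
                       a=float(popt[2]), b=float(popt[3]), c=float(popt[4]),
                       d=float(popt[5]), temperature_k=temperature_k,
                       errors=dict(zip(names, map(float, perr))))


class LambdaMax(NamedTuple):
    """Interpolated emission maximum; ``at_edge`` flags an unreliable value."""

    lambda_max_nm: float
    at_edge: bool


def lambda_max(wavelengths, intensities) -> LambdaMax:
    """Emission maximum by parabolic interpolation through the peak point.

    Fits a parabola through the maximum sample and its two neighbours for
    sub-nanometre resolution. A maximum at either end of the spectrum cannot
    be interpolated and is flagged.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(wavelengths) < 5:
        raise InsufficientDataError("need >= 5 spectral points")
    peak = int(np.argmax(intensities))
    if peak in (0, len(wavelengths) - 1):
        return LambdaMax(float(wavelengths[peak]), at_edge=True)
    x0, x1, x2 = wavelengths[peak - 1:peak + 2]
    y0, y1, y2 = intensities[peak - 1:peak + 2]
    denominator = (y0 - 2 * y1 + y2)
    if denominator == 0:
        return LambdaMax(float(x1), at_edge=False)
    offset = 0.5 * (y0 - y2) / denominator
    step = 0.5 * (x2 - x0)
    return LambdaMax(float(x1 + offset * step), at_edge=False)


@dataclass(frozen=True)
class GammaResult:
    """Colicin-activity statistic from density-corrected luminescence."""

    l_sample: float
    l_control: float
    gamma: float


def gamma_value(l_sample: float, l_control: float) -> GammaResult:
    """gamma = (L_sample - L_control) / L_control, exactly."""
    if l_control <= 0:
        raise ValueError("control luminescence must be positive")
    return GammaResult(l_sample=l_sample, l_control=l_control,
                       gamma=(l_sample - l_control) / l_control)
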