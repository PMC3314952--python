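"""Backbone 15N transverse relaxation of unfolded chains.

An unfolded polypeptide without residual structure relaxes at a rate set by
local polymer hydrodynamics alone. The intrinsic (random-coil) rate of residue
``i`` sums contributions from every residue ``j``, each weighted by its
intrinsic correlation time and attenuated exponentially with sequence
separation:

    R2_i = k * sum_j  tau_j * exp(-|i - j| / lambda_j),      tau_j = Rg_j^3

where ``Rg_j`` is the side-chain radius of gyration of residue ``j`` (Stokes
law gives tau proportional to volume, i.e. Rg^3; the proportionality constant
is amalgamated into the single empirical scale ``k``), and ``lambda_j`` is the
persistence length for segmental motion: 2 residues for motion deriving from
alanine and glycine, 7 for all other residue types. The persistence length
divides the separation — it is a decay constant along the chain — and is
assigned by the *contributing* residue ``j``.

Residues whose measured R2 sit well above this baseline over several
consecutive positions mark hydrophobic clusters: locally interacting,
aliphatic/aromatic-rich stretches that slow segmental motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, PropertyTableError
from .io import read_tsv, write_tsv
from .sequence import ProteinSequence, ResiduePropertyTable

#: Heteronuclear NOE of a rigid, isotropically tumbling amide at this field.
RIGID_LIMIT_NOE = 0.78


@dataclass
class R2Profile:
    """Per-residue transverse relaxation rates (s^-1).

    ``errors`` may be None for model profiles (no uncertainty attached).
    ``conditions`` carries solution labels such as urea and Na2SO4 molarity.
    """

    residues: np.ndarray
    rates: np.ndarray
    errors: np.ndarray | None = None
    field_mhz: float | None = None
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if np.any(self.errors < 0):
                raise ValueError("uncertainties must be >= 0")
            if self.errors.shape != self.rates.shape:
                raise ValueError("errors and rates shape mismatch")
        if len(np.unique(self.residues)) != len(self.residues):
            raise ValueError("residue indices must be unique")
        if self.residues.shape != self.rates.shape:
            raise ValueError("residues and rates shape mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    def to_tsv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame({
            "residue_index": self.residues,
            "rate_s1": self.rates,
            "err_s1": self.errors if self.errors is not None
            else np.full(len(self), np.nan),
        })
        metadata = {}
        if self.field_mhz is not None:
            metadata["field_MHz"] = self.field_mhz
        for key, value in self.conditions.items():
            metadata[key] = value
        write_tsv(path, frame, metadata)

    @classmethod
    def from_tsv(cls, path) -> "R2Profile":
        frame, metadata = read_tsv(path)
        errors = frame["err_s1"].to_numpy(dtype=float)
        if np.all(np.isnan(errors)):
            errors = None
        field_mhz = metadata.pop("field_MHz", None)
        return cls(
            residues=frame["residue_index"].to_numpy(dtype=int),
            rates=frame["rate_s1"].to_numpy(dtype=float),
            errors=errors,
            field_mhz=float(field_mhz) if field_mhz is not None else None,
            conditions=metadata,
        )


@dataclass(frozen=True)
class IntrinsicR2Model:
    """Random-coil baseline model: a global scale times the sequence shape.

    ``scale`` absorbs both the empirical rate coefficient and the Stokes-law
    proportionality between correlation time and side-chain volume.
    """

    scale: float = 1.0
    table: ResiduePropertyTable = field(default_factory=ResiduePropertyTable.default)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _baseline_shape(seq: ProteinSequence, table: ResiduePropertyTable) -> np.ndarray:
    """Unscaled baseline: sum_j Rg_j^3 * exp(-|i-j|/lambda_j), vectorised."""
    try:
        rg = np.array([table.rg[aa] for aa in seq.residues])
        lam = np.array([table.lam[aa] for aa in seq.residues])
    except KeyError as exc:  # pragma: no cover - table totality enforced upstream
        raise PropertyTableError(f"missing property entry for residue {exc}") from exc
    tau = rg ** 3
    pos = np.arange(len(seq))
    sep = np.abs(pos[:, None] - pos[None, :])
    # lambda indexed by the contributing residue j (columns)
    return (tau[None, :] * np.exp(-sep / lam[None, :])).sum(axis=1)


def intrinsic_r2_profile(seq: ProteinSequence,
                         model: IntrinsicR2Model | None = None) -> R2Profile:
    """Intrinsic (random-coil) R2 baseline for a sequence."""
    model = model or IntrinsicR2Model()
    shape = _baseline_shape(seq, model.table)
    return R2Profile(residues=seq.indices, rates=model.scale * shape,
                     conditions={"model": "intrinsic"})


def fit_scale_factor(observed: R2Profile, seq: ProteinSequence,
                     table: ResiduePropertyTable | None = None,
                     exclude: np.ndarray | list | None = None
                     ) -> tuple[float, R2Profile]:
    """Fit the global scale of the intrinsic baseline to an observed profile.

    Uses the least-absolute-deviations proportional fit: the minimiser of
    sum_i |obs_i - k * shape_i| over k is the weighted median of obs_i/shape_i
    with weights shape_i. The robust loss keeps the baseline on the non-cluster
    floor even when some residues are strongly elevated. Residue indices in
    ``exclude`` (e.g. known cluster regions) are dropped before fitting.

    Returns the fitted scale and the scaled baseline over the full sequence.
    """
    table = table or ResiduePropertyTable.default()
    shape_full = _baseline_shape(seq, table)
    index_of = {int(r): i for i, r in enumerate(seq.indices)}
    mask = np.array([int(r) in index_of for r in observed.residues])
    if exclude is not None:
        excluded = set(int(r) for r in exclude)
        mask &= np.array([int(r) not in excluded for r in observed.residues])
    obs = observed.rates[mask]
    shape = np.array([shape_full[index_of[int(r)]]
                      for r in observed.residues[mask]])
    if len(obs) < 5:
        raise InsufficientDataError(
            f"need >= 5 overlapping residues to fit the scale, got {len(obs)}")
    ratios = obs / shape
    order = np.argsort(ratios)
    weights = shape[order]
    cumulative = np.cumsum(weights)
    scale = float(ratios[order][np.searchsorted(cumulative,
                                                0.5 * cumulative[-1])])
    baseline = R2Profile(residues=seq.indices, rates=scale * shape_full,
                         conditions={"model": "intrinsic-fitted"})
    return scale, baseline


@dataclass(frozen=True)
class DecayFit:
    """Monoexponential decay fit result; ``flagged`` marks unphysical rates."""

    rate: float
    sigma: float
    i0: float
    flagged: bool = False
    message: str = ""


def fit_exponential_decay(times, intensities, noise: float | None = None
                          ) -> DecayFit:
    """Fit I(t) = I0 * exp(-R2 t) by nonlinear least squares.

    Initialised from the log-linear regression of log I on t. Duplicate time
    points, when present, inflate the reported uncertainty by the pooled
    duplicate spread (relative to the fitted curve), mirroring error estimation
    from duplicate experiments plus spectral noise.

    Non-positive fitted rates are flagged, not silently returned.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(times) < 3:
        raise InsufficientDataError("need >= 3 time points for a decay fit")
    if len(times) != len(intensities):
        raise ValueError("times and intensities length mismatch")

    positive = intensities > 0
    if positive.sum() >= 2:
        slope, intercept = np.polyfit(times[positive],
                                      np.log(intensities[positive]), 1)
        p0 = (float(np.exp(intercept)), max(float(-slope), 1e-6))
    else:
        p0 = (float(np.max(np.abs(intensities)) or 1.0), 1.0)

    def model(t, i0, rate):
        return i0 * np.exp(-rate * t)

    sigma = np.full_like(times, noise) if noise else None
    popt, pcov = curve_fit(model, times, intensities, p0=p0, sigma=sigma,
                           absolute_sigma=noise is not None, maxfev=10000)
    i0, rate = popt
    rate_sigma = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf

    # duplicate-point spread inflates the uncertainty
    unique, counts = np.unique(times, return_counts=True)
    if np.any(counts > 1):
        residual_spreads = []
        for t in unique[counts > 1]:
            values = intensities[times == t]
            residual_spreads.append(np.std(values, ddof=1))
        spread = float(np.mean(residual_spreads))
        typical = float(np.mean(np.abs(model(times, *popt)))) or 1.0
        rate_sigma = float(np.hypot(rate_sigma, rate * spread / typical))

    if rate <= 0:
        return DecayFit(rate=float(rate), sigma=rate_sigma, i0=float(i0),
                        flagged=True, message="fitted rate <= 0 (no decay)")
    return DecayFit(rate=float(rate), sigma=rate_sigma, i0=float(i0))


@dataclass(frozen=True)
class ClusterCall:
    """A maximal run of residues with R2 elevated above the baseline."""

    start: int
    end: int
    center: int
    mean_excess: float

    def __post_init__(self) -> None:
        if not self.start <= self.center <= self.end:
            raise ValueError("cluster center outside its interval")


def detect_clusters(observed: R2Profile, baseline: R2Profile,
                    min_run: int = 3, z: float = 2.0) -> list[ClusterCall]:
    """Find maximal runs of >= ``min_run`` consecutive residues whose observed
    rate exceeds the baseline by more than ``z`` times the local uncertainty.

    When the observed profile carries no per-residue uncertainties, a robust
    spread of the excess (1.4826 * MAD) stands in. Each run is reported with
    the residue of maximal excess as its center.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    base_map = {int(r): v for r, v in zip(baseline.residues, baseline.rates)}
    mask = np.array([int(r) in base_map for r in observed.residues])
    if not mask.any():
        raise InsufficientDataError("observed and baseline profiles do not overlap")
    residues = observed.residues[mask]
    excess = observed.rates[mask] - np.array(
        [base_map[int(r)] for r in residues])
    if observed.errors is not None:
        threshold = z * observed.errors[mask]
    else:
        mad = np.median(np.abs(excess - np.median(excess)))
        threshold = np.full_like(excess, z * 1.4826 * mad)

    above = excess > threshold
    calls: list[ClusterCall] = []
    i = 0
    n = len(residues)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        # a run must be consecutive in residue number, not just in array order
        while (j + 1 < n and above[j + 1]
               and residues[j + 1] == residues[j] + 1):
            j += 1
        if j - i + 1 >= min_run:
            segment = slice(i, j + 1)
            seg_excess = excess[segment]
            # flat-top runs: take the middle of the tied maxima
            tied = np.nonzero(seg_excess >= seg_excess.max() - 1e-12)[0]
            center = int(residues[segment][tied[len(tied) // 2]])
            calls.append(ClusterCall(
                start=int(residues[i]), end=int(residues[j]), center=center,
                mean_excess=float(excess[segment].mean())))
        i = j + 1
    return calls


@dataclass(frozen=True)
class NOERecord:
    """Heteronuclear NOE: ratio of peak heights with / without 1H saturation."""

    residue: int
    i_sat: float
    i_ref: float
    noe: float
    sigma: float
    above_rigid_limit: bool = False


def het_noe(i_sat: float, i_ref: float, sigma_sat: float = 0.0,
            sigma_ref: float = 0.0, residue: int = 0) -> NOERecord:
    """NOE ratio I_sat / I_ref with first-order propagated uncertainty.

    sigma = |noe| * sqrt((sigma_sat/I_sat)^2 + (sigma_ref/I_ref)^2). Values
    above the rigid-tumbling reference (+0.78) are flagged: they exceed what a
    rigid, isotropically tumbling amide can produce at this field.
    """
    if i_ref == 0:
        raise ValueError("reference intensity must be non-zero")
    noe = i_sat / i_ref
    if i_sat == 0:
        sigma = abs(sigma_sat / i_ref)
    else:
        sigma = abs(noe) * np.hypot(sigma_sat / i_sat, sigma_ref / i_ref)
    above = noe > RIGID_LIMIT_NOE
    if above:
        warnings.warn(f"NOE {noe:.3f} exceeds the rigid limit "
                      f"({RIGID_LIMIT_NOE})", stacklevel=2)
    return NOERecord(residue=residue, i_sat=i_sat, i_ref=i_ref,
                     noe=float(noe), sigma=float(sigma), above_rigid_limit=above)
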