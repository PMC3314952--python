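"""Seeded generators emulating each experimental input.

Every generator is a pure function of its parameters and a seed, so identical
calls give byte-identical datasets. The defaults reproduce the study
conditions of the unfolded Im7 analysis: an 87-residue chain with four
hydrophobic clusters centred at residues 18/42/56/73 over the random-coil R2
baseline, region helix fractions of roughly 13/8/4/16 percent, couplings in
the 5-9.5 Hz window at a 12.54 ms HNHA delay, a wild-type stability of
24.9 kJ/mol unfolding free energy titrated over 0-8 M urea in 0.2 M steps,
and 11-point monoexponential relaxation decays spanning 1.6-191.6 ms.

Noise is Gaussian and homoscedastic per observable by default; pass an array
for heteroscedastic noise where supported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .relaxation import IntrinsicR2Model, R2Profile, intrinsic_r2_profile
from .sequence import HelixRegions, ProteinSequence, im7_sequence
from .shifts import (FULL_HELIX_SHIFT, RandomCoilReference, ShiftTable,
                     random_coil_shifts)
from .stability import DenaturationCurve, two_state_signal
from .couplings import DEFAULT_DELTA, hnha_ratio

#: The 11 relaxation mixing times (s), evenly spaced over 1.60-191.6 ms.
DECAY_TIMES_S = tuple(np.round(np.linspace(0.0016, 0.1916, 11), 6))

#: Default cluster truth: (center, amplitude s^-1, width residues).
DEFAULT_CLUSTERS = ((18, 1.5, 2.0), (42, 1.5, 2.0), (56, 1.5, 2.0),
                    (73, 1.5, 2.0))

#: Default per-region helix fractions for the shift generator.
DEFAULT_HELIX_FRACTIONS = {"I": 0.131, "II": 0.081, "III": 0.043, "IV": 0.163}


def unfolded_im7_variant() -> ProteinSequence:
    """The triple-substituted unfolded-state mimic L18A-L19A-L37A."""
    return im7_sequence({18: "A", 19: "A", 37: "A"})


@dataclass
class SimulationSpec:
    """Serialisable description of one synthetic dataset.

    ``kind`` selects the generator; ``params`` are its keyword arguments.
    Identical spec + seed give identical data.
    """

    seed: int
    kind: str
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps({"seed": self.seed, "kind": self.kind,
                           "params": self.params}, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as handle:
                handle.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SimulationSpec":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(seed=int(payload["seed"]), kind=payload["kind"],
                   params=payload.get("params", {}))


def simulate_r2_dataset(seed: int, seq: ProteinSequence | None = None,
                        scale: float = 0.07,
                        clusters: Sequence[tuple[float, float, float]]
                        = DEFAULT_CLUSTERS,
                        noise: float = 0.15, field_mhz: float = 50.66
                        ) -> tuple[R2Profile, R2Profile, list[tuple]]:
    """Observed R2 profile = scaled baseline + Gaussian cluster bumps + noise.

    Returns (observed, true baseline, cluster truth). The default scale puts
    the baseline near 3-4 s^-1 at 50.66 MHz, with 1.5 s^-1 bumps of 2-residue
    width at the four cluster centers and 0.15 s^-1 measurement noise —
    magnitudes typical of an unfolded 87-residue chain.
    """
    rng = np.random.default_rng(seed)
    seq = seq or unfolded_im7_variant()
    baseline = intrinsic_r2_profile(seq, IntrinsicR2Model(scale=scale))
    indices = baseline.residues.astype(float)
    lo, hi = indices.min(), indices.max()
    bumps = np.zeros_like(indices)
    for center, amplitude, width in clusters:
        if not lo <= center <= hi:
            raise ValueError(f"cluster center {center} outside sequence")
        bumps += amplitude * np.exp(-0.5 * ((indices - center) / width) ** 2)
    observed_rates = baseline.rates + bumps + rng.normal(0.0, noise,
                                                         len(indices))
    errors = np.full(len(indices), noise)
    observed = R2Profile(residues=baseline.residues, rates=observed_rates,
                         errors=errors, field_mhz=field_mhz,
                         conditions={"urea_M": 0.0, "na2so4_M": 0.0,
                                     "synthetic": "r2"})
    return observed, baseline, [tuple(c) for c in clusters]


def simulate_shift_dataset(seed: int, seq: ProteinSequence | None = None,
                           ref: RandomCoilReference | None = None,
                           helix_fractions: Mapping[str, float]
                           = DEFAULT_HELIX_FRACTIONS,
                           regions: HelixRegions | None = None,
                           noise: float = 0.0,
                           nuclei: Sequence[str] = ("CA", "CB")) -> ShiftTable:
    """Shift table = random-coil reference + fraction x full-helix offset + noise.

    ``helix_fractions`` maps region names to fractional helix populations in
    [0, 1]; the Cbeta offset carries its physical (negative-in-helix) sign.
    """
    rng = np.random.default_rng(seed)
    seq = seq or unfolded_im7_variant()
    ref = ref or RandomCoilReference.default()
    regions = regions or HelixRegions()
    for name, fraction in helix_fractions.items():
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"helix fraction for region {name!r} outside [0,1]")
    table = random_coil_shifts(seq, ref, nuclei=nuclei)
    fraction_at = np.zeros(len(table.data))
    for name, fraction in helix_fractions.items():
        start, end = regions[name]
        inside = ((table.data["residue_index"] >= start)
                  & (table.data["residue_index"] <= end))
        fraction_at[inside.to_numpy()] = fraction
    offsets = table.data["nucleus"].map(
        lambda nu: FULL_HELIX_SHIFT.get(nu, 0.0)).to_numpy()
    shifted = (table.data["shift_ppm"].to_numpy() + fraction_at * offsets
               + rng.normal(0.0, noise, len(table.data)))
    data = table.data.copy()
    data["shift_ppm"] = shifted
    return ShiftTable(data, temperature_k=table.temperature_k, ph=table.ph,
                      label="synthetic-shifts")


def simulate_hnha(seed: int, j_values: Mapping[int, float] | None = None,
                  delta: float = DEFAULT_DELTA, i_diag: float = 100.0,
                  noise_fraction: float = 0.0) -> pd.DataFrame:
    """Intensity-pair table from chosen couplings through the forward model.

    Diagonal peaks sit at a fixed intensity; cross peaks are ratio x diagonal;
    Gaussian noise of ``noise_fraction`` x i_diag is added to both. Default J
    values sweep the observed 5-9.5 Hz window.
    """
    rng = np.random.default_rng(seed)
    if j_values is None:
        j_grid = np.linspace(5.0, 9.5, 10)
        j_values = {i + 1: float(j) for i, j in enumerate(j_grid)}
    records = []
    sigma = noise_fraction * i_diag
    for residue, j in sorted(j_values.items()):
        ratio = hnha_ratio(j, delta)  # raises at/above the singularity
        cross = ratio * i_diag + rng.normal(0.0, sigma)
        diag = i_diag + rng.normal(0.0, sigma)
        records.append((residue, cross, diag, sigma, j))
    return pd.DataFrame(records, columns=["residue_index", "i_cross", "i_diag",
                                          "noise", "j_true"])


def simulate_denaturation(seed: int, dg: float = 24.9, m: float = 6.0,
                          a: float = 0.0, b: float = 1.0, c: float = 0.0,
                          d: float = 0.0, temperature_k: float = 283.15,
                          urea_max: float = 8.0, urea_step: float = 0.2,
                          noise: float = 0.02) -> DenaturationCurve:
    """Two-state titration curve over 0-8 M urea in 0.2 M steps plus noise.

    Defaults give the wild-type-like curve: unfolding free energy 24.9 kJ/mol,
    m-value 6 kJ/mol/M (midpoint ~4.2 M) at 10 C with flat unit baselines and
    2 percent Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    urea = np.round(np.arange(0.0, urea_max + 0.5 * urea_step, urea_step), 10)
    signal = two_state_signal(urea, dg, m, a, b, c, d, temperature_k)
    signal = signal + rng.normal(0.0, noise * max(abs(b), abs(d), 1e-12),
                                 len(urea))
    curve = DenaturationCurve(urea, signal, probe="synthetic-CD",
                              temperature_k=temperature_k)
    return curve


def simulate_decay_series(seed: int, rates: Mapping[int, float] | None = None,
                          times: Sequence[float] = DECAY_TIMES_S,
                          i0: float = 1.0, noise: float = 0.02,
                          duplicate_times: Sequence[float] = ()
                          ) -> pd.DataFrame:
    """Per-residue monoexponential decay series on the 11 standard delays.

    Columns: residue_index, time_s, intensity, noise. ``duplicate_times`` adds
    repeat measurements at the given delays so the duplicate-spread error
    inflation path of the decay fitter is exercised.
    """
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = {i + 1: r for i, r in enumerate(np.linspace(2.0, 15.0, 14))}
    for residue, rate in rates.items():
        if rate <= 0:
            raise ValueError(f"rate for residue {residue} must be positive")
    all_times = list(times) + list(duplicate_times)
    records = []
    for residue, rate in sorted(rates.items()):
        for t in all_times:
            intensity = i0 * np.exp(-rate * t) + rng.normal(0.0, noise * i0)
            records.append((residue, t, intensity, noise * i0))
    return pd.DataFrame(records, columns=["residue_index", "time_s",
                                          "intensity", "noise"])


_GENERATORS = {
    "r2": simulate_r2_dataset,
    "shifts": simulate_shift_dataset,
    "hnha": simulate_hnha,
    "denaturation": simulate_denaturation,
    "decay": simulate_decay_series,
}


def simulate(spec: SimulationSpec):
    """Dispatch a :class:`SimulationSpec` to its generator."""
    try:
        generator = _GENERATORS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown simulation kind {spec.kind!r}; choose from "
                         f"{sorted(_GENERATORS)}") from None
    return generator(spec.seed, **spec.params)
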