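# coiltools

Residue-level analysis of unfolded and disordered protein states, built
around the experiments used to characterise the unfolded ensemble of the
four-helix immunity protein Im7: backbone ¹⁵N relaxation, chemical shifts,
scalar couplings, sedimentation velocity and equilibrium denaturation.

## Who this is for

Protein-folding and IDP labs that have residue-resolved NMR observables
(R₂ decay series, chemical-shift tables, HNHA intensity pairs, heteronuclear
NOEs), sedimentation-velocity records and urea titrations for a denatured or
intrinsically disordered chain, and want to ask: *is this ensemble a random
coil, or does it contain hydrophobic clusters, residual helicity and
compaction?*

## What it computes

* **Random-coil R₂ baseline and hydrophobic clusters.** The intrinsic
  transverse relaxation rate of residue *i* in a structureless chain is

  R₂ᵢ = k · Σⱼ τⱼ · exp(−|i−j|/λⱼ),  with τⱼ = R₉ⱼ³,

  where R₉ⱼ is the side-chain radius of gyration of residue *j* (proline
  raised from 1.25 to 2.0 Å for ring closure) and λⱼ is the persistence
  length for segmental motion (2 residues for Ala/Gly, 7 otherwise). The
  single scale *k* is fitted to observed rates by a robust (least absolute
  deviations) proportional fit so the baseline hugs the non-cluster floor.
  Runs of residues elevated above the baseline by more than *z*·σ over ≥ 3
  consecutive positions are reported as hydrophobic clusters.
* **Secondary shifts and SSP helicity.** Observed minus random-coil shifts,
  urea-difference shifts (reference-free), and a windowed
  secondary-structure-propensity score from Cα/Cβ shifts (+1 = 100% helix,
  −1 = 100% strand), summarised per native-helix region as % helix.
* **³J(HNHA) couplings.** J = atan(√(−I_cross/I_diag))/(2πΔ) with
  first-order error propagation and helical (≤ 6 Hz) / extended (≥ 8 Hz)
  classification.
* **Hydrodynamics.** s → s₂₀,w standardisation, the Svedberg equation
  f = M(1−v̄ρ)/(N_A s₂₀,w), the equal-volume Stokes sphere
  (R₀, f₀ = 6πηR₀), the frictional ratio f/f₀ and R_h = (f/f₀)·R₀, plus the
  empirical power laws R_h = 4.75·N^0.29 (folded) and 2.21·N^0.57
  (denatured) and compaction metrics.
* **Stability and activity.** CD helicity from 222 nm mean residue
  ellipticity, six-parameter two-state urea-denaturation fits with an F-test
  gate for "no cooperative transition", fluorescence λ_max by parabolic
  interpolation, and the luminescence-protection γ statistic.
* **Synthetic data.** Seeded generators emulate each input (decays, R₂
  profiles with injected clusters, shift tables with injected helix
  fractions, HNHA pairs, titrations), so every pipeline is testable without
  downloads.

## Worked example

```python
import coiltools as ct

# unfolded-state mimic of Im7 (L18A-L19A-L37A) and a synthetic R2 dataset
seq = ct.unfolded_im7_variant()
observed, baseline, truth = ct.simulate_r2_dataset(seed=1)
scale, fitted = ct.fit_scale_factor(observed, seq)
for c in ct.detect_clusters(observed, fitted):
    print(f"cluster {c.start}-{c.end}, center {c.center}, "
          f"mean excess {c.mean_excess:.2f} s^-1")

# sedimentation chain for a native-like particle
record = ct.SedimentationRecord(
    s_obs=1.45, temperature_k=293.15, buffer_density=0.998207,
    buffer_viscosity_mpas=1.002, vbar=0.73, molar_mass=10600).analyze()
print(f"s20,w = {record.s20w:.2f} S, f/f0 = {record.f_ratio:.2f}, "
      f"Rh = {record.rh:.1f} A")
```

prints

```
cluster 16-21, center 18, mean excess 0.93 s^-1
cluster 39-45, center 42, mean excess 0.79 s^-1
cluster 53-58, center 57, mean excess 0.94 s^-1
cluster 70-76, center 74, mean excess 0.87 s^-1
s20,w = 1.45 S, f/f0 = 1.20, Rh = 17.4 A
```

The four recovered clusters sit at (or within one residue of) the injected
centers 18, 42, 56 and 73 — the hydrophobic clusters of the unfolded Im7
chain, one per native helix. The sedimentation record gives a frictional
ratio of 1.20 and a hydrodynamic radius of 17.4 Å: a compact, nearly
spherical particle, matching the 17.7 Å that the folded-state power law
predicts for a 94-residue His-tagged chain
(`ct.wilkins_rh(94, "folded")`).

A `coiltools` command-line tool exposes the same operations
(`simulate`, `run --config`, `hydro`, `unfold-fit`, `helicity`, `gamma`).

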