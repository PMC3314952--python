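# Methods

This note records the models implemented in coiltools, the defaults chosen
where the design was genuinely open, what the synthetic-data generators do
and do not emulate, and the numerical conventions that make runs
reproducible.

## Sequence model and property tables

Sequences use wild-type numbering: residue *k* of the stored string has
index `first_index + k − 1`, so an N-terminal expression tag can be loaded
with `first_index = 1 − tag_length` and carries indices ≤ 0 while the native
chain keeps its familiar numbers. The packaged example is the 87-residue
Im7 sequence; `unfolded_im7_variant()` applies the L18A-L19A-L37A
substitutions that trap the chain in its unfolded state under native-like
conditions.

Three per-residue scales ship as a replaceable TSV:

* **Side-chain radius of gyration** (Levitt 1976, Å). The proline value is
  raised from 1.25 to 2.0 Å at table construction — ring closure restricts
  the conformational space of the preceding segment, and the intrinsic-R₂
  model absorbs that as a larger effective volume. The override happens
  once, in the loader, so re-loading is idempotent.
* **Persistence length** λ (residues): 2 for alanine and glycine (small side
  chains decouple segmental motion), 7 for all other types.
* **AABUF** (average area buried upon folding, Rose et al. 1985, Å²), a
  hydrophobicity-like scale that tracks cluster formation in denatured
  states. The profile is a sliding-window mean (default window 9, uniform
  weights — a conventional smoothing width; the profile's region-level
  ranking is insensitive to windows 7–11) min-max rescaled to [0, 10];
  constant profiles map to 0 by convention.

The native helix intervals default to I:12–25, II:31–45, III:51–56,
IV:65–79 (inclusive, wild-type numbering) and are overridable per region.

## Intrinsic R₂ baseline and cluster detection

The random-coil baseline is R₂ᵢ = k · Σⱼ Rgⱼ³ · exp(−|i−j|/λⱼ). Two reading
choices deserve note:

* the exponent divides the sequence separation by λ — λ is a persistence
  *length* along the chain, so it must scale the separation for the
  exponent to be dimensionless;
* λ is indexed by the **contributing** residue *j*, not the observed residue
  *i*: a flexible Ala/Gly at position *j* transmits its motion over a
  shorter range regardless of what is being observed.

The Stokes-law proportionality between a residue's correlation time and its
side-chain volume, and the overall empirical rate coefficient, are
amalgamated into the single scale *k*. How that scale should be chosen
against data is an open design point; coiltools fits it by least absolute
deviations, whose proportional-fit minimiser is the shape-weighted median
of observed/shape ratios. This is deterministic, closed-form, and robust:
cluster-elevated residues act as outliers and barely move the fit, so the
baseline tracks the non-cluster floor. Residue indices can additionally be
excluded explicitly (e.g. known cluster regions).

Clusters are maximal runs of ≥ `min_run` (default 3) consecutive residues
whose observed − baseline excess exceeds `z` (default 2) times the local
uncertainty; when the profile carries no uncertainties, 1.4826 × the median
absolute deviation of the excess stands in. The run's center is the residue
of maximal excess; flat-topped ties resolve to the middle of the tied
stretch. With the default synthetic conditions (1.5 s⁻¹ bumps of 2-residue
width on 0.15 s⁻¹ noise) recovery is essentially perfect; the acceptance
suite quantifies this over 100 seeds.

R₂ values come from monoexponential fits I(t) = I₀e^(−R₂t) to 11-point
decay series (delays spanning 1.60–191.6 ms; only the range is standard, so
the generator spaces the 11 delays evenly across it). Fits use nonlinear
least squares with log-linear initialisation; duplicate time points inflate
the reported uncertainty by the pooled duplicate spread. Non-positive
fitted rates are flagged rather than silently returned. Heteronuclear NOEs
are the exact peak-height ratio I_sat/I_ref with first-order error
propagation; ratios above the rigid-tumbling reference (+0.78 at this
field) are flagged as unphysical for a rigid isotropic tumbler.

## Chemical shifts and SSP

The random-coil reference is a per-(residue type, nucleus) base table plus
optional nearest-neighbour (offsets ±1, ±2), temperature and pH corrections;
absent corrections contribute zero. The packaged base table is a
Wishart-style consensus set with zero corrections — the analyses record the
table label, and any table with the same columns can be substituted. The
urea-difference analysis (δ(0 M) − δ(6 M)) deliberately avoids the
reference altogether: the random-coil term cancels between conditions, and
Cα differences above 1 ppm are flagged as atypical (full helix formation
moves Cα by ~2.6 ppm; an unfolded state should stay well inside 1 ppm).

The SSP score pools Cα/Cβ secondary shifts over a centred window (default
5): each shift is oriented helix-positive (Cβ enters with inverted sign),
summed, and divided by the summed full-structure magnitudes — full-helix
values (Cα +2.6, Cβ −0.4 ppm) when the window consensus is positive,
full-sheet values (Cα −1.4, Cβ +2.2 ppm) when negative. Shifts larger than
3× their full-structure value are excluded as outliers; scores are clamped
to [−1, 1]; positions with fewer than two usable values are undefined.
Glycine (no Cβ) is scored from Cα alone. Region helicity is the arithmetic
mean score over a helix interval × 100. Because windows near region
boundaries average across the edge, a uniform injected fraction is
recovered with a small (< 1.5 percentage point) downward edge bias at the
region level; the acceptance suite bounds the total error at 2 points.
Numeric agreement with any particular published SSP implementation is not a
goal (reference sets differ between versions); the score's defining
properties — bounds, translation invariance, fraction recovery — are tested
instead.

## HNHA couplings

I_cross/I_diag = −tan²(2πJΔ) with Δ = 12.54 ms (mixing time 2Δ = 25.08 ms)
by default. The inversion J = atan(√(−ratio))/(2πΔ) is exact on
(0, 1/(4Δ) ≈ 19.9 Hz); the measured 4.96–9.54 Hz range sits comfortably
inside. Positive ratios are an error, not clipped — they indicate phase or
assignment problems and should fail loudly. Uncertainties propagate the two
peak-height noises independently (no cross/diagonal noise correlation is
assumed); the derivative diverges at ratio 0, so σ_J is reported as
infinite there when noise is non-zero. No correction is applied for
differential relaxation during the delay. Classification: helical ≤ 6 Hz,
extended ≥ 8 Hz, intermediate between.

## Hydrodynamics

All arithmetic is cgs (g, cm, s, poise) with 1 Svedberg = 10⁻¹³ s;
reported radii are Å. Water density follows the Kell (1975) correlation and
viscosity the standard two-branch empirical correlation anchored at
1.002 mPa·s at 20 °C; buffer density/viscosity and the partial specific
volume v̄ are user inputs (they normally come from buffer-composition
software, which is out of scope). The reference sphere uses the
**anhydrous** volume Mv̄/N_A: the equation chain
f/f₀ · R₀ = R_h only closes exactly on the equal-volume sphere, so that is
the default even though the comparison is often described against a
"hydrated" sphere; an optional hydration parameter δ (g water/g protein)
adds bound-water volume for users who want the hydrated reference. With
M = 10 600 g/mol, v̄ = 0.73 mL/g and s = 1.45 S the chain gives
f/f₀ = 1.20 and R_h = 17.4 Å, within a few percent of measured native
values — exact agreement is not expected because the authors' v̄ and buffer
properties are not published.

Empirical radii: R_h = 4.75·N^0.29 Å (folded) and 2.21·N^0.57 Å
(denatured). The construct length for these predictions is a user input;
the packaged example uses N = 94 (87 native residues + a 7-residue
Met-His₆ tag), since the exact tagged length is not printed anywhere.
Compaction metrics report both the radius ratio a/b and
100·(1 − a/b) "% more compact"; the 1.4× expansion statement is computed
from the mean of the two 0 M-urea unfolded radii over the native radius
(the statement's reference condition is ambiguous; the mean is the neutral
reading).

## Stability and activity

The two-state titration model is

Signal = ((a·u + b)·K + (c·u + d)) / (1 + K),  K = exp((ΔG°_UF − m·u)/RT)

with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹, u the urea molarity, ΔG°_UF the
**unfolding** free energy (positive for a stable fold) and a,b / c,d the
folded / unfolded baselines. Results also expose the folding free energy
−ΔG°_UF, the convention in which stabilities are usually quoted (wild-type
Im7: −24.9 kJ/mol at 10 °C). Initial guesses: baselines from linear fits to
the first/last three points, m = 5 kJ/mol/M, ΔG from the half-signal
crossing. Before parameters are reported, an F-test (α = 0.01) compares the
six-parameter model against a straight line; indistinguishable-from-linear
data raise an explicit no-transition error — the signature of a variant
with no cooperative unfolding event — instead of returning meaningless
parameters. Optional normalisation to the 8 M urea signal is provided. CD
helicity is (MRE_variant/MRE_wt at 222 nm) × 50, the factor 50 encoding
that half of the wild-type residues are helical in the crystal structure.
λ_max uses parabolic interpolation through the peak sample and its
neighbours (sub-nm resolution; edge maxima are flagged, not interpolated).
γ = (L_sample − L_control)/L_control on density-corrected luminescence.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed); identical calls give
byte-identical files in the same TSV/JSON dialects the readers consume.
Defaults encode the study conditions: an 87-residue chain with four
Gaussian R₂ bumps (centers 18/42/56/73, amplitude 1.5 s⁻¹, width 2
residues, noise 0.15 s⁻¹ — magnitudes typical of an unfolded chain at
50.66 MHz ¹⁵N frequency), region helix fractions 13.1/8.1/4.3/16.3%,
couplings swept over 5–9.5 Hz, titrations from ΔG°_UF = 24.9 kJ/mol and
m = 6 kJ/mol/M (the wild-type m-value is not published; 6 is typical for a
protein of this size and puts the midpoint near 4.2 M) over 0–8 M urea in
0.2 M steps with 2% Gaussian noise, and 11-point decays over rates
2–15 s⁻¹ at 2% noise.

Noise is Gaussian and homoscedastic per observable; cluster bumps are
Gaussian in residue index. Real data differ in ways the generators do not
attempt: heteroscedastic and correlated peak-height errors, conformational
exchange line-broadening (which inflates R₂ non-locally, as kosmotrope
titration shows), missing assignments (prolines, overlap), baseline drifts
in CD, and boundary-spreading effects in sedimentation. Passing recovery
tests therefore demonstrates that the estimators are correct and unbiased
under their stated noise model, not that every systematic effect in real
spectra is handled.

## Numerical conventions

* TSV dialect: tab-separated, UTF-8, '.' decimal, `#key=value` metadata
  headers; outputs are bit-stable for fixed config + seed.
* All randomness flows through `numpy.random.default_rng(seed)`; pipeline
  stage *k* draws from `seed + k`.
* Degenerate inputs fail loudly: flotation (1 − v̄ρ ≤ 0), positive HNHA
  ratios, zero reference intensities, empty overlaps, reversed or
  overlapping regions, non-positive decay rates (flagged), sub-unity
  frictional ratios (warning).
* Problem sizes in the test and acceptance suites (100–200 seeded
  replicates for recovery statistics, N ≤ 200 for baseline equivalence)
  are chosen so that Monte-Carlo error is several times smaller than the
  tolerance being asserted.

## Known limitations

* The absolute scale of the intrinsic R₂ baseline is empirical; only the
  shape is physical. Whether cluster residues should be excluded when
  fitting the scale is data-dependent; the robust fit makes the choice
  largely moot but an explicit exclusion list is supported.
* The packaged random-coil set carries no neighbour/temperature/pH
  corrections; users comparing absolute secondary shifts across conditions
  should supply a corrected reference table. Urea-difference shifts are the
  reference-free alternative.
* Three-state fits, spectral-density mapping, c(S) distribution inversion
  and φ-angle inference from couplings are out of scope.
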