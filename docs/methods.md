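# Methods

## The measurement this package models

A fluorescence quenching titration holds a fluorophore-bearing protein
(here, human serum albumin, HSA, whose single tryptophan dominates the
intrinsic emission near λ_em = 335 nm under 275–280 nm excitation) at a
fixed concentration and steps up the concentration C of a small-molecule
ligand. If the ligand binds, the emission intensity F falls below the
unquenched intensity F0, and the emission maximum typically blue-shifts
as the tryptophan microenvironment becomes less polar. A 3-D
excitation–emission matrix (EEM) of the same system shows two
fluorescence peaks — a peptide-backbone peak near (λ_ex 235, λ_em 325) nm
and the tryptophan/tyrosine peak near (280, 335) nm — plus a first-order
Rayleigh scatter ridge along λ_ex = λ_em whose height grows with solute
particle size.

## Models and estimators

**Modified Stern–Volmer.** With fa the fraction of fluorophores
accessible to the quencher and K_SV′ the effective quenching constant,

    F0/(F0 − F) = 1/(fa·K_SV′·C) + 1/fa

An ordinary least-squares line of y = F0/(F0−F) on x = 1/C gives
intercept = 1/fa and slope = 1/(fa·K_SV′), hence fa = 1/intercept and
K_SV′ = intercept/slope. The bimolecular quenching rate constant is
Kq = K_SV′/τ0 with τ0 the unquenched lifetime (default 1e-8 s, the
standard biopolymer value; overridable). Kq above the diffusion-collision
ceiling of 2.0e10 L/(mol·s) cannot be produced by collisional quenching,
so the mechanism is called *static* iff Kq strictly exceeds that
threshold (a value exactly at the ceiling stays `dynamic_consistent`).

fa is deliberately **not** constrained to (0, 1]: several experimentally
fitted intercepts are below 1, implying fa > 1, and the estimator
reproduces the unconstrained algebra, logging a warning when fa > 1.

**Double-logarithmic binding isotherm** (Lineweaver–Burk-type). For
independent binding to n equivalent sites with association constant KA,

    lg((F0 − F)/F) = lg KA + n·lg C

so the log-log line's slope estimates the apparent site number n and
10^intercept estimates KA (reported in nominal L/mol even when n ≠ 1,
following common usage; formally the units are (L/mol)^n).

Both fits run through `scipy.stats.linregress`; the results objects carry
the coefficient standard errors it provides. R² is 1 − SS_res/SS_tot,
with the degenerate constant-y case (SS_tot = 0) defined as R² = 1
(a horizontal line reproduces the data exactly). Points with C = 0 or
F ≥ F0 cannot enter either transform; the C = 0 point defines F0 only,
and F ≥ F0 points (no quench signal, e.g. noise at low C) are dropped
with a logged warning rather than an error. A fit needs at least three
usable points; a non-positive slope or intercept on the transformed
coordinates contradicts the quenching model and raises `FitInvalidError`.

## Concentrations and units

Concentrations are explicit molar values supplied by the caller; KA and
K_SV′ are then in L/mol. The default synthetic ladder applies
volume-mixing dilution to a 5:0, 5:1, 5:5, 5:10, 5:15, 5:20, 5:30
protein:ligand volume-ratio protocol with both stocks at 1e-3 mol/L,
giving ligand concentrations 0, 1.67e-4, 5.0e-4, 6.67e-4, 7.5e-4,
8.0e-4, 8.57e-4 mol/L (7 points, 6 usable). Whether a given published
line was fitted on dilution-corrected molar values or nominal ratio
indices is generally unrecoverable; this affects the units of KA but not
the reproduction of printed line coefficients, which is what the
validation suite asserts.

## Synthetic data generator

The generator exists so that every pipeline stage is testable without
instrument data; each generator is a deterministic function of its seed.

* `simulate_titration_sv`: mean F(C) = F0·(1 − fa·Ksv·C/(1 + Ksv·C)),
  the exact generative inverse of the modified Stern–Volmer line.
* `simulate_titration_lb`: mean F(C) = F0/(1 + KA·C^n), the exact inverse
  of the double-log line. The two generative models are incompatible in
  general; recovery tests always pair a fitter with its matching model.
* Noise is multiplicative Gaussian on F (a shot/gain approximation),
  applied to every point including the C = 0 blank; an additive option
  exists. The true instrument noise magnitude is not knowable from the
  reported fits alone; the 1% default is a placeholder of the right order
  (it reproduces the ~0.98–0.999 R² range of the published lines).
* `simulate_titration_scans` attaches a Gaussian emission scan to every
  point (grid 285–430 nm, 5 nm step). The scan's **peak height equals the
  point's scalar intensity** (the natural reading that makes
  `emission_maximum` of a scan return the series' scalar F), and its
  centre moves linearly with the quenched fraction from 335 nm at C = 0
  to 335 − 25 = 310 nm at the most-quenched rung; only the endpoints of
  that shift are experimentally anchored, the linear interpolation is a
  modelling choice.
* `simulate_eem` sums separable 2-D Gaussians per fluorescence peak plus
  a Rayleigh ridge: a Gaussian of cross-width 8 nm around λ_ex = λ_em,
  modulated along the diagonal by a Gaussian profile centred at 290 nm
  (σ 30 nm) so the ridge has a single maximum at (290, 290). The HSA
  preset uses peak widths σ_ex = σ_em = 12 nm (chosen so cross-talk
  between the peaks and the ridge stays well under 1% of any recovered
  intensity; no widths are experimentally reported) and amplitudes
  362.3 / 1803 / 1058 for peak 1, peak 2 and the ridge. Baseline noise is
  additive Gaussian clipped at zero. Second-order scatter (λ_em ≈ 2λ_ex),
  inner-filter effects, Raman scatter, photobleaching and instrument
  spectral response are not modelled.

## EEM peak machinery

A fluorescence peak is a cell strictly greater than all 8 neighbours
(edge cells compare against existing neighbours only), outside the band
|λ_ex − λ_em| ≤ 10 nm (two grid steps; configurable), with intensity at
least 5% of the global matrix maximum (configurable). Plateau ties are
therefore never reported (strictness); ordering ties in the output sort
break by (lower λ_ex, then lower λ_em) for determinism. The Rayleigh
locator returns the maximum cell inside the band, first-in-grid-order on
ties. Both operations are verified against exhaustive brute-force scans
on randomized grids up to 50×50.

Published peak-1/peak-2 coordinates are quoted with λ_em/λ_ex labels that
contradict the stated scan ranges (235 nm lies in the excitation range,
not the emission range); this package follows the ranges, i.e. treats the
pairs as (λ_ex 235, λ_em 325) and (λ_ex 280, λ_em 335).

## Cross-compound comparison

Compounds are ranked by KA descending (ties broken lexicographically by
ligand id). Group summaries average **lg KA** rather than KA, so a single
strong binder (PFOS, KA ≈ 395) does not dominate a family mean. Ordering
assertions are declared as chained strict inequalities ("PFOS > PFHxS >
PFOA") and evaluated on the fitted constants. Docking summaries (an
AutoDock-Vina-style table of binding energies; docking itself is never
run here) are joined by ligand id, and concordance between spectroscopic
KA and docking affinity (−binding energy) is the Spearman rank
correlation with midranks; with fewer than two matched compounds it is
reported as absent. The coefficient is reported, never thresholded —
the underlying experimental claims are qualitative.

## Statistical behaviour and known limitations

The lg KA estimate is the *intercept* of the log-log line, i.e. an
extrapolation to lg C = 0 from data centred near lg C ≈ −3.3 over a span
of only ~0.7 decades (the dilution ladder's 5:1 to 5:30 range compresses
a 30-fold volume ratio into a 5.1-fold concentration range). Coefficient
noise is therefore amplified ≈ |x̄|/σ_x ≈ 13-fold into the intercept:
with 1% multiplicative intensity noise the intercept standard deviation
is ≈ 0.1 lg units, i.e. a median relative KA error of roughly 10–20%
depending on the quench strength at the chosen parameter point (measured:
≈12% at KA = 150, n = 0.7 over 200 replicates). Single-titration KA
values at this noise level should accordingly be read as order-of-
magnitude-plus estimates; n (the slope) is far better determined.
Passing recovery tests on synthetic data show estimator correctness
under the assumed noise model, not robustness to the systematic effects
real titrations carry (inner-filter attenuation, baseline drift,
pipetting bias), none of which the generator emulates.

Problem sizes throughout the test suite and the reproduction script are
the study's own: 7-point ladders (6 usable points per fit), 29×39 EEM
grids, 200 replicates for the stochastic recovery measurement.
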