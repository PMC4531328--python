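# Methods

## Model summary and assumptions

The package implements a deterministic, semi-empirical "LET efficiency"
model of RBE for charged-particle beams.  Its premises:

* Cell survival is linear-quadratic at every radiation quality:
  SF(d) = exp(−αd − βd²).
* Each ion species has a single turnover LET (LET_U) at which both α and β
  — and hence RBE — peak; past it, extra deposited energy is overkill.
* LET_U saturates with ion charge Z, and the maximal radiosensitivities
  (α_U, β_U) saturate with their low-LET counterparts (α_L, β_L).  All
  three saturation laws are closed-form solutions of dy/dx = slope − rate·y.
* α and β are scaled between their low-LET and turnover values by one
  shared efficiency function of LET.  Using the same efficiency (and hence
  the same LET_U) for both coefficients is what keeps the position of the
  RBE peak invariant as dose or survival level changes; the package asserts
  this symmetry in tests.
* A single effective LET characterises the beam.  Mixed-LET spectra,
  dose-averaged vs track-averaged LET, hypoxia, and neutron spectra are out
  of scope.

The model is intended as a sanity check alongside mechanistic RBE models,
not as a replacement for them.

## Parameters, units, defaults

| parameter | meaning | unit | default | origin |
|---|---|---|---|---|
| anchor_let | LET_U at Z = 1 | keV/μm | 30.5 | proton turnover estimate |
| S, k | initial slope / rate of LET_U(Z) | keV/μm per charge; 1/charge | calibrated | fitted to the packaged 4-point table (S/k ≈ 205.2, k ≈ 0.423) |
| alpha_mode, alpha_c | α_U = c·α_L | – | linear, c = 6.47 | published ion regression, valid for α_L < 0.35 Gy⁻¹ |
| A, j | nonlinear α_U law | Gy⁻¹·Gy; Gy | none | not published for ions; must be user-supplied or fitted |
| beta_mode, R, u | β_U = (R/u)(1 − e^(−u β_L)) | –; Gy² | nonlinear, R = 2.5, u = 25 | published; ceiling R/u = 0.1 Gy⁻² |
| let_c | control (low-LET reference) LET | keV/μm | 1.2 | the worked-example photon value; configurable, never fixed by the source material |
| post_turnover | overkill branch form | – | "reciprocal" | see below |

Constant-β mode (β_U = β_L) is provided because β may reasonably be treated
as LET-invariant at low doses.  Fast-neutron regression coefficients
(α: 2.72 linear / A = 5.37, j = 3.68; β: 1.57 linear / R = 2.29, u = 23.57)
ship as named presets but are flagged unsuitable for ion-beam RBE — neutron
LET spectra sit below the ionic turnover, so they understate α_U and β_U.

## Design choices where the design was open

* **Post-turnover branch.**  The overkill decline admits two readings: an
  inefficiency normalised by LET_U, giving efficiency
  1 − (LET_x − LET_U)/LET_U, or by LET_x, giving efficiency LET_U/LET_x.
  The first goes negative beyond 2·LET_U (α_H below α_L and eventually
  negative — unphysical); the second decays asymptotically to zero and is
  the form the model's own worked arithmetic uses (e.g. 120/240 = 50%
  efficiency at LET 240).  Default is the reciprocal form; a
  `post_turnover="strict"` flag reproduces the other, with efficiency
  clamped at 0.  The post-turnover branch ignores LET_C, accepting an
  infinitesimal derivative discontinuity at LET_U.
* **Below the control LET** the efficiency is undefined and raises rather
  than extrapolating.
* **Zero-dose RBE** (SF = 1) is reported as the analytic limit α_H/α_L with
  a `limit` flag rather than as an error, so curve families have their
  low-dose envelope.
* **High-LET BED.**  The iso-effect right side is implemented as
  m·d_H·[RBE_max + RBE_min²·d_H/(α/β)_L] — the standard high-LET BED, and
  the only dimensionally consistent reading of the relation.
* **Charge as a real number.**  Z is conceptually an integer but the
  saturation law treats it as continuous; the API accepts any real ≥ 1.

## Fitting

All nonlinear fits are deterministic: the saturation forms are linear in
their amplitude for a fixed rate constant, so the rate is profiled over a
400-point log grid spanning 1e−3…1e2 (the upper end covers steep relations
such as u = 25 Gy²), the conditionally optimal amplitude is solved in
closed form at each point, and the best candidate is polished by
Levenberg–Marquardt (tolerances 1e−14).  No stochastic search; identical
data give identical fits, audited against a 50×50 RSS grid in tests.

The Z-fit holds the proton anchor fixed (the relation is constructed as a
normalisation to LET_U(1) = 30.5); `fix_anchor=False` frees it.  Fits are
unweighted by default; per-point weights are accepted.  LQ survival is
fitted as non-negative linear least squares of −ln SF on d and d² with no
intercept, the standard log-scale practice for clonogenic assays.
Standard errors come from the Gauss–Newton covariance s²(JᵀJ)⁻¹ and are NaN
when there are no residual degrees of freedom.

Calibrating to the packaged four-point table gives S/k = 205.17 keV/μm,
k = 0.4231, and predicted turnovers 211 (carbon, Z = 6), 231 (neon, Z = 10)
and 236 (argon, Z = 18) keV/μm — within 0.4–1% of the published nine-ion
family values, though not digit-identical to them, since the family values
were produced by an independent historical fit of the same relation.

## Synthetic survival data

`generate_synthetic_survival` emulates clonogenic LQ survival with
multiplicative lognormal noise of mean 1 and user-chosen coefficient of
variation (a seed is mandatory whenever noise is requested).  It reproduces
the error structure of colony counts to first order but none of the real
complications — plating-efficiency drift, Poisson colony statistics,
between-experiment biological variation, or LET-spectrum spread.  A green
parameter-recovery test therefore establishes correctness of the estimator
under the stated noise model, not fidelity to any laboratory dataset; the
historical survival curves behind the published figures are not available
in machine-readable form and are deliberately not re-digitised.

## Numerical notes

* Iso-effect doses use the explicit positive quadratic root (the negative
  root is never physical for positive effect and β); verified against a
  bisection oracle to 1e−9 Gy on 1000 random draws.
* Efficiency is exactly 1 at LET_U from both branches; continuity there is
  tested to 1e−10.
* Degenerate inputs (all-unity survival, repeated doses, fewer than two
  non-anchor calibration points, α = β = 0) raise `ValueError` rather than
  returning garbage; CLI maps validation errors to exit code 2 and
  non-convergence to 3.

## Known limitations

* The nonlinear ion-beam α_U(α_L) constants are not published; linear mode
  (c = 6.47) is the default and is only supported below α_L ≈ 0.35 Gy⁻¹.
  (A published remark that α_U = 1.18 Gy⁻¹ "by the charge relation" cannot
  be reproduced — that relation maps Z to LET_U, not α_L to α_U — and is
  treated as a typo for the unpublished nonlinear α law.)
* The calibration table has four points and two free parameters; standard
  errors are accordingly wide, and heavy-ion extrapolation (Z > 10) leans
  on the asymptote.
* RBE_max > RBE_min is typical but not assumed; for tissues where β rises
  proportionally more than α the RBE increases with dose, and the package
  computes rather than forbids that regime.
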