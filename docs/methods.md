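# Methods

## Signal model

All three weighted contrasts (PDw, T1w, MTw) are multi-echo RF- and
gradient-spoiled gradient-echo (FLASH) acquisitions.  The steady-state
signal at echo time TE is modelled as

    S_c(TE) = fR_c · S_c(0) · exp(−TE · R2*)

with a single effective transverse relaxation rate R2* shared by all
contrasts of a voxel.  For the PDw and T1w contrasts the TE = 0 steady
state is the Ernst equation

    S(0) = A sin(α) (1 − E1) / (1 − cos(α) E1),   E1 = exp(−TR · R1),

where A is the apparent amplitude (proportional to proton density times
the receive sensitivity), R1 the longitudinal relaxation rate, and
α = fT · α_nominal the local flip angle under the transmit field fT.  For
the MTw contrast the steady state carries an additional per-excitation
saturation δ (in percent units) from the off-resonance MT pulse and is
modelled in the small-angle rational form

    S_MT(0) = A α R1 TR / (α²/2 + R1 TR + δ/100)    (TR in seconds).

This rational form is the exact algebraic inverse of the MT-saturation
map formula below, so a noiseless simulate-then-fit round trip closes
identically for δ; the full steady-state expression differs from it only
at higher order in α² and TR·R1.

## Estimation

**Joint R2* (ESTATICS).**  Taking logarithms makes the decay linear:
ln S_c(TE) = ln S_c(0) − R2*·TE.  All echoes of all available contrasts are
pooled into one ordinary-least-squares fit per voxel with a shared slope
−R2* and one intercept per contrast.  Pooling raises the effective number
of observations behind the slope, which lowers the variance of R2*
relative to per-contrast fits (verified by Monte Carlo in the tests).
The fit is unweighted OLS in the log domain; no iterative reweighting.
Voxels with any non-positive signal among the used echoes are excluded
via the validity mask rather than epsilon-clipped — the masking is
transparent and keeps the estimator's statistics clean.  Negative R2*
estimates are retained internally (residuals and QA use them) and clipped
to zero only in the exported map.  An optional maximum-TE cut can drop
late echoes; the default uses all echoes.

**R1 and A (variable flip angle).**  With two TE = 0 intercepts at
different flip angles the Ernst equation is inverted using the small-TR /
small-flip-angle rational approximations

    R1 = ½ (S_T1 α_T1/TR_T1 − S_PD α_PD/TR_PD) / (S_PD/α_PD − S_T1/α_T1)
    A  = S_PD S_T1 (TR_PD α_T1/α_PD − TR_T1 α_PD/α_T1)
         / (S_T1 TR_PD α_T1 − S_PD TR_T1 α_PD)

with angles in radians and TR in ms (R1 converted to s⁻¹ on output).
These formulas are exact inverses of the rational signal model and biased
with respect to the full Ernst equation by roughly 1% at TR 25 ms,
α = 6°/21° and R1 = 1 s⁻¹ (quantified in the tests against an exact
closed-form inversion, which is possible when both TRs are equal because
E1 is then shared and linear in the two signal equations).  The exact
inversion is deliberately *not* used in the production path: the rational
formulas are the standard estimator for this protocol family and keep the
bias fields' algebra multiplicative.

**MT saturation.**

    δ = 100 · [ (A α_MT / S_MT − 1) R1 TR_MT − α_MT²/2 ]

with TR in seconds and R1 in s⁻¹.  Removing the A, R1 and flip-angle
dependence distinguishes δ from the plain MT ratio.  Because A and R1
enter this formula, the pipeline's δ inherits their rational-approximation
error (~0.7% under the default protocol); fed with exact A and R1 the
formula inverts the simulator's MTw model to numerical precision.

**Unit regimes.**  Deliberately explicit per formula to avoid silent
1000× errors: metadata stores TR/TE in ms; the R1/A formulas work in ms
and convert to s⁻¹ at the end; the δ formula converts TR to seconds.

## Bias corrections

* **Transmit (fT).**  Scales local flip angles in all map formulas.
  Sources: the actual-flip-angle (AFI) two-TR method, inverted with
  cos α = (r·n − 1)/(n − r), r = S2/S1, n = TR2/TR1 — the exact inverse of
  the short-TR interleaved steady state (the relation is first-order in
  TR·R1 against the full two-exponential steady state, an error of
  ~0.1–0.4% at physiological TR/T1, shrinking linearly with TR); or a
  pre-computed map ingested with a median heuristic to auto-detect p.u.
  versus fraction.  AFI maps are smoothed (8 mm FWHM default) by
  normalised convolution so invalid voxels do not leak in.
* **Receive (fR).**  Divides the raw echoes per contrast before fitting.
  Sensitivity maps come from smoothed head/body coil image ratios (12 mm
  FWHM default).  `single` mode shares one map across contrasts and is
  only valid without between-contrast motion; `per_contrast` mode is
  robust to it.  The body coil's own receive profile is not modelled;
  this residual modulation is recorded in provenance as a limitation.
* **Imperfect spoiling.**  T1_corr = Acoef(fT) + Bcoef(fT)·T1_app with
  user-supplied, protocol-specific polynomials; disabled (identity) by
  default since no universal coefficients exist.
* **MT residual B1.**  δ_corr = δ(1 − C)/(1 − C·fT) with C = 0.4 by
  default (configurable); an empirical constant describing the residual
  transmit dependence of the MT pulse's saturation efficiency.
* **Order** (fixed, recorded in provenance): receive correction → decay
  fit → transmit-dependent maps → spoiling correction of R1 → δ → MT B1
  correction → PD calibration.

**PD calibration.**  PD = A · target / mean(A over mask).  With a
user-supplied white-matter-like mask the default target is 69 p.u.; with
no mask the validity-mask mean is set to 100 p.u. and the map is marked
"uncalibrated-relative" in provenance.

## Tissue-weighted (VBQ) smoothing

Plain Gaussian smoothing mixes values across tissue boundaries and biases
quantitative maps there.  Tissue-weighted smoothing computes
p = [g⊛(w·q)] / [g⊛w] per tissue class, a Gaussian-weighted within-class
mean, defined only where the smoothed weight exceeds a threshold (default
0.05 after normalising w to unit maximum, making the result exactly
invariant to global weight rescaling).  Boundary handling is zero padding
(weights vanish outside the head and absorb the edge effect; replicate
padding is available).  Output voxels outside the support carry a NaN
sentinel plus an explicit companion mask — never silent zeros, because
zero is a valid map value.  Segmentation and nonlinear registration are
consumed as inputs (pre-computed weight maps from any tool), not
implemented.

## Quality assessment

Two descriptive indices from the joint fit: the pooled SD of log-domain
residuals per contrast within a mask (a proxy for intra-scan degradation
such as motion; SD rather than MAD, pooled over voxels and echoes), and
the median-absolute-deviation of voxelwise log-intercept differences per
contrast pair after removing the mask median (sensitive to spatially
varying inter-contrast inconsistency, exactly insensitive to global
scaling).  No pass/fail thresholds: the report is descriptive and labels
both indices as proxies.

## Digital phantom

The simulator emulates exactly the input format the pipeline consumes:
per-echo NIfTI volumes with BIDS-convention JSON sidecars, plus a
`truth/` tree.  The layered phantom has three concentric ellipsoidal
compartments with brain-like values — cortex-like (R1 0.65 s⁻¹, R2*
17 s⁻¹, A 850, δ 1.0 p.u.), white-matter-like (1.05, 21, 690, 1.9) and an
iron-rich deep-grey core (0.90, 30, 800, 1.3) — chosen so the
rational-approximation error stays within its documented envelope over
the foreground (a CSF-like R1 ≈ 0.25 s⁻¹ would push the approximation
error above 2% and was deliberately excluded from the foreground).
Transmit and receive fields are smooth random quadratics, normalised so
the configured range (±20% fT, ±15% fR, ±5% per-contrast fR deviation by
default, emulating between-contrast motion) is attained inside the
foreground.  Noise is Gaussian (additive) or Rician
(|S + n₁ + i·n₂|), drawn independently per echo volume from a seed stored
in the phantom, so runs are exactly reproducible.

What the phantom does **not** emulate: k-space artefacts, motion between
or within scans (beyond distinct per-contrast fR fields), spoiling
imperfection, chemical shift/susceptibility effects, or spatially
correlated noise.  Passing the round-trip tests therefore demonstrates
the correctness of the estimators and the bias-correction algebra, not
robustness to every real-world confound.

## Numerical choices and problem sizes

* Grid tolerance on affines: 1e-4 absolute; no resampling anywhere —
  inputs must be pre-aligned.
* Non-finite input voxels are zeroed, counted, and excluded via the
  validity mask.
* Degenerate variable-flip-angle protocols (identical effective angles)
  raise immediately; voxelwise degeneracies (non-positive signals or
  rates) are masked, not clipped.
* End-to-end validation runs on a 48³ phantom (≈40k foreground voxels);
  Monte-Carlo checks use 200 single-voxel repetitions at echo-1 SNR 50
  and 5 noise levels × 50 repetitions on a 16³ phantom — sizes chosen so
  the whole validation completes in seconds while keeping Monte-Carlo
  error far below the tested effect sizes.

## Known limitations

* The rational approximations bias R1 low by ~1% (protocol-dependent);
  the exact inversion exists in the test oracles only.
* Rician noise biases the magnitude signal at low SNR; no Rician bias
  correction is applied (out of scope).
* Data-driven (segmentation-based) transmit/receive estimation, DICOM
  import, reorientation, registration and group statistics are out of
  scope; the SE/STE EPI B1 family is supported only through pre-computed
  maps.
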