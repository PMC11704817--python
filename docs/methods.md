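# Methods

## Power-vector conventions

A spherocylinder (S, C × α) maps to (EQ, C0, C45) with EQ = S + C/2,
C0 = C·cos 2α, C45 = C·sin 2α, where α is the cylinder axis — the flat
corneal meridian when keratometry is written in plus-cylinder form. The
sign convention is fixed so that with-the-rule astigmatism (steep meridian
60–120°) has positive C0 and against-the-rule negative C0.

Two details are easy to get wrong and are therefore locked by tests:

* **Factor of two.** C0/C45 are *full-cylinder* projections, twice the
  Jackson-cross-cylinder J0/J45. Consequently the defocus equivalent is
  `DEQ = sqrt(EQ² + ¼C0² + ¼C45²)` with ¼ (not 1) on the astigmatism terms.
* **Laterality.** Left and right eyes are mirror-symmetric about the
  vertical; analyses run in the right-eye convention by flipping the sign
  of C45 for left eyes (equivalently mirroring every angle θ → 180 − θ).
  The synthetic generator samples in right-eye convention and mirrors
  angles when writing device-frame records; modelling tables mirror them
  back. The orientation classes WTR/ATR are mirror-invariant; the two
  oblique sub-bands exchange but remain OBL.

Internally a spherocylindrical power or vergence is the symmetric matrix
m11 = EQ − C0/2, m22 = EQ + C0/2, m12 = −C45/2, whose eigenvalues are the
principal powers. The matrix form is what allows adding and propagating
surfaces with non-aligned astigmatic axes without any axis bookkeeping.

## The pseudophakic eye model and RCP

Three thin refracting elements: spectacle plane (vertex 12 mm, n = 1.0
to the cornea), cornea, toric IOL at the Haigis effective lens position
ELP = a₀ + a₁·ACD + a₂·AL (a₀/a₁/a₂ = 0.912/0.4/0.1 for the AT TORBI 709,
0.96/0.4/0.1 for the AT LISA 939), aqueous n_A = 1.336 between cornea and
IOL, vitreous n_V = 1.336 to the focal plane at the axial length. The
object sits at the 6 m refraction lane, i.e. −1/6 D at the spectacle plane
(applied literally, not approximated as 0). The vergence behind the IOL
aimed at the retina is the reciprocal of the *reduced* distance,
n_V/(AL − ELP) in dioptres with lengths in metres — the only reading of
"spherical vergence (AL−ELP)/n_V" that is dimensionally meaningful.

Reconstruction subtracts the forward-propagated spectacle vergence (path A)
from the backward-propagated retinal vergence (path B) at the corneal
plane. The forward model (`simulate_refraction`) applies the same chain in
reverse order, which makes the pair exactly inverse by construction; the
test suite verifies `reconstruct ∘ simulate = identity` to 1e-9 D over
1000 random eyes including oblique toric IOLs, and agreement with an
independent scalar per-meridian vergence chain for aligned/spherical cases
to 1e-12 D. A vergence focusing exactly at the next surface raises a
`DegenerateVergenceError` rather than returning infinities.

Labelled toric IOL powers are vectorized as principal powers
IOLSEQ ∓ IOLC/2 at the marked flat axis IOLMA / IOLMA + 90°.

## Nomogram models

**REG.** Multivariate linear regression of the RCP vector on the
preoperative corneal power vector, with intercept. With complete data and
multivariate-normal residuals the maximum-likelihood optimum coincides
with per-component ordinary least squares, so the fit is a single `lstsq`
solve; iterative ECM-style fitting engines reach the same optimum and are
not reimplemented. The reported logL is the Gaussian log-likelihood at the
ML plug-in residual covariance, −n/2·(d·log 2π + log det Σ̂ + d). The
published coefficient sets (both 3×3 matrices and intercepts) are stored
verbatim and locked by transcription tests.

**NET.** A 3-12-8-3 feedforward network. Unstated implementation choices
were resolved as follows and are configurable: tanh hidden activations
with a linear output (the conventional choice for shallow regression
networks of this shape); z-scoring of inputs *and* outputs, since EQ ≈ 44 D
against astigmatism components ≈ 0 D makes raw-scale training badly
conditioned; the Adam optimizer (deterministic under the stored seed) with
early stopping on a held-out 15% of the training data, max 4000 epochs,
tolerance 1e-7. Fitting is delegated to scikit-learn's `MLPRegressor`; the
learned weights are extracted into a self-contained, JSON-serializable
`NetworkModel` whose forward pass is pure numpy, so saved models predict
bit-identically without scikit-learn state. Non-convergence is surfaced
via the fit report and the optimizer's warning.

**Crossvalidation.** Random 70/30 split with training size
`round(0.7·N)` (309/133 at N = 442), reproducible under seed. Performance
metrics are the mean difference vector (MDV, mean Euclidean norm of the
3-component residual) and the generalized MSE (mean squared norm); MDV ≤
√MSE by Jensen's inequality, which every fit report must satisfy. Both
metrics include the EQ component; the published (MDV, MSE) pairs are
consistent with that 3-component reading and are asserted as inequality
consistency checks only, since the underlying clinical per-eye data are
not available.

## Error ellipses and other outcome statistics

The 95% error ellipse of the (C0, C45) residuals uses the sample
covariance Σ and the large-sample χ²₂ scaling k = χ²₂(0.95) ≈ 5.9915:
semi-axes √(k·eigenvalues), area π·k·√det Σ. No small-sample F correction
is applied — under this convention independent SDs of 0.5138 and 0.5061
with zero correlation give 4.89 D², reproducing the published figure for
the RCP − preoperative-keratometry comparison. (The published 3.52 D² for
RCP − postoperative total corneal power is incompatible with the same
table's SDs, which bound the area at ≈1.18 D²; only the internally
consistent value is used as a check.) Ellipse coverage is validated by
simulation: 95% ± 1% of a bivariate-normal sample falls inside its own
ellipse at n = 10⁵.

Acuity regressions are ordinary least squares of LogMAR acuity on a
dioptric predictor (DEQ, |REFEQ| or residual cylinder), with the slope
also reported in decimal lines per dioptre (10 × LogMAR/D) and the exact
t-test p-value for Pearson R. Axis-binned cylinder summaries use 8 bins of
22.5° over [0°, 180°) (180° wraps to 0°), a ≥0.25 D cylinder inclusion
threshold, and per-bin means/medians plus a within-bin cumulative density
grid; empty bins yield NaN, never silent zeros.

## Synthetic cohort

The generator emulates a toric-IOL case series end to end; its defaults
are the source cohort's published marginal statistics:

| quantity | default | origin |
|---|---|---|
| AL | N(23.6688, 1.2167²) mm, truncated 20–30 | cohort table |
| ACD | N(3.1219, 0.4232²) mm, truncated 2–4.5 | cohort table |
| AL–ACD correlation | 0.4 | assumed (not reported) |
| preop K (EQ, C0, C45) | N(43.7843, 1.5160²), N(−0.1401, 1.2984²), N(−0.1152, 0.6970²) D | cohort table |
| TK − K offset | (+0.0631, −0.1648, −0.0439) D + N(0, 0.05²) | cohort table differences |
| surgical change | N(0, 0.10²) D per component, shared by K and TK | small, zero-mean (paralimbal 1.8 mm incisions) |
| IOL axis misalignment | N(0, 3²) deg | plate-haptic stability |
| refraction noise | N(0, 0.25²) D per component, then 0.25 D steps | calibrated to the cohort's mean residual cylinder 0.39 D |
| acuity | UDVA = 0.015 + 0.22·DEQ + N(0, 0.10²), floor −0.2 | 2.2 lines/D decay |
| lens mix | 63.8% TORBI / 36.2% LISA; 51% right eyes | cohort counts |

IOL powers are chosen by per-meridian scalar vergence targeting of
emmetropia on the preoperative total corneal power, rounded to 0.5 D
(cylinder floored at 1.0 D, capped at 12 D), with the marked flat axis on
the steep corneal meridian. Astigmatism axes arise implicitly from the
component-wise Gaussians — all orientations are populated, with the
ATR-shifted means of the source data — rather than from an explicit axis
mixture.

**Ground-truth mode** replaces the physical postoperative cornea with
`map(preoperative keratometry vector) + isotropic noise` for a supplied
linear map and disables refraction noise/quantization, so that fitting the
reconstructed RCP against preoperative keratometry recovers the map's
coefficients exactly up to sampling error. With the published keratometry
nomogram as truth and σ = 0.27 D (so 3σ² ≈ 0.22 D², the published test
MSE), n = 10⁴ recovers every weight-matrix entry within ±0.02 (slope
standard errors are 0.002–0.004 D). The intercepts are checked at ±0.30:
their standard errors are ~0.08 D because the EQ regressor has mean
43.8 D against SD 1.5 D, so a ±0.02 intercept band would be rejected by a
perfect implementation most of the time.

What the generator does **not** emulate — and hence what passing tests do
not establish about clinical data: IOL-power labelling tolerances and
formula prediction error (the synthetic spherical-equivalent scatter,
SD ≈ 0.30 D, is below the clinical 0.63 D), lens tilt/decentration,
irregular astigmatism, joint correlations beyond AL–ACD, and any
systematic nonlinearity in the keratometry→RCP relation (the ground-truth
mode is linear by construction, which is exactly why the network cannot
beat the regression on held-out synthetic data).

## Problem sizes and numerical choices

Round-trip properties run at 1000 random configurations (tolerance
1e-9 D); coverage simulations at n = 10⁵; parameter recovery at n = 10⁴;
the network-vs-regression comparison at n = 2000 over 5 seeds — sizes
chosen to keep Monte-Carlo error well below the asserted tolerances while
the full suite runs in well under a minute. Matrix inversion guards reject
translations with |det| < 1e-9; residual covariances are floored by
machine epsilon on the diagonal before log-determinants; axis arithmetic
is mod-180 throughout, with 180° wrapping to 0°.
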