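# Methods

`iclvol` implements the quantitative chain used to characterize a
volume-sensitive chloride conductance (I_Cl,vol) in articular chondrocytes
from a joint-destabilization (ACLT) osteoarthritis model: solution chemistry,
whole-cell voltage-clamp analysis with Boltzmann conductance fitting, a
cell-swell imaging assay, and caspase-3/7 plate statistics.  Because no raw
recordings are deposited for this kind of study, every stage is paired with a
seeded synthetic generator that emulates the published study conditions, so
the full chain is testable end to end.

## Solution chemistry

Recipes are lists of chemicals with concentrations in mM.  `dissociate`
expands them stoichiometrically assuming full dissociation of strong salts
(di-/tri-valent chloride salts contribute 2×/3× Cl⁻); Hepes, EGTA and
Tris-ATP count as osmotically active particles with ~zero net charge at
pH 7.2–7.4 and no free Cl⁻.  Under these assumptions the pipette recipe
carries 54 mM Cl⁻ and the iso-osmotic bath 108.09 mM, giving a chloride
Nernst potential E = (RT/zF)·ln([Cl]_out/[Cl]_in) of −18.5 mV at 310.15 K —
magnitude 19 mV, matching the calculated reversal reported for this
preparation.  The recording temperature is a configurable field defaulting to
37 °C (310.15 K); at room temperature the magnitude would round to 18 mV.

Charge balance is enforced as a warning, not an error, because aspartate and
Hepes charge states are approximations.  `nominal_osmolarity` is the plain
particle sum with no osmotic coefficients; for the patch bath it gives
377.6 mOsm/L against a measured ~360 mOsm — the gap is expected and the value
is documented as nominal, not as an osmometer prediction.

## Voltage-clamp simulator

The membrane model is a Boltzmann-gated conductance with ohmic driving force
plus an optional linear leak:

    I(t) = C·[ g(V)·(V − E_rev) + g_leak·(V − E_leak) ]·10⁻³  (pA)
    g(V) = g_max / (1 + exp(−(V − V_h)/k)),  k > 0

with conductance densities in pS/pF, voltages in mV and capacitance in pF
(default 10 pF).  The printed form of the Boltzmann equation in the source
literature is typographically ambiguous; the adopted form is the only one
producing an outwardly rectifying activation curve in which a "steeper slope"
means a smaller k.

Protocols: a square-step family (holding −30 mV; 200 ms test steps from +80
to −100 mV in 10 mV decrements, 19 sweeps; 50 ms pre/post holding segments)
and constant ramps (|dV/dt| = 0.25 V/s, repeated at 6 s onsets).  Sampling is
1 ms.  Capacitive transients are not modeled because the analysis reads only
steady-state windows; gating is instantaneous by default, with an optional
first-order relaxation (5–20 ms is realistic) to exercise the windowed
averaging.  A "switch" condition blends the isotonic into the hypotonic
channel state with a configurable osmotic transition time constant, emulating
bath exchange.  Additive Gaussian current noise (default 5 pA) is drawn from
a mandatory per-cell seed; identical seeds give bit-identical traces.
Channel blockers are represented only as a scalar g_max multiplier.

## Analysis chain

* `step_iv` averages the final 20 ms of each 200 ms step (configurable) and
  divides by capacitance.
* `difference_current` is the pointwise hypotonic-minus-isotonic density on
  an identical voltage grid within one cell; no interpolation across cells is
  allowed.  Any background conductance common to both conditions cancels
  exactly, which is the property that isolates the swelling-activated
  component.
* `estimate_reversal` interpolates the zero crossing linearly; with several
  crossings the one nearest the configured expectation is taken.
* `conductance_transform` divides by the driving force (V − E_rev), excluding
  voltages within 10 mV of the reversal (configurable) where the division is
  unstable.
* `fit_boltzmann` is nonlinear least squares with an analytic Jacobian and a
  deterministic start grid (V_h ∈ {−40, 0, 40} mV × k ∈ {15, 40} mV, g_max =
  max observed conductance); the best-RSS solution wins, ties broken toward
  the lower V_h.  On noise-free simulated data the chain inverts the
  generator to ~1e−13 relative error across a wide parameter grid.
* A liquid-junction-potential correction is a single configurable offset
  subtracted from command voltages, default 0.

### Confidence intervals

The default 95 % CIs are a seeded percentile **wild bootstrap with HC3
leverage adjustment** (resampled value = fit + residual/(1−h)·ξ, ξ ~ N(0,1),
1000 resamples by default, warm-started refits).  The driving-force division
makes conductance residuals strongly heteroscedastic — noise is ~9× larger at
the retained voltage nearest the reversal than at +80 mV — and a plain iid
residual bootstrap measurably undercovers there (V_h coverage ≈ 91–92 % at
nominal 95 % in a 500-replicate simulation).  The wild scheme keeps each
voltage's own residual magnitude and restores calibration (V_h 94 %, k 95 %).
Asymptotic covariance CIs (Student-t quantiles) are available as the fast
alternative and are used wherever a point estimate alone is needed.

### Multiple comparisons

Benjamini–Hochberg adjustment delegates to statsmodels.  Dunnett-style
many-to-one comparisons use a seeded Monte-Carlo reference distribution of
max|T| under the global null (group means and the pooled variance simulated
directly; ≥10⁵ draws by default) rather than tabulated critical values, which
makes the family-wise error rate directly testable: 2000 null simulations on
the unbalanced swell design give FWER ≈ 4.8 % at α = 0.05, and the p-values
agree with the multivariate-t implementation in scipy to ±0.01.

## Swell assay

Cells are rendered as anti-aliased bright disks on a dark background
(192×192 px, 0.25 µm/px) whose area follows a saturating exponential toward a
plateau relative area P with rise time constant 90 s, optionally opposed by a
slower RVD term (off by default — the 5-min window shows monotone swell).
Group defaults are the published cohort parameters: initial areas
875/726/935 µm² and 5-min relative areas 1.06/1.08/1.11 for control/2-week/
4-week cohorts of 15/21/11 cells.  The printed initial sizes carry the
ambiguous unit "µm"; they are interpreted as cross-sectional areas in µm².
Per-cell biology is emulated by jittering the swell amplitude (fractional SD
35 %) and initial area (5 %); frames carry 1 % area jitter and Gaussian pixel
noise (5 % of contrast).  The generator reproduces the group mean time
courses; the printed between-cell CIs imply a somewhat larger biological
spread than the default jitter produces, so passing tests demonstrate the
measurement chain, not the full biological variance structure.  Segmentation
is Otsu threshold → largest connected component → pixel count × scale²,
accurate to ≤2 % on noise-free disks (and much better after per-cell
normalization, which cancels the consistent edge bias).  Normalization
divides by the pre-challenge (t ≤ 0) frame, making each cell its own control.

## Caspase-3/7 plates

Wells are lognormal around group geometric means expressed as folds vs
control (defaults 1.00/1.24/1.52/2.15/1.00/1.05 for control/2w/4w/TNFα/
DCPIB/TNFα+DCPIB; the last two are nominal near-unity choices since only
"not significant" is reported), CV 6 %, n = 20.  Analysis normalizes to the
control-group mean per plate (scale-invariant), summarizes folds with a
delta-method ratio CI — a fold is a ratio of means, so the control mean's own
uncertainty must propagate; a plain t-CI of fold values covers the generating
fold only ~84 % of the time versus ~95 % for the ratio CI — and compares
groups against control with the shared Monte-Carlo Dunnett procedure.  The
2-week vs 4-week contrast is reported as a planned two-sided t test.

## Numerical and testing choices

* All randomness flows through explicit integer seeds (numpy Generator);
  every pipeline stage requires a seed in its configuration and reruns are
  byte-identical.
* Calibration test sizes: bootstrap coverage uses 500 noisy replicates × 399
  resamples; the Dunnett FWER check uses 2000 null datasets × 10⁴ reference
  draws; the fold-CI recovery check uses 500 plates.
* Degenerate inputs fail loudly: unknown chemicals, non-reversing I-V curves,
  all-excluded conductance points, identical iso/hypo conditions (zero
  difference), zero-variance groups, blank frames.

## Known limitations

* The simulator is a deterministic two-state conductance; it does not model
  single-channel stochasticity, series resistance, capacitive transients or
  pharmacological kinetics.
* The swell generator renders single centered disks; multi-cell scenes,
  bright-field artifacts and true 3-D volume changes are out of scope.
* Osmolarity is ideal; activity coefficients and multi-ion (GHK) reversal
  potentials are deliberately not implemented.
* The per-voltage drug analysis of the full factorial (voltage × drug) model
  is out of scope; blockers appear only as fractional g_max inhibition.
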