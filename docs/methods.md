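# Methods

## Scope and model

`paglucose` implements the full analysis chain of a single-wavelength
mid-infrared photoacoustic (PA) glucose measurement on skin phantoms, with a
seeded generator standing in for the instrument. The physical layer keeps
only the closed-form laws that drive the analysis:

- **Thermal diffusion length** μ = √(D/(π f)) for the coupling gas or the
  sample at modulation frequency f.
- **Gas-coupling factor** F = γ·P₀·t(λ)·I₀·μ_g / (c₀·l_g·T₀). Printed
  variants of this formula disagree on the denominator constant, so c₀ is a
  parameter; the default is the conventional 4√2.
- **Amplitude law** A_PA ∝ I₀·α / (V₀·f^{3/2}). This is the glucose
  mechanism: the absorption coefficient α grows with concentration, and the
  amplitude law is linear in α.

The cell is a lumped two-mode resonator (16.50 and 21.80 kHz). Heat
diffusion, cell acoustics (finite-element level) and laser drivers are out
of scope.

## The synthetic study

The generator reproduces the statistical structure of a three-day phantom
experiment: 3 days × 10 rounds × 10 concentrations (75…300 mg/dL, step 25)
at 6 N/cm² contact pressure, swept 10–30 kHz in 150 Hz steps (134 points;
the last grid point is 29.95 kHz because the span is not a multiple of the
step and the feature count is fixed at 134).

**Deterministic part.** Each sweep is a baseline plus two resonance lines.
Lines are power Lorentzians, 1/(1+u²)² with u=(f−f₀)/γ — the power response
of a driven resonant mode, whose fast tail decay keeps the 16.5 kHz line's
leakage into the 19–23 kHz analysis band near 1 %. Mode half-widths default
to γ = f₀/(2Q) ≈ 1 kHz (visual peak span ≈ 2 kHz). The 21.8 kHz line height
scales affinely with concentration through the amplitude law:
α(c) = α₀·(1 + 0.023·(c−75)/25), i.e. 2.3 % of the base per 25 mg/dL step.
Contact pressure multiplies the response by 1 + p/9 N cm⁻² (signal doubles
at 9 N/cm²), and amplitudes clip at the cell's amplification limit —
operating below that limit is what preserves the inter-class differences.

**Carbon reference.** A noise-free, strictly positive, glucose-independent
spectrum sharing the resonance structure with broadened lines
(heights 4.0/0.8, width scale 2.2, floor 0.05). These constants were fixed,
once, to make the deterministic part of the pipeline self-consistent: with
them the noise-free normalized band integral at 75 mg/dL is ≈2.2 and the
glucose-independent in-band contribution (16.5 kHz tail + baseline) biases
the adjacent-resolution statistic by < 0.5 % relative. Note a structural
property of the affine height law: the resolution statistic is a mean of
ratios, so even noise-free it evaluates to ≈2.09 % rather than exactly
2.3 % (the first adjacent pair gives exactly 2.3 %, later pairs slightly
less against their larger denominators).

**Stochastic part.** Four components, switched off cleanly by
`StudyPlan.noise_free()`:

1. *Coupling-gain jitter* — one multiplicative factor per scan (laser power
   drift, contact coupling). Its sd is calibrated per concentration so that
   the realized sd of the carbon-normalized band integral equals the
   study's measured per-concentration values (`MEASURED_INTEGRAL_SD`,
   ≈2–3×10⁻²): the scan-level share is √8/3 of the target and the
   per-(day, concentration) offset (phantom degradation between days, new
   samples each day) carries the remaining third.
2. *Contact frequency shift* — one whole-spectrum shift per scan,
   N(0, 15 Hz). Rectification aligns sweeps to whole bins, so a sub-bin
   residual remains; 15 Hz keeps that residual's contribution to the
   integral noise well inside the calibrated budget.
3. *Bin noise* — iid N(0, 0.002) per frequency point (microphone/lock-in
   floor; peak amplitudes are O(5)).
4. *Noise bursts* — with probability 0.06 per scan, a 2–3-bin positive
   transient of height 0.5–1.0 placed below the analysis band (ambient
   transients amplified around the first resonance). These are the
   outliers the moving-median stage exists to remove; placing them outside
   19–23 kHz reflects that the band statistics (`MEASURED_INTEGRAL_SD`) already
   include all in-band variability.

The free constants with no published value — bin-noise sd, shift sd, burst
rate and size — were calibrated once so the study reproduces the reported
operating point of the real experiment (≈87–89 % raw and ≈92–94 %
preprocessed cross-validated accuracy, against reported values of 86.7 %
and 90.4 %), then frozen. They are ordinary `StudyPlan` fields and can be
changed freely.

An ambient-background model (`generate_background_pair`) emulates the
acoustic absorption panels: the damped spectrum's mean is (1−s) times the
noisy one's; at the panels' measured s = 0.78 the suppression metric
returns ≈78 %.

## Signal chain

- **Rectification** aligns each sweep's in-band argmax to the median argmax
  across the record set (ties break toward lower frequency; the reference
  bin uses the floor of the median). Shifts are whole bins; bins entering
  from outside the grid are edge-padded, never wrapped into the band.
- **Normalization** is the pointwise ratio to the carbon reference
  (a scalar-reference mode is deliberately not the default; pointwise
  division is what cancels the system response shape).
- **Band integral** is the trapezoid over 19–23 kHz divided by the band
  width — a mean amplitude, invariant to grid refinement, which keeps the
  resolution statistic grid-free.
- **Adjacent resolution** = mean over adjacent concentration pairs of
  100·(A_{i+1}−A_i)/A_i; **calibration** is an OLS line of integral vs.
  concentration with Pearson R (per-day means for the headline figure;
  per-round also reported).
- **Moving-median outlier filter**: a point is an outlier when it deviates
  from the median of its asymmetric window (10 samples back through 2
  forward, the point included — the common matrix-tool semantics for a
  [10 2] moving window) by more than 2.3 × scaled MAD (MAD × 1.4826);
  flagged points are replaced by the window median. On pure Gaussian noise
  the realized flag rate is ≈5 % (the 13-point window's MAD underestimates
  dispersion; the asymptotic rate at threshold 2.3 would be 2.1 %).

## Classifier

The feature table is the 300 × 134 matrix (rows ordered day → class →
round, columns ascending frequency, label = concentration; 30 rows per
class). The random-subspace ensemble trains each of 30 base learners on 67
feature columns drawn uniformly without replacement, independently per
learner; the base learner is 1-NN (a linear discriminant is selectable).
Prediction aggregates hard votes; ties break to the lowest concentration.
Evaluation is seeded stratified 10-fold cross-validation (a grouped-by-day
mode is provided, because day effects make within-day replicates easier to
classify than unseen-day data — see Limitations). Preprocessing applies the
moving-median filter down each feature column *within a class block*, so
the window compares replicate scans of the same phantom set and never
spans two concentrations; for record sets shorter than the window the
look-back is clamped. Metrics: overall accuracy, per-class
precision/recall (TPR), FNR, F1 and macro-F1 (classes are balanced, so
macro equals weighted), plus the 10 × 10 confusion matrix.

## Clinical evaluation

Clarke zones follow the original piecewise boundaries as commonly
implemented; boundary points go to the lower-risk zone so the assignment is
deterministic. The confusion matrix converts to a weighted EGA point set
(mass conserved). Majority voting takes the modal prediction per group —
per class (30 scans) by default, which is the grouping that reproduces the
all-diagonal zone-A result; per (day, sample) grouping (10 scans) is also
available. Vote ties resolve to the label nearest the group's median
prediction, then to the lower concentration. The regulatory check passes
when zones A+B hold ≥ 99 % of the points.

## Numerical and design choices

- Whole-bin rectification (no sub-bin interpolation): matches the discrete
  sweep character; the residual sub-bin misalignment is treated as part of
  the measurement noise budget.
- The day effect is drawn per (day, concentration) — each day uses freshly
  prepared phantoms — at one third of the per-concentration integral sd.
- Per-fold ensemble seeds derive deterministically from the run seed, so an
  identical configuration reproduces every report byte for byte.
- Degenerate inputs fail eagerly with domain errors (empty record sets,
  non-positive reference spectra, bands outside the grid, classes smaller
  than the fold count, subspaces wider than the feature count).

## What the generator does and does not capture

It captures: the per-concentration dispersion of normalized band integrals,
the day-to-day offsets, contact-induced frequency shifts, amplitude
saturation, occasional impulsive outliers, and an affine
concentration-to-amplitude response. It does not capture: phantom
chemistry, FT-IR optical properties, microphone transfer functions, drift
within a day, correlated (non-impulsive) interference, or any in vivo skin
variability. Passing tests therefore demonstrate that the *pipeline*
reproduces the study's statistics under a faithful noise model — not that
the instrument itself would.

## Limitations

- Stratified cross-validation mixes days within the training folds, so
  replicates of a test scan's own (day, class) cell are available to the
  classifier — the same protocol as the original analysis, but optimistic
  relative to deployment on unseen days. The grouped-by-day mode quantifies
  the gap.
- The affine height law makes the ratio-based resolution statistic
  systematically ≈0.2 percentage points below the nominal per-step
  increment (mean-of-ratios effect, see above).
- The Clarke implementation covers the classic five-zone grid only; Parkes
  and ISO 15197 bands are out of scope.
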