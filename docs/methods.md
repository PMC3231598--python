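# Methods

This note documents the models, estimators, numerical choices and known
limitations of the `etongue` package.

## Forward sensor model

Electrode potentials follow the Nikolsky-Eisenmann law

    E = e0 + s · log10( a_i + a_bg + Σ_j 10^(log k_j) · a_j^(z_i/z_j) )

with all activities in mol/L and potentials in mV.  Points of note:

* **Signed charge-ratio exponents.**  For the anion pairs handled here both
  exponents are positive: a perchlorate electrode (z = −1) sees sulfide
  (z = −2) through `a_S^(1/2)`, and a sulfide electrode sees perchlorate
  through `a_ClO4^2`.  The squared exponent makes sulfide electrodes nearly
  immune to perchlorate at trace levels even for moderate selectivity
  coefficients — which is why their fixed-interference characterization
  needs molar-level interferent backgrounds (see below).
* **Low-end flattening.**  The additive background activity `a_bg` bends the
  calibration curve into a plateau as `a_i → 0`.  The IUPAC two-segment
  detection-limit construction applied to this response recovers exactly
  `a_bg`, tying each electrode's detection limit to a testable mechanism.
  Panel files therefore declare the detection limit (the measurable
  quantity); `a_bg = γ(z, I_ref) · LOD` is derived at load time at the
  calibration reference ionic strength (0.05 M).
* **The generic electrode.**  The quaternary-ammonium membrane G responds to
  both anions with a Hofmeister-type preference for lipophilic perchlorate
  (its selectivity coefficient measured with sulfide as primary exceeds 1).
  A single Nikolsky-Eisenmann law cannot reproduce both of its measured
  characterizations simultaneously, because the membrane's sulfide response
  is a mixed S²⁻/HS⁻ process outside the model class.  G is encoded with its
  *preferred* ion as primary — perchlorate, slope −60.1 mV/decade,
  log k_pot(S²⁻) = −1.25, detection limit 7.5e-6 M — which keeps the
  simulated electrode cross-responsive to both ions across the working
  range, as the array premise requires.  (The alternative sulfide-primary
  encoding, slope −44.3 with log k_pot(ClO₄⁻) = +1.13, degenerates to a
  fifth sulfide electrode in-range: the squared exponent crushes the
  perchlorate term at trace levels.)  The super-Nernstian −44.3 mV/decade
  sulfide slope is thus not reproduced; no hydrolysis/speciation model is
  attempted.
* **Activities.**  Davies equation by default
  (`log10 γ = −A z² (√I/(1+√I) − 0.3 I)`, A = 0.511 at 25 °C, valid to
  I ≈ 0.5 M), extended Debye-Hückel as a configuration option, and an
  `ideal` (γ = 1) formalism for algebraic tests.  Ionic strength counts the
  Na⁺ counter-ion of each salt (`I = I_bg + c_ClO4 + 3 c_S`) plus a fixed
  background term representing the 0.05 M lithium-acetate electrolyte used
  in single-ion calibrations; mixture and application measurements are
  simulated without background, as unbuffered measurements.
* **Noise model.**  Additive Gaussian noise per reading (default
  0.5 mV — the "low instrumental noise" regime) and an optional per-session
  Gaussian shift of e0 (default 2 mV) representing day-to-day drift.  With
  these defaults the slope RSD of the steep perchlorate electrode across
  five sessions averages ≈ 0.7%, inside the observed sub-1% band;
  shallow-slope sulfide electrodes show proportionally larger slope RSD
  (~2.5%) because the same mV noise is a larger fraction of their
  sensitivity.  Temperature is fixed at 25 °C.

## Synthetic experiments

All experiment tables are pure functions of (configuration, seed).

* **Cumulative additions.**  Series are built by exact mass balance:
  `c_new = (c V + c_stock v)/(V + v)`, all ions diluted per step.  Stocks
  are restricted to the laboratory ladder {1e-4, 1e-3, 1e-2, 1e-1, 1} M;
  addition volumes are solved backward from target-concentration ladders,
  choosing the smallest stock at least 25× the target so volumes stay in
  the microliter-to-milliliter range.
* **Mixture design.**  Seven sequences (12+12+12+11+11+11+10 = 79 samples):
  one single-ion ramp per ion (axis points), one combined equal-ramp
  (diagonal), two hold-one-ion-low ramps and two alternating unequal ramps
  (interior coverage).  Per-ion concentrations span exactly
  5.0e-6–3.3e-4 M using two stock levels per ion.  The exact pipetting
  volumes of the original protocol are not public; the shipped sequences
  reproduce the published aggregates (sample count, range endpoints, stock
  levels, axis + interior coverage), which are the reproducible surface.
* **Train/test split.**  59/20 at random, except that any sample attaining
  a per-ion (nonzero) design minimum or maximum is forced into training, so
  the external test subset never requires extrapolation.
* **Spiked application samples.**  Six samples with per-ion baselines drawn
  uniformly from 0.3e-6–3.4e-5 M, spiked from the 0.01 M standard by the
  same mass-balance arithmetic.  Final per-ion levels are six log-spaced
  targets from 5e-5 M to the stated 5.0e-4 M maximum, paired between the
  two ions by a seeded permutation.  Two consequences are deliberate: (i)
  the top sample lies ~1.5× above the response model's training range, so
  the network genuinely extrapolates there, and (ii) independent pairing
  produces strongly interference-dominated compositions (low perchlorate
  with high sulfide), a stringent test of mixture resolution.
* **Selectivity runs** are direct concentration grids (constant interferent,
  13 log-spaced primary levels spanning ±2 decades around the expected
  flattening), not cumulative additions — the estimator then faces a
  constant interferent level, as the fixed-interference method assumes.
  Default interferent levels are chosen so the interference term is
  100–1000× the electrode's own background activity, clipped to the 1 M
  stock; for sulfide electrodes versus perchlorate this lands at molar
  levels, as the squared exponent demands.

## Characterization estimators

* **Calibration fit.**  The full curved response
  `E = e0 + s·log10(a + a0)` is fitted by least squares (three parameters,
  `a0` on a log scale), which leaves the slope unbiased by points near the
  flattening; a plain log-linear OLS is the fallback for short series.  The
  reported linear range and r² refer to points with `a > 10·a0`.  On
  noise-free simulated data the generating slope is recovered exactly.
* **Detection limit.**  Two constructions: `segments` — independent plateau
  and linear segments with the split chosen by total squared error, exact
  for ideally piecewise-linear data — and `smooth` — the asymptote
  intersection of the fitted curved response, exact for the additive-
  background mechanism.  `auto` (default) keeps whichever explains the data
  with the smaller squared error; the flattening activity is converted to a
  concentration through the series' own concentration–activity relation.
  An error is raised when the series does not bracket the flattening
  region.
* **Selectivity.**  Fixed-interference (default): each run's flattening
  activity is `a_bg + k·a_j^p`; the electrode's own blank flattening
  (from the zero-level run) is subtracted before dividing by `a_j^p`.  The
  interferent activity is evaluated over the plateau branch of the run,
  where the primary ion does not yet inflate the ionic strength.  Runs
  whose interference term does not exceed 5% of the blank are flagged
  unidentifiable (a zero-selectivity electrode yields an explicit −∞ /
  flagged estimate rather than a spurious number).  A joint nonlinear fit
  of the full response with the coefficient free is provided as a
  cross-check; the two methods agree within 0.1 log units on noise-free
  data.
* **Reproducibility.**  Slope RSD% across repeated calibration sessions,
  `100·sd/|mean|` with ddof = 1.

## Inverse model and training

* Architecture 5-H-2 (H = 8 by default, following the hidden-layer scan),
  tansig hidden transfer, linear output, min–max scaling to [−1, 1] fitted
  on the training subset only; outputs are concentrations on a linear scale
  (a log-concentration option exists but is off by default).
* Bayesian regularization in the Foresee–Hagan convention: E_D = Σe²,
  E_W = Σw², F = βE_D + αE_W, Gauss-Newton Hessian H ≈ 2βJᵀJ + 2αI with an
  analytic Jacobian, Levenberg-Marquardt damping ×10/÷10 within
  [1e-20, 1e10].  Evidence updates (γ = N_w − 2α·tr(H⁻¹), α ← γ/2E_W,
  β ← (n−γ)/2E_D) run once per epoch **after a 10-epoch pure-LM warm-up**:
  the re-estimation formulas assume the weights sit near a posterior
  optimum, and applying them from a random initialization (large misfit,
  tiny weight norm) locks in an excessive weight decay and stalls training
  at a poor self-consistent point.  Exhausting the damping schedule without
  descent is treated as convergence (the gradient is numerically flat); the
  error path is reserved for persistently singular systems.
* Stopping: 300 epochs or |ΔF| < 1e-9 for 10 consecutive epochs.  Weight
  initialization: seeded uniform in [−0.5, 0.5].  Five restarts from
  different seeded initializations; the model with the smallest test RMSE
  is kept and the across-restart RMSE spread is reported as the model's
  precision.  The learning-rate (0.1) and momentum (0.4) settings are
  honoured only by the fallback gradient-descent strategy; the regularized
  LM updates are governed by the damping schedule, as in the toolbox
  implementations of the same era.

## Evaluation

RMSE per ion and pooled (the scan's scalar criterion);
obtained-vs-expected OLS with t-based 95% confidence intervals on slope and
intercept; percentage relative errors (reported as relative errors even
though such charts are often titled "absolute errors (%)"), aggregated by
mean (median available), defined only where the expected concentration is
positive and, for the application samples, above 1e-5 M; Student's paired
t-test with the two-tailed critical value (2.57 at df = 5, 95%).  The
single-ISE baseline inverts `E = e0 + s·log10(a + a0)` for one designated
electrode per ion (P1 for perchlorate; S3, the most sulfide-selective, for
sulfide), ignoring interference, and converts activity back to
concentration self-consistently; readings below the detection limit or
beyond the calibrated span are flagged.

## Typical results and limitations

Problem sizes used throughout (tests, examples, acceptance script): the
79-sample design, 59/20 split, 6 spiked samples, 10-point calibrations,
13-point selectivity runs, 5 training restarts of a 66-parameter network —
the full pipeline completes in about one second.

* With no noise, every estimator recovers its generating parameter (slope
  to <0.01 mV/decade, detection limits to <0.1%, log k to ≤0.03 — the
  largest deviation arising from ionic-strength drift along molar-level
  selectivity runs), and the trained network reaches test R² > 0.999 for
  both ions.
* At the default 0.5 mV noise, mean relative errors on the spiked samples
  are typically 4–10% for perchlorate and 3–6% for sulfide across master
  seeds, always an order of magnitude below the single-electrode baseline
  (which fails at 25–300% on perchlorate because sulfide feeds directly
  into the P1 signal).  Two mechanisms dominate the array error: (i) the
  sample spiked to 5.0e-4 M sits above the trained range, and tanh-network
  extrapolation degrades quickly — occasionally severely — there; and (ii)
  for compositions with low perchlorate and high sulfide, the interference
  term exceeds the primary signal on every perchlorate-sensitive electrode
  and the propagated noise floor alone reaches ~5–15% (a nonlinear
  least-squares inversion using the *true* sensor parameters shows the same
  per-sample errors), so no inverse model could do much better under these
  conditions.  A fixed ≤5% per-ion target is therefore met only on
  favourable seeds.
* The simulator emulates cross-sensitivity, activity effects, low-end
  curvature, reading noise and session drift.  It does **not** emulate
  sulfide acid-base speciation (HS⁻/S²⁻), electrode drift within a session,
  carry-over/memory effects, matrix effects of real wastewater, or membrane
  ageing — so passing tests demonstrate correctness of the estimation
  machinery under the stated response model, not robustness to those
  real-world effects.
* Davies activity corrections are extrapolated beyond their nominal
  validity (I ≈ 0.5 M) in molar-level selectivity runs; since generator and
  estimator share the same formalism, recovery is unaffected, but absolute
  activities at such ionic strengths should not be over-interpreted.
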