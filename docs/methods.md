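# Methods

## Airway airflow model

The conducting airways are modelled as a symmetric dichotomous tree of 24
generations (trachea = generation 0). Generation *z* carries 2ᶻ parallel
branches of a single diameter *d(z)*; the embedded default diameters are
the canonical Weibel model-A means at total lung capacity (TLC), 18.0 mm at
the trachea down to 0.41 mm at generation 23, shipped as a versioned TSV
(`airglt/data/weibel_model_a.tsv`, `weibel-1963-model-A/v1`) that users can
override with any (generation, diameter) table. Outputs carry the table
version in the run manifest.

Velocities assume incompressible flow, conserved volume flow across
generations and a uniform profile per generation: *v(z) = Q/A(z)* with
*A(z) = 2ᶻ π d(z)²/4*. The model is steady-state per condition: a single
constant tracheal flow *Q* per breathing phase, with no waveform shape or
inspiratory/expiratory duty-cycle weighting. 15 L/min (2.5·10⁻⁴ m³/s)
represents tidal breathing at rest and 75 L/min (1.25·10⁻³ m³/s) moderate
exercise.

Airway hysteresis is applied as a bracketed fractional narrowing of the TLC
diameter on exhalation: 13% for *d* < 1.7 mm, 16% for 1.7–3.5 mm, 10% for
3.5–7 mm, 7% at and above 7 mm. The brackets are half-open
([1.7, 3.5), [3.5, 7.0), ≥ 7.0) so that every positive diameter maps to
exactly one fraction; contiguity was preferred over any reading of the
ambiguous interval endpoints in the source bronchographic percentages.
Inhalation uses the unadjusted TLC diameters; no separate
functional-residual-capacity diameter table is applied, since none is
available at matching resolution — the narrowing fractions are the entire
inhale/exhale asymmetry.

Reynolds numbers *Re = ρ v d/μ* default to humidified air at body
temperature (ρ = 1.12 kg/m³, μ = 1.87·10⁻⁵ Pa·s, preset `body`; a dry
room-air preset is provided). The laminarity conclusion has large headroom:
at 15 L/min the tree-wide maximum is Re ≈ 1139 (tracheal exhalation),
against the conventional laminar bound of 2000, and plausible gas-property
choices move it by a few percent only. At 75 L/min generations 0–3 exceed
2000 on both phases (transitional/turbulent), which the model reports via
the per-row laminar flag but does not attempt to correct for.

### Deep-airway asymmetry: computed vs published

With the canonical model-A diameters and the bracket rules above, the
expiratory-minus-inspiratory velocity difference at 75 L/min is ≥ 1 m/s
only in generations 3, 4 and 6 (Δv at the trachea is 0.77 m/s), so the
"deepest generation down to which Δv ≥ 1 m/s holds everywhere" is
undefined (None). Published estimates from the same kind of model state
that a > 1 m/s expiratory-vs-inspiratory difference reaches generation 10.
The two are reported side by side rather than forced to agree: the
published airway-by-airway diameter/velocity table behind that statement is
not available, and the claim is in fact consistent with a related quantity
this model does reproduce — the expiratory velocity itself exceeds 1 m/s
down to generation 10 exactly (v_ex(10) = 1.22 m/s, v_ex(11) = 0.86 m/s at
75 L/min). Users can recompute both with
`airway.flow_table` / `airway.deepest_generation_with_asymmetry`.

## Bead-track GLT analysis

Input trajectories are TrackMate-dialect tables (track id, frame, x/y in
μm, time in s or a declared frame rate; the spot-export's extra header rows
are tolerated). The pulse protocol defaults to 5 s no flow, 5 s air pulse,
5 s recoil, imaged at 100 fps.

Design choices where the procedure was genuinely open:

- **Signed projections, not Euclidean distances.** All displacement
  metrics are signed projections onto the declared airflow axis, so
  retrograde recoil is negative and net = pulse + recoil holds exactly as
  an identity. Rotating the coordinates together with the axis leaves every
  metric unchanged.
- **Completeness rule.** A track is kept only if its first point lies
  within one frame interval of the protocol start and its last within one
  frame interval of the protocol end; everything else is excluded with a
  recorded reason and contributes to no statistic.
- **Drift model.** Ciliary motion is one constant velocity vector per
  field, estimated as the across-track average of each track's mean
  velocity over the no-flow window, then subtracted as
  position − drift·(t − t₀). Per-field estimation (not pooling across
  cultures) is assumed. The intended field size is 10–20 beads; estimates
  from fewer emit a warning.
- **Protocol-time sampling.** Metrics sample the nearest recorded frame to
  each protocol time (≤ 10 ms error at 100 fps) rather than interpolating.
- **Percent recovery** uses magnitudes, |recoil|/|pulse|·100, and is
  defined as 0 when the pulse displacement magnitude is below a
  configurable noise floor (default 0.05 μm) to avoid 0/0 blow-ups.
- **Ensembles** report mean ± SD (SD = 0 with a warning at n = 1).

## Radiotracer clearance analysis

Percent cleared is 100·(1 − counts(t)/counts(0)). Optional radionuclide
decay correction (half-life 6.01 h) rescales counts by 2^(t/T½) before the
ratio; it is off by default because the effect over a 15 min acquisition is
under 3%, and with it enabled a non-clearing decaying source reads exactly
0% cleared. Background subtraction defaults to 0.

The initial clearance rate is the OLS slope of percent cleared vs time
restricted to a window, default 0–5 min, in %/min; an endpoint-difference
variant is exposed (`method="endpoint"`) since either definition is
defensible and they differ on concave curves.

Biphasic kinetics use the standard two-compartment exponential,
percent(t) = 100·[F(1−e^(−k_fast t)) + (1−F)(1−e^(−k_slow t))], fit by
bounded nonlinear least squares from four starting points, with the
compartments reordered afterwards so k_fast ≥ k_slow. Fits with F near 0
or 1 or k_fast/k_slow < 2 are flagged degenerate (effectively
single-exponential) rather than silently reported; non-convergence raises
with diagnostics. On noiseless model data the fit is self-inverse to
numerical precision.

Frame coregistration assumes a stable ordering of a few well-separated
fiducial markers and estimates a per-frame rigid translation as the shift
of the fiducial centroid relative to frame 0; no correspondence matching or
rotation is attempted. Neonatal bead clearance is
100·(injected − recovered)/injected, with recovered > injected clamped
under a warning.

## Synthetic generators

The generators produce data with the statistical structure the analyses
assume, plus a serialized ground truth sufficient to recompute every metric
the analyses report. All randomness flows through one seeded NumPy
generator; identical parameters and seed give byte-identical output.

**Trajectories.** Along the airflow axis each bead follows
s(t) = 0 before the pulse; A(1 − e^(−(t−t₀)/τ_f)) + v_s(t−t₀) during it (a
saturating fast phase plus steady creep, reproducing the observed biphasic
displacement); after the pulse an exponential recoil removes a fraction R
of the pulse displacement with time constant τ_r. A constant drift vector
acts throughout and i.i.d. Gaussian localization noise is added per point.
This is a minimal phenomenological form chosen for closed-form ground
truth, not a rheological model. Defaults (15 beads, 100 fps, A = 8 μm,
τ_f = 0.3 s, v_s = 2 μm/s, R = 0.4, τ_r = 0.5 s, drift (0.5, −0.3) μm/s,
noise SD 0.1 μm) describe a healthy-mucus field under the 5/5/5 s protocol
at order-of-magnitude realism; they are not calibrated to any measured
displacement trace. Ground truth records pulse displacement, the
finite-window recoil/net at the protocol end, and the asymptotic net
(1 − R)·pulse.

**Gamma series.** Retained fraction r(t) = F e^(−k_fast t) +
(1−F) e^(−k_slow t); observed counts are Poisson with mean
baseline · r(t) — the physically standard model for scintillation
counting — with defaults F = 0.7, k_fast = 0.5/min, k_slow = 0.01/min,
baseline 3000 counts, frames every 30 s for 15 min. Fiducials are a fixed
triangular layout plus per-frame rigid animal motion (SD 0.5 units) and
Gaussian jitter (SD 0.1). The recorded true initial rate is the OLS slope
of the noiseless percent-cleared values over the 0–5 min frames — exactly
the estimand of the analysis-side estimator.

**Frequency cohorts.** Breathing frequencies uniform over 60–130 bpm;
rate = slope·bpm + intercept + Gaussian noise, default slope 0.08 %/min/bpm
with noise SD chosen (0.7 %/min at n = 20 in the recovery tests) to land in
a strong-correlation regime (mean R² ≈ 0.85).

What the generators deliberately do not emulate: bead loss and out-of-focus
truncation statistics (completeness filtering is tested with constructed
truncated tracks instead), heteroscedastic or correlated localization
error, detector dead time and scatter, ROI redefinition error after
registration, and any dependence of transport on mucus concentration —
passing recovery tests therefore shows estimator correctness under the
assumed noise structure, not robustness to un-modelled imaging artifacts.

## Problem sizes and numerics

The test suite runs the full airway tree (24 generations, exact closed
forms), 100-seed trajectory recoveries at 15 beads × 1501 frames, and
50-seed clearance recoveries at 31 frames, a few seconds in total; these
sizes give Monte-Carlo error comfortably inside the asserted bounds while
keeping the suite quick. Floating-point identities (mass conservation,
metric additivity, rotation consistency) are asserted at 1e−9…1e−12;
stochastic recoveries at 3-standard-error or stated percentage bounds.

## Known limitations

- Steady per-phase flow: no intra-breath waveform, duty-cycle weighting
  (an optional half-cycle weighting hook is deliberately not a default), or
  pressure-drop/resistance network; no turbulence modelling beyond the
  laminar flag.
- The symmetric tree ignores branching asymmetry and the mouse-vs-human
  geometry difference; only the human table ships.
- Drift correction assumes constant-velocity ciliary motion per field;
  rotational mucus flow fields violate this and would bias metrics.
- The biphasic form is a descriptive compartment model; its parameters are
  not identifiable on curves much shorter than 1/k_slow, which the
  degeneracy flag surfaces but cannot fix.
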