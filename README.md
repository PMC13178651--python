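# airglt

Tools for quantifying **cilia-independent gas–liquid transport (GLT)** of
airway mucus — the clearance mode in which the asymmetry between expiratory
and inspiratory airflow, rather than ciliary beating or cough, moves the
mucus layer up the airways. The package is aimed at respiratory
physiologists and biofluid modellers who need to (a) estimate per-generation
airflow velocities in a human airway tree, (b) reduce bead-tracking
microscopy of mucus under a breath-mimicking air pulse to transport metrics,
and (c) turn gamma-camera radiotracer time series into clearance rates and
kinetic fits. Every stage has a matching synthetic-data generator with
recorded ground truth, so the full pipeline runs and is testable with no
external data.

## The models

**Airway airflow asymmetry** (`airglt.airway`). The conducting airways are a
symmetric dichotomous tree of 24 generations (trachea = generation 0;
generation *z* holds 2ᶻ branches of diameter *d(z)*, embedded canonical
Weibel model-A values). For a tracheal volumetric flow *Q*,

&nbsp;&nbsp;&nbsp;&nbsp;*v(z) = Q / A(z)*,&nbsp;&nbsp; *A(z) = 2ᶻ · π d(z)² / 4*,

assuming incompressible flow and conserved volume flow. Exhalation
diameters are narrowed from the inhalation (TLC) diameters by bracketed
percentages (13% below 1.7 mm, 16% for 1.7–3.5 mm, 10% for 3.5–7 mm, 7% at
7 mm and above), so *v*ₑₓ(z) > *v*ᵢₙ(z) at equal *Q* — the asymmetry that
biases transport toward the mouth. Reynolds numbers *Re = ρ v d / μ* use
humidified body-temperature air by default (ρ = 1.12 kg/m³,
μ = 1.87·10⁻⁵ Pa·s).

**Bead-track GLT metrics** (`airglt.tracks`). Trajectories from a
spot-tracking tool (TrackMate-dialect CSV) recorded through a
no-flow / air-pulse / recoil protocol are filtered for completeness,
corrected for the field's constant ciliary drift (estimated from the
no-flow window), projected on the airflow axis, and reduced to signed pulse
displacement, recoil distance, net displacement
(net = pulse + recoil), percent recovery and peak velocity, with ensemble
mean ± SD.

**Radiotracer clearance** (`airglt.clearance`). Gamma-camera ROI counts
become percent cleared, 100·(1 − counts(t)/counts(0)); the initial rate is
the least-squares slope over 0–5 min (%/min); biphasic kinetics are fit as
a two-compartment exponential
100·[F(1−e^(−k_fast t)) + (1−F)(1−e^(−k_slow t))]; clearance-rate vs
breathing-frequency cohorts get an OLS slope (%/min/bpm) with R².
Fiducial-marker centroids provide rigid-translation frame coregistration.

## Worked example

```bash
$ airglt airflow-table --flow-lpm 15 -o table.tsv
wrote 24 generations to table.tsv
```

The first row of `table.tsv` is the trachea: inhalation diameter 18.0 mm,
exhalation 16.74 mm, velocities 0.982 vs 1.136 m/s, Reynolds numbers 1059
and 1139 — expiratory velocity exceeds inspiratory by 0.153 m/s and the
largest Reynolds number in the whole tree (1138.9) stays well inside the
laminar regime (< 2000).

```bash
$ airglt simulate tracks --seed 7 -o sim
simulated 15 beads -> sim
$ airglt analyze-tracks --tracks sim/tracks.csv -o out
15 tracks analyzed, 0 excluded; mean net displacement 10.75 um
```

The generator's ground truth (`sim/ground_truth.json`) records a true net
displacement of 10.80 μm per pulse (18.0 μm pulse displacement, 40% elastic
recovery); with 0.1 μm localization noise and ciliary drift
(0.5, −0.3) μm/s the pipeline recovers 10.75 μm.

```bash
$ airglt simulate clearance --seed 7 -o simc
$ airglt analyze-clearance --series simc/series.csv -o outc
initial clearance rate 12.36 %/min over (0.0, 5.0)
```

against a ground-truth analytic rate of 12.31 %/min; the biphasic fit in
`outc/report.json` recovers F = 0.72, k_fast = 0.49/min, k_slow = 0.005/min
(truth: 0.7, 0.5, 0.01) with R² = 0.998.

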