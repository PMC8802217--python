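# burstloco

Burst-locomotion performance analysis for small quadrupedal prey animals —
from synchronized force-plate and hip-marker recordings of accelerative
half-bound strides to the ontogenetic statistics that link body size,
muscle power, mechanics, and survival. The motivating system is the
eastern cottontail rabbit (*Sylvilagus floridanus*), whose juveniles must
out-sprint the same predators as adults despite smaller bodies.

## What it computes

**Per-trial mechanics** (`burstloco.kinetics`, `burstloco.kinematics`):

- mean COM acceleration over a stride, a_COM = mean(F_FA)/M_b;
- escape speed by impulse integration, v_esc = (∫ F_FA dt)/M_b + v₀;
- initial velocity v₀ from a quintic-spline-smoothed hip-marker trajectory
  (tolerance 0.75 mm²), refined by least-squares matching of the kinetic
  and kinematic velocity profiles;
- mean COM mechanical power P_COM from positive fluctuations of COM
  kinetic + potential energy over the hindlimb push-off;
- stride segmentation and forelimb/hindlimb girdle attribution from
  two-plate stance detection.

**Muscle power capacity** (`burstloco.muscle`): PCSA = MM·cosθ/(L_F·ρ)
with ρ = 1.06 g/cm³, F_max = 30 N/cm² × PCSA, V_max = 6.3 fascicle
lengths/s, P_peak = 0.1·F_max·V_max, and total hindlimb capacity
P_musc = 2·ΣP_peak (both hindlimbs extend together in a half-bound).

**Ontogenetic statistics** (`burstloco.ontogeny`, `burstloco.pathmodel`,
`burstloco.scenarios`): quadratic performance–mass models (mixed per-trial
fits with mass-dependent residual sd, or per-individual-peak GLS) with AICc
comparison; peak-performance vertex −b₁/(2b₂) with case-bootstrap CIs and
mass→age mapping through a cubic growth model in ∛M_b; log-log allometry
with geometric (1.00) and mechanical (1.33) similarity verdicts;
repeatability (ICC) from random-intercept variance components; Welch tests
with Cohen's d categories; Box-Cox + one-tailed Pearson correlation and
Fisher-z power analysis; recursive path analysis (standardized β-weights,
χ², RMSEA, CFI, iterative pruning of non-significant paths); and
constant-acceleration escape scenarios (distance in the first second, time
to refuge, strides to top speed).

**Synthetic data** (`burstloco.simulate`): a seeded generator for
gravity-consistent half-bound trials with known accelerations, marker
noise/dropout, and for whole cohorts with quadratic-in-mass peak
performance, controlled ICC, allometric muscle scaling, and a tunable
speed–survival coupling. Every downstream stage has a parameter-recovery
test against this ground truth.

## Worked example

```python
from burstloco import process_trial
from burstloco.simulate import TrialSimParams, simulate_trial

params = TrialSimParams(body_mass_kg=0.86, accel_mean_m_s2=6.2, v0_m_s=0.25,
                        accel_profile="half-sine", marker_noise_sd_m=1e-3,
                        force_noise_sd_n=0.5, seed=42)
bundle, truth = simulate_trial(params)
perf = process_trial(bundle)
print(f"a_COM   = {perf.a_com:.3f} m/s^2   (truth {truth.accel_mean_m_s2:.3f})")
print(f"v0      = {perf.v0:.3f} m/s     (truth {truth.v0_m_s:.3f})")
print(f"v_esc   = {perf.v_esc:.3f} m/s     (truth {truth.v_esc_m_s:.3f})")
print(f"P_COM   = {perf.p_com:.2f} W       ({perf.p_com_per_kg:.2f} W/kg)")
```

prints

```
a_COM   = 6.246 m/s^2   (truth 6.200)
v0      = 0.257 m/s     (truth 0.250)
v_esc   = 1.806 m/s     (truth 1.800)
P_COM   = 2.66 W       (3.09 W/kg)
```

i.e. with 1 mm marker noise and 0.5 N force noise, the pipeline recovers
this trial's mean acceleration within ~1%, the initial and escape speeds
within 0.01 m/s, and reports a mass-specific COM power of ~3 W/kg for a
0.86 kg animal accelerating at ~6 m/s².

A command-line interface mirrors the library:

```sh
burst simulate --kind trial --seed 3 --out demo/
burst process-trial --force demo/force.csv --markers demo/markers.csv \
      --mass 0.8 --rabbit-id r1
burst scenarios --accel-juv 6 --accel-adult 4
```

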