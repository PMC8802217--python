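# Methods

`burstloco` reconstructs burst-locomotion performance of small quadrupedal
prey (the motivating system is the eastern cottontail, *Sylvilagus
floridanus*) from synchronized force-plate and marker recordings, estimates
hindlimb muscle power capacity from dissection-style architecture tables,
and fits the ontogenetic statistics that connect morphology, mechanics, and
survival. This note documents the models, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Per-trial mechanics

**Conventions.** SI units internally; fore-aft positive in the direction of
travel, vertical positive up; force plates zeroed (unloaded reading ≈ 0 N);
force and camera streams share a common trigger at t = 0. Default sampling:
500 Hz forces, 250 Hz markers.

**Stance detection and stride segmentation.** Stance is any contiguous
interval where a plate's vertical force exceeds a threshold, by default 2%
of body weight. Two robustness layers matter in practice: the channel is
median-filtered (width 5, edge-preserving) before thresholding, and the
threshold is floored at 4× the robust noise sd of the channel (1.4826 ×
MAD), because broadband plate noise of a few tenths of a newton otherwise
produces spurious stances at a 2%-body-weight threshold for sub-kilogram
animals. Runs are gap-merged (20 ms) and duration-filtered (20 ms). Detected
edges are refined to the midpoint between the last sub- and first
supra-threshold sample, which recovers true on/off times to half a sample.
The stride spans the first stance onset to the last stance offset; the
earlier-contacting plate is assigned to the forelimb girdle, the later to
the hindlimb. Hindlimb stroke duration t is the hindlimb stance length.

**Acceleration and escape speed.** Mean COM acceleration is the stride mean
of total fore-aft force over body mass, a_COM = mean(F_FA)/M_b. Escape
speed integrates the impulse: v_esc = (∫ F_FA dt)/M_b + v₀ (trapezoidal
quadrature at the force clock). Integration windows are padded by one
sample on each side so the sub-threshold loading ramps at stance edges are
not truncated.

**Initial velocity.** Marker coordinates are fit per axis with a quintic
smoothing spline (tolerance 0.75 mm², interpreted as a bound on the mean
squared residual per visible frame; a total-SSR mode is available).
Invisible frames are interpolated by the spline. The sagittal-plane
(fore-aft × vertical) velocity from 10 frames before to 10 frames after the
contact period seeds v₀ as the mean pre-contact fore-aft velocity; v₀ is
then refined by minimizing the summed squared difference between this
kinematic profile and the kinetic profile v(t; v₀) = v₀ + cumulative
impulse/M_b evaluated at the marker timestamps. The objective is quadratic
in v₀, so the minimizer is closed form (the mean residual); a bounded
golden-section search reproduces it as a cross-check and warns beyond
1e-6 m/s.

**COM power.** COM velocities come from integrating F_FA/M_b (from v₀) and
(F_V − M_b g)/M_b (vertical velocity assumed 0 at stride onset — a static
start; configurable). Outside the detected stride the body is treated as
externally supported, not in free fall. COM energy is E = ½M_b(v_fa² +
v_v²) + M_b g h; P_COM sums the positive increments of E over the hindlimb
stance and divides by the hindlimb stroke duration (the push-off phase
dominates propulsion). A whole-stride window and a kinetic-energy-only mode
are selectable.

**Work–energy relation.** `work_energy_acceleration` implements
a = √(P/(2 M_b t)) exactly as conventionally printed. Note its meaning: for
a stroke at constant power P, v(t) = √(2Pt/M), and differentiating gives
the *instantaneous* acceleration at the end of the stroke, √(P/(2Mt)). It
equals the stride-*mean* acceleration only for particular stroke/stride
geometries; with the whole velocity gain delivered during a hindlimb stroke
occupying 40% of the stride the two coincide exactly, which is the fixture
used in the consistency tests. On generic fixtures the two differ by a
factor approaching 2 — an algebraic property, not an implementation error.

## Muscle power capacity

For each muscle: PCSA = MM·cos θ / (L_F·ρ) with ρ = 1.06 g/cm³; F_max =
σ·PCSA with σ = 30 N/cm²; V_max = 6.3 fascicle lengths/s (fast MHC-2X
fibres); P_peak = 0.1·F_max·V_max. Total hindlimb capacity doubles the sum
over sampled extensors because a half-bound extends both hindlimbs
synchronously. Inputs stay in g/cm so the PCSA formula reads as printed;
SI conversion happens only inside the power step. Where multiple pennation
sites are measured, the representative θ is the mean angle (cosine taken
afterwards), matching the single-θ formula. Note the cancellation P_peak ∝
MM: fascicle length drops out of the chain, so the allometry of total
power tracks the allometry of summed muscle mass.

## Ontogenetic statistics

**Quadratic performance–mass models.** Two levels. *Per-trial*: all trials,
random intercept per individual, residual sd modelled as a linear function
of the predictor, sd = s₀(1 + c·mass), fit by full ML (profile likelihood:
closed-form GLS for the fixed effects and a Nelder–Mead search over the
variance parameters; per-individual blocks use the Woodbury identity).
*Per-peak*: each individual's maximum, GLS with the same variance function
(1-D profile over c). The wording "variance of the error term modeled as a
linear function of the predictor" is ambiguous between sd-linear and
variance-linear; sd-linear is implemented as the default. AICc uses the
trial count (per-trial) or individual count (per-peak) for the small-sample
correction; the reported R² is the marginal (fixed-effect) share for mixed
fits and the ordinary R² for GLS fits.

**Vertex (peak performance).** For curvature b₂ < 0 the peak mass is
−b₁/(2b₂). Confidence intervals use a case-resampling bootstrap with
individuals as the resampling unit (2000 draws by default, percentile
interval, seeded); draws whose refit loses the interior maximum are
discarded and counted. Peak age maps the vertex mass through a growth
model: a least-squares cubic of age in days on the cube root of body mass,
with 95% prediction intervals and a monotonicity check over the reference
range. The package fits whatever reference growth table it is given; no
literature table is bundled.

**Allometry.** OLS of log₁₀ P_musc on log₁₀ M_b; the exponent's 95% CI is
compared with the geometric-similarity null (1.00) and the
mechanical-similarity null (4/3 ≈ 1.33). Two-point fits return an
infinite-width CI flag.

**Repeatability.** ICC = between-individual variance / total variance from
an intercept-only random-intercept model (own ML fitter, 1-D profile over
the variance ratio; cross-checked against statsmodels MixedLM in the test
suite). CIs by parametric bootstrap on the observed design. A design point
worth noting: when performance also trends with mass, that trend is real
between-individual variance, so an empirical ICC exceeds the
variance-component design value; the component-recovery simulations
therefore use a flat (negligible-curvature) cohort.

**Comparisons, transforms, correlation, power.** Group comparisons use
Welch's t with Cohen's d (pooled sd) categorized on the very small … huge
scale (0.2/0.5/0.8/1.2/2.0 thresholds). Box-Cox λ is chosen by profile
likelihood on a fixed grid (−2…2, step 0.01) and the transformed values are
z-scored (n−1 denominator). Pearson correlations are one-tailed for a
positive association (the directional prediction that faster animals
survive longer). Power uses the Fisher-z approximation, power =
Φ(atanh(r)·√(n−3) − z₁₋α); required-n inverts it with a ceiling guard.

## Path analysis

The structural model: body mass and muscle power capacity (correlated
exogenous variables) determine COM power; COM power and body mass determine
acceleration. All variables are z-scored, so single-headed coefficients are
β-weights and the double-headed one a correlation. Fitting minimizes the
normal-theory ML discrepancy F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p with
Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ, starting from (and, for recursive models, coinciding
with) per-equation least squares — the equivalence is asserted to 1e-6 in
the tests. Conventions that affect the indices and are therefore fixed and
documented: S uses the n−1 denominator; χ² = (n−1)·F_min; RMSEA =
√(max(χ²−df,0)/(df(n−1))); CFI uses the independence baseline (all
variables uncorrelated). Standard errors come from the numerical Hessian of
F (acov = 2/(n−1)·H⁻¹) with normal-theory p-values. Pruning removes one
edge per iteration — the least significant with p > α — and refits;
simultaneous removal was rejected to keep the procedure deterministic. If a
variable loses all incoming paths it is dropped with a warning. Raw P_COM
with body-mass edges is the default variable form; a mass-specific ratio
form can be assembled by the caller.

## Scenarios

From predicted constant accelerations for a juvenile (default 0.8 kg) and
an adult (default 1.2 kg): distance in the first second (a/2), time to a
refuge 10 m away (√(2R/a)), and strides to reach 11.1 m/s top speed
(⌈(v_top/a)/T_stride⌉). The stride-count scenario requires a stride
duration with no published value; the intended input is the mean hindlimb
stride period of the processed dataset at hand, and this scenario is the
most sensitive to that choice. The ratio identity distance-ratio ×
time-ratio² = 1 holds exactly.

## Synthetic data

**Trials.** A prescribed fore-aft acceleration profile (constant or
half-sine; the half-sine peak is π/2 × its mean) acts over one stride;
F_FA = M_b·a(t). Vertical force is two half-sine stance pulses (forelimb
pair at stride onset, hindlimb pair at stride end, default duty 30% of the
stride each) whose summed impulse balances gravity over the stride, with
flight at F_V = 0 — physically consistent, deliberately not biofidelic (no
pitching, no compliant-limb dynamics). Marker positions double-integrate
the analytic accelerations from (v₀, standing hip height 0.08 m) on a fine
grid, then sample at the camera rate with Gaussian noise and Bernoulli
dropout (endpoints kept visible). Stride boundaries sit at half-sample
offsets of the force clock and in-stride samples are rescaled (≈1e-4
relative) so the trapezoidal impulse of the sampled trace is exact; the
generator invariant ∫F_FA dt/M_b + v₀ = v_esc then holds to 1e-6 at 500 Hz.

**Cohorts.** Default design: 38 individuals over 0.106–1.434 kg (juvenile
below 1 kg; a boundary mass of exactly 1 kg is classed adult), 5 usable
trials each. True peak acceleration is quadratic in mass in vertex form
with peak 6 m/s² at 0.74 kg and curvature −6 m/s²/kg² — values chosen once
to give realistic juvenile/adult contrasts and trial R² in the 0.2–0.4
range. Trial values decompose as quadratic(m) + between-individual deviate
(sd 0.6 m/s²) + within-individual noise (sd 0.8 m/s²). Escape speed derives
as v₀ + a·T with T = 0.25 s and v₀ ~ N(0.2, 0.1) m/s clipped at 0. Muscle
tables scale a fixed adult reference architecture: belly masses ∝
M_b^1.33 by default (mechanical similarity; set 1.0 for geometric), with
0.02-dex lognormal scatter, fascicle lengths ∝ M_b^(1/3). Survival
durations are baseline 60 d + 10 d per sd of standardized peak escape speed
+ N(0, 29 d), floored at 1 day — a weak positive speed–survival coupling
(r ≈ 0.3) of the kind field studies struggle to resolve at n ≈ 15.

**Problem sizes used in the test-suite and acceptance recomputations** (the
package's own choices for a desk-scale check): 100 noisy trials for
pipeline recovery; 50 replicate cohorts × 400 bootstrap draws for vertex-CI
coverage; 8 replicate 100 × 10 cohorts for ICC recovery (a single replicate
estimates ICC with sd ≈ 0.04, so recovery of the design value is judged on
the replicate mean); n = 5000 for path-model recovery.

**What passing these checks shows — and does not.** They show the pipeline
recovers known kinematic, kinetic, architectural, and statistical ground
truth under realistic noise, and that the estimators are implemented
correctly. They do not validate the generator's simplifications against
real rabbits: real trials have pitching and rolling dynamics, correlated
(not white) sensor noise, imperfect plate strikes (both girdles on one
plate, partial strikes), digitizing error that is worst at high image
velocity, and survival processes far richer than a linear model in one
performance trait.

## Known limitations

* Girdle attribution assumes one plate per girdle; a single-plate trial is
  attributed wholly to the hindlimb and flagged.
* The heteroscedastic mixed fit profiles only an intercept random effect;
  no random slopes.
* The path module covers observed-variable recursive models only — no
  latent variables, mean structures, or multi-group fits.
* Peak-age CIs inherit the growth model's point mapping; growth-curve
  uncertainty is not propagated into the bootstrap.
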