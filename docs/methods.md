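# Methods

`strainfit` personalises mechanistic models of regional ventricular strain
by a two-step subset-reduction strategy: screen out parameters the model
output does not respond to, then iteratively shrink the remaining subset to
the parameters that measured strain data can actually identify, validating
every shrink by re-fitting the cohort.  The framework only touches the
model through a normalized-parameter-in / strain-traces-out interface, so
any forward model with that signature can be plugged in; the bundled toy
model exists to make the whole pipeline runnable and falsifiable without a
proprietary cardiac simulator or patient data.

## Parameter space

Every parameter lives in a registry entry `(name, group, lower, upper,
reference, units)` and is used internally as a dimensionless coordinate
`x = (p - lower)/(upper - lower)` in `[0, 1]`.  The default registry has
110 parameters — 12 tissue parameters for each of five wall segments (RV
apex/mid/base, septum, LV free wall) plus 50 global/non-ventricular
parameters — mirroring the structure of a full lumped-parameter heart
model.  The bounds shipped here are package fixtures on plausible physical
scales, not a published table: tissue parameters of the RV mid and basal
segments get wide ranges (the region where arrhythmogenic cardiomyopathy
expresses), everything else narrow ranges around a shared reference.
A `SubsetMask` freezes excluded parameters at their normalized reference
value; all search stages operate on the active subspace.

A 20-parameter demo registry (`build_demo_registry`) carries the 16
parameters the toy model actually reads plus four inert placeholders; it is
the configuration used by the end-to-end tests and the acceptance script.

## Toy forward model

Each wall segment obeys a linear tension law

    F(t) = k_s (u_s(t) - p_s) + c_s a_s(t)

with `u_s` segment strain (%), `k_s` linear stiffness, `p_s` a pre-stretch
offset (mapped from the zero-stress sarcomere length), `c_s` contractility
and `a_s(t) = sin^2(pi (t - t_act,s)/T_sys)` on its activation window,
`t_act,s = AV-delay + dT_s`.  The three RV free-wall segments share one
tension `F(t)`, fixed at each instant by requiring their mean strain to
equal a prescribed global shortening pulse `G(t)`; the septum and LV free
wall are single segments driven by the same tension.  `G` is supported on
`[AV-delay, t_pvc]` (no net shortening during the isovolumic phase), peaks
at 80% of ejection with a quartic-linear bump, and scales with a cardiac
output-like factor.  Strain is engineering strain in percent re-referenced
to zero at QRS onset; the output grid step is 2 ms.

This construction reproduces the regional phenomenology the pipeline needs:
a weak or late-activated segment is stretched by its neighbours early in
systole (pre-stretch), shortens less, and peaks late (post-systolic
shortening).  Parameters the model does not read (placeholders, and tissue
parameters other than `SfAct`, `k_lin`, `dT`, `Ls0`) are genuine no-ops, so
screening must flag them.  A corner of the hypercube — very low stiffness
combined with very high contractility somewhere in the wall — returns a
`crashed` status with no trace, emulating forward models whose numerics
fail on non-physiological inputs; under uniform sampling of the full
registry this covers ≈3.5% of the hypercube, so quasi-Monte Carlo success
rates land around 96–98%.

A caveat this simulator deliberately accepts: because the global pulse
returns to zero at pulmonary valve closure, "systolic strain" at valve
closure is near zero and most shortening recovers within systole — the
morphology indices remain well defined and parameter-sensitive, but their
absolute values are not those of clinical traces.

## Strain morphology indices and fit error

Seven indices summarise one segment's curve: times to 10/50/90% of total
shortening (measured from the early pre-stretch maximum down to peak
strain, reported relative to QRS onset), pre-stretch, systolic strain
(value at pulmonary valve closure), post-systolic strain and peak strain.
Flat curves use a degenerate convention (times zero, flag set) rather than
failing, so screening can consume any output.  The ambiguity of the 0%
shortening level is resolved toward the pre-stretch maximum, which keeps
`t10 <= t50 <= t90` exact by construction.

The fit error between model and measurement is

    E_SS = alpha * sum_seg A_seg^2 + beta * (T_model - T_meas)^2
    A_seg^2 = int_{t_QRS}^{t_50relax} (eps_model - eps_meas)^2 dt

with `alpha = 1 /s`, `beta = 0.1 /s^2`, summed over the five segments.  The
window ends at 50% relaxation of the global RV strain (mean of the three RV
segments), measured toward the end-of-cycle value rather than zero so that
baseline drift in the measurement does not corrupt the window; curves that
never relax half-way use the full cycle and warn.  Both curves are linearly
interpolated onto a common 2 ms grid and integrated by the trapezoid rule;
refinement beyond that grid changes results by well under 0.1%.  Crashed
model runs score `+inf`.

## Morris screening

Trajectories on a z-level grid (`z = 8`, levels `{0, 1/7, ..., 1}`) start
at a uniformly drawn grid point and change each parameter once, in random
order, by the signed step `delta = z/(2(z-1)) = 4/7` — the level-preserving
choice that makes all grid points equally likely.  Elementary effects are
signed difference quotients of the 35 outputs (7 indices x 5 segments);
`mu*` is their mean absolute value over trajectories.  A parameter is
dropped when `mu*` falls strictly below the column mean for *every* output;
positive ties retain the parameter.  Output columns that respond to no
parameter at all are skipped in that test — with them included, the strict
inequality is vacuously false and one constant output would veto all
exclusion.  Trajectories containing a crashed evaluation are discarded
whole and counted; screening repeats on the surviving subset until a round
drops nothing.  Stability is checked leave-one-out: dropping any single
trajectory must not change the selected set.  Desk-scale default is 200
successful trajectories per round (a config value; production-scale budgets
are simply larger numbers).

## Quasi-Monte Carlo and diaphony

The active subspace is sampled with the unscrambled Sobol sequence (initial
all-zeros point skipped), one forward run per point shared across the whole
cohort — the cycle time is itself a sampled parameter, so each subject
scores every run with its own `E_SS`.  For each subject the best
`N_b = 100` runs are kept and each parameter's coordinates are condensed
into the first-harmonic diaphony

    d_i = | (1/N_b) sum_b exp(2 pi i x_i^(b)) |

which is 0 for a homogeneously spread sample (the parameter does not
constrain the fit) and 1 when all best runs agree on one value.  Note the
finite-sample floor: for 100 i.i.d. uniform coordinates `d_i` is Rayleigh
with mean ≈0.089, and the max over subjects of that floor reaches ≈0.2 —
ranking, not thresholding, is what the reduction uses.  Defaults sample
`n = 2^14` points per round (config value).

## Particle swarm optimization

Thirty particles with Clerc-constriction constants `w = 0.729`,
`c1 = c2 = 1.49445`, seeded at the 30 best qMC runs with zero velocity
(Sobol-padded when fewer finite-error seeds exist).  Velocity updates use
the canonical attraction form `v <- w v + c1 Z1 (xp - x) + c2 Z2 (xg - x)`
with elementwise uniform `Z`; positions outside the unit hypercube score
`+inf` and can never become bests (ties update the personal best only for
finite scores, which also lets flat objectives collapse the swarm).  A
particle has converged when its energy
`|v|^2 + |x - xp|^2 + |x - xg|^2` drops below 0.1; the run stops when all
particles have converged or after 1000 iterations.

A property worth knowing: on a smooth unimodal objective the energy rule
stops the swarm when it has *collapsed*, not when the best value is
numerically exact — on the 5-dimensional sphere it halts after ~50
iterations at a best value around 3e-6.  Optimizing to tighter precision
requires a smaller energy tolerance (1e-3 reaches 1e-6 reliably); parameter
estimation against noisy strain data never needs that, and on the strain
objective the cap of 1000 iterations binds long before the energy rule.

## Subset reduction loop

Per round: Sobol sweep of the active subset → rank parameters ascending by
their maximum diaphony over subjects → propose omitting the batch below the
0.25 quantile (optionally whole stems across the three RV segments,
all-or-none) → re-fit every subject with PSO on both the old and the
proposed subset (swarms seeded from the round's best qMC points, re-scored
under the reduced embedding) → accept when

    mean E_SS(after) <= (1 + tol) * mean E_SS(before),   tol = 0.5
    and mean E_SS(after) <= (1 + tol_total) * baseline,  tol_total = 1.0

where `baseline` is the mean error of the initial subset.  The per-round
rule alone compounds (ten accepted rounds could quadruple the error while
each round looks "similar"); the cumulative guard caps the whole run at a
doubling, which matches the total degradation a practitioner accepts over a
full reduction campaign.  On rejection, the batch is halved and retried;
the loop ends when no omission is accepted, a floor is reached, or a round
cap.  The full audit trail (subsets, diaphony tables, omissions, PSO errors,
accept/reject) is returned and serializable.

## Synthetic cohort

Virtual subjects draw a ground-truth point per disease-stage archetype
(jitter s.d. 0.05 on all model-read parameters, clipped to `[0.02, 0.98]`,
crash-region draws rejected):

* **concealed** — near reference with a mild basal contractility deficit
  (shift −0.12..−0.04);
* **electrical** — basal activation delayed by +0.35..+0.55 of the
  normalized range (≈40–65 ms);
* **structural** — basal and mid contractility reduced (−0.45..−0.30),
  passive stiffness increased (+0.08..+0.18) and the basal delay of the
  electrical stage (+0.40..+0.60) — disease staging is progressive, so the
  structural phenotype includes the electrical one.

The default cohort mix is 6:4:5 concealed:electrical:structural, allocated
deterministically by largest remainder.  Measurements resample the model
trace to 60 Hz, add i.i.d. Gaussian noise (s.d. 0.5% strain) and a linear
baseline drift (slope uniform in ±1% per cycle), and re-reference at QRS
onset; the reference frame itself carries no noise, because engineering
strain is zero there by construction.  Drift is on by default so the
fit-window logic is always exercised.

What this generator does *not* emulate: speckle-tracking image formation,
frame-to-frame correlated noise, inter-observer variability, arrhythmic
beats, or probe-angle artefacts.  Passing recovery tests therefore show the
pipeline's statistical machinery works under honest noise, not that
clinical strain data identify the same parameters.

## Known limitations

* With strain-only data and shared wall tension, a segment's contractility
  is nearly degenerate with its stiffness and activation delay: freezing
  basal contractility at reference changes the cohort's attainable fit
  error by only a few percent, so the reduction loop legitimately discards
  it while retaining basal stiffness and delay (which carry the same
  abnormality at ρ ≳ 0.8 rank correlation with ground truth).  Breaking
  this degeneracy needs non-strain data (pressures, volumes) — outside this
  package's scope.
* Recovery is scored by Spearman rank correlation across the cohort; for
  parameters whose ground truth is near-tied over most subjects (anything
  at reference plus jitter), the within-tie ranks are noise-level and a
  single inversion costs ~0.01–0.02 of ρ, so values just below a nominal
  0.8 bar can coexist with excellent recovery of the disease signal.
* Morris budgets, qMC sample counts and PSO populations default to
  desk-scale values; all are configuration, and the methods scale linearly
  in them.
* The toy model's closed-form solve is exact; real simulators would add
  solver noise to elementary effects, which the discard-crashed-trajectory
  policy only partially models.
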