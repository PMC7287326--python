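# strainfit

Parameter subset reduction and estimation for mechanistic models of
regional ventricular strain.

## The problem

Personalising a mechanistic heart model to a patient's echocardiographic
strain curves is an inverse problem over a hundred-plus parameters, most of
which the data cannot constrain.  Fitting them all produces unstable,
non-unique estimates; fixing the wrong ones biases the clinically
interesting ones (regional tissue properties of the right ventricle, where
arrhythmogenic cardiomyopathy expresses first).  `strainfit` implements a
model-agnostic two-step strategy for finding the identifiable subset:

1. **Screening** — iterative Morris elementary-effects screening over the
   normalized parameter hypercube.  For parameter *i*, output *j* and
   trajectory *r* on a z-level grid (z = 8, step Δ = z/(2(z−1)) = 4/7):

       E_ij^(r) = (Y_j(x + e_i Δ) − Y_j(x)) / Δ,
       μ*_ij = (1/N_r) Σ_r |E_ij^(r)|

   A parameter is dropped when μ*_ij < (1/D) Σ_k μ*_kj for every output j
   (the outputs are 7 strain-morphology indices × 5 wall segments).

2. **Estimation and reduction** — Sobol quasi-Monte Carlo sweeps score each
   sampled point against every subject's measured strain with the fit error

       E_SS = α Σ_seg ∫ (ε_model − ε_meas)² dt + β (T_model − T_meas)²,

   (α = 1 s⁻¹, β = 0.1 s⁻², integral from QRS onset to 50% relaxation of
   the global RV strain).  Per subject, the 100 best points yield each
   parameter's diaphony d_i = |(1/N_b) Σ e^{2πi x_i}| — 0 when the best
   fits leave the parameter uniform (unidentifiable), 1 when they agree on
   a value.  The least identifiable parameters are omitted, and the
   omission is validated by re-fitting every subject with
   constriction particle-swarm optimization (30 particles, w = 0.729,
   c1 = c2 = 1.49445, energy-based stopping): a reduction is accepted only
   if the cohort's mean fit error stays similar.

A bundled phenomenological multi-segment strain simulator (equal-tension
coupling of the RV free-wall segments, with a configurable
"crashed-simulation" region) and a synthetic echo-like cohort generator
(60 Hz sampling, 0.5% strain noise, baseline drift, concealed / electrical /
structural disease archetypes) make the whole pipeline runnable and
testable end to end without patient data.  See `docs/methods.md` for the
full model and design discussion.

## Worked example

```python
import numpy as np
from strainfit import (ToyModel, SubsetMask, build_demo_registry,
                       make_cohort, run_reduction, ReductionConfig)

space = build_demo_registry()          # 20 parameters, 4 inert placeholders
model = ToyModel(space)
cohort = make_cohort(model, 10, rng=np.random.default_rng(42))
record = run_reduction(model, SubsetMask.full(space),
                       [s.measured for s in cohort],
                       ReductionConfig(qmc_n=2**14),
                       rng=np.random.default_rng(7))
for r in record.rounds:
    print(f"round {r.round}: omit {r.omitted} accepted={r.accepted} "
          f"mean E_SS {np.mean(r.pso_errors_before):.3f}"
          f" -> {np.mean(r.pso_errors_after):.3f}")
print("final subset:", record.final_active)
```

prints (about five minutes on one CPU):

```
round 1: omit ['SfAct_RV_apex', 'SfAct_LVfw', 'aux_b_RV_base', 'aux_global_00', 'aux_global_01'] accepted=True mean E_SS 0.295 -> 0.329
round 2: omit ['dT_RV_apex', 'SfAct_IVS', 'rel_systole', 'aux_a_RV_mid'] accepted=True mean E_SS 0.329 -> 0.405
round 3: omit ['SfAct_RV_base', 'dT_RV_base', 'av_delay'] accepted=False mean E_SS 0.405 -> 2.667
round 3: omit ['SfAct_RV_base'] accepted=True mean E_SS 0.405 -> 0.393
round 4: omit ['k_lin_RV_apex', 'dT_RV_mid', 'k_lin_IVS'] accepted=False mean E_SS 0.393 -> 0.609
round 4: omit ['dT_RV_mid'] accepted=True mean E_SS 0.393 -> 0.411
round 5: omit ['k_lin_RV_apex', 'dT_RV_base', 'k_lin_IVS'] accepted=False mean E_SS 0.411 -> 2.622
round 5: omit ['dT_RV_base'] accepted=False mean E_SS 0.411 -> 2.407
final subset: ['k_lin_RV_apex', 'SfAct_RV_mid', 'k_lin_RV_mid', 'k_lin_RV_base', 'dT_RV_base', 'k_lin_IVS', 'av_delay', 'cardiac_output', 'cycle_time']
```

Reading it: all four placeholder parameters leave in the first two rounds
at essentially no cost to the cohort fit (mean E_SS is in %²·s).  Proposals
that touch the parameters carrying the synthetic disease — basal activation
delay, basal/mid stiffness — blow the fit error up sixfold and are
rejected, so they survive to the final subset; subsequent particle-swarm
fits on that subset recover their per-subject ground-truth values with
Spearman rank correlations of 0.79–0.95 (the lowest belongs to basal
stiffness, whose ground truth is near-tied across the unaffected
subjects).  Basal contractility is the
instructive exception: with strain-only data under shared wall tension its
omission barely moves the fit (0.405 → 0.393), so the loop discards it —
the identifiability analysis is telling you that separating contractility
from stiffness and timing needs more than strain curves.

The same stages are scriptable from a shell (`strainfit cohort make`,
`strainfit morris run`, `strainfit qmc run`, `strainfit pso fit`,
`strainfit reduce run`), each driven by a YAML config with a single root
seed.

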