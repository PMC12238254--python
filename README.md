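# orthoplan

Multi-task reinforcement-learning treatment planning for combined
orthodontic-orthognathic therapy, with an explainability layer for clinical
review.

Severe dentofacial deformities — skeletal class II/III discrepancies,
asymmetries, vertical problems — are treated over ~2 years by interleaving
orthodontic tooth movement with orthognathic surgery and soft-tissue
management.  Planning such treatment means balancing four competing
objectives (function, aesthetics, efficiency, stability) across a long
sequence of interdependent decisions.  `orthoplan` frames this as a Markov
decision process and provides, for researchers in clinical decision support
and medical RL:

* a **synthetic patient simulator**: cohorts calibrated to an adult surgical
  orthodontic population (age 22.7 ± 4.3 y on [18, 35], 57.1% female,
  exclusive sagittal class II/III with class-conditional ANB −2.8°/5.9°,
  independent asymmetry and vertical-discrepancy labels), plus a treatment
  environment with saturating biomechanical proxy dynamics over a
  137-measurement craniofacial state;
* a **multi-task soft actor-critic planner** maximising
  `J(π) = E[Σ_t γ^t Σ_i w_i r_i(s_t, a_t)]` with twin vector critics
  `Q_θ(s,a) = [Q¹, …, Q⁴]`, shared/task-specific state encoders
  `φ(s) = [h_shared, h_task]`, a hybrid continuous/categorical action space
  (jaw movement vectors ±15/±10/±8 mm, 50–300 g force systems, appliance and
  phase decisions, 4–8 week recall intervals) and auto-tuned entropy
  temperature;
* **explainability tools**: Shapley-sampling feature attribution with
  enforced completeness, decision-tree policy surrogates with held-out
  fidelity, bounded counterfactual search, and phase-segmented trajectory
  narratives;
* **evaluation metrics**: the composite treatment-plan quality score
  `TPQS = 4 Σ_i w_i Q_i` (AHP weights 0.30/0.25/0.25/0.20, components 0–25
  points, reported on 0–100), forecast accuracy
  `1 − (1/m) Σ_j |ŷ_j − y_j|/y_j`, the efficiency index
  `Q_outcome/(ΔT·C_resources)`, the clinician confidence score, a
  chronological 70/15/15 splitter, and a permutation-test policy-comparison
  harness.

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

```python
import orthoplan as op
from orthoplan.agent import TrainConfig

cohort = op.sample_cohort(op.CohortConfig(n=50, seed=7))
planner = op.TreatmentPlanner(
    cohort,
    train_config=TrainConfig(total_steps=8_000, start_steps=500,
                             update_every=2, eval_every=4_000,
                             eval_episodes=3, seed=3),
)
results = planner.fit()
print(results.summary(n_episodes=20, seed=11))
```

```
Multi-task SAC treatment planner
======================================================
cohort size:              50
task weights (F/A/E/S):   (0.3, 0.25, 0.25, 0.2)
training steps:           8000
config hash:              c874dff8324eac8a
------------------------------------------------------
mean scalarized return:     3.7638 (sd 0.6917, n=20)
random-policy baseline:     3.1010 (sd 0.0819)
per-task returns (F/A/E/S): (0.2424, 0.2885, 9.9571, 5.6483)
mean episode TPQS (0-100):   51.98
======================================================
```

The trained planner's mean scalarized discounted return (3.76) clearly
exceeds the random-policy baseline (3.10); the per-task returns show where
it earns that margin (here mostly efficiency — long recall intervals — and
stability — small, well-timed movements that let relapse risk decay).  The
mean TPQS of deterministic planned episodes summarises end-of-treatment
quality on the 0–100 clinical scale.

```python
report = results.plan(cohort[0], seed=0)
print(f"patient {report.patient_id}: TPQS {report.tpqs:.1f}, "
      f"{len(report.actions)} planned visits")
```

```
patient syn-7-00000: TPQS 56.8, 28 planned visits
```

`report.actions` lists each visit's jaw-movement command, force system,
appliance, phase decision and recall interval; `report.predicted_trajectory`
tracks ANB, facial harmony, relapse risk and per-step rewards.
`results.simulate(...)` + `orthoplan.explain_trajectory(...)` produce the
phase-by-phase narrative, and `orthoplan.attribute / fit_surrogate /
counterfactual` explain individual recommendations.

A command-line interface mirrors the library
(`orthoplan simulate-cohort | rollout | train | plan | explain | evaluate |
run-pipeline`); `orthoplan run-pipeline --seed 0 --out runs/demo` executes
the full cohort → train → evaluate → explain chain and writes a manifest
sufficient to reproduce the run.

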