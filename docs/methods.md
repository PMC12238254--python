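# Methods

`orthoplan` models combined orthodontic-orthognathic treatment planning as a
multi-task Markov decision process and trains a soft actor-critic (SAC)
planner against a synthetic biomechanical proxy environment.  This note
documents the model, its assumptions, the parameters that matter, and the
design choices made where the design was genuinely open.

## The decision problem

Treatment of severe dentofacial deformities interleaves orthodontic tooth
movement, orthognathic surgical repositioning of the jaws, and soft-tissue
management over roughly two years of visits.  We cast this as an MDP
(S, A, P, R, γ):

* **State** `s_t = [skeletal, dental, soft_tissue, functional,
  treatment_status]`: 68 3-D skeletal landmarks (mm) plus cephalometric
  angles SNA/SNB/ANB and Angle class; 28 tooth positions (mm) with
  tip/torque/rotation (deg) and arch dimensions; a 64-point tissue-thickness
  map, lip competence, nasal breathing, and a 0–10 facial-harmony index;
  three functional indices on [0, 1] (occlusal function, TMJ health,
  respiration); and treatment status (phase 1–4, relapse risk, bone density,
  tissue adaptation — all on [0, 1] — and elapsed months).  Every state also
  answers a canonical 137-measurement schema (45 skeletal + 52 dental + 40
  soft-tissue parameters).  Beyond SNA/SNB/ANB and the named clinical
  indices, the remaining schema entries are documented placeholder
  parameters derived deterministically from the stored geometry — the
  counts, not the names, are fixed by convention.
* **Action** (hybrid): a continuous sub-vector — jaw movement commands
  (sagittal ±15 mm, vertical ±10 mm, transverse ±8 mm), orthodontic force
  (50–300 g, 3-D unit direction; magnitude 0 encodes "no active appliance"),
  and the recall interval (4–8 weeks) — plus categorical choices: appliance
  (brackets/wires/elastics), soft-tissue technique (V-Y advancement /
  reduction / none), timing (simultaneous/staged) and the phase decision
  (proceed/hold/modify).
* **Reward** `R = Σ w_i r_i` over four tasks, each clamped to [0, 1]:
  functional (mean full-scale improvement of the three functional indices),
  aesthetic (facial-harmony improvement on its 0–10 scale plus a
  profile-balance proxy from ANB moving toward its ~2° norm), efficiency
  (1 − normalised per-step time cost − visit burden − staged-surgery
  penalty), and stability ((1 − relapse risk) shaped by tissue adaptation:
  `(1 − relapse)(0.5 + 0.5·adaptation)`).  Default weights are the
  AHP-derived clinical priorities 0.30/0.25/0.25/0.20
  (function/aesthetics/efficiency/stability).

## Transition model (proxy dynamics)

No public transition model exists for this domain, so the environment uses a
first-order saturating linear-response model per block; all coefficients are
package conventions in `EnvConfig`, not literature claims:

* **Skeletal**: a commanded jaw vector `m` is realised as
  `sat(m) · (0.5 + 0.5·bone_density)` with `sat(x) = s·(1 − e^{−|x|/s})·sign x`
  and saturation scale `s = 8 mm/step` — diminishing returns for large
  per-step movements.  ANB changes by 0.5°/mm of realised sagittal movement
  (positive sagittal = maxillary advancement relative to the mandible,
  i.e. class III correction); SNB absorbs the change and the Angle class is
  re-derived (I for ANB 0–4°, II above, III below).
* **Dental**: angulations decay toward 0 at rate `k·e(F)` per month with
  `k = 0.25`; force effectiveness `e(F)` is linear up to the 150 g reference
  force and saturates above it (bonus ≤ 0.2) — the classic
  diminishing-returns force-response shape.
* **Soft tissue**: facial harmony moves toward its target (8.5) by a
  fraction proportional to 0.6 × the step's normalised skeletal correction,
  plus a small bonus when a surgical soft-tissue technique is used.
* **Functional**: the three indices relax toward 0.95 in proportion to the
  step's correction activity; with a null action they do not move.
* **Status**: relapse risk rises with per-step movement magnitude
  (0.15 × saturated fraction) and falls with tissue adaptation
  (0.05 × adaptation per month); bone density and tissue adaptation heal
  toward 1 at 0.08/month, slowed by heavy movement; phase advances on
  `proceed` only when stability gates pass (relapse ≤ 0.45, bone density
  ≥ 0.55), and completing phase 4 ends the episode.  Episodes otherwise end
  after 28 steps or 36 months.
* **Noise**: additive Gaussian perturbations (0.05 mm / 0.05° / 0.01 on unit
  scales), clipped back into valid ranges; setting the scales to zero makes
  `step` equal the deterministic response core exactly.

Consequences worth knowing: with a null action, morphology is a fixed point
and only time and healing indicators advance; repeated maximal correction
moves ANB monotonically; and two 5 mm steps realise more total movement than
one 10 mm step while carrying smaller per-step relapse increments.

## Synthetic cohort

The generator emulates the marginal statistics of an adult surgical
orthodontic population: age from a [18, 35]-truncated normal whose location
is calibrated (via the truncated-normal mean equation) so the sampled mean
is 22.7 y (sd 4.3 before truncation); 57.1% female; one mutually exclusive
sagittal class per patient with P(III) = 53.9/(40.9 + 53.9) — the published
class frequencies renormalised, since class II and III cannot co-occur —
plus independent asymmetry (0.380) and vertical-discrepancy (0.274) labels;
class-conditional ANB from truncated normals (III on [−12, −0.05]°, II on
[4.05, 14]°) calibrated to means −2.8° and 5.9°, keeping labels
sign-consistent with the cephalometric definition; and treatment duration
26.3 ± 6.7 months (calibration only).  Each record draws from a named,
spawned child stream of the cohort seed, so cohorts are bit-reproducible and
order-independent.

What the generator does **not** model: correlations among the 137
measurements beyond the class-conditional ANB structure, growth (the study
population excludes growing patients), imaging noise, and missing data.
Passing tests therefore demonstrate the machinery is correct under these
idealised marginals, not that the planner transfers to clinical data.

## Multi-task SAC

The planner is entropy-regularised off-policy actor-critic with:

* **Vector critics**: twin critics each output a 4-vector of per-task
  values.  Each critic encodes the state with a shared trunk
  (tanh MLP, 64-64) followed by per-task feature heads (32), matching the
  shared/task-specific representation φ(s) = [h_shared, h_task]; task value
  heads consume the task features together with the action.  Targets are
  per-task: `y_i = r_i + γ(min_twin Q_i(s', a') − α log π(a'|s'))`, so the
  weight-scalarized target identity `Σ w_i y_i = r_scalar + γ(Q̄' − α log π')`
  holds exactly for simplex weights.
* **Hybrid policy**: continuous sub-actions from a tanh-squashed Gaussian
  head mapped into the clinical bounds; categorical sub-actions from softmax
  heads.  The critics consume categorical *probability* vectors (one-hot
  for replayed samples), which keeps the actor loss fully reparameterized;
  the categorical entropy enters the soft objective analytically as −H(p).
  This relaxation is this package's concrete reading of a "modified" SAC
  for hybrid clinical actions.
* **Actor loss** `E[α log π(ã|s) − Σ w_i min_twin Q_i(s, ã)]` with
  reparameterized ã; **temperature** auto-tuned toward an entropy target
  (−dim(A_cont) by default; for discrete-only problems 0.2·Σ log K).
* **Optimisation**: Adam (lr 1e-3), batch 128, replay 10⁵, Polyak target
  rate 0.005, one update per two environment steps after 1,000 warm-up
  steps.  Default budget 50,000 steps; the test-suite and acceptance runs
  use a scaled-down budget of 8,000 steps on a 50-patient cohort (and a
  12,000-step run on the two-state oracle problem), sizes chosen as the
  smallest at which the learning contrasts of interest are statistically
  unambiguous.

All networks are small dense MLPs implemented directly on numpy with
hand-written backward passes; every backward pass (MLP, critic, full actor
loss including the tanh-Gaussian path and the softmax relaxation) is
verified against central finite differences in the test suite.
Observations are standardised with statistics from short random-policy
warm-up rollouts, frozen at model construction.  Bit-exact reproducibility
is promised for serial CPU execution with fixed seeds.

## Explanation layer

* **Attribution**: permutation-sampling Shapley estimator (default 256
  permutations; the tests and pipeline use fewer where the model is cheap to
  certify).  Each permutation's marginal contributions telescope to
  f(x) − f(baseline), so completeness holds to numerical precision;
  residual dust is redistributed equally.  For additive models the estimate
  equals the closed-form Shapley value exactly, for any number of
  permutations.  A finite-difference integrated-gradients variant
  (64-step straight path) is provided.  Because there is no imaging
  front-end, "attention over anatomy" is rendered as attribution totals per
  anatomical block (skeletal / dental / soft tissue / status).
* **Surrogate rules**: bounded-depth scikit-learn decision tree distilled
  from the policy's discrete decision; fidelity is always reported on a
  held-out half of the state sample, and constant policies yield a flagged
  one-leaf tree.
* **Counterfactuals**: minimise weighted-L1 distance + λ·sparsity subject to
  a target predicate (a margin function ≥ 0), clinical bounds, and a
  mutability mask (age and sex immutable by default), using greedy
  best-gain-per-cost feasibility search over per-feature candidate grids
  followed by coordinate-descent cost polishing, multi-started from random
  perturbations.  Infeasibility is reported as a result, not an exception.
  On small discretised problems the search is verified against exhaustive
  enumeration.
* **Trajectory explanations**: episodes are segmented by treatment phase;
  each segment is labelled with its dominant reward component (argmax of
  the weight-scaled component sums) and representative actions, with
  per-step justification records.  Reports render deterministically from
  templates in two registers: numeric tables for specialists, ranked
  qualitative statements for interdisciplinary communication.

## Evaluation metrics

* Forecast accuracy `1 − (1/m) Σ_j |ŷ_j(t) − y_j(t)| / y_j(t)`: exact
  predictions give 1; large errors may drive it negative.  A zero actual
  value is a hard domain error naming the outcome — the formula is
  undefined there and silent epsilon-smoothing would distort results.
* Efficiency index `Q_outcome / (ΔT_treatment · C_resources)`;
  `C_resources` is dimensionless with default 1.0 and must be supplied
  explicitly to mean anything else.
* Confidence score `α·Explainability + β·EvidenceStrength +
  γ·ConsensusAlignment` with simplex weights, default α=β=γ=1/3 (the
  surveyed weights behind this formula are unpublished; these defaults are
  package conventions).  Sub-score sources when computed from a fitted
  planner: surrogate fidelity for explainability; the others accept
  externally supplied scores.
* Chronological partition: sort by enrollment index; train and validation
  sizes are round-half-away-from-zero of fraction × N, the test split
  absorbs the remainder (347 → 243/52/52; 10 → 7/2/1).
* Policy comparison: matched episode seeds; paired sign-flip permutation
  tests (no normality assumption at small n; a paired t-test is available
  via scipy for users who prefer it) with Bonferroni correction across the
  reported metrics.  TPQS per episode is computed from the final clinical
  state: function = 25 × mean functional index, aesthetics =
  25 × harmony/10, efficiency = 25 × (1 − elapsed/horizon), stability =
  25 × (1 − relapse)(0.5 + 0.5·adaptation), aggregated with the AHP weights
  and scaled ×4 onto 0–100 — the ×4 maps the weighted 0–25 aggregate onto
  the 0–100 reporting scale without altering any relative comparison.

## Numerical choices and degenerate inputs

Reported percentages round half-away-from-zero to one decimal.  The
tanh-Gaussian log-density uses a 1e-6 floor inside the log; log-std is
tanh-bounded to [−5, 2] so its gradient is exact (no clipping
discontinuity).  Double-Q minima break ties toward the first critic.
Replay sampling is with replacement.  Zero-length cohorts, empty
trajectories, out-of-range TPQS components, non-simplex weights and
stepping a finished episode all raise typed errors rather than degrading
silently.

## Known limitations

The transition model is a qualitative proxy: it honours direction,
saturation, relapse and healing effects but is not calibrated to measured
tissue mechanics, and TMJ dynamics and growth are out of scope.  The
synthetic cohort reproduces marginals only.  Learned-policy quality is
assessed against a random-policy baseline and a dynamic-programming oracle
on small problems — not against clinicians.  Counterfactual search is a
heuristic with a verified optimality ratio only on small grids.
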