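# Methods

## Model

`boolsde` simulates cell-signaling cascades as *extended Boolean
networks*: node activities are continuous, non-negative real variables
rather than binary states, and the logic gates act on real-valued
interaction weights. The activity `x_i(t)` of protein `i` in a weighted
directed network obeys the stochastic differential equation

    dx_i = ( k_u * Σ_{k ∈ up(i)} B_k x_k  −  k_d * B_i x_i ) dt
           + σ x_i dW_i(t)

with one independent Wiener process `W_i` per node. The first term is
activation by the immediately upstream proteins, the second is loss of
activity through engagement with downstream partners (the protein is
released and inactivated after it has acted), and the multiplicative
noise term models stochastic self-activity — spontaneous production or
degradation proportional to the current activity level, so the inactive
state `x = 0` is noise-free and absorbing.

`B_i` is the **Waller–Kraft gate** of node `i`, evaluated over the
node's full set of outgoing edge weights `w_i = (w_i1, …, w_im)`:

    B_i(w; r) = r · min(w) + (1 − r) · max(w),    0 ≤ r ≤ 1.

`r = 1` reduces to the fuzzy AND (minimum), `r = 0` to the fuzzy OR
(maximum); `r ∈ [0.5, 1]` is conventionally read as the AND regime. The
gate captures simultaneous binding/detachment on a scaffold: a protein's
throughput is one blended value over all of its interactions, and that
same gated output drives *each* of its downstream targets. Only this
single operator family is implemented; the OR regime is reached by
choosing `r < 0.5`, not by a separate operator.

Boundary roles follow topology. Receptors (no incoming edges) have no
upstream term (`k_u` effectively 0 for them) and are activated only by
external stimuli, which set their activity to exactly 1. Terminal
readout nodes (no outgoing edges, e.g. a phenotype node) have no
downstream loss term (`k_d` effectively 0) and no gate of their own.

### Assumptions

- Activated proteins bind a scaffold instantaneously and independently;
  after acting on their immediate downstream partner they detach and
  inactivate. Binding/detachment is not modeled mechanistically — it is
  summarized by the gate and the loss term.
- All interactions are activating; weights lie in [0, 1], are drawn
  once per simulation from U[0, 1] (or assigned), and do not change
  over time.
- No feedback loops, no inhibitory edges, no spatial effects, binding
  kinetics, or phosphorylation rates.

## Numerical integration

The system is integrated with the explicit Euler–Maruyama scheme

    X(t+Δt) = X(t) + f(X(t)) Δt + g(X(t)) ΔW.

Two noise-increment conventions are exposed through
`SimulationConfig.noise_scale`:

- `variance_dt` (default): `ΔW ~ N(0, Δt)`, i.e. standard deviation
  `√Δt` — the standard Wiener-increment reading, under which `σ` has
  its usual meaning as a diffusion rate and the scheme converges to the
  SDE above.
- `sd_dt`: increments with standard deviation `Δt`. This variant is
  provided because "standard deviation Δt" is a convention that appears
  in some descriptions of this class of model; under it the effective
  diffusion is `σ√Δt` and vanishes in the continuum limit. All shipped
  defaults and experiments use `variance_dt`.

The discrete drift step can overshoot below zero even though
multiplicative noise preserves sign in continuous time; by default
activities are floored at 0 after each step (`clamp_floor=True`),
matching the interpretation of 0 as the inactive state. There is no
ceiling — activities may exceed 1, which is how near-simultaneous
stimulation of several receptors produces adaptor overshoot.

Reference resolution is `Δt = 0.001` with 60,000 steps (t ∈ [0, 60]).
The test suite, the `--fast` preset profile and the acceptance script
use a reduced profile, `Δt = 0.01` with 6,000 steps — the same horizon
at a tenth of the cost; the Euler error is first-order in `Δt` and the
ensemble statistics of interest are insensitive to the change (the
convergence test verifies the order directly).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `k_u` | 1.0 | upstream activation rate (0 for receptors) |
| `k_d` | 1.0 | downstream inactivation rate (0 for terminals) |
| `σ` | 1.0 | self-activity noise rate (0 = deterministic ODE limit) |
| `r` | 0.75 | Waller–Kraft blend; AND-regime default |
| `Δt` | 0.001 | time step (dimensionless time units) |
| `n_steps` | 60,000 | horizon t ∈ [0, 60] |

## The MAPK fixture

`build_mapk_fixture()` returns the simplified MAPK cascade used
throughout: 11 proteins, 14 weighted interactions. The constrained part
is: receptors EGFR, ERBB2 and MET, each with exactly two outgoing
interactions and all three converging on the adaptor GRB2 (in-degree
exactly 3); GRB2 with a single outgoing interaction to SOS; the backbone
GRB2 → SOS → RAS → RAF → MEK → ERK → Phenotype, where Phenotype stands
for an ERK-controlled cell phenotype (proliferation, migration,
survival) and is the only terminal.

The remaining wiring is a **documented reconstruction** — the source
network diagram is not tabulated edge-by-edge anywhere, so the identity
of the 11th node and the routing of the last edges is a modeling choice.
The fixture adds one auxiliary internal adaptor node (`AUX`, an SHC/GAB-
like layer, standard in receptor-tyrosine-kinase signaling): each
receptor's second edge targets AUX, and AUX feeds the backbone at SOS
and RAS. This choice is forced by the model's signal-accounting
structure: integrating the activity equation over a run that starts and
ends near zero gives

    B_i · AUC_i ≈ Σ_{k ∈ up(i)} B_k · AUC_k,

so each node's gated total activity equals the sum over its upstream
inflows, which telescopes to the number of directed receptor-to-node
paths. A terminal auxiliary node adds no paths, and mean total activity
then cannot grow along the backbone; the parallel adaptor route yields
path counts 1, 2, 3, 3, 3, 3 along GRB2…ERK — downstream signal
amplification, which is the cascade behavior the model exists to
reproduce. Users can always load their own wiring from SIF / JSON /
edge-list files instead.

## Stimulation

A `StimulusSchedule` names receptors set to activity 1 at t = 0, timed
explicit activations (applied at the first grid point at or after the
event time), and optionally *threshold-triggered re-stimulation*: a
receptor that has returned to (almost) the inactive state is re-excited.
"Almost inactive" is quantified as activity < ε with ε = 0.01 by
default. A refractory rule prevents chatter at the threshold: a node
becomes eligible for re-stimulation only after its activity has risen
to at least 2ε, and each reset disarms it until it re-crosses 2ε (which
the reset to 1 does immediately, so the node fires exactly once per
downward crossing). Stimulation always overwrites the activity with
exactly 1 rather than adding to it.

## Ensembles and statistics

`run_ensemble` repeats the simulation under per-run U[0,1] weight draws
and independent noise streams. All randomness derives from one root
seed: member `s` draws weights from the `SeedSequence` child with spawn
key `(s, 0)` and noise from `(s, 1)`, so every member is reproducible
in isolation and results do not depend on the ensemble size. Runs are
integrated simultaneously (vectorized over the run axis) and summaries
are accumulated online, so full trajectories are only stored on request.

Per run and node:

- **AUC** — trapezoidal integral of activity over the full horizon
  (activity × time units); the "overall activity" measure.
- **peak** — earliest argmax of activity (ties resolved to the earlier
  time).
- **decay time** — first grid time after the peak at which activity
  falls to a stated fraction (default 10%) of the peak value. Undefined
  (NaN) when the level is never reached within the horizon; pooled
  analyses right-censor undefined values at the horizon. Terminal nodes
  are excluded from pooled decay comparisons: with `k_d = 0` they have
  no deterministic inactivation route, so their "decay" is not a
  comparable quantity between the noisy and noise-free conditions.
- **time to full inactivation** — first grid time at which every
  non-receptor activity is below ε = 0.01, counted only after at least
  one non-receptor has exceeded ε (at t = 0 the condition would hold
  vacuously), censored at the horizon.

Aggregates are the per-time-step mean and sample standard deviation
over runs, and per-node mean/SD/CV of the AUC distribution, with
CV = s/μ using the (n−1)-denominator sample standard deviation. The
Student (pooled-variance) two-sample t-test is the default comparison;
Welch's variant is available.

## Experiment presets

`run_preset` packages the canned experiments: single EGFR stimulus with
σ = 0 and σ = 1; the MEK→ERK weight sweep (all weights 0.5, MEK→ERK at
0.25/0.5/0.75 — the sweep defaults to σ = 1, overridable, since the
variant σ is not pinned down by the protocol); the 1000-run ensemble
with its paired σ = 0 companion and decay-time t-test; repeated
threshold-triggered stimulation of all three receptors with a peak-time
report and a fixed-window (t ∈ [0, 15]) AUC/CV report; the k_u/k_d/σ
sweep at 100%/50%/10% of defaults; and the r-sweep over
{0.0, 0.25, 0.75, 1.0} with pairwise t-tests on time-to-full-
inactivation. Reports carry both the integer step index and real time.

## What the synthetic setup does and does not show

The fixture plus U[0,1] weights is a study system, not a calibrated
model: rate constants and weights are not fit to measurements, time is
dimensionless, and the network omits feedback, inhibition and spatial
structure. Passing tests therefore demonstrate properties of the model
class — sequential activation down the cascade, downstream
amplification of both signal and noise, noise-accelerated inactivation,
receptor-coincidence overshoot of the adaptor — not quantitative
predictions about any real cell line.

Two statistical caveats are inherent to the setup. Per-run AUC is
heavy-tailed (a node's total activity scales with the reciprocal of its
own gate, and reciprocals of uniform draws have slowly-converging
means), so adjacent backbone nodes with theoretically tied means
permute freely in finite ensembles; amplification claims are therefore
checked as proximal-vs-distal and endpoint comparisons rather than
strict per-pair monotonicity of sample means. And the AND/OR contrast
of inactivation times is dominated by the left tail of the min-gate at
exactly r = 1 (on the fixture only the receptors and AUX carry
multi-weight gates), which makes the r = 1.0 vs r = 0.75 contrast
measurably non-null in this reconstruction — a wiring-dependent
property worth keeping in mind when comparing operator regimes on other
networks.

## Numerical and design details

- Validation rejects self-loops, duplicate edges, dangling endpoints,
  weights outside [0, 1], and declared roles contradicting topology;
  error messages name the offending record.
- Gate evaluation for a terminal node (empty outgoing weight set) is
  defined as 0 at the engine level; the operator itself rejects empty
  weight lists.
- Non-finite activities abort the run with the step and run context.
- Ties in `peak` go to the earliest grid index; `decay_time` scans
  strictly after the peak index.
- Degenerate t-test inputs (zero pooled variance) raise instead of
  returning NaN.
- Trajectory writers emit tidy TSV (`time, node, activity`) and wide
  CSV with the resolved configuration embedded as `#` header comments;
  reruns with identical inputs are byte-identical.
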