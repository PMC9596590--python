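# Methods

## Model

The learned state of a parallel fibre → Purkinje cell synapse is a
single unitless weight *L*, confined to the open interval (0, 1).  The
model deliberately abstracts the molecular induction machinery (calcium
dynamics, CaMKII, AMPA-receptor trafficking) into this scalar: rising
*L* is depression (LTD), falling *L* is the extinction direction, and
the only trial-level inputs are whether a climbing-fibre teaching
signal is present (*T* ∈ {0, 1}) and, for the feedback gate, the
parallel-fibre firing rates of the co-activated group.

Three update rules are implemented.

* **core** — `L_n = L_{n-1} + k (T_n − L_{n-1})`.  Geometric relaxation
  toward the teaching signal.  Under an all-paired schedule it has the
  closed form `L_n = 1 − (1 − L_0)(1 − k)^n`, which the tests use as an
  independent oracle.
* **inertia** — the core step multiplied by `m = L_{n-1}` (paired) or
  `m = 1 − L_{n-1}` (unpaired), times a strength constant fixed at 1.
  Steps are smallest near the limit the trial pushes away from, which
  produces sigmoid acquisition/extinction curves and makes *L* = 0 and
  *L* = 1 exact fixed points.
* **inertia_adjusted** — as inertia, except unpaired trials taken from
  `L_{n-1} > b` use the damped down-step
  `ΔL = − L (1−L)² / ((1−b)(1−k))`, whose magnitude is strictly
  decreasing on (b, 1) and vanishes as *L* → 1.  This models a learned,
  microzone-wide reduction of dendritic calcium influx (via trained
  feed-forward inhibition) that preferentially suppresses extinction at
  strongly depressed synapses: acquired memories become progressively
  harder to erase.  The down-step is discontinuous with the plain
  inertia step at *L* = b (no value of *k* makes them match); it is
  implemented exactly as stated, with no smoothing.

**Feedback gate.**  A group of synapses activated in volley receives
its teaching signal through `T = H(f ⟨r⟩ − ⟨r L⟩)`: the climbing-fibre
signal is blocked when the group's average rate–weight product exceeds
the threshold `f ⟨r⟩`.  Both averages use the current trial's sampled
rates of the active group's members only, so the threshold is set
trial by trial — this embodies the assumption that excitatory drive to
the inferior olive scales linearly with the mean parallel-fibre rate,
and makes the gate exactly invariant to rescaling all rates.  Exact
equality blocks the signal (H(0) = 0); the convention is configurable
(`tie_rule`) and immaterial in practice since ties have measure zero.

**Drift criterion.**  Near the lower limit the inertia rule multiplies
*L* by (1 + k) on paired and (1 − k) on unpaired trials, so the
expected per-trial change of ln L is `p ln(1+k) + (1−p) ln(1−k)`.  Its
sign predicts whether a synapse trained at pairing probability *p*
reliably escapes the bottom of the range (learns) or collapses back.
At p = 0.6 the criterion is clearly negative at k = 0.8 (−0.291),
clearly positive at k ≤ 0.2, and nearly zero at k = 0.4 (−0.0024) —
the near-critical coefficient whose erratic, fluctuation-driven onsets
the ensembles reproduce.  The symmetric criterion at the upper limit
follows with p ↦ 1 − p.

## Synthetic trial generation

The generator defines the study conditions; it produces two kinds of
schedule.

*Single synapse*: the synapse is active every trial and *T* is drawn
i.i.d. Bernoulli(p), with no gate.  Used for the learning-coefficient
sweep (p = 0.6, 1500 trials, k ∈ {0.8, 0.4, 0.2, 0.1, 0.05}).

*Population*: a G×G grid (default 4×4) with G row-groups and G
column-groups; every synapse belongs to exactly one of each.  With
probability `cf_prob` (default 0.5) a trial is a climbing-fibre trial:
one of the 2G groups, chosen uniformly, is activated in volley with
olivary drive, and the gate decides *T* for its members.  Non-members
are silent on such trials.  Otherwise each synapse independently
receives an unpaired background activation with probability `a`,
calibrated in closed form so that the probability an activation is
paired (before any feedback blocking) equals the synapse's assigned
`p_pair`:  `a = [cf_prob · 2/(2G)] · (1 − p_pair) / (p_pair (1 − cf_prob))`.
Monte-Carlo tests confirm the realised pairing probability to within
sampling error.

`p_pair` values are drawn from four bands (0.66–0.72, 0.72–0.78,
0.78–0.84, 0.84–0.90) arranged as a random Latin square, so every row
and column group contains one synapse from each band.  All bands lie in
the regime that would individually teach acquisition — the point of the
study design is that the feedback threshold forces a split anyway.
Firing rates are drawn per activation, uniformly in [100, 300] Hz in
the full condition.  Two controls: `fixed_all` (all rates 200 Hz,
p_pair = 0.8 everywhere) and `variable_rates_only` (p_pair = 0.8,
per-synapse 50 Hz sub-intervals centred on a base drawn from
[125, 275] Hz).  Whether rates are redrawn per activation or fixed per
synapse is ambiguous in principle; per-activation redraw is the
default, with per-synapse limits as the `variable_rates_only` reading.

Within a climbing-fibre trial the gate is evaluated on pre-trial
weights and all member updates are applied synchronously, matching the
recurrence's indexing of every update by `L_{n-1}`.  A single seeded
RNG with a documented draw order (band assignment → profiles →
per-trial draws) makes schedules bit-reproducible; schedules serialise
to CSV and replay exactly (`%.17g` formatting and round-trip float
parsing — the default fast CSV parser is not correctly rounded and
would break bit-exact replay).

What the generator does **not** emulate: real mossy-fibre → granule
cell recoding or pattern content (patterns are reduced to group
identity), non-stationary or correlated pairing probabilities (each
synapse's probability is fixed for the run, whereas real training
statistics drift), spike timing, and any physiological magnitude for
`cf_prob`.  Passing tests therefore show that the circuit-level
mechanism produces its claimed outcomes under the stated stochastic
conditions — not that those conditions quantitatively match recorded
cerebellar activity.

## Parameter defaults and rationale

| parameter | default | meaning / rationale |
|---|---|---|
| k | 0.1 | learning coefficient; the value in the reliable, consistently paced regime at mid-range pairing probabilities |
| b | 0.95 | onset of the damped extinction step.  The adjustment models a near-saturation stabilising effect; because the damped step just above *b* is intrinsically ~1/(k(1−k)) times the inertia step, a mid-range *b* would act as a strong mid-range destabiliser instead of a memory-stabiliser, so *b* is placed in the top 5 % of the range |
| eps | 1e-9 | clamp margin keeping weights off the absorbing boundaries.  Chosen small enough to be numerically inert: a larger margin acts as a reflecting floor that measurably inflates the probability of lucky escapes at large k |
| f_coeff | 0.8 | feedback threshold coefficient; sets the depressed fraction of a trained group and approximates the reported 80–85 % of strongly depressed parallel-fibre synapses |
| inertia_strength | 1.0 | the multiplier scale, treated as a constant |
| grid_size | 4 | 4 groups of four synapses with 4 overlapping cross-groups |
| cf_prob | 0.5 | a climbing-fibre signal in half of trials on average |
| n_trials | 1500 / 3000 | single-synapse and population runs respectively |
| L0 | 0.001 / 0.5 / 0.99 | acquisition runs start at the bottom of the range (a visibly naive synapse; starting at 1 % of the range already inflates lucky escapes at k = 0.8), population runs at the unbiased mid-point, extinction runs near saturation |
| delta | 0.1 | tolerance for counting a weight "at the limits" in polarisation summaries; reported with the counts so results are auditable at other values |

## Equilibrium structure of the population study

With groups of four and threshold *f*, at most three members of a group
can saturate high (a fourth would hold the product average above
threshold indefinitely).  The stable configuration is therefore three
saturated synapses plus one "loser" whose equilibrium weight
`x* ≈ 4f − 3` (0.2 at f = 0.8) maintains the group average at the
threshold: the loser is *stranded*.  Which synapse loses is decided by
the band assignment and stochastic history; the overlapping column
constraints force the losers toward a transversal of the grid.  The
modal ensemble outcome at the defaults is accordingly 12 of 16 weights
at the range limits with 4 stranded.  Counts of 13–16 occur when
individual losers are driven to the low limit instead; the count is a
transition-region quantity and single runs can print intermediate
values (e.g. 14) that are not the ensemble mode.  The acceptance suite
asserts the stronger, stable claims — every group's time-averaged
balance within 0.05 of threshold (18–20 of 20 seeds at the defaults;
occasional late-converging groups reach ≈ 0.06 at the 3000-trial
horizon) and a strictly smaller polarised fraction in the fixed-variable
control — alongside the modal-count check.

## Problem sizes and numerical choices

Ensembles use 50 runs per coefficient for the single-synapse sweep and
20 seeds for the population study, sizes at which the reported
fractions have standard errors well below the asserted margins.  Onset
latency is the first trial at which *L* ≥ 0.9 ("no learning" = no
crossing within the run).  The memory-stability comparison uses a
net-extinction mixed schedule (p = 0.4 from L0 = 0.99): at p ≥ 0.5 both
rule variants hold the weight high essentially always and the
comparison is degenerate.  Balance time-averages use expected
(mid-range) rates and post-trial weights; the per-trial sampled-rate
balance of the gated group is logged alongside.  All validation happens
at configuration time (open-interval constraints on k, b, f_coeff;
b ≥ k for the adjusted variant, which guarantees the damped step cannot
overshoot below zero — verified by brute-force grid in the tests;
unknown config keys rejected by name).

## Known limitations

* Group size 4 quantises the polarised fraction (3/4 saturate high for
  any f ∈ (0.75, 1)); the threshold-proportionality of the depressed
  fraction only emerges at larger grids.
* The adjusted extinction step's discontinuity at *L* = b is kept as
  stated; dynamics that linger exactly at *b* are sensitive to it.
* The at-limits count near the stranding boundary (x* ≈ δ) is
  intrinsically noisy; balance deviations are the stabler diagnostic.
* No attempt is made to fit k, f or the rate ranges to recorded
  physiology; they are study conditions, not estimates.
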