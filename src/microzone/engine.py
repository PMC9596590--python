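"""Seeded end-to-end simulation runs.

Three entry points:

* :func:`run_single_synapse` — one synapse trained on a Bernoulli
  schedule (every trial active, teaching signal drawn with fixed
  pairing probability, no feedback gate).
* :func:`run_k_sweep` — ensembles of single-synapse runs over a list of
  learning coefficients, with onset-latency and success summaries.
* :func:`run_population` — the grid population trained with overlapping
  climbing-fibre groups and the nucleo-olivary gate.  Three variants:
  ``fixed_all`` (all rates fixed at 200 Hz, pairing probability 0.8
  everywhere — the fully controlled condition), ``variable_rates_only``
  (pairing fixed at 0.8 but rates variable within per-synapse 50 Hz
  sub-intervals), and ``full`` (banded pairing probabilities and rates
  drawn from the full 100-300 Hz range per activation).

Within a climbing-fibre trial the gate is evaluated on the pre-trial
weights and all member updates are applied synchronously.  Background
activations update with T = 0.  Runs are deterministic given their
seed; :func:`replay_schedule` re-executes a serialised schedule and
must reproduce the stored trajectory exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LayoutError
from .feedback import FeedbackParams, GroupTrialInputs, teacher_signal
from .rules import RuleParams, apply_trial
from .schedules import (
    PAIRING_BANDS,
    PopulationLayout,
    SynapseProfile,
    TrialEvent,
    as_rng,
    assign_bands,
    bernoulli_schedule,
    calibrate_background_prob,
    sample_trial,
)

__all__ = [
    "POPULATION_VARIANTS",
    "TrajectoryRecord",
    "KSweepResult",
    "make_profiles",
    "run_single_synapse",
    "run_k_sweep",
    "run_population",
    "replay_schedule",
]

logger = logging.getLogger("microzone")

POPULATION_VARIANTS = ("fixed_all", "variable_rates_only", "full")

#: default trial counts: single-synapse sweeps and population training
N_TRIALS_SINGLE = 1500
N_TRIALS_POPULATION = 3000

#: default k values for the learning-coefficient sweep
K_SWEEP_DEFAULT = (0.8, 0.4, 0.2, 0.1, 0.05)


@dataclass
class TrajectoryRecord:
    """Per-trial log of a simulation run.

    ``weights`` has shape ``(n_trials + 1, n_synapses)`` (row 0 is the
    initial state).  For population runs, ``teacher`` holds the gated
    signal of each climbing-fibre trial (-1 on background trials),
    ``blocked`` flags cf trials whose signal the feedback gate removed,
    ``sampled_balance`` is the target group's mean(rL)/mean(r) computed
    with that trial's sampled rates and pre-trial weights (NaN on
    background trials), and ``expected_balance`` logs, for every group
    and trial, mean(rL)/mean(r) computed with expected (mid-range)
    rates and post-trial weights.
    """

    weights: np.ndarray
    teacher: np.ndarray
    target_group: Optional[np.ndarray] = None
    blocked: Optional[np.ndarray] = None
    sampled_balance: Optional[np.ndarray] = None
    expected_balance: Optional[np.ndarray] = None
    events: Optional[list[TrialEvent]] = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.weights.shape[0] - 1

    @property
    def final_weights(self) -> np.ndarray:
        return self.weights[-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format weight trajectory: trial, synapse, L."""
        n_trials_p1, n_syn = self.weights.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n_trials_p1), n_syn),
                "synapse": np.tile(np.arange(n_syn), n_trials_p1),
                "L": self.weights.ravel(),
            }
        )

    def blocked_count(self) -> int:
        return 0 if self.blocked is None else int(np.sum(self.blocked))


@dataclass
class KSweepResult:
    """Ensemble summary of a learning-coefficient sweep.

    ``table`` has one row per (k, rep): final weight, onset latency
    (NaN if the threshold was never reached) and success flag.
    ``trajectories`` maps (k, rep) to the weight time series.
    """

    table: pd.DataFrame
    trajectories: dict[tuple[float, int], np.ndarray]

    def summary(self) -> pd.DataFrame:
        """Per-k success fraction and latency statistics."""
        def _agg(g: pd.DataFrame) -> pd.Series:
            lat = g["latency"].dropna()
            return pd.Series(
                {
                    "success_fraction": g["success"].mean(),
                    "latency_median": lat.median() if len(lat) else np.nan,
                    "latency_var": lat.var(ddof=1) if len(lat) > 1 else np.nan,
                    "n": len(g),
                }
            )

        return self.table.groupby("k", sort=False).apply(_agg, include_groups=False)


def run_single_synapse(
    params: RuleParams,
    p: float,
    n_trials: int = N_TRIALS_SINGLE,
    seed=0,
    L0: float = 0.001,
) -> TrajectoryRecord:
    """Train one synapse on a Bernoulli(p) schedule (no feedback gate)."""
    rng = as_rng(seed)
    schedule = bernoulli_schedule(p, n_trials, rng)
    weights = np.empty((n_trials + 1, 1))
    L = float(L0)
    weights[0, 0] = L
    for n, T in enumerate(schedule):
        L = apply_trial(L, int(T), True, params)
        weights[n + 1, 0] = L
    return TrajectoryRecord(
        weights=weights,
        teacher=schedule,
        metadata={"p": p, "L0": L0, "params": params, "seed": seed},
    )


def run_k_sweep(
    k_list: Sequence[float] = K_SWEEP_DEFAULT,
    p: float = 0.6,
    n_trials: int = N_TRIALS_SINGLE,
    reps: int = 6,
    seed=0,
    L0: float = 0.001,
    variant: str = "inertia",
    success_threshold: float = 0.9,
) -> KSweepResult:
    """Ensembles of single-synapse runs across learning coefficients.

    Each (k, rep) pair gets an independent child seed spawned from
    ``seed``; onset latency is the first trial at which the weight
    reaches ``success_threshold``.
    """
    from .metrics import onset_latency  # local import to avoid a cycle

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(k_list) * reps)
    rows = []
    trajectories: dict[tuple[float, int], np.ndarray] = {}
    idx = 0
    for k in k_list:
        params = RuleParams(k=k, variant=variant)
        for rep in range(reps):
            rec = run_single_synapse(params, p, n_trials, seed=children[idx], L0=L0)
            idx += 1
            traj = rec.weights[:, 0]
            lat = onset_latency(traj, success_threshold)
            rows.append(
                {
                    "k": k,
                    "rep": rep,
                    "final_L": traj[-1],
                    "latency": np.nan if lat is None else float(lat),
                    "success": lat is not None,
                }
            )
            trajectories[(k, rep)] = traj
    return KSweepResult(table=pd.DataFrame(rows), trajectories=trajectories)


def make_profiles(
    layout: PopulationLayout,
    rng,
    variant: str = "full",
) -> list[SynapseProfile]:
    """Build per-synapse generative profiles for a population variant."""
    rng = as_rng(rng)
    if variant not in POPULATION_VARIANTS:
        raise ConfigurationError(
            f"variant must be one of {POPULATION_VARIANTS}; got {variant!r}"
        )
    if variant == "full":
        return assign_bands(layout, rng)
    profiles = []
    for _ in range(layout.n_synapses):
        if variant == "fixed_all":
            lo = hi = 200.0
        else:  # variable_rates_only: 50 Hz sub-interval around a per-synapse base
            base = float(rng.uniform(125.0, 275.0))
            lo, hi = base - 25.0, base + 25.0
        p = 0.8
        profiles.append(
            SynapseProfile(
                p_pair=p,
                rate_lo=lo,
                rate_hi=hi,
                background_prob=calibrate_background_prob(p, layout),
            )
        )
    return profiles


def _expected_balances(
    weights: np.ndarray,
    expected_rates: np.ndarray,
    group_members: Sequence[tuple[int, ...]],
) -> np.ndarray:
    out = np.empty(len(group_members))
    for g, members in enumerate(group_members):
        r = expected_rates[list(members)]
        w = weights[list(members)]
        out[g] = (r * w).mean() / r.mean()
    return out


def _run_events(
    events: Sequence[TrialEvent],
    layout: PopulationLayout,
    profiles: Sequence[SynapseProfile],
    params: RuleParams,
    fb: FeedbackParams,
    L0,
) -> TrajectoryRecord:
    n_syn = layout.n_synapses
    n_trials = len(events)
    L = np.full(n_syn, float(L0)) if np.ndim(L0) == 0 else np.asarray(L0, float).copy()
    if L.shape != (n_syn,):
        raise LayoutError(f"initial weights must have shape ({n_syn},)")
    group_members = [layout.group_members(g) for g in range(layout.n_groups)]
    expected_rates = np.array([pr.expected_rate for pr in profiles])

    weights = np.empty((n_trials + 1, n_syn))
    weights[0] = L
    teacher = np.full(n_trials, -1, dtype=np.int64)
    target_group = np.full(n_trials, -1, dtype=np.int64)
    blocked = np.zeros(n_trials, dtype=bool)
    sampled_balance = np.full(n_trials, np.nan)
    expected_balance = np.empty((n_trials, layout.n_groups))

    for n, ev in enumerate(events):
        if ev.kind == "cf_trial":
            members = list(ev.active_synapses)
            inputs = GroupTrialInputs(ev.rates, tuple(L[members]), ev.drive_present)
            T = teacher_signal(inputs, fb)
            r = np.asarray(ev.rates)
            sampled_balance[n] = float((r * L[members]).mean() / r.mean())
            teacher[n] = T
            target_group[n] = ev.target_group
            blocked[n] = T == 0
            if logger.isEnabledFor(logging.DEBUG):
                logger.debug(
                    "trial %d: group %d balance %.4f -> T=%d",
                    n, ev.target_group, sampled_balance[n], T,
                )
            L[members] = apply_trial(L[members], T, np.ones(len(members), bool), params)
        else:
            if ev.active_synapses:
                act = list(ev.active_synapses)
                L[act] = apply_trial(L[act], 0, np.ones(len(act), bool), params)
        weights[n + 1] = L
        expected_balance[n] = _expected_balances(L, expected_rates, group_members)

    return TrajectoryRecord(
        weights=weights,
        teacher=teacher,
        target_group=target_group,
        blocked=blocked,
        sampled_balance=sampled_balance,
        expected_balance=expected_balance,
        events=list(events),
    )


def run_population(
    layout: Optional[PopulationLayout] = None,
    profiles: Optional[Sequence[SynapseProfile]] = None,
    params: Optional[RuleParams] = None,
    fb: Optional[FeedbackParams] = None,
    n_trials: int = N_TRIALS_POPULATION,
    seed=0,
    variant: str = "full",
    L0=0.5,
) -> TrajectoryRecord:
    """Train the grid population with the feedback gate.

    When ``profiles`` is None they are generated for ``variant`` from
    the run's RNG (band/profile draws precede trial draws).  The update
    rule defaults to the ``inertia_adjusted`` variant used for
    population training; initial weights default to the unbiased 0.5.
    """
    layout = layout or PopulationLayout()
    params = params or RuleParams(variant="inertia_adjusted")
    fb = fb or FeedbackParams()
    rng = as_rng(seed)
    if profiles is None:
        profiles = make_profiles(layout, rng, variant)
    events = [sample_trial(layout, profiles, rng) for _ in range(n_trials)]
    rec = _run_events(events, layout, profiles, params, fb, L0)
    rec.metadata = {
        "layout": layout,
        "profiles": list(profiles),
        "params": params,
        "feedback": fb,
        "variant": variant,
        "seed": seed,
        "L0": L0,
    }
    return rec


def replay_schedule(
    events: Sequence[TrialEvent],
    layout: PopulationLayout,
    profiles: Sequence[SynapseProfile],
    params: RuleParams,
    fb: FeedbackParams,
    L0=0.5,
) -> TrajectoryRecord:
    """Re-execute a serialised schedule; deterministic (no RNG draws)."""
    return _run_events(events, layout, profiles, params, fb, L0)
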