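"""Stochastic training-schedule generation.

Two kinds of schedule are produced:

* a single-synapse Bernoulli schedule — every trial activates the
  synapse, and the teaching signal is drawn i.i.d. with a fixed pairing
  probability (used for learning-coefficient sweeps);

* a population schedule for a grid of synapses with overlapping
  climbing-fibre groups.  A G x G grid carries G row-groups and G
  column-groups; every synapse belongs to exactly one of each, so the
  groups can be visualised as a matrix.  Half of trials (on average)
  are climbing-fibre trials in which one group, chosen uniformly from
  all 2G, is activated in volley with excitatory drive to the olive;
  in the remaining trials each synapse may independently receive an
  unpaired activation, with a per-synapse background probability
  calibrated so that its overall probability of being paired *when
  active* equals an assigned target ``p_pair``.

``p_pair`` targets are drawn from four bands (low 0.66-0.72, mid-low
0.72-0.78, mid-high 0.78-0.84, high 0.84-0.90) arranged as a Latin
square so that every row-group and every column-group contains one
synapse from each band.  Firing rates are drawn per activation,
uniformly within per-synapse limits inside 100-300 Hz.

Draw order is fixed for reproducibility: band assignment, then profile
draws (synapse id order), then per-trial draws (branch, target or
background mask, rates in synapse id order).  Identical seeds give
bit-identical schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LayoutError

__all__ = [
    "PAIRING_BANDS",
    "PopulationLayout",
    "SynapseProfile",
    "TrialEvent",
    "assign_bands",
    "calibrate_background_prob",
    "sample_trial",
    "sample_rate",
    "bernoulli_schedule",
    "schedule_to_frame",
    "frame_to_schedule",
]

#: pairing-probability bands: low, mid-low, mid-high, high
PAIRING_BANDS: tuple[tuple[float, float], ...] = (
    (0.66, 0.72),
    (0.72, 0.78),
    (0.78, 0.84),
    (0.84, 0.90),
)

RATE_MIN, RATE_MAX = 100.0, 300.0


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PopulationLayout:
    """G x G synapse grid with overlapping row and column groups.

    Synapse ``(row, col)`` has flat id ``row * G + col`` and belongs to
    row-group ``row`` (group ids ``0 .. G-1``) and column-group ``col``
    (group ids ``G .. 2G-1``).  ``cf_prob`` is the probability that a
    trial is a climbing-fibre trial.
    """

    grid_size: int = 4
    cf_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.grid_size < 1:
            raise ConfigurationError(f"grid_size must be >= 1; got {self.grid_size}")
        if not 0.0 < self.cf_prob < 1.0:
            raise ConfigurationError(
                f"cf_prob must lie in the open interval (0, 1); got {self.cf_prob}"
            )

    @property
    def n_synapses(self) -> int:
        return self.grid_size * self.grid_size

    @property
    def n_groups(self) -> int:
        return 2 * self.grid_size

    def group_members(self, group_id: int) -> tuple[int, ...]:
        """Flat synapse ids of a group (rows first, then columns)."""
        G = self.grid_size
        if not 0 <= group_id < 2 * G:
            raise LayoutError(f"group id {group_id} outside 0..{2 * G - 1}")
        if group_id < G:  # row group
            return tuple(group_id * G + c for c in range(G))
        col = group_id - G
        return tuple(r * G + col for r in range(G))

    def group_map(self) -> dict[int, tuple[int, ...]]:
        return {g: self.group_members(g) for g in range(self.n_groups)}

    def groups_of(self, synapse_id: int) -> tuple[int, int]:
        G = self.grid_size
        return synapse_id // G, G + synapse_id % G


@dataclass(frozen=True)
class SynapseProfile:
    """Per-synapse generative parameters.

    ``p_pair`` is the target probability that an activation of this
    synapse is paired with a climbing-fibre signal (before any feedback
    blocking); ``rate_lo``/``rate_hi`` bound its per-activation firing
    rate; ``background_prob`` is the calibrated per-trial probability of
    an unpaired background activation; ``band`` indexes the pairing band
    the synapse was drawn from (-1 when bands are not used).
    """

    p_pair: float
    rate_lo: float
    rate_hi: float
    background_prob: float
    band: int = -1

    def __post_init__(self) -> None:
        if not 0.0 < self.p_pair < 1.0:
            raise ConfigurationError(f"p_pair must lie in (0, 1); got {self.p_pair}")
        if not RATE_MIN <= self.rate_lo <= self.rate_hi <= RATE_MAX:
            raise ConfigurationError(
                f"rate limits must satisfy {RATE_MIN} <= lo <= hi <= {RATE_MAX}; "
                f"got ({self.rate_lo}, {self.rate_hi})"
            )
        if not 0.0 <= self.background_prob < 1.0:
            raise ConfigurationError(
                f"background_prob must lie in [0, 1); got {self.background_prob}"
            )

    @property
    def expected_rate(self) -> float:
        return 0.5 * (self.rate_lo + self.rate_hi)


@dataclass(frozen=True)
class TrialEvent:
    """One generated training trial.

    ``kind`` is ``"cf_trial"`` (one group activated in volley with
    olivary drive) or ``"background_trial"`` (independent unpaired
    activations, no drive).  ``rates`` aligns with ``active_synapses``.
    """

    kind: str
    target_group: Optional[int]
    active_synapses: tuple[int, ...]
    rates: tuple[float, ...]
    drive_present: bool

    def __post_init__(self) -> None:
        if self.kind not in ("cf_trial", "background_trial"):
            raise ConfigurationError(f"unknown trial kind {self.kind!r}")
        if len(self.active_synapses) != len(self.rates):
            raise LayoutError("rates must align with active synapses")
        if self.kind == "background_trial" and self.drive_present:
            raise LayoutError("background trials carry no olivary drive")


def latin_square(G: int, rng: np.random.Generator) -> np.ndarray:
    """Random G x G Latin square over symbols 0..G-1.

    A cyclic base square is randomised by independent row, column and
    symbol permutations, which preserve the Latin property.
    """
    base = (np.arange(G)[:, None] + np.arange(G)[None, :]) % G
    rows = rng.permutation(G)
    cols = rng.permutation(G)
    syms = rng.permutation(G)
    return syms[base[np.ix_(rows, cols)]]


def calibrate_background_prob(p_pair: float, layout: PopulationLayout) -> float:
    """Background-activation probability realising ``p_pair`` exactly.

    A synapse belongs to m = 2 of the 2G groups, so per trial
    P(active & paired) = cf_prob * m / (2G).  Solving
    P(paired | active) = p_pair for the per-trial background probability
    ``a`` gives ``a = [cf_prob * m / (2G)] * (1 - p_pair) /
    [p_pair * (1 - cf_prob)]``.
    """
    if not 0.0 < p_pair <= 1.0:
        raise ConfigurationError(f"p_pair must lie in (0, 1]; got {p_pair}")
    if p_pair == 1.0:
        return 0.0
    paired_rate = layout.cf_prob * 2.0 / layout.n_groups
    a = paired_rate * (1.0 - p_pair) / (p_pair * (1.0 - layout.cf_prob))
    if a >= 1.0:
        raise ConfigurationError(
            f"p_pair={p_pair} is infeasible for this layout: required "
            f"background probability {a:.3f} >= 1"
        )
    return a


def assign_bands(
    layout: PopulationLayout,
    rng,
    bands: Sequence[tuple[float, float]] = PAIRING_BANDS,
    rate_lo: float = RATE_MIN,
    rate_hi: float = RATE_MAX,
) -> list[SynapseProfile]:
    """Assign pairing bands as a Latin square and draw per-synapse profiles.

    Requires as many bands as grid rows so that every row-group and
    every column-group contains exactly one synapse from each band.
    ``p_pair`` is drawn uniformly within the synapse's band.  All
    synapses share the given rate limits (drawn per activation).
    """
    rng = as_rng(rng)
    G = layout.grid_size
    if len(bands) != G:
        raise ConfigurationError(
            f"need exactly one band per grid row: grid_size={G} but {len(bands)} bands"
        )
    square = latin_square(G, rng)
    profiles: list[SynapseProfile] = []
    for sid in range(layout.n_synapses):
        band = int(square[sid // G, sid % G])
        lo, hi = bands[band]
        p = float(rng.uniform(lo, hi))
        profiles.append(
            SynapseProfile(
                p_pair=p,
                rate_lo=rate_lo,
                rate_hi=rate_hi,
                background_prob=calibrate_background_prob(p, layout),
                band=band,
            )
        )
    return profiles


def sample_rate(profile: SynapseProfile, rng) -> float:
    """Uniform per-activation firing rate within the synapse's limits."""
    if profile.rate_lo == profile.rate_hi:
        return float(profile.rate_lo)
    return float(as_rng(rng).uniform(profile.rate_lo, profile.rate_hi))


def sample_trial(
    layout: PopulationLayout,
    profiles: Sequence[SynapseProfile],
    rng,
) -> TrialEvent:
    """Draw one trial of the population schedule."""
    rng = as_rng(rng)
    if len(profiles) != layout.n_synapses:
        raise LayoutError(
            f"expected {layout.n_synapses} profiles, got {len(profiles)}"
        )
    if rng.random() < layout.cf_prob:
        g = int(rng.integers(layout.n_groups))
        members = layout.group_members(g)
        rates = tuple(sample_rate(profiles[i], rng) for i in members)
        return TrialEvent("cf_trial", g, members, rates, True)
    u = rng.random(layout.n_synapses)
    active = tuple(
        i for i in range(layout.n_synapses) if u[i] < profiles[i].background_prob
    )
    rates = tuple(sample_rate(profiles[i], rng) for i in active)
    return TrialEvent("background_trial", None, active, rates, False)


def bernoulli_schedule(p: float, n_trials: int, rng) -> np.ndarray:
    """Single-synapse schedule: i.i.d. Bernoulli(p) teaching signals.

    The synapse is active in every trial and no feedback gate applies.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"p must lie in [0, 1]; got {p}")
    if n_trials < 0:
        raise ConfigurationError(f"n_trials must be >= 0; got {n_trials}")
    return (as_rng(rng).random(n_trials) < p).astype(np.int64)


def schedule_to_frame(events: Sequence[TrialEvent]) -> pd.DataFrame:
    """Serialise a schedule to a tidy frame (one row per trial).

    Active synapse ids and rates are ';'-joined; rates use ``repr`` so
    the round trip is bit-exact.
    """
    rows = []
    for n, ev in enumerate(events):
        rows.append(
            {
                "trial": n,
                "kind": ev.kind,
                "target_group": -1 if ev.target_group is None else ev.target_group,
                "active_synapses": ";".join(str(i) for i in ev.active_synapses),
                "rates": ";".join(repr(r) for r in ev.rates),
                "drive_present": int(ev.drive_present),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial",
            "kind",
            "target_group",
            "active_synapses",
            "rates",
            "drive_present",
        ],
    )


def frame_to_schedule(frame: pd.DataFrame) -> list[TrialEvent]:
    """Inverse of :func:`schedule_to_frame` (bit-exact)."""
    events = []
    for _, row in frame.sort_values("trial").iterrows():
        active = tuple(
            int(t) for t in str(row["active_synapses"]).split(";") if t != "" and t != "nan"
        )
        rates = tuple(
            float(t) for t in str(row["rates"]).split(";") if t != "" and t != "nan"
        )
        tg = int(row["target_group"])
        events.append(
            TrialEvent(
                kind=str(row["kind"]),
                target_group=None if tg < 0 else tg,
                active_synapses=active,
                rates=rates,
                drive_present=bool(int(row["drive_present"])),
            )
        )
    return events
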