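"""Summary statistics and analytic diagnostics over trajectories.

Includes the population polarisation summary (how many weights finish
at the limits of their range, which are stranded mid-range), onset
latency of single-synapse acquisition, and the multiplicative drift
criterion that explains the learning-coefficient regimes: near L = 0
the inertia rule multiplies L by (1 + k) in paired trials and (1 - k)
in unpaired ones, so the expected per-trial change of log L is

    p log(1 + k) + (1 - p) log(1 - k).

A positive value predicts reliable escape from the lower limit
(learning); a negative one predicts collapse back to it (no learning),
independent of how long training runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .feedback import FeedbackParams, GroupTrialInputs, group_balance

__all__ = [
    "PolarisationSummary",
    "polarisation_summary",
    "onset_latency",
    "drift_criterion",
]


@dataclass(frozen=True)
class PolarisationSummary:
    """Final-state polarisation of a synapse population.

    A weight counts as at-limit when ``L >= 1 - delta`` or
    ``L <= delta``; the rest are stranded mid-range.  When a group map
    and rate/threshold information are supplied, per-group balance
    deviations (mean(rL)/mean(r) - f_coeff, expected rates) are
    reported alongside.
    """

    n_at_limits: int
    at_limits: tuple[int, ...]
    stranded: tuple[int, ...]
    delta: float
    balance_deviations: Optional[dict[int, float]] = None

    @property
    def n_stranded(self) -> int:
        return len(self.stranded)


def polarisation_summary(
    final_weights,
    group_map: Optional[Mapping[int, Sequence[int]]] = None,
    delta: float = 0.1,
    expected_rates=None,
    f_coeff: Optional[float] = None,
) -> PolarisationSummary:
    """Count at-limit and stranded synapses; optionally group balances."""
    if not 0.0 < delta < 0.5:
        raise ConfigurationError(f"delta must lie in (0, 0.5); got {delta}")
    w = np.asarray(final_weights, dtype=float)
    at = np.flatnonzero((w >= 1.0 - delta) | (w <= delta))
    stranded = np.flatnonzero((w > delta) & (w < 1.0 - delta))
    deviations = None
    if group_map is not None and expected_rates is not None and f_coeff is not None:
        fb = FeedbackParams(f_coeff=f_coeff)
        r = np.asarray(expected_rates, dtype=float)
        deviations = {
            g: group_balance(
                GroupTrialInputs(tuple(r[list(m)]), tuple(w[list(m)])), fb
            )
            for g, m in group_map.items()
        }
    return PolarisationSummary(
        n_at_limits=int(at.size),
        at_limits=tuple(int(i) for i in at),
        stranded=tuple(int(i) for i in stranded),
        delta=delta,
        balance_deviations=deviations,
    )


def onset_latency(trajectory, threshold: float = 0.9) -> Optional[int]:
    """First trial index at which the weight reaches ``threshold``.

    Returns None when the trajectory never crosses (no learning within
    the run).
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must lie in (0, 1); got {threshold}")
    traj = np.asarray(trajectory, dtype=float).ravel()
    hits = np.flatnonzero(traj >= threshold)
    return int(hits[0]) if hits.size else None


def drift_criterion(k: float, p: float) -> float:
    """Expected per-trial log-growth of the weight near the lower limit.

    The sign predicts the single-synapse learning regime at pairing
    probability ``p``; by the rule's symmetry, the criterion at the
    upper limit follows with p replaced by 1 - p.
    """
    if not 0.0 < k < 1.0:
        raise ConfigurationError(f"k must lie in (0, 1); got {k}")
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"p must lie in [0, 1]; got {p}")
    return p * np.log1p(k) + (1.0 - p) * np.log1p(-k)
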