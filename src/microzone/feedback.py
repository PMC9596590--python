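"""Nucleo-olivary feedback gate.

A microzone's Purkinje cells inhibit, via the deep cerebellar nuclei, the
inferior olive group that supplies their climbing fibres.  As training
depresses parallel-fibre transmission, Purkinje output falls, the
GABAergic nucleo-olivary pathway is disinhibited, and — once the group's
learned depression is deep enough — the feedback blocks the olivary
discharge, so a nominally paired trial arrives with no teaching signal.

The gate is binary per trial.  With ``r`` the parallel-fibre firing
rates of the active group and ``L`` their weights, the teaching signal is

    T = H( f <r> - <r L> )

where ``<.>`` is the average over the group's members this trial, ``f``
is a coefficient < 1, and H is the Heaviside step.  The threshold
``f <r>`` is recomputed trial by trial from the sampled rates, which
embodies the model's assumption that excitatory drive to the olive
scales linearly with the mean parallel-fibre rate: scaling every rate by
a positive constant leaves the gate decision unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, LayoutError

__all__ = ["FeedbackParams", "GroupTrialInputs", "teacher_signal", "group_balance"]

TIE_RULES = ("block", "teach")


@dataclass(frozen=True)
class FeedbackParams:
    """Feedback threshold coefficient and the H(0) convention.

    ``f_coeff`` sets the gate threshold at ``f_coeff * mean(rates)``; it
    determines the fraction of a trained group that saturates in the
    depressed direction.  ``tie_rule`` resolves exact equality of the
    product average with the threshold: ``"block"`` (default, H(0) = 0)
    or ``"teach"`` (H(0) = 1).
    """

    f_coeff: float = 0.8
    tie_rule: str = "block"

    def __post_init__(self) -> None:
        if not 0.0 < self.f_coeff < 1.0:
            raise ConfigurationError(
                f"f_coeff must lie in the open interval (0, 1); got {self.f_coeff}"
            )
        if self.tie_rule not in TIE_RULES:
            raise ConfigurationError(
                f"tie_rule must be one of {TIE_RULES}; got {self.tie_rule!r}"
            )


@dataclass(frozen=True)
class GroupTrialInputs:
    """One trial's inputs for a climbing-fibre target group.

    ``rates`` are the sampled parallel-fibre frequencies (Hz) of the
    group's members this trial; ``weights`` are the same members'
    current L values; ``drive_present`` flags excitatory drive to the
    olive (the gate is only consulted when drive is present).
    """

    rates: tuple[float, ...]
    weights: tuple[float, ...]
    drive_present: bool = True

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if rates.size == 0 or weights.size == 0:
            raise LayoutError("a climbing-fibre group must have at least one member")
        if rates.shape != weights.shape:
            raise LayoutError(
                f"rates and weights must align; got {rates.shape} vs {weights.shape}"
            )
        if np.any(rates <= 0.0):
            raise LayoutError("firing rates must be positive")


def teacher_signal(inputs: GroupTrialInputs, params: FeedbackParams) -> int:
    """Binary teaching signal for the group, 0 when feedback blocks it.

    Returns 1 iff ``f_coeff * mean(rates) > mean(rates * weights)``;
    equality is resolved by ``params.tie_rule``.
    """
    r = np.asarray(inputs.rates, dtype=float)
    w = np.asarray(inputs.weights, dtype=float)
    margin = params.f_coeff * r.mean() - (r * w).mean()
    if margin > 0.0:
        return 1
    if margin < 0.0:
        return 0
    return 0 if params.tie_rule == "block" else 1


def group_balance(inputs: GroupTrialInputs, params: FeedbackParams) -> float:
    """Signed deviation of the group's product average from threshold.

    ``mean(rates * weights) / mean(rates) - f_coeff``; a trained group
    pinned at the feedback threshold has a time-averaged balance near 0.
    """
    r = np.asarray(inputs.rates, dtype=float)
    w = np.asarray(inputs.weights, dtype=float)
    return float((r * w).mean() / r.mean() - params.f_coeff)
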