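"""Per-synapse, per-trial weight update rules.

The learned state of a parallel fibre synapse is a single scalar weight
``L`` confined to the open interval (0, 1).  A *rising* L represents
long-term depression (LTD) of transmission; extinction (the LTP
direction) drives L back down.  Each training trial either carries a
climbing-fibre teaching signal (``T = 1``, a *paired* trial) or does not
(``T = 0``, *unpaired*), and the weight relaxes one step toward T.

Three rule variants are provided:

``core``
    ``L_n = L_{n-1} + k (T_n - L_{n-1})`` — geometric relaxation toward
    the teaching signal with learning coefficient ``k``.

``inertia``
    The core step multiplied by an early-stage inertia factor: ``L_{n-1}``
    when T = 1 and ``1 - L_{n-1}`` when T = 0.  Steps are small near the
    limit the trial pushes away from, giving sigmoid acquisition and
    extinction curves; L = 0 and L = 1 are fixed points.

``inertia_adjusted``
    As ``inertia``, except that unpaired (extinction) steps taken from a
    weight above the onset threshold ``b`` use a damped down-step,
    ``L - L (1 - L)^2 / ((1 - b)(1 - k))``, whose magnitude vanishes as
    L -> 1.  This models the learned reduction of dendritic calcium
    influx by feed-forward inhibition, which preferentially suppresses
    extinction at well-trained synapses and so stabilises acquired
    memories.

All functions operate elementwise on scalars or numpy arrays and clamp
their result to ``[eps, 1 - eps]``: the exact boundaries are absorbing
for the inertia rules and would freeze learning permanently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DispatchError

__all__ = [
    "RULE_VARIANTS",
    "RuleParams",
    "step_core",
    "step_inertia",
    "step_adjusted_extinction",
    "apply_trial",
]

RULE_VARIANTS = ("core", "inertia", "inertia_adjusted")


@dataclass(frozen=True)
class RuleParams:
    """Parameters of the weight-update rule.

    Parameters
    ----------
    k
        Learning coefficient in (0, 1); sets the per-trial step size.
    b
        Onset threshold in (0, 1) above which the adjusted extinction
        step applies (``inertia_adjusted`` variant only).  ``b >= k`` is
        required for that variant: it guarantees the damped down-step
        can never overshoot below zero.
    variant
        One of ``core``, ``inertia``, ``inertia_adjusted``.
    inertia_strength
        Scale factor on the inertia multiplier; the model treats it as
        a constant equal to 1.
    eps
        Clamp margin keeping weights strictly inside (0, 1).
    """

    k: float = 0.1
    b: float = 0.95
    variant: str = "inertia"
    inertia_strength: float = 1.0
    eps: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ConfigurationError(f"k must lie in the open interval (0, 1); got {self.k}")
        if not 0.0 < self.b < 1.0:
            raise ConfigurationError(f"b must lie in the open interval (0, 1); got {self.b}")
        if self.variant not in RULE_VARIANTS:
            raise ConfigurationError(
                f"variant must be one of {RULE_VARIANTS}; got {self.variant!r}"
            )
        if self.variant == "inertia_adjusted" and self.b < self.k:
            raise ConfigurationError(
                f"inertia_adjusted requires b >= k (got b={self.b}, k={self.k}); "
                "otherwise the adjusted down-step could overshoot below 0"
            )
        if not 0.0 < self.eps < 0.5:
            raise ConfigurationError(f"eps must lie in (0, 0.5); got {self.eps}")
        if self.inertia_strength <= 0.0:
            raise ConfigurationError(
                f"inertia_strength must be positive; got {self.inertia_strength}"
            )


def _maybe_scalar(x):
    return float(x) if np.ndim(x) == 0 else x


def _check_weight(L) -> None:
    arr = np.asarray(L, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ConfigurationError(f"weight must lie strictly inside (0, 1); got {L!r}")


def _check_teacher(T) -> None:
    if T not in (0, 1):
        raise ConfigurationError(f"teaching signal must be 0 or 1; got {T!r}")


def _clamp(L, eps: float):
    return np.clip(L, eps, 1.0 - eps)


def step_core(L_prev, T: int, params: RuleParams):
    """Core rule: relax one step of size ``k`` toward the teaching signal."""
    _check_weight(L_prev)
    _check_teacher(T)
    L = np.asarray(L_prev, dtype=float)
    return _maybe_scalar(_clamp(L + params.k * (T - L), params.eps))


def step_inertia(L_prev, T: int, params: RuleParams):
    """Inertia rule: the core step scaled by L (paired) or 1 - L (unpaired)."""
    _check_weight(L_prev)
    _check_teacher(T)
    L = np.asarray(L_prev, dtype=float)
    m = params.inertia_strength * (L if T == 1 else 1.0 - L)
    return _maybe_scalar(_clamp(L + params.k * (T - L) * m, params.eps))


def _adjusted_down_step(L: np.ndarray, params: RuleParams) -> np.ndarray:
    # damped extinction step; valid for any L but dispatched only above b
    return L - L * (1.0 - L) ** 2 / ((1.0 - params.b) * (1.0 - params.k))


def step_adjusted_extinction(L_prev, params: RuleParams):
    """Damped extinction step for weights above the onset threshold ``b``.

    Only defined for unpaired trials with ``L_prev > b``; the caller is
    responsible for routing weights at or below ``b`` to
    :func:`step_inertia`.
    """
    _check_weight(L_prev)
    L = np.asarray(L_prev, dtype=float)
    if np.any(L <= params.b):
        raise DispatchError(
            f"step_adjusted_extinction requires L_prev > b={params.b}; "
            "route weights at or below b to step_inertia"
        )
    return _maybe_scalar(_clamp(_adjusted_down_step(L, params), params.eps))


def apply_trial(L_prev, T: int, active, params: RuleParams):
    """Apply one trial to one or more synapses, dispatching on variant.

    Inactive synapses are returned unchanged.  For the
    ``inertia_adjusted`` variant, unpaired trials use the damped
    extinction step wherever ``L_prev > b`` and the plain inertia step
    elsewhere.
    """
    _check_weight(L_prev)
    _check_teacher(T)
    L = np.asarray(L_prev, dtype=float)
    if params.variant == "core":
        stepped = np.asarray(step_core(L, T, params))
    elif params.variant == "inertia":
        stepped = np.asarray(step_inertia(L, T, params))
    else:  # inertia_adjusted
        if T == 1:
            stepped = np.asarray(step_inertia(L, 1, params))
        else:
            plain = np.asarray(step_inertia(L, 0, params))
            damped = _clamp(_adjusted_down_step(L, params), params.eps)
            stepped = np.where(L > params.b, damped, plain)
    out = np.where(np.asarray(active, dtype=bool), stepped, L)
    return _maybe_scalar(out)
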