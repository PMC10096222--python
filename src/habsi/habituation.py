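"""Habituation kinetics for repeated-contact spreading processes.

Habituation is the decline of a response to a stimulus that is presented over
and over.  In a spreading process on a social network the stimulus is a
transmission attempt (a "contact") from an infected neighbour; every attempt
that fails lowers the target node's *responsiveness* ``R``, which in turn
multiplies the base propagation probability of every later attempt:

    effective PP = PP * R(v)

Responsiveness decays exponentially with the number of failed contacts ``c``::

    y(c) = y0 - (S / alpha) * (1 - exp(-alpha * c / tau))

so a fresh node sits at the baseline ``y0`` (1.0 by default) and repeated
failures drive it towards the floor ``y0 - S/alpha``.  With the reference
parameters (S=1, alpha=1.05, tau=5) a node falls to 0.82 after one failed
contact, 0.67 after two, and 0.19 after nine.

During contact-free periods responsiveness may recover towards baseline::

    y(t) = y0 - (y0 - y1) * exp(-alpha * (t - 1) / tau)

where ``y1`` is the level at which the decline stopped and ``t`` counts quiet
periods (``t = 1`` is the moment recovery begins, so ``y(1) = y1``).  In a pure
SI process infected neighbours attack every step, so recovery never triggers;
it is provided for completeness and is off by default in the simulator.

Both formulas count *contacts*, not simulation steps: a node attacked three
times within one step habituates three times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HabituationError",
    "HabituationParams",
    "ResponsivenessState",
    "BASELINE",
    "DECREASING",
    "RECOVERING",
    "responsiveness_after_failures",
    "responsiveness_recovery",
    "register_failed_contact",
    "register_quiet_period",
    "effective_probability",
]

#: phase labels for :class:`ResponsivenessState`
BASELINE = "baseline"
DECREASING = "decreasing"
RECOVERING = "recovering"

_EPS = 1e-12


class HabituationError(ValueError):
    """Invalid habituation parameters or state transitions."""


@dataclass(frozen=True)
class HabituationParams:
    """Kinetic constants of the habituation process.

    Parameters
    ----------
    S : float
        Stimulus magnitude per contact; dimensionless.  One transmission
        attempt delivers one unit of stimulus, hence the default ``1.0``.
    alpha : float
        Rate constant (> 0).  Controls both the decay floor ``y0 - S/alpha``
        and the recovery speed; larger alpha means a shallower decay and a
        faster rebound.  Reference values: 1.05 and 1.2.
    tau : float
        Time constant in contact-count units (> 0).  Small tau means rapid
        habituation.  Reference values: 5, 10, 15, 20, 25.
    y0 : float
        Baseline responsiveness in (0, 1]; default 1.0.

    The decay floor ``y0 - S/alpha`` must be non-negative so that
    responsiveness remains a valid probability multiplier; parameter sets
    violating this are rejected rather than clamped.
    """

    S: float = 1.0
    alpha: float = 1.05
    tau: float = 5.0
    y0: float = 1.0

    def __post_init__(self) -> None:
        if self.S <= 0:
            raise HabituationError(f"stimulus magnitude S must be > 0, got {self.S}")
        if self.alpha <= 0:
            raise HabituationError(f"rate constant alpha must be > 0, got {self.alpha}")
        if self.tau <= 0:
            raise HabituationError(f"time constant tau must be > 0, got {self.tau}")
        if not 0 < self.y0 <= 1:
            raise HabituationError(f"baseline y0 must be in (0, 1], got {self.y0}")
        if self.y0 - self.S / self.alpha < -_EPS:
            raise HabituationError(
                f"decay floor y0 - S/alpha = {self.y0 - self.S / self.alpha:.6g} "
                "is negative; responsiveness would leave [0, 1]"
            )

    @property
    def floor(self) -> float:
        """Asymptotic responsiveness under unbounded failed contacts."""
        return self.y0 - self.S / self.alpha


@dataclass(frozen=True)
class ResponsivenessState:
    """A single node's habituation state.

    ``failed_contacts`` is the total number of failed transmission attempts
    received, ``phase`` is one of :data:`BASELINE`, :data:`DECREASING`,
    :data:`RECOVERING`, and ``y_current`` the responsiveness R(v).  ``y1`` and
    ``recovery_elapsed`` are recovery bookkeeping: the level at which the last
    decline stopped, and the number of quiet periods since recovery began.
    """

    failed_contacts: int = 0
    phase: str = BASELINE
    y_current: float = 1.0
    y1: float | None = None
    recovery_elapsed: int = 0

    @classmethod
    def baseline(cls, params: HabituationParams) -> "ResponsivenessState":
        """Fresh, never-contacted node at baseline responsiveness."""
        return cls(y_current=params.y0)


def responsiveness_after_failures(params: HabituationParams, c: int) -> float:
    """Responsiveness after ``c`` consecutive failed contacts.

    Evaluates the decay law ``y(c) = y0 - (S/alpha)(1 - exp(-alpha*c/tau))``.
    ``c = 0`` returns the baseline ``y0``; the limit for large ``c`` is the
    floor ``y0 - S/alpha``.
    """
    if c != int(c) or c < 0:
        raise HabituationError(f"failed-contact count must be a non-negative integer, got {c!r}")
    return params.y0 - (params.S / params.alpha) * (1.0 - math.exp(-params.alpha * c / params.tau))


def responsiveness_recovery(params: HabituationParams, y1: float, t: int) -> float:
    """Responsiveness after ``t`` quiet periods of recovery from level ``y1``.

    Evaluates ``y(t) = y0 - (y0 - y1) exp(-alpha (t-1)/tau)``; ``y(1) = y1``
    and the limit for large ``t`` is full recovery to ``y0``.
    """
    if t != int(t) or t < 1:
        raise HabituationError(f"quiet-period count must be an integer >= 1, got {t!r}")
    if not params.floor - _EPS <= y1 <= params.y0 + _EPS:
        raise HabituationError(
            f"recovery start level y1={y1!r} outside [{params.floor:.6g}, {params.y0:.6g}]"
        )
    return params.y0 - (params.y0 - y1) * math.exp(-params.alpha * (t - 1) / params.tau)


def register_failed_contact(
    state: ResponsivenessState, params: HabituationParams
) -> ResponsivenessState:
    """Record one failed transmission attempt against a node.

    Increments the failure count, moves the node into the decreasing phase,
    recomputes responsiveness from the decay law at the new count, and resets
    any recovery bookkeeping.
    """
    c = state.failed_contacts + 1
    return ResponsivenessState(
        failed_contacts=c,
        phase=DECREASING,
        y_current=responsiveness_after_failures(params, c),
        y1=None,
        recovery_elapsed=0,
    )


def register_quiet_period(
    state: ResponsivenessState, params: HabituationParams
) -> ResponsivenessState:
    """Record one contact-free period for a node.

    A node at baseline has nothing to recover and is returned unchanged.  A
    node in the decreasing phase enters recovery with ``y1`` pinned to its
    current level (the recovery law's ``t = 1`` boundary leaves y unchanged).
    A recovering node advances one tick along the recovery curve.
    """
    if state.phase == BASELINE:
        return state
    if state.phase == DECREASING:
        return ResponsivenessState(
            failed_contacts=state.failed_contacts,
            phase=RECOVERING,
            y_current=state.y_current,
            y1=state.y_current,
            recovery_elapsed=1,
        )
    t = state.recovery_elapsed + 1
    assert state.y1 is not None
    return ResponsivenessState(
        failed_contacts=state.failed_contacts,
        phase=RECOVERING,
        y_current=responsiveness_recovery(params, state.y1, t),
        y1=state.y1,
        recovery_elapsed=t,
    )


def effective_probability(pp: float, state: ResponsivenessState) -> float:
    """Habituation-scaled transmission probability ``PP * R(v)``."""
    if not 0 <= pp <= 1:
        raise HabituationError(f"base propagation probability must be in [0, 1], got {pp!r}")
    return pp * state.y_current
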