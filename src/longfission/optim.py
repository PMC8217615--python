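"""Minibatch SGD with momentum, step learning-rate decay, and compensated sums.

The optimizer follows the velocity form

    v_{t+1} = mu * v_t + alpha * g_t
    theta_{t+1} = theta_t - v_{t+1}

where ``g_t`` is the minibatch-averaged gradient.  Note the learning rate
multiplies the gradient *inside* the velocity update (no dampening, no
Nesterov).  The step schedule substitutes ``alpha <- gamma * alpha`` every
``period`` epochs, i.e. ``alpha(epoch) = alpha0 * gamma ** (epoch // period)``.

The compensated (Kahan) accumulator carries a running residual that cancels
floating-point rounding error, giving near-double-precision totals even when
accumulating in single precision.  It is used for epoch-level loss/accuracy
averaging when enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SGDState:
    """Parameter vector theta, velocity v, learning rate alpha, momentum mu.

    ``params`` is a list of arrays updated in place; one velocity buffer of
    matching shape is kept per parameter, initialized to zero.
    """

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        self.params = params
        self.velocities = [np.zeros_like(p) for p in params]
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.t = 0


def sgd_step(state: SGDState, grads: list[np.ndarray]) -> SGDState:
    """One momentum-SGD update; mutates ``state`` in place and returns it."""
    if len(grads) != len(state.params):
        raise ValueError("gradient list length does not match parameter list")
    for g in grads:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
    for p, v, g in zip(state.params, state.velocities, grads):
        if g.shape != p.shape:
            raise ValueError(f"gradient shape {g.shape} != parameter shape {p.shape}")
        v *= state.momentum
        v += state.lr * g
        p -= v
    state.t += 1
    return state


@dataclass(frozen=True)
class LRSchedule:
    """Step decay: multiply the rate by ``gamma`` every ``period`` epochs."""

    period: int = 7
    gamma: float = 0.1

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")


def lr_step(schedule: LRSchedule, epoch: int, alpha0: float) -> float:
    """Learning rate in force during ``epoch`` (0-based): alpha0 * gamma^(epoch // period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return alpha0 * schedule.gamma ** (epoch // schedule.period)


@dataclass
class CompensatedAccumulator:
    """Kahan running sum S with residual R, both in the working precision."""

    dtype: type = np.float32
    s: np.floating = field(init=False)
    r: np.floating = field(init=False)
    count: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.s = self.dtype(0)
        self.r = self.dtype(0)


def kahan_add(acc: CompensatedAccumulator, x: float) -> CompensatedAccumulator:
    """Add one value via the four-line compensated recursion (in acc.dtype)."""
    xk = acc.dtype(x)
    if not np.isfinite(xk):
        raise FloatingPointError(f"non-finite value {x!r} in compensated sum")
    t = acc.s
    u = acc.dtype(xk + acc.r)
    acc.s = acc.dtype(acc.s + u)
    acc.r = acc.dtype(u - acc.dtype(acc.s - t))
    acc.count += 1
    return acc


def kahan_sum(values, dtype=np.float32) -> float:
    """Compensated sum of an iterable in the given working precision."""
    acc = CompensatedAccumulator(dtype=dtype)
    for v in values:
        kahan_add(acc, v)
    return float(acc.s)
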