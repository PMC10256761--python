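"""The two tangent-space representations of a unit-quaternion series.

A series on :math:`H_1` can be flattened to a real 3-D series in two ways:

* **logarithm transform** — map every sample through the log at the
  identity; the whole series lives in one tangent space, inside the ball
  of radius pi.  Inverted sample-wise by the exponential.
* **angular-velocity transform** — finite-difference approximation
  ``v_i = log(q_i^{-1} q_{i+1}) / h``; sample ``i`` lives in the tangent
  space at ``q_i``, inside the ball of radius pi/h.  Inverted by
  accumulating increments ``q_{i+1} = q_i * exp(h v_i)`` from the stored
  anchor ``q_1``.

Smoothing happens on these real series; the inverse maps reconstruct unit
quaternions exactly when no smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .quaternions import IDENTITY, QuaternionSeries, qexp, qinv, qlog, qmul

__all__ = [
    "TangentSeries",
    "angular_velocity_transform",
    "exp_reconstruct",
    "log_transform",
    "velocity_reconstruct",
]


@dataclass
class TangentSeries:
    """Real 3-D series produced by one of the two tangent transforms.

    ``kind`` records which transform produced it ("log" or "velocity");
    ``anchor`` keeps the first quaternion of the source series, needed to
    reconstruct from velocities.
    """

    values: np.ndarray
    kind: Literal["log", "velocity"]
    h: float = 1.0
    anchor: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("TangentSeries expects an (N, 3) array")
        if self.kind not in ("log", "velocity"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not self.h > 0:
            raise ValueError("time step h must be positive")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "TangentSeries":
        """Copy carrying new values (used after smoothing)."""
        return TangentSeries(values, self.kind, self.h, self.anchor)


def log_transform(s: QuaternionSeries) -> TangentSeries:
    """Map a (sign-aligned) series through the quaternion log, row-wise.

    Every output row lies in the closed pi-ball.
    """
    return TangentSeries(qlog(s.q), "log", s.h, anchor=s.q[0].copy())


def exp_reconstruct(t: TangentSeries) -> QuaternionSeries:
    """Invert :func:`log_transform` by the row-wise exponential."""
    if t.kind != "log":
        raise ValueError(f"expected a log tangent series, got kind={t.kind!r}")
    return QuaternionSeries(qexp(t.values), t.h)


def angular_velocity_transform(s: QuaternionSeries) -> TangentSeries:
    """Finite-difference angular velocities ``log(q_i^{-1} q_{i+1}) / h``.

    Returns ``N - 1`` rows, each with norm at most pi/h; the first
    quaternion is stored as the anchor for reconstruction.
    """
    rel = qmul(qinv(s.q[:-1]), s.q[1:])
    # shortest-arc branch: the relative rotation between adjacent samples
    # of a well-sampled series is small, so force w >= 0
    rel = np.where(rel[:, :1] < 0, -rel, rel)
    return TangentSeries(qlog(rel) / s.h, "velocity", s.h, anchor=s.q[0].copy())


def velocity_reconstruct(t: TangentSeries) -> QuaternionSeries:
    """Accumulate velocity increments from the anchor.

    ``q_1 = anchor``, then ``q_{i+1} = q_i * exp(h * v_i)`` — the
    increment right-multiplies because ``v_i`` measures the step from
    ``q_i`` to ``q_{i+1}`` in the tangent space at ``q_i``.  Exactly
    inverts :func:`angular_velocity_transform` when the velocities are
    untouched.
    """
    if t.kind != "velocity":
        raise ValueError(f"expected a velocity tangent series, got kind={t.kind!r}")
    if t.anchor is None:
        raise ValueError("velocity reconstruction needs the anchor quaternion")
    n = len(t.values) + 1
    out = np.empty((n, 4))
    out[0] = t.anchor
    steps = qexp(t.values * t.h)
    for i in range(n - 1):
        out[i + 1] = qmul(out[i], steps[i])
    return QuaternionSeries(out, t.h)
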