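"""Unit-quaternion algebra and uniformly sampled quaternion series.

Quaternions are stored as float arrays in ``(w, x, y, z)`` order — scalar
part first, vector part last — and every constructor normalizes to unit
norm, so all arrays handled here live on the 3-sphere :math:`H_1`.  A unit
quaternion represents a 3-D rotation; ``q`` and ``-q`` represent the same
rotation (double cover), which is why continuity-based sign alignment is
applied before any logarithm-based operation.

All element-wise operations broadcast over leading axes, so a series of
``N`` quaternions is just an ``(N, 4)`` array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IDENTITY",
    "QuaternionSeries",
    "as_unit_quaternion",
    "geodesic_distance",
    "qexp",
    "qinv",
    "qlog",
    "qmul",
    "random_unit_quaternions",
    "resample",
    "sign_align",
    "slerp",
]

#: Identity rotation (w, x, y, z).
IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

# below this vector-part norm the rotation axis is numerically undefined and
# the zero-angle branch of log/exp is taken
_AXIS_EPS = 1e-12


def as_unit_quaternion(q, *, atol: float = 1e-9) -> np.ndarray:
    """Validate and normalize an ``(..., 4)`` array of quaternions.

    Raises ``ValueError`` if any input norm deviates from 1 by more than
    ``atol`` (guards against passing raw sensor output that was never
    normalized) or if a norm is (near) zero.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ValueError(f"expected trailing dimension 4, got shape {q.shape}")
    norms = np.linalg.norm(q, axis=-1)
    if np.any(norms < _AXIS_EPS):
        raise ValueError("zero quaternion cannot be normalized")
    if np.any(np.abs(norms - 1.0) > atol):
        raise ValueError(
            f"quaternion norm deviates from 1 by {np.abs(norms - 1.0).max():.3g} "
            f"(> atol={atol}); not a unit quaternion"
        )
    return q / norms[..., None]


def qmul(a, b) -> np.ndarray:
    """Hamilton product of unit quaternions, renormalized.

    Broadcasts over leading axes.  The product is *not* commutative:
    ``qmul(i, j) = k`` but ``qmul(j, i) = -k``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    out = np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def qinv(q) -> np.ndarray:
    """Inverse of a unit quaternion: its conjugate ``(w, -x, -y, -z)``."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qlog(q) -> np.ndarray:
    """Logarithm map :math:`H_1 \\to \\mathbb{R}^3` at the identity.

    Returns ``arccos(w) * v / |v|`` where ``v = (x, y, z)``; the zero
    vector when the vector part vanishes.  The image is the closed ball of
    radius pi.  For ``w`` near -1 (rotation by pi) the direction of the
    returned vector is not determined by the rotation alone; a warning is
    raised and the stored vector part is used as-is.  Sign-align series
    first so that this branch is unreachable.
    """
    q = np.asarray(q, dtype=float)
    w = np.clip(q[..., 0], -1.0, 1.0)
    v = q[..., 1:]
    vnorm = np.linalg.norm(v, axis=-1)
    if np.any(w < -1.0 + 1e-9):
        warnings.warn(
            "quaternion log at w ~ -1 (rotation by pi): axis direction is "
            "ambiguous; sign-align the series first",
            RuntimeWarning,
            stacklevel=2,
        )
    # atan2(|v|, w) equals arccos(w) on the unit sphere but stays accurate
    # for small rotation angles where arccos loses precision
    angle = np.arctan2(vnorm, w)
    scale = np.where(vnorm > _AXIS_EPS, angle / np.where(vnorm > _AXIS_EPS, vnorm, 1.0), 0.0)
    return v * scale[..., None]


def qexp(v) -> np.ndarray:
    """Exponential map :math:`\\mathbb{R}^3 \\to H_1`.

    ``v`` is a pure-quaternion tangent vector; returns
    ``(cos|v|, sin|v| * v/|v|)``, the identity at ``v = 0``.  Always unit
    norm by construction.
    """
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v, axis=-1)
    w = np.cos(theta)
    # sin(t)/t with a guarded small-angle branch
    small = theta < _AXIS_EPS
    sinc = np.where(small, 1.0, np.sin(np.where(small, 1.0, theta)) / np.where(small, 1.0, theta))
    return np.concatenate([w[..., None], v * sinc[..., None]], axis=-1)


def geodesic_distance(a, b) -> np.ndarray:
    """Rotation-geodesic distance ``2 arccos(|<a, b>|)`` in [0, pi].

    Invariant under the sign ambiguity: ``d(q, -q) = 0``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.sum(a * b, axis=-1))
    return 2.0 * np.arccos(np.minimum(1.0, dot))


def sign_align(q) -> np.ndarray:
    """Resolve the q/-q ambiguity along a series by continuity.

    The first quaternion is flipped if its scalar part is negative; each
    subsequent one is flipped whenever its 4-vector inner product with the
    (aligned) predecessor is negative.  Idempotent; represented rotations
    are unchanged.  Accepts and returns an ``(N, 4)`` array.
    """
    q = np.array(q, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError("sign_align expects an (N, 4) array")
    if q[0, 0] < 0:
        q[0] = -q[0]
    for i in range(1, len(q)):
        if np.dot(q[i], q[i - 1]) < 0:
            q[i] = -q[i]
    return q


def slerp(a, b, u) -> np.ndarray:
    """Spherical linear interpolation along the shortest arc.

    ``u`` may be a scalar or array in [0, 1]; ``u=0`` gives ``a`` and
    ``u=1`` gives ``b`` exactly.  Falls back to normalized linear
    interpolation when the arc is numerically degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    u = np.asarray(u, dtype=float)
    dot = float(np.dot(a, b))
    if dot < 0:  # shortest arc on the double cover
        b = -b
        dot = -dot
    dot = min(dot, 1.0)
    omega = np.arccos(dot)
    if omega < 1e-10:
        out = (1.0 - u)[..., None] * a + u[..., None] * b if u.ndim else (1.0 - u) * a + u * b
    else:
        s = np.sin(omega)
        wa = np.sin((1.0 - u) * omega) / s
        wb = np.sin(u * omega) / s
        out = wa[..., None] * a + wb[..., None] * b if u.ndim else wa * a + wb * b
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def random_unit_quaternions(n: int, rng, *, positive_w: bool = False) -> np.ndarray:
    """Draw ``n`` quaternions uniformly on the 3-sphere (seeded ``rng``)."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    if positive_w:
        q[q[:, 0] < 0] *= -1
    return q


@dataclass
class QuaternionSeries:
    """Uniformly sampled unit-quaternion time series.

    Parameters
    ----------
    q : (N, 4) array
        Unit quaternions, ``(w, x, y, z)``; normalized on construction.
    h : float
        Time step between consecutive samples (seconds, or normalized
        gait-cycle time).  Sample ``i`` sits at ``t_i = i * h``.
    """

    q: np.ndarray
    h: float = field(default=1.0)

    def __post_init__(self) -> None:
        self.q = as_unit_quaternion(self.q)
        if self.q.ndim != 2:
            raise ValueError("QuaternionSeries expects an (N, 4) array")
        if len(self.q) < 2:
            raise ValueError("a series needs at least two samples")
        if not self.h > 0:
            raise ValueError("time step h must be positive")

    def __len__(self) -> int:
        return len(self.q)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.q)) * self.h

    @property
    def duration(self) -> float:
        return (len(self.q) - 1) * self.h

    def aligned(self) -> "QuaternionSeries":
        """Return a sign-aligned copy (see :func:`sign_align`)."""
        return QuaternionSeries(sign_align(self.q), self.h)

    def is_aligned(self) -> bool:
        dots = np.sum(self.q[1:] * self.q[:-1], axis=1)
        return bool(self.q[0, 0] >= 0 and np.all(dots >= 0))


def resample(s: QuaternionSeries, m: int) -> QuaternionSeries:
    """SLERP-resample a series to ``m`` uniformly spaced points.

    The new grid spans the original time span exactly (endpoints
    preserved); the step becomes ``duration / (m - 1)``.
    """
    if m < 2:
        raise ValueError("resample needs m >= 2")
    n = len(s)
    # positions of the new grid in units of the old index
    pos = np.linspace(0.0, n - 1.0, m)
    lo = np.minimum(np.floor(pos).astype(int), n - 2)
    frac = pos - lo
    out = np.empty((m, 4))
    for j in range(m):
        out[j] = slerp(s.q[lo[j]], s.q[lo[j] + 1], frac[j])
    return QuaternionSeries(out, s.duration / (m - 1))
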