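"""Synthetic two-class gait-like quaternion series with tangent-space
Gaussian-process noise.

The generator emulates an individual-gait-pattern study: each subject
contributes one unit-quaternion series over a normalized gait cycle,
starting (and ending) at the identity rotation, recorded under one of
two walking conditions.  A series is built in log coordinates as a
class-specific median curve plus a zero-mean Gaussian process with
exponential covariance

    C(s, t) = alpha * exp(-beta * |s - t|),

independent across the three components, and mapped back to the
3-sphere by the quaternion exponential.  ``alpha`` scales the noise
variance; ``beta`` is the inverse correlation range, with ``|s - t|``
measured on the 0-100 percent-of-cycle axis regardless of the number of
sample points, so a given (alpha, beta) pair means the same noise
process at any sampling density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .classification import LabeledDataset
from .quaternions import QuaternionSeries, qexp

__all__ = [
    "ClassTemplate",
    "NoiseParams",
    "ORIGINAL_PROXY",
    "STUDY_NOISE_SETTINGS",
    "default_templates",
    "exp_cov_matrix",
    "generate_dataset",
    "sample_gp_noise",
]

#: span of the normalized gait-cycle time axis used for |s - t| in the
#: exponential covariance (percent of cycle)
CYCLE_SPAN = 100.0


@dataclass(frozen=True)
class NoiseParams:
    """Exponential-covariance noise parameters (variance scale ``alpha``,
    inverse correlation range ``beta``, both >= 0)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


#: the five noise regimes studied: (variance, inverse correlation range)
STUDY_NOISE_SETTINGS = (
    NoiseParams(0.001, 0.01),   # low noise, moderately correlated
    NoiseParams(0.01, 0.001),   # moderate noise, highly correlated
    NoiseParams(0.01, 0.01),    # moderate noise, moderately correlated
    NoiseParams(0.01, 0.1),     # moderate noise, weakly correlated
    NoiseParams(0.1, 0.01),     # high noise, moderately correlated
)

#: near-noise-free setting standing in for the original (clean) data
ORIGINAL_PROXY = NoiseParams(0.0001, 0.0001)


@dataclass(frozen=True)
class ClassTemplate:
    """Median log-space curve of one class.

    Component ``k`` follows ``A_k * (sin(2 pi t + phi_k) - sin(phi_k))``
    on normalized time ``t in [0, 1]`` — one harmonic per component with
    class-specific amplitude and phase, pinned to zero at both endpoints
    so the quaternion series starts and ends at the identity.
    """

    amplitudes: tuple
    phases: tuple

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        phi = np.asarray(self.phases, dtype=float)
        return a * (np.sin(2.0 * np.pi * t[:, None] + phi) - np.sin(phi))


def default_templates() -> tuple[ClassTemplate, ClassTemplate]:
    """Two subtly separated class templates.

    Amplitudes are a few tenths of a radian — hip-rotation scale, well
    inside the pi-ball even with high noise.  The two conditions share
    the overall curve shape and differ by a deviation of order 0.1 rad
    in amplitude and phase: perfectly separable without noise, but
    increasingly confusable as the noise scale sqrt(alpha) approaches
    the class difference, so classifier performance degrades across the
    studied noise range instead of sitting at ceiling.
    """
    natural = ClassTemplate(amplitudes=(0.60, 0.40, 0.30), phases=(0.0, 0.6, 1.1))
    hindered = ClassTemplate(amplitudes=(0.66, 0.34, 0.33), phases=(0.15, 0.72, 1.02))
    return natural, hindered


def exp_cov_matrix(times: np.ndarray, p: NoiseParams) -> np.ndarray:
    """Exponential covariance ``alpha * exp(-beta |s - t|)`` on a grid."""
    times = np.asarray(times, dtype=float)
    lags = np.abs(times[:, None] - times[None, :])
    return p.alpha * np.exp(-p.beta * lags)


def sample_gp_noise(
    cov: np.ndarray,
    n_series: int,
    seed: Union[int, np.random.Generator],
    n_components: int = 3,
) -> np.ndarray:
    """Zero-mean Gaussian draws with covariance ``cov``.

    Returns an ``(n_series, N, n_components)`` array, independent across
    series and components.  A 1e-10 diagonal jitter is added before the
    Cholesky factorization; an all-zero covariance yields exactly zero
    noise.
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n):
        raise ValueError("cov must be square")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not np.any(cov):
        return np.zeros((n_series, n, n_components))
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = rng.standard_normal((n_series, n_components, n))
    return np.einsum("ij,scj->sic", chol, z)


def generate_dataset(
    templates: Optional[Sequence[ClassTemplate]] = None,
    n_per_class: int = 27,
    n_points: int = 128,
    noise: NoiseParams = ORIGINAL_PROXY,
    seed: Union[int, np.random.Generator] = 0,
    *,
    pin_endpoints: bool = True,
    h: Optional[float] = None,
) -> LabeledDataset:
    """Generate a two-class labelled dataset of unit-quaternion series.

    Defaults mirror the study conditions: 27 series per class (54 total),
    128 time points, normalized-time step ``h = 1/(n_points - 1)``.  The
    class median curve is evaluated in log coordinates, GP noise is added
    independently to each component, and the rows are mapped through the
    quaternion exponential.  ``pin_endpoints`` zeroes the noise at t = 0
    so every series starts exactly at the identity quaternion.
    """
    if templates is None:
        templates = default_templates()
    if len(templates) != 2:
        raise ValueError("exactly two class templates are required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    cov = exp_cov_matrix(t * CYCLE_SPAN, noise)
    step = h if h is not None else 1.0 / (n_points - 1)

    series, labels, ids = [], [], []
    for cls, template in enumerate(templates):
        median = template.evaluate(t)
        eps = sample_gp_noise(cov, n_per_class, rng)
        if pin_endpoints:
            eps[:, 0, :] = 0.0
        for i in range(n_per_class):
            series.append(QuaternionSeries(qexp(median + eps[i]), step))
            labels.append(cls)
            ids.append(f"c{cls}_s{i:02d}")
    return LabeledDataset(series, np.asarray(labels), ids)
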