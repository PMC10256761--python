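"""Smoothers for 3-D tangent-space series.

Three families, all operating on the real ``(N, 3)`` values of a
:class:`~quatsmooth.transforms.TangentSeries`:

* **wavelet** — component-wise DWT (periodic boundary), vector soft
  thresholding of the detail coefficients across the three components at
  the universal threshold ``t_p = sigma * sqrt(3 log N)``, with the noise
  scale estimated from the pooled level-1 details by the robust MAD rule.
* **fourier** — ordinary least-squares projection onto a truncated
  Fourier basis (constant plus sine/cosine pairs); no penalty.
* **spline** — penalized regression splines on 71 equally spaced interior
  knots, penalty weight selected per component by generalized
  cross-validation (GCV).

The vector form of soft thresholding shrinks the *norm* of the 3-vector
of same-position detail coefficients, preserving its direction — the
natural rule when the three components are coordinates of one spatial
signal rather than unrelated channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pywt
from scipy.interpolate import BSpline
from scipy.linalg import solve_triangular

from .transforms import TangentSeries

__all__ = [
    "SmootherConfig",
    "WAVELET_FILTERS",
    "estimate_sigma",
    "fourier_smooth",
    "smooth",
    "soft_threshold_vectors",
    "spline_smooth",
    "universal_threshold",
    "wavelet_smooth",
]

# field-style filter names -> PyWavelets names.  "d<L>"/"la<L>" give the
# Daubechies extremal-phase and least-asymmetric (symlet) filters of
# length L, i.e. db/sym with L/2 vanishing moments.  The best-localized
# family ("bl14", "bl20") has no PyWavelets equivalent; see SmootherConfig.
WAVELET_FILTERS = {
    "haar": "haar",
    "d4": "db2",
    "d6": "db3",
    "d8": "db4",
    "d16": "db8",
    "la8": "sym4",
    "la16": "sym8",
    "la20": "sym10",
}

_UNSUPPORTED_FILTERS = ("bl14", "bl20")

_GCV_LAMBDA_GRID = np.logspace(-10.0, 6.0, 17)


@dataclass(frozen=True)
class SmootherConfig:
    """Configuration of one smoother; only fields relevant to ``family``
    are validated, others are ignored.

    ``smoothing_parameter`` applies to the spline family: ``"cv"`` selects
    the roughness-penalty weight by GCV per curve, a float fixes it.
    ``threshold`` overrides the wavelet universal threshold when set
    (mainly for diagnostics; ``0.0`` makes the wavelet path an identity).
    """

    family: str = "wavelet"
    wavelet_name: str = "d4"
    decomposition_level: int = 4
    n_basis: int = 40
    spline_degree: int = 3
    n_knots: int = 71
    smoothing_parameter: Union[str, float] = "cv"
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in ("wavelet", "fourier", "spline", "none"):
            raise ValueError(f"unknown smoother family {self.family!r}")
        if self.family == "wavelet":
            if self.wavelet_name not in WAVELET_FILTERS and self.wavelet_name not in _UNSUPPORTED_FILTERS:
                raise ValueError(f"unknown wavelet filter {self.wavelet_name!r}")
            if not 1 <= self.decomposition_level:
                raise ValueError("decomposition_level must be >= 1")
        elif self.family == "spline":
            if self.spline_degree not in (1, 3, 5):
                raise ValueError("spline_degree must be 1, 3 or 5")
            if self.n_knots < 1:
                raise ValueError("n_knots must be >= 1")
        elif self.family == "fourier":
            if self.n_basis < 1:
                raise ValueError("n_basis must be >= 1")

    def label(self) -> str:
        """Short human-readable tag used in experiment records."""
        if self.family == "wavelet":
            return f"wavelet_{self.wavelet_name}_dl{self.decomposition_level}"
        if self.family == "fourier":
            return f"fourier_{self.n_basis}"
        if self.family == "spline":
            return f"spline_deg{self.spline_degree}"
        return "none"


def estimate_sigma(d1: np.ndarray) -> float:
    """Robust noise-scale estimate MAD(d1) / 0.6745 from pooled level-1
    detail coefficients (0.6745 is the normal quartile making the
    estimator consistent for a Gaussian standard deviation)."""
    d1 = np.asarray(d1, dtype=float).ravel()
    if d1.size == 0:
        raise ValueError("cannot estimate sigma from an empty coefficient vector")
    mad = np.median(np.abs(d1 - np.median(d1)))
    return float(mad / 0.6745)


def universal_threshold(sigma: float, n: int) -> float:
    """Universal threshold for 3-component signals: ``sigma * sqrt(3 ln n)``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sigma * math.sqrt(3.0 * math.log(n)))


def soft_threshold_vectors(w: np.ndarray, t: float) -> np.ndarray:
    """Vector soft thresholding: each row's norm is shrunk by ``t``,
    rows with norm <= ``t`` are zeroed, directions are preserved."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    w = np.asarray(w, dtype=float)
    norms = np.linalg.norm(w, axis=-1)
    safe = np.where(norms > 0, norms, 1.0)
    factor = np.where(norms > t, 1.0 - t / safe, 0.0)
    return w * factor[..., None]


def _require_dyadic(n: int) -> None:
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"wavelet smoothing needs a power-of-two length, got {n}")


def _pywt_name(name: str) -> str:
    if name in _UNSUPPORTED_FILTERS:
        raise NotImplementedError(
            f"the best-localized filter {name!r} is not available in the "
            "PyWavelets backend; choose one of "
            + ", ".join(sorted(WAVELET_FILTERS))
        )
    return WAVELET_FILTERS[name]


def wavelet_smooth(t: TangentSeries, cfg: SmootherConfig) -> TangentSeries:
    """DWT shrinkage of a tangent series.

    Each of the three components is decomposed to
    ``cfg.decomposition_level`` with periodic boundary handling; the noise
    scale is estimated once from the level-1 details of all components
    pooled; detail vectors at every decomposed level are soft-thresholded
    jointly across components; approximation coefficients are untouched.
    """
    v = t.values
    n = len(v)
    _require_dyadic(n)
    level = cfg.decomposition_level
    if level > int(math.log2(n)):
        raise ValueError(f"decomposition level {level} exceeds log2({n})")
    wavelet = _pywt_name(cfg.wavelet_name)

    coeffs = [pywt.wavedec(v[:, c], wavelet, mode="periodization", level=level) for c in range(3)]
    if cfg.threshold is not None:
        tp = float(cfg.threshold)
    else:
        d1 = np.concatenate([coeffs[c][-1] for c in range(3)])
        tp = universal_threshold(estimate_sigma(d1), n)

    # coeffs[c] = [cA_L, cD_L, ..., cD_1]; threshold every detail level
    for lev in range(1, level + 1):
        stacked = np.stack([coeffs[c][lev] for c in range(3)], axis=1)  # (M, 3)
        shrunk = soft_threshold_vectors(stacked, tp)
        for c in range(3):
            coeffs[c][lev] = shrunk[:, c]

    out = np.stack(
        [pywt.waverec(coeffs[c], wavelet, mode="periodization")[:n] for c in range(3)], axis=1
    )
    return t.with_values(out)


def _fourier_design(x: np.ndarray, n_basis: int) -> np.ndarray:
    n_pairs = (n_basis - 1) // 2
    cols = [np.ones_like(x)]
    for k in range(1, n_pairs + 1):
        cols.append(np.sin(2.0 * np.pi * k * x))
        cols.append(np.cos(2.0 * np.pi * k * x))
    return np.column_stack(cols)


def fourier_smooth(t: TangentSeries, cfg: SmootherConfig) -> TangentSeries:
    """OLS projection of each component onto a truncated Fourier basis.

    ``n_basis`` counts total basis functions: one constant plus
    ``(n_basis - 1) // 2`` sine/cosine pairs on the series' time span.
    """
    v = t.values
    n = len(v)
    if cfg.n_basis > n:
        raise ValueError(f"n_basis={cfg.n_basis} exceeds the series length {n}")
    x = np.arange(n) / (n - 1)  # normalized time in [0, 1]
    design = _fourier_design(x, cfg.n_basis)
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return t.with_values(design @ coef)


# ---------------------------------------------------------------------------
# penalized regression splines with GCV


class _SplineBasis:
    """Penalized B-spline machinery for one (n, degree, n_knots) geometry.

    Precomputes the B-spline design matrix on the unit grid and the
    derivative-penalty Gram matrix (order ``(degree + 1) // 2``, exact
    Gauss–Legendre quadrature).  Fits solve
    ``(B'B + lam * P) beta = B'y`` by a fresh Cholesky per lambda — with
    71 interior knots the basis is nearly (or, for short series, exactly)
    rank-deficient without the penalty, so one-shot diagonalizations are
    numerically fragile while the per-lambda normal equations stay well
    conditioned.  A relative ridge of 1e-9 guards the lambda -> 0 limit.
    """

    def __init__(self, n: int, degree: int, n_knots: int) -> None:
        x = np.arange(n) / (n - 1)
        interior = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
        knots = np.concatenate(
            [np.zeros(degree + 1), interior, np.ones(degree + 1)]
        )
        k = len(knots) - degree - 1  # number of basis functions
        spl = BSpline(knots, np.eye(k), degree, extrapolate=False)
        self.design = np.nan_to_num(spl(x))

        m = (degree + 1) // 2  # penalize the m-th derivative
        breaks = np.concatenate([[0.0], interior, [1.0]])
        npts = max(degree - m + 1, 1)
        gx, gw = np.polynomial.legendre.leggauss(npts)
        mid = 0.5 * (breaks[1:] + breaks[:-1])
        half = 0.5 * (breaks[1:] - breaks[:-1])
        qx = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
        qw = (half[:, None] * gw[None, :]).ravel()
        d = np.nan_to_num(spl.derivative(m)(qx))
        # basis derivatives sum to zero pointwise (the constant is in the
        # penalty null space); enforce it exactly so huge lambdas cannot
        # shrink the mean level through rounding in d
        d -= d.mean(axis=1, keepdims=True)
        self.penalty = (d * qw[:, None]).T @ d
        # square root of the penalty, for the augmented least-squares form
        w, e = np.linalg.eigh(self.penalty)
        self.penalty_root = np.sqrt(np.maximum(w, 0.0))[:, None] * e.T
        self.n = n

    def _solve(self, lam: float) -> np.ndarray:
        """Return X with the hat matrix S = X'X, via QR of the design
        augmented with sqrt(lam) times the penalty root — numerically far
        better conditioned than the penalized normal equations."""
        aug = np.vstack([self.design, np.sqrt(lam) * self.penalty_root])
        r = np.linalg.qr(aug, mode="r")
        return solve_triangular(r.T, self.design.T, lower=True)

    def fit(self, y: np.ndarray, lam: float) -> np.ndarray:
        x = self._solve(lam)
        return x.T @ (x @ y)

    def gcv_lambda(self, y: np.ndarray, grid: np.ndarray = _GCV_LAMBDA_GRID) -> float:
        best_lam, best_score = grid[0], np.inf
        for lam in grid:
            x = self._solve(lam)
            fitted = x.T @ (x @ y)
            rss = float(np.sum((y - fitted) ** 2))
            df = float(np.sum(x * x))  # tr(X'X)
            denom = max(self.n - df, 1e-8)
            score = self.n * rss / denom**2
            if score < best_score - 1e-15:
                best_score, best_lam = score, lam
        return float(best_lam)


_SPLINE_CACHE: dict[tuple[int, int, int], _SplineBasis] = {}


def _spline_basis(n: int, degree: int, n_knots: int) -> _SplineBasis:
    key = (n, degree, n_knots)
    if key not in _SPLINE_CACHE:
        _SPLINE_CACHE[key] = _SplineBasis(*key)
    return _SPLINE_CACHE[key]


def spline_smooth(t: TangentSeries, cfg: SmootherConfig) -> TangentSeries:
    """Penalized regression spline fit of each component.

    Degree 1, 3 or 5 with ``cfg.n_knots`` equally spaced interior knots;
    the roughness penalty is the integrated squared derivative of order
    ``(degree + 1) // 2`` (whose null space matches the polynomial trend
    the degree can carry), weighted by a per-component GCV-selected
    lambda, or by ``cfg.smoothing_parameter`` when it is a number.
    """
    if cfg.spline_degree not in (1, 3, 5):
        raise ValueError("spline_degree must be 1, 3 or 5")
    v = t.values
    basis = _spline_basis(len(v), cfg.spline_degree, cfg.n_knots)
    out = np.empty_like(v)
    for c in range(3):
        y = v[:, c]
        if cfg.smoothing_parameter == "cv":
            lam = basis.gcv_lambda(y)
        else:
            lam = float(cfg.smoothing_parameter)
        out[:, c] = basis.fit(y, lam)
    return t.with_values(out)


def smooth(t: TangentSeries, cfg: SmootherConfig) -> TangentSeries:
    """Dispatch to the configured smoother family ("none" is identity)."""
    if cfg.family == "none":
        return t
    if cfg.family == "wavelet":
        return wavelet_smooth(t, cfg)
    if cfg.family == "fourier":
        return fourier_smooth(t, cfg)
    if cfg.family == "spline":
        return spline_smooth(t, cfg)
    raise ValueError(f"unknown smoother family {cfg.family!r}")
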