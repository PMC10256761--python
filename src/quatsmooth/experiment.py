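"""Grid evaluation of transform x smoother x noise combinations and the
bootstrap logit-regression meta-analysis of the resulting performance.

``run_pipeline`` composes one full analysis: tangent transform ->
smoothing in R^3 -> reconstruction on the 3-sphere -> DTW 5-NN
cross-validated accuracy and AUC.  ``run_grid`` expands the Cartesian
product over transforms, smoother configurations, noise settings and
replicates (one freshly generated dataset per noise setting and
replicate, shared across methods so they are compared on identical data
and folds).  ``bootstrap_regression`` regresses the logit of a
performance metric on the transform, the smoother family and the two
noise parameters, with case-resampling bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .classification import LabeledDataset, cross_validate
from .quaternions import QuaternionSeries, sign_align
from .simulate import (
    ClassTemplate,
    NoiseParams,
    ORIGINAL_PROXY,
    STUDY_NOISE_SETTINGS,
    generate_dataset,
)
from .smoothing import SmootherConfig, smooth
from .transforms import (
    angular_velocity_transform,
    exp_reconstruct,
    log_transform,
    velocity_reconstruct,
)

__all__ = [
    "TRANSFORMATIONS",
    "bootstrap_regression",
    "default_noise_grid",
    "run_grid",
    "run_pipeline",
    "smooth_series",
]

TRANSFORMATIONS = ("logarithm", "angular_velocity", "none")


def _next_pow2(n: int) -> int:
    m = 1
    while m < n:
        m *= 2
    return m


def _smooth_values(tangent, cfg: SmootherConfig):
    """Apply a smoother, zero-padding to a dyadic length for the DWT.

    The angular-velocity series has N - 1 rows, which is not a power of
    two when N is; trailing zero rows are appended for the transform and
    dropped afterwards.
    """
    n = len(tangent.values)
    if cfg.family == "wavelet" and (n & (n - 1)) != 0:
        m = _next_pow2(n)
        padded = np.vstack([tangent.values, np.zeros((m - n, 3))])
        out = smooth(tangent.with_values(padded), cfg)
        return tangent.with_values(out.values[:n])
    return smooth(tangent, cfg)


def smooth_series(
    s: QuaternionSeries, transformation: str, cfg: SmootherConfig
) -> QuaternionSeries:
    """Transform one series to R^3, smooth, and reconstruct on H_1."""
    s = QuaternionSeries(sign_align(s.q), s.h)
    if transformation == "logarithm":
        return exp_reconstruct(_smooth_values(log_transform(s), cfg))
    if transformation == "angular_velocity":
        return velocity_reconstruct(_smooth_values(angular_velocity_transform(s), cfg))
    raise ValueError(f"unknown transformation {transformation!r}")


def run_pipeline(
    data: LabeledDataset,
    transformation: str = "logarithm",
    cfg: Optional[SmootherConfig] = None,
    cv_seed: int = 0,
    *,
    k: int = 5,
    n_folds: int = 5,
) -> tuple[float, float]:
    """One grid cell: smooth every series (unless ``transformation`` is
    "none"), then cross-validated DTW k-NN accuracy and AUC."""
    if transformation not in TRANSFORMATIONS:
        raise ValueError(f"unknown transformation {transformation!r}")
    if transformation == "none":
        processed = data
    else:
        if cfg is None:
            raise ValueError("a SmootherConfig is required unless transformation='none'")
        processed = LabeledDataset(
            [smooth_series(s, transformation, cfg) for s in data.series],
            data.labels,
            data.ids,
        )
    return cross_validate(processed, k=k, n_folds=n_folds, seed=cv_seed)


def default_noise_grid() -> list[NoiseParams]:
    """The five studied noise settings plus the near-clean proxy."""
    return list(STUDY_NOISE_SETTINGS) + [ORIGINAL_PROXY]


def run_grid(
    smoothers: Sequence[SmootherConfig],
    *,
    transformations: Sequence[str] = ("logarithm", "angular_velocity"),
    noise_settings: Optional[Sequence[NoiseParams]] = None,
    n_replicates: int = 10,
    n_per_class: int = 27,
    n_points: int = 128,
    templates: Optional[Sequence[ClassTemplate]] = None,
    base_seed: int = 0,
    k: int = 5,
    n_folds: int = 5,
    include_baseline: bool = True,
    progress: bool = False,
) -> pd.DataFrame:
    """Expand and run the full evaluation grid.

    One dataset is generated per (noise setting, replicate); every
    transform/smoother combination — and, once, the no-smoothing
    baseline — is evaluated on that same dataset with the same CV folds.
    Returns one row per grid cell with the achieved accuracy and AUC.
    """
    if noise_settings is None:
        noise_settings = default_noise_grid()
    records = []
    for si, noise in enumerate(noise_settings):
        for rep in range(n_replicates):
            data_seed = int(
                np.random.SeedSequence([base_seed, si, rep]).generate_state(1)[0] % (2**31)
            )
            cv_seed = data_seed + 1
            data = generate_dataset(
                templates, n_per_class, n_points, noise, seed=data_seed
            )
            cells = [("none", None)] if include_baseline else []
            cells += [(tr, cfg) for tr in transformations for cfg in smoothers]
            for transformation, cfg in cells:
                acc, auc = run_pipeline(
                    data, transformation, cfg, cv_seed, k=k, n_folds=n_folds
                )
                records.append(
                    {
                        "transformation": transformation,
                        "smoother": cfg.label() if cfg is not None else "none",
                        "family": cfg.family if cfg is not None else "none",
                        "alpha": noise.alpha,
                        "beta": noise.beta,
                        "replicate": rep,
                        "seed": data_seed,
                        "accuracy": acc,
                        "auc": auc,
                    }
                )
                if progress:
                    r = records[-1]
                    print(
                        f"alpha={noise.alpha} beta={noise.beta} rep={rep} "
                        f"{r['transformation']}/{r['smoother']}: "
                        f"acc={acc:.3f} auc={auc:.3f}",
                        flush=True,
                    )
    return pd.DataFrame.from_records(records)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def bootstrap_regression(
    records: pd.DataFrame,
    target: str = "accuracy",
    B: int = 1000,
    seed: int = 0,
    *,
    n_effective: int = 54,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap linear regression of logit(target) on the design factors.

    Covariates: transformation (dummy for "logarithm", reference
    "angular_velocity"), smoother family (dummies for "spline" and
    "wavelet", reference "fourier"), and the numeric noise parameters
    alpha and beta.  The target is clipped to
    ``[eps, 1 - eps]`` with ``eps = 1 / (2 * n_effective)`` before the
    logit (``n_effective`` = number of classified observations behind
    each metric value).  Case-resampling bootstrap with ``B`` replicates;
    percentile confidence intervals.
    """
    if target not in records.columns:
        raise ValueError(f"records has no column {target!r}")
    df = records[records["transformation"].isin(("logarithm", "angular_velocity"))].copy()
    if df["transformation"].nunique() < 2:
        raise ValueError("records must span both transformations")
    if df["family"].nunique() < 2:
        raise ValueError("records must span at least two smoother families")

    eps = 1.0 / (2.0 * n_effective)
    y = _logit(np.clip(df[target].to_numpy(float), eps, 1.0 - eps))
    if np.ptp(y) == 0:
        raise ValueError(f"target {target!r} is constant across records: degenerate fit")

    x = np.column_stack(
        [
            np.ones(len(df)),
            (df["transformation"] == "logarithm").to_numpy(float),
            (df["family"] == "spline").to_numpy(float),
            (df["family"] == "wavelet").to_numpy(float),
            df["alpha"].to_numpy(float),
            df["beta"].to_numpy(float),
        ]
    )
    names = [
        "intercept",
        "transformation_logarithm",
        "smoothing_method_spline",
        "smoothing_method_wavelet",
        "noise_variance_alpha",
        "noise_autocorrelation_beta",
    ]

    fit = sm.OLS(y, x).fit()
    estimates = fit.params

    rng = np.random.default_rng(seed)
    n = len(y)
    boot = np.empty((B, x.shape[1]))
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot[b], *_ = np.linalg.lstsq(x[idx], y[idx], rcond=None)
    lo = 100.0 * alpha_level / 2.0
    return pd.DataFrame(
        {
            "estimate": estimates,
            "stdev": boot.std(axis=0, ddof=1),
            "ci_low": np.percentile(boot, lo, axis=0),
            "ci_high": np.percentile(boot, 100.0 - lo, axis=0),
        },
        index=names,
    )
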