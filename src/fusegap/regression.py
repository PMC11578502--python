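"""Probabilistic aggregation, displacement-moment regression, sensitivity.

The probabilistic sweep yields per-sample, per-angle quantities (regional
stress maxima, monitor-point gap displacements, section moments).  This
module reduces them to mean/SD summaries, fits the linear
displacement-versus-moment relationships Delta_u(M) = a M + b with their
coefficient of determination R^2, ranks the influence of the sampled moduli
through standardized regression coefficients, and compares real against
artificial bone parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ProbabilisticSummary:
    """Per-angle mean and sample SD of one scalar quantity."""

    quantity: str
    angles: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": self.quantity,
                "angle": self.angles,
                "mean": self.mean,
                "sd": self.sd,
                "n_samples": self.n_samples,
            }
        )


@dataclass
class RegressionResult:
    """Ordinary least squares fit y = slope x + intercept."""

    slope: float       #: mm per N mm (equivalently 1/N)
    intercept: float   #: mm
    r_squared: float
    stderr_slope: float
    stderr_intercept: float
    n: int
    degenerate: bool = False

    def predict(self, x):
        return self.slope * np.asarray(x) + self.intercept


def aggregate_samples(values, angles=None, quantity: str = "") -> ProbabilisticSummary:
    """Mean and sample SD (n-1 denominator) across samples, per angle.

    ``values`` is (n_samples,) or (n_samples, n_angles).
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[0] < 1 or v.size == 0:
        raise ValueError("need at least one sample")
    if angles is None:
        angles = np.arange(v.shape[1])
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros(v.shape[1])
    return ProbabilisticSummary(
        quantity=quantity, angles=np.asarray(angles), mean=mean, sd=sd,
        n_samples=v.shape[0],
    )


def fit_linear(x, y) -> RegressionResult:
    """OLS line fit with R^2 = 1 - SS_res/SS_tot (0 when SS_tot = 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired observations")
    if np.ptp(x) == 0:
        return RegressionResult(
            slope=0.0, intercept=float(np.mean(y)), r_squared=0.0,
            stderr_slope=np.inf, stderr_intercept=np.inf, n=len(x),
            degenerate=True,
        )
    res = stats.linregress(x, y)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 0.0
    else:
        ss_res = float(((y - (res.slope * x + res.intercept)) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=r2, stderr_slope=float(res.stderr),
        stderr_intercept=float(res.intercept_stderr), n=len(x),
    )


def sensitivity(X, y, names=None) -> pd.DataFrame:
    """Standardized multiple-regression coefficients of y on sampled inputs.

    ``X`` is (n_samples, n_params); both sides are z-scored, so the
    coefficients are comparable across parameters with different units and
    spreads.  Returns a frame sorted by |coefficient| (the influence
    ranking); near-collinear inputs are flagged through the design
    condition number.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more samples than parameters")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if np.any(sx == 0):
        raise ValueError("constant input column")
    Z = (X - X.mean(axis=0)) / sx
    zy = (y - y.mean()) / sy if sy > 0 else np.zeros(n)
    A = np.column_stack([Z, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, zy, rcond=None)
    cond = float(np.linalg.cond(Z))
    df = pd.DataFrame(
        {
            "parameter": names,
            "coefficient": coef[:p],
            "abs_coefficient": np.abs(coef[:p]),
            "collinear": cond > 1e8,
        }
    ).sort_values("abs_coefficient", ascending=False, ignore_index=True)
    df["rank"] = np.arange(1, p + 1)
    return df


def compare_bone_models(
    summary_real: ProbabilisticSummary, summary_artificial: ProbabilisticSummary
) -> float:
    """Mean percent difference |real - artificial| / |real| over angles."""
    if summary_real.quantity != summary_artificial.quantity or not np.array_equal(
        summary_real.angles, summary_artificial.angles
    ):
        raise ValueError("summaries do not describe matching quantities/angles")
    a, b = summary_real.mean, summary_artificial.mean
    if np.any(a == 0):
        raise ValueError("zero reference mean")
    return float(np.mean(np.abs(a - b) / np.abs(a)) * 100.0)
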