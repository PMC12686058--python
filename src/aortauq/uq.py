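"""Quasi-Monte Carlo propagation, Sobol sensitivity and CDF validation.

The uncertainty pipeline propagates the 9-D epistemic input box through the
(surrogate) model with scrambled Sobol sequences, attributes output variance
to inputs with Sobol total-effect indices (Saltelli A/B/AB_i matrices,
Jansen estimator), attaches association signs from Spearman rank
correlations, and validates the predicted diameter distribution against the
imaging comparator with the CDF area metric

    d = integral |F_model(x) - F_comparator(x)| dx     (units: mm),

where the comparator CDF is Normal(measured mean, scanner sd).  The metric
is reported both in mm and as a percentage of a normalization length
(default: the comparator mean), and compared against the rigor threshold
(default 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .doe import INPUT_NAMES, InputBounds

__all__ = [
    "SensitivityResult",
    "ValidationResult",
    "StressUQ",
    "sobol_sample",
    "total_effect_indices",
    "association_signs",
    "area_metric",
    "prob_leq",
    "density_mode",
]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _bounds_arrays(bounds) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(bounds, InputBounds):
        return bounds.lb, bounds.ub, list(INPUT_NAMES)
    lb, ub = (np.asarray(b, dtype=float) for b in bounds)
    if lb.shape != ub.shape or np.any(lb >= ub):
        raise ValueError("need LB < UB per dimension")
    return lb, ub, [f"x{i + 1}" for i in range(lb.size)]


def sobol_sample(bounds, n: int, seed: int | None = None, scramble: bool = True) -> pd.DataFrame:
    """``n`` rows of a (scrambled) Sobol sequence scaled per column to
    [LB, UB]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lb, ub, names = _bounds_arrays(bounds)
    sampler = qmc.Sobol(d=lb.size, scramble=scramble, seed=seed)
    with warnings.catch_warnings():
        # n need not be a power of two for plain propagation sampling.
        warnings.simplefilter("ignore", UserWarning)
        unit = sampler.random(n)
    return pd.DataFrame(qmc.scale(unit, lb, ub), columns=names)


# ---------------------------------------------------------------------------
# Sobol total-effect sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    """Total-effect indices with Pareto ordering and association signs."""

    names: list[str]
    tei: np.ndarray  # fractions; need not sum to 1
    base_n: int
    seed: int | None
    signs: dict[str, str] = field(default_factory=dict)

    @property
    def tei_percent(self) -> np.ndarray:
        return self.tei * 100.0

    @property
    def ranking(self) -> list[str]:
        """Input names in descending total-effect order (Pareto order)."""
        return [self.names[i] for i in np.argsort(self.tei)[::-1]]

    def as_frame(self) -> pd.DataFrame:
        order = np.argsort(self.tei)[::-1]
        return pd.DataFrame(
            {
                "input": [self.names[i] for i in order],
                "tei": self.tei[order],
                "tei_percent": self.tei_percent[order],
                "rank": np.arange(1, len(order) + 1),
                "sign": [self.signs.get(self.names[i], "") for i in order],
            }
        )

    def to_dict(self) -> dict:
        return {
            "base_n": self.base_n,
            "seed": self.seed,
            "tei_percent": {n: float(t) for n, t in zip(self.names, self.tei_percent)},
            "ranking": self.ranking,
            "signs": dict(self.signs),
        }


def total_effect_indices(
    predict_fn,
    bounds,
    base_n: int = 1024,
    seed: int | None = 0,
) -> SensitivityResult:
    """Sobol total-effect indices by the Jansen estimator.

    Builds Saltelli sample matrices A, B and A_B^(i) from one scrambled
    Sobol stream ((d + 2) * base_n model evaluations) and estimates

        ST_i = E[(f(A) - f(A_B^(i)))^2] / (2 Var[f]).

    ``predict_fn`` must map an (n, d) array to n outputs.
    """
    if base_n < 64:
        raise ValueError("base_n must be >= 64")
    lb, ub, names = _bounds_arrays(bounds)
    d = lb.size
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        unit = sampler.random(base_n)
    A = qmc.scale(unit[:, :d], lb, ub)
    B = qmc.scale(unit[:, d:], lb, ub)
    fA = np.asarray(predict_fn(A), dtype=float).ravel()
    fB = np.asarray(predict_fn(B), dtype=float).ravel()
    var = float(np.var(np.concatenate([fA, fB]), ddof=0))
    if var == 0.0:
        raise ValueError("output variance is zero; total-effect indices undefined")
    tei = np.empty(d)
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = np.asarray(predict_fn(ABi), dtype=float).ravel()
        tei[i] = float(np.mean((fA - fABi) ** 2) / (2.0 * var))
    return SensitivityResult(names=names, tei=tei, base_n=base_n, seed=seed)


def association_signs(X, y, names: list[str] | None = None, tol: float = 0.01) -> dict[str, str]:
    """Per-input association sign from the Spearman rank correlation with
    the output; |rho| < ``tol`` is flagged indeterminate."""
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y must have matching length")
    out = {}
    for j, name in enumerate(names):
        rho = stats.spearmanr(X[:, j], y).statistic
        if not np.isfinite(rho) or abs(rho) < tol:
            out[name] = "indeterminate"
        else:
            out[name] = "+" if rho > 0 else "-"
    return out


# ---------------------------------------------------------------------------
# CDF area metric
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    """Model-vs-comparator CDF comparison."""

    area_mm: float
    area_percent: float
    threshold_percent: float
    passed: bool
    comp_mean: float
    comp_sd: float
    normalization: float
    n_sample: int

    def to_dict(self) -> dict:
        return {
            "area_mm": self.area_mm,
            "area_percent": self.area_percent,
            "threshold_percent": self.threshold_percent,
            "passed": self.passed,
            "comparator_mean_mm": self.comp_mean,
            "comparator_sd_mm": self.comp_sd,
            "normalization_mm": self.normalization,
            "n_sample": self.n_sample,
        }


def _normal_cdf_integral(a: float, b: float, m: float, s: float) -> float:
    """Exact integral of Phi((x - m)/s) over [a, b]."""
    za, zb = (a - m) / s, (b - m) / s

    def anti(z):
        return s * (z * stats.norm.cdf(z) + stats.norm.pdf(z))

    return anti(zb) - anti(za)


def _abs_level_minus_normal(a: float, b: float, c: float, m: float, s: float) -> float:
    """Exact integral of |c - Phi((x - m)/s)| over [a, b] for constant c."""
    if b <= a:
        return 0.0
    pieces = [a, b]
    if 0.0 < c < 1.0:
        xc = m + s * stats.norm.ppf(c)
        if a < xc < b:
            pieces = [a, xc, b]
    total = 0.0
    for lo, hi in zip(pieces[:-1], pieces[1:]):
        phi_int = _normal_cdf_integral(lo, hi, m, s)
        total += abs(c * (hi - lo) - phi_int)
    return total


def area_metric(
    model_sample,
    comp_mean: float,
    comp_sd: float,
    normalization: float | None = None,
    threshold: float = 5.0,
) -> ValidationResult:
    """CDF area metric between the model's empirical output distribution and
    the Normal comparator, by exact piecewise integration of the step CDF
    against the Normal CDF.

    ``normalization`` (mm) converts the metric to the dimensionless
    percentage compared against ``threshold``; it defaults to the comparator
    mean, which makes the 5% rigor rule a fraction of aneurysm size.
    """
    x = np.sort(np.asarray(model_sample, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("model sample is empty")
    if comp_sd <= 0:
        raise ValueError("comp_sd must be positive")
    n = x.size
    lo = min(x[0], comp_mean) - 8.0 * comp_sd
    hi = max(x[-1], comp_mean) + 8.0 * comp_sd

    edges = np.concatenate([[lo], x, [hi]])
    area = 0.0
    for k in range(n + 1):
        area += _abs_level_minus_normal(edges[k], edges[k + 1], k / n, comp_mean, comp_sd)

    norm = comp_mean if normalization is None else normalization
    if norm <= 0:
        raise ValueError("normalization must be positive")
    pct = 100.0 * area / norm
    return ValidationResult(
        area_mm=float(area),
        area_percent=float(pct),
        threshold_percent=float(threshold),
        passed=bool(pct <= threshold),
        comp_mean=float(comp_mean),
        comp_sd=float(comp_sd),
        normalization=float(norm),
        n_sample=n,
    )


def prob_leq(sample, threshold: float) -> float:
    """Empirical probability that the output is <= ``threshold``."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("sample is empty")
    return float(np.mean(x <= threshold))


# ---------------------------------------------------------------------------
# Output-density summaries
# ---------------------------------------------------------------------------


@dataclass
class StressUQ:
    """Kernel-density summary of a propagated output sample."""

    sample: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    mode: float
    interval95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "interval95": list(self.interval95),
            "n_sample": int(self.sample.size),
        }


def density_mode(sample, grid_n: int = 512) -> StressUQ:
    """Gaussian-kernel density estimate (Silverman bandwidth) of the sample;
    the mode is the argmax on a ``grid_n``-point grid and a 95% central
    interval is attached."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 sample points")
    lo95, hi95 = np.percentile(x, [2.5, 97.5])
    if np.ptp(x) == 0.0:
        c = float(x[0])
        grid = np.full(grid_n, c)
        return StressUQ(x, grid, np.full(grid_n, np.inf), c, (c, c))
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_n)
    dens = kde(grid)
    return StressUQ(
        sample=x,
        grid=grid,
        density=dens,
        mode=float(grid[np.argmax(dens)]),
        interval95=(float(lo95), float(hi95)),
    )
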