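"""Success rate as a function of contact cutoff, and asymmetric-sigmoid fits.

Sweeping the cutoff from bond length to the structure's diameter takes the
pathway success rate from 0% to 100% along a sigmoidal curve; systems of
different geometric complexity differ in where the curve rises.  The curve is
summarized by the five-parameter logistic (asymmetric sigmoid)

    y(x) = d + (a - d) / [1 + (x/c)^b]^m

with a = y(0), d the plateau as x -> inf (for a < d and b, c, m > 0), c a
location scale in A, b a slope exponent and m the asymmetry exponent.

The sweep uses common random numbers: the same selection streams are replayed
at every cutoff, so the rate sequence is non-decreasing *exactly* (an edge
set at a smaller cutoff is a subset of the edge set at a larger one), not
just statistically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .contacts import DistanceMatrix, neighbor_map
from .errors import FitError, InputError
from .nullmodel import DEFAULT_TOLERANCE, ExperimentStats, run_experiment

__all__ = [
    "SweepResult",
    "LogisticFit",
    "cutoff_sweep",
    "fit_5pl",
    "eval_5pl",
    "sweep_to_csv",
    "fit_to_json",
    "plot_sweep",
]


@dataclass
class SweepResult:
    cutoffs: list[float]
    stats: list[ExperimentStats]

    def __post_init__(self) -> None:
        if len(self.cutoffs) != len(self.stats):
            raise InputError("cutoffs and stats must have equal length")
        if any(b <= a for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise InputError("cutoffs must be strictly increasing")

    @property
    def rates(self) -> list[float]:
        return [s.mean_rate for s in self.stats]


@dataclass(frozen=True)
class LogisticFit:
    """Fitted 5PL parameters.  ``a`` is the value at x=0 (%), ``d`` the far
    asymptote (%), ``c`` a location (A); ``b``, ``m`` positive exponents."""

    a: float
    b: float
    c: float
    d: float
    m: float
    rss: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.b > 0 and self.c > 0 and self.m > 0):
            raise InputError("b, c and m must be positive")


def cutoff_sweep(
    dm: DistanceMatrix,
    cutoffs,
    fraction: float,
    start: int,
    end: int,
    n_selections: int,
    n_trials: int,
    base_seed: int,
    tolerance: float = DEFAULT_TOLERANCE,
    coords: np.ndarray | None = None,
) -> SweepResult:
    """Run the null-model experiment at each cutoff with common random numbers.

    The same base seed (hence the same per-trial selection streams) is reused
    at every cutoff, which makes the mean-rate sequence non-decreasing
    exactly, by edge-set monotonicity.
    """
    cutoffs = [float(c) for c in cutoffs]
    if not cutoffs:
        raise InputError("cutoffs must be non-empty")
    if any(c < 0 for c in cutoffs):
        raise InputError("cutoffs must be non-negative")
    stats = [
        run_experiment(
            dm, c, fraction, start, end, n_selections, n_trials, base_seed,
            tolerance=tolerance, coords=coords, graph=neighbor_map(dm, c),
        )
        for c in cutoffs
    ]
    return SweepResult(cutoffs=cutoffs, stats=stats)


def _eval_5pl_raw(x, a: float, b: float, c: float, d: float, m: float):
    """Stable evaluation of d + (a-d)/[1+(x/c)^b]^m in log space."""
    x = np.asarray(x, dtype=np.float64)
    out = np.full(x.shape, float(a))
    pos = x > 0
    if np.any(pos):
        t = b * (np.log(x[pos]) - np.log(c))
        # log[(1+e^t)^m] = m * log1p(e^t), via logaddexp for stability.
        log_denom = m * np.logaddexp(0.0, t)
        out[pos] = d + (a - d) * np.exp(-log_denom)
    return out


def eval_5pl(fit: LogisticFit, x):
    """Evaluate a 5PL curve; exact ``a`` at x=0, stable for extreme exponents."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if np.any(x_arr < 0):
        raise InputError("x must be non-negative")
    y = _eval_5pl_raw(x_arr, fit.a, fit.b, fit.c, fit.d, fit.m)
    return float(y[0]) if np.isscalar(x) or np.ndim(x) == 0 else y


def fit_5pl(xs, ys) -> LogisticFit:
    """Least-squares 5PL fit with positivity enforced by log-parameterization.

    Initialization: a = min(y), d = max(y), c = x at the half-range crossing,
    b = 5, m = 1.  Constant data yield a flat degenerate fit (flagged) rather
    than an error.
    """
    xs = np.asarray(xs, dtype=np.float64)
    ys = np.asarray(ys, dtype=np.float64)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise InputError("xs and ys must be 1-D arrays of equal length")
    if len(xs) < 6:
        raise InputError("need at least 6 points to fit 5 parameters")
    if np.any(np.diff(xs) <= 0):
        raise InputError("xs must be strictly increasing")

    if np.ptp(ys) < 1e-9:
        level = float(ys[0])
        return LogisticFit(a=level, b=5.0, c=max(float(np.median(xs)), 1e-6),
                           d=level, m=1.0, rss=0.0, degenerate=True)

    a0, d0 = float(ys.min()), float(ys.max())
    half = 0.5 * (a0 + d0)
    cross = np.nonzero(ys >= half)[0]
    c0 = float(xs[cross[0]]) if len(cross) else float(np.median(xs))
    c0 = max(c0, 1e-3)
    theta0 = np.array([a0, d0, np.log(5.0), np.log(c0), 0.0])

    def residuals(theta):
        a, d, log_b, log_c, log_m = theta
        return _eval_5pl_raw(xs, a, np.exp(log_b), np.exp(log_c), d, np.exp(log_m)) - ys

    result = least_squares(residuals, theta0, method="lm", max_nfev=20000)
    if not result.success:
        raise FitError(f"5PL fit did not converge: {result.message}", result)
    a, d, log_b, log_c, log_m = result.x
    return LogisticFit(
        a=float(a), b=float(np.exp(log_b)), c=float(np.exp(log_c)),
        d=float(d), m=float(np.exp(log_m)),
        rss=float(np.sum(result.fun**2)),
    )


# ---------------------------------------------------------------------------
# Serialization / plotting
# ---------------------------------------------------------------------------

def sweep_to_csv(sweep: SweepResult, path) -> None:
    frame = pd.DataFrame(
        {
            "cutoff_angstrom": sweep.cutoffs,
            "mean_rate_percent": [s.mean_rate for s in sweep.stats],
            "stdev_rate_percent": [s.stdev_rate for s in sweep.stats],
            "converged": [s.converged for s in sweep.stats],
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def fit_to_json(fit: LogisticFit, path=None, grid: np.ndarray | None = None) -> str:
    obj = {
        "a_percent": fit.a,
        "b": fit.b,
        "c_angstrom": fit.c,
        "d_percent": fit.d,
        "m": fit.m,
        "rss": fit.rss,
        "degenerate": fit.degenerate,
    }
    if grid is not None:
        obj["grid_x_angstrom"] = [float(v) for v in grid]
        obj["grid_y_percent"] = [float(v) for v in np.atleast_1d(eval_5pl(fit, grid))]
    text = json.dumps(obj, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def plot_sweep(sweep: SweepResult, fit: LogisticFit | None, path) -> None:
    """Rate vs cutoff with the fitted curve, written as SVG/PNG by extension."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(sweep.cutoffs, sweep.rates, "o", label="measured rate")
    if fit is not None:
        grid = np.linspace(min(sweep.cutoffs), max(sweep.cutoffs), 200)
        ax.plot(grid, eval_5pl(fit, grid), "-", label="5PL fit")
    ax.set_xlabel("cutoff (Å)")
    ax.set_ylabel("pathway success rate (%)")
    ax.set_ylim(-2, 102)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
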