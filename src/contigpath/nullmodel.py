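"""Monte Carlo null model for contiguous-pathway significance.

The benchmark question: if 20% of a protein's residues are picked uniformly
at random -- with the allosteric-site and active-site residues always
included -- how often does the picked set contain a contiguous path between
the two sites under a given contact cutoff?  That success rate is the null
distribution against which an observed pathway (e.g. one proposed from
coevolution analysis) is judged.

A *selection* is one random subset; a *trial* evaluates S selections and
reports the fraction that contained a path; an *experiment* repeats trials
with independent sub-seeds and checks convergence across trials.  For tiny
systems :func:`exact_success_probability` enumerates every selection
exhaustively and serves as the independent oracle for the Monte Carlo path.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactGraph, DistanceMatrix, induced_subgraph, neighbor_map
from .errors import EnumerationLimitError, InputError
from .search import connected_oracle, find_path_astar

__all__ = [
    "DEFAULT_FRACTION",
    "DEFAULT_TOLERANCE",
    "Selection",
    "TrialResult",
    "ExperimentStats",
    "selection_size",
    "sample_selection",
    "run_trial",
    "run_experiment",
    "exact_success_probability",
    "stats_to_csv",
    "stats_to_json",
]

#: Default selection fraction: 20% of residues, the size of a typical
#: coevolution-derived sector.
DEFAULT_FRACTION = 0.2

#: Default convergence tolerance: sample stdev of trial rates, percentage points.
DEFAULT_TOLERANCE = 1.0


@dataclass(frozen=True)
class Selection:
    """A fixed-size residue subset that always contains both endpoints."""

    k: int
    members: frozenset[int]
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.members) != self.k:
            raise InputError("selection size does not match k")
        if self.start not in self.members or self.end not in self.members:
            raise InputError("selection must contain both endpoints")
        if self.start == self.end:
            raise InputError("start and end must differ")


@dataclass(frozen=True)
class TrialResult:
    n_selections: int
    n_success: int

    @property
    def rate(self) -> float:
        """Success rate in percent."""
        return 100.0 * self.n_success / self.n_selections


@dataclass
class ExperimentStats:
    """Per-trial rates with their mean/spread and a convergence flag."""

    trial_rates: list[float]
    tolerance: float
    trials: list[TrialResult] = field(default_factory=list)
    trial_seeds: list[int] = field(default_factory=list)

    @property
    def mean_rate(self) -> float:
        return float(np.mean(self.trial_rates))

    @property
    def stdev_rate(self) -> float:
        if len(self.trial_rates) < 2:
            return 0.0
        return float(np.std(self.trial_rates, ddof=1))

    @property
    def converged(self) -> bool:
        return self.stdev_rate <= self.tolerance


def selection_size(n_residues: int, fraction: float) -> int:
    """Selection size k = round(fraction * n), half away from zero, endpoints included."""
    return int(math.floor(fraction * n_residues + 0.5))


def sample_selection(
    n_residues: int,
    fraction: float,
    start: int,
    end: int,
    rng: np.random.Generator,
) -> Selection:
    """Draw one random selection: both endpoints plus k-2 uniform others."""
    k = selection_size(n_residues, fraction)
    members = _sample_members(n_residues, k, start, end, rng)
    return Selection(k=k, members=frozenset(int(m) for m in members), start=start, end=end)


def _others(n_residues: int, start: int, end: int) -> np.ndarray:
    others = np.arange(n_residues)
    return others[(others != start) & (others != end)]


def _validate_selection_args(n_residues: int, k: int, start: int, end: int) -> None:
    if start == end:
        raise InputError("start and end must differ")
    if not (0 <= start < n_residues and 0 <= end < n_residues):
        raise InputError("endpoint index out of range")
    if k < 2 or k > n_residues:
        raise InputError(f"selection size k={k} out of range [2, {n_residues}]")


def _sample_members(
    n_residues: int, k: int, start: int, end: int, rng: np.random.Generator
) -> np.ndarray:
    _validate_selection_args(n_residues, k, start, end)
    others = _others(n_residues, start, end)
    picked = rng.choice(others, size=k - 2, replace=False)
    return np.concatenate([[start, end], picked])


def run_trial(
    dm: DistanceMatrix,
    cutoff_c: float,
    fraction: float,
    start: int,
    end: int,
    n_selections: int,
    rng: np.random.Generator,
    coords: np.ndarray | None = None,
    graph: ContactGraph | None = None,
    fast_fail: bool = True,
) -> TrialResult:
    """One trial: S random selections, success = path exists in the induced subgraph.

    Each selection succeeds iff A* finds a path between the endpoints in the
    contact subgraph induced by the selection.  When ``fast_fail`` is on, a
    selection in which the start or end residue has no selected neighbour is
    scored as a failure without running the search -- an equivalence, not an
    approximation, since such an endpoint is isolated in the subgraph.

    ``coords`` (representative coordinates) feeds the A* heuristic; when
    absent the end residue's distance-matrix row is used instead, which is
    the same geometric quantity measured between closest atoms.  Path
    existence does not depend on this choice.
    """
    if n_selections < 1:
        raise InputError("n_selections must be >= 1")
    if graph is None:
        graph = neighbor_map(dm, cutoff_c)
    k = selection_size(dm.n, fraction)
    _validate_selection_args(dm.n, k, start, end)
    h = None if coords is not None else dm.d[:, end]
    adj_start = graph.adjacency[start]
    adj_end = graph.adjacency[end]
    mask = np.zeros(dm.n, dtype=bool)
    n_success = 0
    for _ in range(n_selections):
        members = _sample_members(dm.n, k, start, end, rng)
        mask[:] = False
        mask[members] = True
        if fast_fail and not (mask[adj_start].any() and mask[adj_end].any()):
            continue
        sub = induced_subgraph(graph, members)
        result = find_path_astar(sub, coords, start, end, heuristic=h)
        if result.found:
            n_success += 1
    return TrialResult(n_selections=n_selections, n_success=n_success)


def derive_trial_seeds(base_seed: int, n_trials: int) -> list[int]:
    """Deterministic, independent per-trial seeds from a single user seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_trials)]


def run_experiment(
    dm: DistanceMatrix,
    cutoff_c: float,
    fraction: float,
    start: int,
    end: int,
    n_selections: int,
    n_trials: int,
    base_seed: int,
    tolerance: float = DEFAULT_TOLERANCE,
    coords: np.ndarray | None = None,
    graph: ContactGraph | None = None,
) -> ExperimentStats:
    """Repeat trials with independent derived sub-seeds; converged iff the
    sample stdev of trial rates is within ``tolerance`` percentage points."""
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    if graph is None:
        graph = neighbor_map(dm, cutoff_c)
    seeds = derive_trial_seeds(base_seed, n_trials)
    trials = [
        run_trial(
            dm, cutoff_c, fraction, start, end, n_selections,
            np.random.default_rng(seed), coords=coords, graph=graph,
        )
        for seed in seeds
    ]
    return ExperimentStats(
        trial_rates=[t.rate for t in trials],
        tolerance=tolerance,
        trials=trials,
        trial_seeds=seeds,
    )


def exact_success_probability(
    dm: DistanceMatrix,
    cutoff_c: float,
    fraction: float,
    start: int,
    end: int,
    limit: int = 10**6,
) -> float:
    """Exact pathway probability by exhaustive enumeration of all selections.

    Enumerates every C(n-2, k-2) selection and checks connectivity with the
    heuristic-free BFS oracle.  Refuses above ``limit`` combinations; use the
    Monte Carlo experiment there instead.
    """
    k = selection_size(dm.n, fraction)
    _validate_selection_args(dm.n, k, start, end)
    n_comb = math.comb(dm.n - 2, k - 2)
    if n_comb > limit:
        raise EnumerationLimitError(
            f"C({dm.n - 2}, {k - 2}) = {n_comb} combinations exceeds the limit "
            f"of {limit}; use run_experiment (Monte Carlo) instead"
        )
    graph = neighbor_map(dm, cutoff_c)
    others = _others(dm.n, start, end)
    n_success = 0
    for combo in itertools.combinations(others, k - 2):
        members = (start, end) + combo
        sub = induced_subgraph(graph, members)
        if connected_oracle(sub, start, end):
            n_success += 1
    return n_success / n_comb


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def stats_to_csv(stats: ExperimentStats, path) -> None:
    """One row per trial: trial id, seed, S, successes, rate (%)."""
    frame = pd.DataFrame(
        {
            "trial": range(len(stats.trials)),
            "seed": stats.trial_seeds,
            "n_selections": [t.n_selections for t in stats.trials],
            "n_success": [t.n_success for t in stats.trials],
            "rate_percent": [t.rate for t in stats.trials],
        }
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def stats_to_json(stats: ExperimentStats, path=None, parameters: dict | None = None) -> str:
    from . import __version__

    obj = {
        "mean_rate_percent": stats.mean_rate,
        "stdev_rate_percent": stats.stdev_rate,
        "converged": stats.converged,
        "tolerance_percent": stats.tolerance,
        "trial_rates_percent": stats.trial_rates,
        "parameters": parameters or {},
        "software_version": __version__,
    }
    text = json.dumps(obj, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
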