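"""The Monte Carlo null model against exact enumeration and sampling theory."""

import itertools
import math

import numpy as np
import pytest

from contigpath import (
    EnumerationLimitError,
    InputError,
    build_distance_matrix,
    exact_success_probability,
    make_globule,
    neighbor_map,
    run_experiment,
    run_trial,
    sample_selection,
    selection_size,
)
from contigpath.contacts import induced_subgraph
from contigpath.search import connected_oracle

from conftest import make_chain


def test_selection_size_matches_field_conventions():
    assert selection_size(115, 0.2) == 23   # PDZ: endpoints + 21 random
    assert selection_size(1530, 0.2) == 306  # MutS: endpoints + 304 random
    assert selection_size(10, 0.25) == 3    # half-away-from-zero rounding
    assert selection_size(14, 0.25) == 4


def test_sample_selection_contract():
    rng = np.random.default_rng(0)
    sel = sample_selection(115, 0.2, start=5, end=80, rng=rng)
    assert sel.k == 23 == len(sel.members)
    assert {5, 80} <= sel.members
    # k = 2 -> exactly the endpoints.
    sel2 = sample_selection(10, 0.2, start=0, end=9, rng=rng)
    assert sel2.members == frozenset({0, 9})
    with pytest.raises(InputError):
        sample_selection(10, 0.05, start=0, end=9, rng=rng)  # k < 2
    with pytest.raises(InputError):
        sample_selection(10, 0.2, start=3, end=3, rng=rng)


def test_sample_selection_is_uniform_over_non_endpoints():
    """Inclusion frequency of each free node ~ Binomial(draws, (k-2)/(n-2))."""
    n, fraction = 20, 0.3  # k = 6
    draws = 100_000
    rng = np.random.default_rng(42)
    counts = np.zeros(n)
    for _ in range(draws):
        sel = sample_selection(n, fraction, start=0, end=19, rng=rng)
        for m in sel.members:
            counts[m] += 1
    p = 4 / 18
    se = math.sqrt(p * (1 - p) / draws)
    freqs = counts[1:-1] / draws
    assert np.all(np.abs(freqs - p) <= 4 * se)
    assert counts[0] == counts[19] == draws


def test_run_trial_cutoff_extremes(globule100_dm):
    rng = np.random.default_rng(1)
    full = run_trial(globule100_dm, globule100_dm.diameter(), 0.2, 0, 99, 50, rng)
    assert full.rate == 100.0
    none = run_trial(globule100_dm, 0.0, 0.2, 0, 99, 50, rng)
    assert none.rate == 0.0


def chain_oracle_probability(n, k, start, end, reach):
    """Second, independent oracle for a straight chain whose contact graph
    links residues within ``reach`` sequence steps: a selection succeeds iff
    the sorted selected indices step from start to end with gaps <= reach."""
    others = [i for i in range(n) if i not in (start, end)]
    wins = total = 0
    for combo in itertools.combinations(others, k - 2):
        total += 1
        chosen = sorted(set(combo) | {start, end})
        lo, hi = chosen.index(start), chosen.index(end)
        lo, hi = min(lo, hi), max(lo, hi)
        ok = all(chosen[i + 1] - chosen[i] <= reach for i in range(lo, hi))
        wins += ok
    return wins / total


def test_exact_enumeration_matches_combinatorial_chain_oracle(chain12_dm):
    # 12-bead chain, cutoff 12 A -> edges within 3 sequence steps; k = 6.
    p_exact = exact_success_probability(chain12_dm, 12.0, 0.5, start=0, end=11)
    p_oracle = chain_oracle_probability(12, 6, 0, 11, reach=3)
    assert p_exact == pytest.approx(p_oracle, abs=1e-12)
    assert 0 < p_exact < 1


def test_monte_carlo_approaches_exact_probability(chain12_dm):
    p_exact = exact_success_probability(chain12_dm, 12.0, 0.5, start=0, end=11)
    S = 10_000
    trial = run_trial(chain12_dm, 12.0, 0.5, 0, 11, S, np.random.default_rng(3))
    se = math.sqrt(p_exact * (1 - p_exact) / S)
    assert abs(trial.rate / 100 - p_exact) <= 3 * se


def test_exact_probability_trivial_cases(chain12_dm):
    assert exact_success_probability(chain12_dm, 0.0, 0.5, 0, 11) == 0.0
    # k = n with a connecting graph -> probability 1.
    assert exact_success_probability(chain12_dm, 4.0, 1.0, 0, 11) == 1.0
    with pytest.raises(EnumerationLimitError):
        exact_success_probability(chain12_dm, 12.0, 0.5, 0, 11, limit=10)


def test_experiment_determinism_and_stats(globule100_dm, globule100):
    coords = globule100.rep_coords()
    kwargs = dict(cutoff_c=6.5, fraction=0.2, start=0, end=99,
                  n_selections=300, n_trials=5, base_seed=11, coords=coords)
    a = run_experiment(globule100_dm, **kwargs)
    b = run_experiment(globule100_dm, **kwargs)
    assert a.trial_rates == b.trial_rates
    assert a.trial_seeds == b.trial_seeds
    assert a.mean_rate == pytest.approx(np.mean(a.trial_rates))
    assert a.stdev_rate == pytest.approx(np.std(a.trial_rates, ddof=1))
    assert a.converged == (a.stdev_rate <= a.tolerance)


def test_trial_spread_consistent_with_binomial_sampling(chain12_dm):
    """Across-trial stdev within a factor 3 of 100*sqrt(p(1-p)/S)."""
    p = exact_success_probability(chain12_dm, 12.0, 0.5, 0, 11)
    S = 2000
    stats = run_experiment(chain12_dm, 12.0, 0.5, 0, 11, S, 10, base_seed=5)
    predicted = 100 * math.sqrt(p * (1 - p) / S)
    assert predicted / 3 <= stats.stdev_rate <= predicted * 3


def test_per_seed_monotonicity_in_cutoff(globule100_dm):
    """With common selections, success at c1 implies success at c2 >= c1."""
    g1 = neighbor_map(globule100_dm, 5.0)
    g2 = neighbor_map(globule100_dm, 6.5)
    rng = np.random.default_rng(9)
    for _ in range(300):
        sel = sample_selection(globule100_dm.n, 0.2, 0, 99, rng)
        ok1 = connected_oracle(induced_subgraph(g1, sel.members), 0, 99)
        ok2 = connected_oracle(induced_subgraph(g2, sel.members), 0, 99)
        assert ok2 or not ok1


def test_fast_fail_is_equivalent_to_searching(globule100_dm):
    kwargs = dict(cutoff_c=6.0, fraction=0.2, start=0, end=99, n_selections=2000)
    with_ff = run_trial(globule100_dm, rng=np.random.default_rng(2), **kwargs)
    without = run_trial(globule100_dm, rng=np.random.default_rng(2),
                        fast_fail=False, **kwargs)
    assert with_ff.n_success == without.n_success


def test_search_algorithm_does_not_change_success(globule100, globule100_dm):
    """Success is a property of the subgraph, not of the search route."""
    graph = neighbor_map(globule100_dm, 6.0)
    coords = globule100.rep_coords()
    rng = np.random.default_rng(21)
    from contigpath import find_path_astar, find_path_dfs

    for _ in range(200):
        sel = sample_selection(globule100_dm.n, 0.2, 3, 90, rng)
        sub = induced_subgraph(graph, sel.members)
        a = find_path_astar(sub, coords, 3, 90).found
        d = find_path_dfs(sub, coords, 3, 90).found
        o = connected_oracle(sub, 3, 90)
        assert a == d == o
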