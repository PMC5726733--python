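"""Distance matrices and contact graphs, checked against brute force."""

import numpy as np
import pytest

import contigpath.contacts as contacts
from contigpath import (
    InputError,
    build_distance_matrix,
    induced_subgraph,
    make_globule,
    neighbor_map,
    residue_min_distance,
)
from contigpath.contacts import (
    DistanceMatrix,
    graph_to_json,
    load_distance_npz,
    read_distance_tsv,
    save_distance_npz,
    write_distance_tsv,
)
from contigpath.structures import Atom, Residue, Structure

from conftest import make_chain


def random_residue(rng, number, n_atoms=5, chain="A"):
    return Residue(
        chain_id=chain,
        author_number=number,
        insertion_code="",
        name="ALA",
        atoms=tuple(
            Atom(name=f"C{j}", element="C", xyz=rng.uniform(-10, 10, 3))
            for j in range(n_atoms)
        ),
    )


def brute_force_matrix(structure):
    n = len(structure)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            best = np.inf
            for a in structure.residues[i].atoms:
                for b in structure.residues[j].atoms:
                    best = min(best, float(np.linalg.norm(a.xyz - b.xyz)))
            d[i, j] = best
    np.fill_diagonal(d, 0.0)
    return d


def test_residue_min_distance_basics():
    rng = np.random.default_rng(0)
    res = random_residue(rng, 1)
    assert residue_min_distance(res, res) == 0.0
    a = Residue("A", 1, "", "GLY", (Atom("CA", "C", np.zeros(3)),))
    b = Residue("A", 2, "", "GLY", (Atom("CA", "C", np.array([3.0, 4.0, 0.0])),))
    assert residue_min_distance(a, b) == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(5))
def test_residue_min_distance_equals_exhaustive_pair_minimum(seed):
    rng = np.random.default_rng(seed)
    res_a, res_b = random_residue(rng, 1), random_residue(rng, 2)
    expected = min(
        float(np.linalg.norm(a.xyz - b.xyz))
        for a in res_a.atoms
        for b in res_b.atoms
    )
    assert residue_min_distance(res_a, res_b) == pytest.approx(expected, abs=1e-12)


def test_distance_matrix_trivial_cases():
    single = Structure("one", [Residue("A", 1, "", "GLY", (Atom("CA", "C", np.zeros(3)),))])
    dm = build_distance_matrix(single)
    np.testing.assert_array_equal(dm.d, [[0.0]])
    chain3 = make_chain(3)
    dm3 = build_distance_matrix(chain3)
    off = sorted(dm3.d[np.triu_indices(3, k=1)])
    np.testing.assert_allclose(off, [3.8, 3.8, 7.6])


def test_distance_matrix_matches_brute_force_on_globule():
    g = make_globule(20, seed=2)
    dm = build_distance_matrix(g)
    np.testing.assert_allclose(dm.d, brute_force_matrix(g), atol=1e-9)
    assert np.array_equal(dm.d, dm.d.T)
    assert np.all(np.diag(dm.d) == 0)


def test_blocked_evaluation_matches_brute_force_multiatom(monkeypatch):
    """Multi-atom residues, block size forced tiny so several blocks run."""
    rng = np.random.default_rng(3)
    structure = Structure(
        "rand", [random_residue(rng, i + 1, n_atoms=int(rng.integers(1, 7)))
                 for i in range(15)]
    )
    expected = brute_force_matrix(structure)
    monkeypatch.setattr(contacts, "_BLOCK_ATOMS", 7)
    np.testing.assert_allclose(build_distance_matrix(structure).d, expected, atol=1e-9)


def test_atom_order_permutation_invariance():
    rng = np.random.default_rng(4)
    residues = [random_residue(rng, i + 1) for i in range(8)]
    shuffled = [
        Residue(r.chain_id, r.author_number, r.insertion_code, r.name,
                tuple(r.atoms[i] for i in rng.permutation(len(r.atoms))))
        for r in residues
    ]
    dm1 = build_distance_matrix(Structure("a", residues))
    dm2 = build_distance_matrix(Structure("b", shuffled))
    np.testing.assert_allclose(dm1.d, dm2.d, atol=1e-12)
    g1 = neighbor_map(dm1, 6.0)
    g2 = neighbor_map(dm2, 6.0)
    for i in g1.adjacency:
        np.testing.assert_array_equal(g1.adjacency[i], g2.adjacency[i])


def test_neighbor_map_cutoff_extremes(globule100_dm):
    empty = neighbor_map(globule100_dm, 0.0)
    assert all(len(v) == 0 for v in empty.adjacency.values())
    full = neighbor_map(globule100_dm, globule100_dm.diameter())
    n = globule100_dm.n
    assert all(len(v) == n - 1 for v in full.adjacency.values())
    with pytest.raises(InputError):
        neighbor_map(globule100_dm, -1.0)


def test_contact_graph_invariants_and_monotonicity(globule100_dm):
    prev_edges = set()
    for cutoff in (2.0, 4.0, 6.0, 9.0):
        graph = neighbor_map(globule100_dm, cutoff)
        edges = set()
        for i, nbrs in graph.adjacency.items():
            assert i not in nbrs  # no self-edges
            for j in nbrs:
                assert i in graph.adjacency[int(j)]  # symmetry
                assert globule100_dm.d[i, j] <= cutoff
                edges.add((min(i, int(j)), max(i, int(j))))
        assert prev_edges <= edges  # every edge at c1 survives at c2 >= c1
        prev_edges = edges


def test_induced_subgraph(globule100_dm):
    graph = neighbor_map(globule100_dm, 6.0)
    # Identity on the full node set.
    same = induced_subgraph(graph, range(globule100_dm.n))
    for i in graph.adjacency:
        np.testing.assert_array_equal(same.adjacency[i], graph.adjacency[i])
    # Two far-apart nodes: both isolated.
    far = int(np.argmax(globule100_dm.d[0]))
    pair = induced_subgraph(graph, [0, far])
    assert len(pair.adjacency[0]) == 0 and len(pair.adjacency[far]) == 0
    # Random selection: edge set equals brute-force filtering.
    rng = np.random.default_rng(5)
    members = set(rng.choice(globule100_dm.n, size=30, replace=False).tolist())
    sub = induced_subgraph(graph, members)
    assert set(sub.adjacency) == members
    for i in members:
        expected = sorted(j for j in graph.adjacency[i] if int(j) in members)
        assert list(sub.adjacency[i]) == expected
    with pytest.raises(InputError):
        induced_subgraph(graph, [0, globule100_dm.n + 5])


def test_distance_matrix_serialization_roundtrip(tmp_path):
    g = make_globule(12, seed=6, start_number=301)
    dm = build_distance_matrix(g)
    tsv = tmp_path / "dm.tsv"
    write_distance_tsv(dm, tsv)
    back = read_distance_tsv(tsv)
    assert back.labels == dm.labels
    np.testing.assert_allclose(back.d, dm.d, atol=5e-4)  # 3-decimal format
    npz = tmp_path / "dm.npz"
    save_distance_npz(dm, npz)
    cached = load_distance_npz(npz)
    assert cached.labels == dm.labels
    np.testing.assert_array_equal(cached.d, dm.d)


def test_graph_json_uses_author_keys(tmp_path):
    g = make_chain(3, start_number=301)
    dm = build_distance_matrix(g)
    text = graph_to_json(neighbor_map(dm, 4.0), dm.labels)
    assert '"A:301:"' in text and '"A:302:"' in text


def test_distance_matrix_shape_validation():
    with pytest.raises(InputError):
        DistanceMatrix(labels=[("A", 1, "")], d=np.zeros((2, 2)))
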