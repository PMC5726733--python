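"""Shared fixtures: small synthetic systems used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from contigpath import build_distance_matrix, make_globule, make_multidomain
from contigpath.structures import Atom, Residue, Structure


def make_chain(n: int, spacing: float = 3.8, start_number: int = 1) -> Structure:
    """Straight collinear bead chain along x (single-atom ALA residues)."""
    residues = [
        Residue(
            chain_id="A",
            author_number=start_number + i,
            insertion_code="",
            name="ALA",
            atoms=(Atom(name="CA", element="C", xyz=np.array([i * spacing, 0.0, 0.0])),),
        )
        for i in range(n)
    ]
    return Structure(f"chain-{n}", residues)


@pytest.fixture(scope="session")
def globule100():
    return make_globule(100, seed=11)


@pytest.fixture(scope="session")
def globule100_dm(globule100):
    return build_distance_matrix(globule100)


@pytest.fixture(scope="session")
def multidomain_small():
    return make_multidomain([30, 30], linker_length=4, seed=17)


@pytest.fixture(scope="session")
def multidomain_small_dm(multidomain_small):
    return build_distance_matrix(multidomain_small)


@pytest.fixture(scope="session")
def chain12_dm():
    return build_distance_matrix(make_chain(12))
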