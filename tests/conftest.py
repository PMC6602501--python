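"""Shared fixtures: synthetic complexes, small potentials, brute-force oracle."""

import itertools
import math

import numpy as np
import pytest

from ppiscore.potential import MODES, N_AA, Potential, uniform_potential
from ppiscore.structure import AA_ORDER
from ppiscore.synth import FixtureSpec, make_complex


def brute_force_contacts(structure, d, clash_cutoff=2.5):
    """Independent all-vs-all contact oracle.

    Returns {(chain_i, chain_j, res_index_i, res_index_j):
             (n_mm, n_ms, n_ss, n_clash, d_min)} computed by looping over
    every inter-chain atom pair with plain Euclidean arithmetic.
    """
    out = {}
    for (ca, cb) in itertools.combinations(range(len(structure.chains)), 2):
        chain_a, chain_b = structure.chains[ca], structure.chains[cb]
        for ia, res_a in enumerate(chain_a.residues):
            for ib, res_b in enumerate(chain_b.residues):
                n = [0, 0, 0]
                n_clash = 0
                d_min = math.inf
                for atom_a in res_a.atoms:
                    for atom_b in res_b.atoms:
                        dist = math.dist(atom_a.coord, atom_b.coord)
                        if dist <= d:
                            mode = int(not atom_a.is_backbone) + int(
                                not atom_b.is_backbone
                            )
                            n[mode] += 1
                            d_min = min(d_min, dist)
                            if dist < clash_cutoff:
                                n_clash += 1
                if sum(n):
                    if chain_a.chain_id <= chain_b.chain_id:
                        key = (chain_a.chain_id, chain_b.chain_id, ia, ib)
                    else:
                        key = (chain_b.chain_id, chain_a.chain_id, ib, ia)
                    out[key] = (n[0], n[1], n[2], n_clash, d_min)
    return out


def contacts_as_dict(iface, structure):
    """Map an InterfaceSet to the oracle's key/value shape."""
    index = {
        c.chain_id: {id(r): i for i, r in enumerate(c.residues)}
        for c in structure.chains
    }
    out = {}
    for p in iface.pairs:
        ca, cb = p.res_i.chain_id, p.res_j.chain_id
        ia, ib = index[ca][id(p.res_i)], index[cb][id(p.res_j)]
        key = (ca, cb, ia, ib) if ca <= cb else (cb, ca, ib, ia)
        out[key] = (p.n_mm, p.n_ms, p.n_ss, p.n_clash, p.d_min)
    return out


@pytest.fixture
def oracle():
    return brute_force_contacts


@pytest.fixture
def dimer():
    """Plain side-chain-contact dimer, 8 rungs, gap 3.5 Å."""
    return make_complex(FixtureSpec(seed=11))


@pytest.fixture
def dimer_structure(dimer):
    return dimer.structure


@pytest.fixture
def zero_potential():
    return uniform_potential(0.0)


@pytest.fixture
def random_potential():
    rng = np.random.default_rng(3)
    w = {}
    for m in MODES:
        half = rng.normal(size=(N_AA, N_AA))
        w[m] = (half + half.T) / 2
    g = {}
    for mode in MODES:
        for a in AA_ORDER[:5]:
            for b in AA_ORDER[:5]:
                if a <= b:
                    g[(mode, a, b)] = {1: 1.0, 2: 0.5, 3: 0.25}
    return Potential(w=w, g=g, kappa=2.0)
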