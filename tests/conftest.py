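"""Shared fixtures: toy pedigrees and a mid-sized synthetic herd."""

import numpy as np
import pytest

from lactbias.io_formats import PedigreeEntry
from lactbias.pedigree import build_A_inverse
from lactbias.synthetic_data import SimulationConfig, simulate_herd


@pytest.fixture(scope="session")
def toy_pedigree():
    """Five animals: two founders, two full sibs, one inbred-line start."""
    return [
        PedigreeEntry("s"),
        PedigreeEntry("d"),
        PedigreeEntry("x", "s", "d"),
        PedigreeEntry("y", "s", "d"),
        PedigreeEntry("z", "s", "x"),
    ]


@pytest.fixture(scope="session")
def artefact_herd():
    """Seasonal herd with the 2-day male gestation offset, no true gender
    effect, interval-centred yields: the conditions under which the
    calving-shift artefact is the only calf-gender signal."""
    cfg = SimulationConfig(n_herds=15, cows_per_herd=100, seed=20160314)
    return simulate_herd(cfg)


@pytest.fixture(scope="session")
def artefact_rel(artefact_herd):
    return build_A_inverse(artefact_herd.pedigree)


def random_pedigree(rng: np.random.Generator, n: int) -> list[PedigreeEntry]:
    """Random acyclic pedigree: each animal's parents drawn from earlier ids
    (or unknown), so sorting and relationship rules get exercised with
    unknown parents, half-sibs and occasional inbreeding."""
    entries = []
    for i in range(n):
        sire = dam = None
        if i >= 2 and rng.random() < 0.7:
            sire = f"A{rng.integers(0, i)}"
        if i >= 2 and rng.random() < 0.7:
            dam = f"A{rng.integers(0, i)}"
            if dam == sire:
                dam = None
        entries.append(PedigreeEntry(f"A{i}", sire, dam))
    return entries


def tabular_A(entries):
    """Independent oracle: numerator relationship matrix by the recursive
    kinship definition (not the package's tabular builder)."""
    from lactbias.pedigree import topological_order

    entries = topological_order(entries)
    idx = {e.animal_id: i for i, e in enumerate(entries)}
    sire = [idx.get(e.sire_id, -1) if e.sire_id else -1 for e in entries]
    dam = [idx.get(e.dam_id, -1) if e.dam_id else -1 for e in entries]
    n = len(entries)
    cache = {}

    def kin(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        if i == j:
            v = 0.5 * (1.0 + kin(sire[i], dam[i]))
        else:
            v = 0.5 * (kin(i, sire[j]) + kin(i, dam[j]))
        cache[(i, j)] = v
        return v

    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * kin(i, j) if i != j else 1.0 + kin(sire[i], dam[i])
    # diagonal: a_ii = 1 + F_i = 2*kin(i,i) as well; keep kinship convention
    for i in range(n):
        A[i, i] = 2.0 * kin(i, i)
    return [e.animal_id for e in entries], A
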