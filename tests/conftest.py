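"""Shared fixtures and independent oracles."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from riboscan.backends import BuiltinBackend
from riboscan.fold_engine import CANONICAL_PAIRS, FoldingEngine, default_model
from riboscan.rna_core import SecondaryStructure


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def engine(model):
    return FoldingEngine(model)


@pytest.fixture(scope="session")
def backend(engine):
    be = BuiltinBackend()
    be.engine = engine  # share the DP cache across the whole session
    return be


# --------------------------------------------------------------------------
# independent oracles


def brute_force_pairsets(res: str, min_hairpin: int = 3) -> list[frozenset]:
    """All canonical, position-disjoint, non-crossing pair sets (1-based).

    A flat include/exclude recursion over the candidate-pair list: completely
    independent of the engine's interval decomposition.
    """
    cand = [
        (i, j)
        for i in range(1, len(res) + 1)
        for j in range(i + min_hairpin + 1, len(res) + 1)
        if res[i - 1] + res[j - 1] in CANONICAL_PAIRS
    ]

    def compatible(p, chosen):
        for q in chosen:
            if len({p[0], p[1], q[0], q[1]}) < 4:
                return False
            a, b = (p, q) if p[0] < q[0] else (q, p)
            if a[0] < b[0] < a[1] < b[1]:
                return False
        return True

    out: list[frozenset] = []

    def rec(idx: int, chosen: tuple):
        if idx == len(cand):
            out.append(frozenset(chosen))
            return
        rec(idx + 1, chosen)
        if compatible(cand[idx], chosen):
            rec(idx + 1, chosen + (cand[idx],))

    rec(0, ())
    return out


def random_structure(rng: random.Random, length: int, max_pairs: int = 8,
                     allow_crossing: bool = False) -> SecondaryStructure:
    """Random valid structure by rejection over position-disjoint pairs."""
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for _ in range(max_pairs):
        i = rng.randint(1, max(1, length - 4))
        j = rng.randint(i + 4, length) if i + 4 <= length else None
        if j is None or i in used or j in used:
            continue
        if not allow_crossing:
            bad = any(a < i < b < j or i < a < j < b for a, b in pairs)
            if bad:
                continue
        pairs.append((i, j))
        used.update((i, j))
    return SecondaryStructure.from_pairs(length, pairs)


@pytest.fixture
def rng():
    return random.Random(20260920)


@pytest.fixture
def nprng():
    return np.random.default_rng(20260920)
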