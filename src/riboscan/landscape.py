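"""Energy landscapes at one elongation length.

A landscape is the set of unique sampled structures at one length, each
placed by its base-pair distance to a reference structure (the lowest-energy
unique structure in the sample) and its 37 C free energy.  The minimum-energy
envelope over distance bins supports barrier estimation between the two
basins found by clustering.

Base-pair distance follows the strip/record/restore procedure: pseudoknot
pairs are recorded per structure, removed before comparison, and play no
part in the distance (the symmetric difference of the nested pair sets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rna_core import SecondaryStructure, StructureError, write_dotbracket
from .sampling_protocol import SampledStructure

__all__ = [
    "LandscapePoint",
    "Landscape",
    "EnergyEnvelope",
    "BarrierEstimate",
    "LandscapeError",
    "SingleBasinError",
    "base_pair_distance",
    "pairwise_distances",
    "build_landscape",
    "energy_envelope",
    "barrier_height",
    "write_landscape_tsv",
    "write_envelope_tsv",
]


class LandscapeError(ValueError):
    pass


class SingleBasinError(LandscapeError):
    """Barrier requested for a landscape without two distinct basins."""


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Number of nested base pairs to break or form to convert a into b.

    Pseudoknot-layer pairs are excluded (strip/compare/restore); the result
    is the size of the symmetric difference of the nested pair sets.
    """
    if a.length != b.length:
        raise LandscapeError(
            f"structures of different length ({a.length} vs {b.length})"
        )
    return len(a.nested_pairs ^ b.nested_pairs)


def pairwise_distances(structs: Sequence[SecondaryStructure]) -> np.ndarray:
    """Symmetric base-pair-distance matrix (zero diagonal)."""
    n = len(structs)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = base_pair_distance(structs[i], structs[j])
    return D


@dataclass(frozen=True)
class LandscapePoint:
    structure: SecondaryStructure | None  # None only for planted landscapes
    d: int  # base-pair distance to the reference
    energy37: float
    multiplicity: int = 1
    pk_pair_count: int = 0


@dataclass(frozen=True)
class Landscape:
    length: int
    reference: SecondaryStructure | None
    points: tuple[LandscapePoint, ...]
    sample_size: int


def build_landscape(samples: Sequence[SampledStructure], length: int) -> Landscape:
    """Collapse an ensemble to unique structures with multiplicities.

    Uniqueness is keyed on the nested pair set (the space the distance lives
    in); the representative kept for each key is its lowest-energy member and
    carries the recorded pseudoknot pair count.  The reference is the unique
    structure of lowest 37 C energy (ties broken by lexicographic
    dot-bracket), so exactly one point sits at distance 0.
    """
    if not samples:
        raise LandscapeError("empty sample")
    for s in samples:
        if s.structure.length != length:
            raise LandscapeError(
                f"sample of length {s.structure.length} in landscape of length {length}"
            )
    groups: dict[frozenset, list[SampledStructure]] = {}
    for s in samples:
        groups.setdefault(s.structure.nested_pairs, []).append(s)

    reps: list[tuple[SampledStructure, int]] = []
    for members in groups.values():
        rep = min(
            members, key=lambda s: (s.energy37, write_dotbracket(s.structure))
        )
        reps.append((rep, len(members)))

    ref = min(
        reps, key=lambda rm: (rm[0].energy37, write_dotbracket(rm[0].structure))
    )[0].structure

    points = tuple(
        sorted(
            (
                LandscapePoint(
                    structure=rep.structure,
                    d=base_pair_distance(rep.structure, ref),
                    energy37=rep.energy37,
                    multiplicity=mult,
                    pk_pair_count=rep.structure.pk_pair_count,
                )
                for rep, mult in reps
            ),
            key=lambda p: (p.d, p.energy37, write_dotbracket(p.structure)),
        )
    )
    return Landscape(
        length=length, reference=ref, points=points, sample_size=len(samples)
    )


@dataclass(frozen=True)
class EnergyEnvelope:
    bin_width: int
    env: dict[int, float]  # occupied bin -> minimum energy37

    @property
    def occupied(self) -> list[int]:
        return sorted(self.env)

    def value(self, b: int) -> float:
        """Envelope at bin b; unoccupied bins are linearly interpolated from
        the flanking occupied bins (error outside the occupied range)."""
        if b in self.env:
            return self.env[b]
        occ = self.occupied
        if not occ or b < occ[0] or b > occ[-1]:
            raise LandscapeError(f"bin {b} outside the occupied envelope range")
        lo = max(x for x in occ if x < b)
        hi = min(x for x in occ if x > b)
        frac = (b - lo) / (hi - lo)
        return self.env[lo] + frac * (self.env[hi] - self.env[lo])


def energy_envelope(ls: Landscape, bin_width: int = 1) -> EnergyEnvelope:
    """Per-bin minimum of energy37 over the landscape's points."""
    if bin_width < 1:
        raise LandscapeError(f"bin width must be >= 1 (got {bin_width})")
    env: dict[int, float] = {}
    for p in ls.points:
        b = p.d // bin_width
        if b not in env or p.energy37 < env[b]:
            env[b] = p.energy37
    return EnergyEnvelope(bin_width=bin_width, env=env)


@dataclass(frozen=True)
class BarrierEstimate:
    minA_bin: int
    minB_bin: int
    minA_energy: float
    minB_energy: float
    saddle: float
    barrier: float  # saddle - min(minA_energy, minB_energy); >= 0


def barrier_height(
    env: EnergyEnvelope, ls: Landscape, labels: Sequence[int]
) -> BarrierEstimate:
    """Barrier between the two cluster basins of a landscape.

    ``labels`` assigns each landscape point to cluster 1 or 2 (the order of
    ``ls.points``).  Each basin's minimum is its cluster's lowest-energy
    point; the saddle is the envelope maximum over bins strictly between the
    two basin-minimum bins (unoccupied interior bins interpolated); the
    barrier is the climb out of the deeper basin.  When the interior never
    rises above both minima (a monotone envelope: the shallower "basin" is a
    shoulder, not a separated state), or no interior bin exists, the two
    states are not barrier-separated and the barrier is 0.
    """
    labels = list(labels)
    if len(labels) != len(ls.points):
        raise LandscapeError("one label per landscape point required")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise SingleBasinError(
            f"two clusters required for a barrier (got {len(uniq)})"
        )

    def basin(which: int) -> tuple[int, float]:
        members = [p for p, lab in zip(ls.points, labels) if lab == which]
        pmin = min(members, key=lambda p: (p.energy37, p.d))
        return pmin.d // env.bin_width, pmin.energy37

    binA, eA = basin(uniq[0])
    binB, eB = basin(uniq[1])
    lo, hi = sorted((binA, binB))
    interior = range(lo + 1, hi)
    saddle = max((env.value(b) for b in interior), default=-np.inf)
    if saddle <= max(eA, eB):
        saddle = min(eA, eB)  # keeps barrier == saddle - min(eA, eB) == 0
        barrier = 0.0
    else:
        barrier = saddle - min(eA, eB)
    return BarrierEstimate(
        minA_bin=binA,
        minB_bin=binB,
        minA_energy=eA,
        minB_energy=eB,
        saddle=saddle,
        barrier=barrier,
    )


def write_landscape_tsv(path: str | Path, ls: Landscape) -> None:
    df = pd.DataFrame(
        {
            "dot_bracket": [
                write_dotbracket(p.structure) if p.structure is not None else ""
                for p in ls.points
            ],
            "d": [p.d for p in ls.points],
            "energy37": [p.energy37 for p in ls.points],
            "multiplicity": [p.multiplicity for p in ls.points],
            "pk_pairs": [p.pk_pair_count for p in ls.points],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_envelope_tsv(path: str | Path, env: EnergyEnvelope) -> None:
    occ = env.occupied
    bins = range(occ[0], occ[-1] + 1) if occ else range(0)
    df = pd.DataFrame(
        {
            "bin": list(bins),
            "min_energy": [env.value(b) for b in bins],
            "occupied": [b in env.env for b in bins],
        }
    )
    df.to_csv(path, sep="\t", index=False)
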