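"""Synthetic inputs with known ground truth for every pipeline stage.

* :func:`make_bistable_sequence` — a designed switch sequence carrying two
  mutually exclusive hairpins of equal stability (the central segment can
  pair either upstream or downstream), emulating the two-state landscapes of
  riboswitch expression platforms.
* :func:`make_planted_landscape` — a landscape built directly from a
  prescribed two-basin envelope (bypassing folding entirely) with known
  partition and barrier, for testing clustering, envelopes and barriers.
* :func:`make_planted_label_series` — per-length label series realizing a
  B/F/C pattern with the implied true windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landscape import Landscape, LandscapePoint, base_pair_distance
from .rna_core import BasePair, RnaSequence, SecondaryStructure
from .window_classifier import (
    BARRIER_LIMITED,
    CLUSTER,
    FUNNEL,
    LandscapeLabel,
    Window,
)

__all__ = [
    "BistableDesign",
    "PlantedLandscapeSpec",
    "PlantedTruth",
    "make_bistable_sequence",
    "make_planted_landscape",
    "make_planted_label_series",
]

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(s))


@dataclass(frozen=True)
class BistableDesign:
    stem_len: int
    loop_len: int
    sequence: RnaSequence
    hairpin5: SecondaryStructure  # central segment paired upstream
    hairpin3: SecondaryStructure  # central segment paired downstream

    def __post_init__(self) -> None:
        assert not (self.hairpin5.nested_pairs & self.hairpin3.nested_pairs)
        assert (
            base_pair_distance(self.hairpin5, self.hairpin3) == 2 * self.stem_len
        )


def make_bistable_sequence(
    stem_len: int,
    loop_len: int = 4,
    seed: int = 0,
    gc_fraction: float = 0.8,
) -> BistableDesign:
    """Design P . L1 . Q . L2 . P with Q the reverse complement of P.

    Q can pair with the upstream P (hairpin5, loop L1) or the downstream
    copy of P (hairpin3, loop L2), mutually exclusively.  Because the two
    helices are the same duplex read in opposite directions, their stack
    sums are identical under any orientation-symmetric stack table, and with
    equal loop lengths the two planted states are exactly degenerate.  Stems
    are GC-biased so the planted hairpins dominate the ensemble at
    desk-scale stem lengths; loops are A-runs.
    """
    if stem_len < 0:
        raise ValueError("stem_len must be >= 0")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    rng = np.random.default_rng(seed)
    gc = gc_fraction / 2.0
    au = (1.0 - gc_fraction) / 2.0
    p = "".join(rng.choice(list("GCAU"), p=[gc, gc, au, au], size=stem_len))
    q = _revcomp(p)
    loop = "A" * loop_len
    residues = p + loop + q + loop + p
    n = len(residues)
    s = stem_len
    l1 = l2 = loop_len
    hairpin5 = SecondaryStructure.from_pairs(
        n, [(i, 2 * s + l1 + 1 - i) for i in range(1, s + 1)]
    )
    hairpin3 = SecondaryStructure.from_pairs(
        n, [(s + l1 + t, n + 1 - t) for t in range(1, s + 1)]
    )
    if stem_len == 0:
        residues = loop + loop  # unstructured
        n = len(residues)
        hairpin5 = hairpin3 = SecondaryStructure(length=n)
    return BistableDesign(
        stem_len=stem_len,
        loop_len=loop_len,
        sequence=RnaSequence(id=f"bistable_s{stem_len}_l{loop_len}_seed{seed}", residues=residues),
        hairpin5=hairpin5,
        hairpin3=hairpin3,
    )


@dataclass(frozen=True)
class PlantedLandscapeSpec:
    """Two-basin landscape prescription.

    ``centers[0]`` must be 0 — the reference basin sits at distance 0 so the
    landscape's reference invariant (lowest-energy point at d = 0) holds.
    """

    n_points: int = 120
    centers: tuple[int, int] = (0, 20)
    spread: int = 3
    basin_energies: tuple[float, float] = (-12.0, -10.5)
    barrier: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.centers[0] != 0:
            raise ValueError("the reference basin center must be 0")
        if self.centers[1] < 2:
            raise ValueError("basin centers must be distinct (second center >= 2)")
        if self.barrier < 0:
            raise ValueError("barrier must be >= 0")
        if self.basin_energies[0] > self.basin_energies[1]:
            raise ValueError(
                "the reference basin (centers[0]) must be the deeper one"
            )
        if self.n_points < self.centers[1] + self.spread + 1:
            raise ValueError("n_points too small to occupy every envelope bin")


@dataclass(frozen=True)
class PlantedTruth:
    labels: tuple[int, ...]  # planted basin assignment per point
    barrier: float
    saddle_bin: int
    distances: tuple[int, ...]  # per-point distance (D matrix is |di - dj|)


def make_planted_landscape(
    spec: PlantedLandscapeSpec,
) -> tuple[Landscape, PlantedTruth]:
    """Landscape realizing the prescribed envelope, plus its ground truth.

    One point sits exactly on the envelope in every bin (so the envelope and
    barrier are realized exactly); the remaining points scatter around the
    two centers strictly above the envelope.  Points carry no structures:
    planted landscapes exist to exercise the stages downstream of folding,
    with dissimilarities |di - dj|.
    """
    c2 = spec.centers[1]
    dmax = c2 + spec.spread
    saddle_bin = c2 // 2
    e1, e2 = spec.basin_energies
    saddle = e1 + spec.barrier  # climb out of the deeper (reference) basin

    def envelope(d: int) -> float:
        if d <= saddle_bin:
            return e1 + (saddle - e1) * d / saddle_bin
        if d <= c2:
            return saddle + (e2 - saddle) * (d - saddle_bin) / (c2 - saddle_bin)
        return e2 + 0.5 * (d - c2)

    rng = np.random.default_rng(spec.seed)
    distances: list[int] = list(range(dmax + 1))  # envelope skeleton
    energies: list[float] = [envelope(d) for d in distances]
    n_extra = spec.n_points - len(distances)
    for _ in range(n_extra):
        center = int(rng.choice(spec.centers))
        d = int(np.clip(round(center + rng.normal(0, spec.spread)), 1, dmax))
        distances.append(d)
        energies.append(envelope(d) + rng.uniform(0.5, 4.0))

    points = tuple(
        LandscapePoint(structure=None, d=d, energy37=e)
        for d, e in zip(distances, energies)
    )
    ls = Landscape(
        length=0, reference=None, points=points, sample_size=len(points)
    )
    labels = tuple(
        1 if abs(d - spec.centers[0]) <= abs(d - spec.centers[1]) else 2
        for d in distances
    )
    return ls, PlantedTruth(
        labels=labels,
        barrier=spec.barrier,
        saddle_bin=saddle_bin,
        distances=tuple(distances),
    )


def planted_dissimilarity(truth: PlantedTruth) -> np.ndarray:
    """|di - dj| dissimilarity matrix for a planted landscape."""
    d = np.asarray(truth.distances, dtype=float)
    return np.abs(d[:, None] - d[None, :])


def make_planted_label_series(
    pattern: str,
    opposition_mask: str | None = None,
    start_len: int = 100,
    min_run: int = 5,
) -> tuple[list[LandscapeLabel], list[bool], list[Window]]:
    """Label series realizing a pattern over {B, F, C}, plus the true windows.

    ``opposition_mask`` marks lengths where functional opposition holds
    ('1'/'0' per position; default all-on for C positions).  True windows are
    computed directly from the pattern's runs.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    code = {"B": BARRIER_LIMITED, "F": FUNNEL, "C": CLUSTER}
    feature = {
        "B": dict(barrier=7.5, sc=0.6, alt_low_energy=True, funnel_vicinity=True),
        "F": dict(barrier=2.0, sc=0.6, alt_low_energy=True, funnel_vicinity=True),
        "C": dict(barrier=12.0, sc=0.6, alt_low_energy=False, funnel_vicinity=True),
    }
    labels = []
    for idx, ch in enumerate(pattern):
        if ch not in code:
            raise ValueError(f"pattern character {ch!r} not in B/F/C")
        labels.append(
            LandscapeLabel(length=start_len + idx, label=code[ch], **feature[ch])
        )
    if opposition_mask is None:
        opposition = [ch == "C" for ch in pattern]
    else:
        if len(opposition_mask) != len(pattern):
            raise ValueError("opposition mask length must match pattern")
        opposition = [c == "1" for c in opposition_mask]

    kind = {"B": "sensing", "F": "downhill", "C": "functional"}
    true_windows: list[Window] = []
    run_start = 0
    for idx in range(1, len(pattern) + 1):
        if idx < len(pattern) and pattern[idx] == pattern[run_start]:
            continue
        run_len = idx - run_start
        ch = pattern[run_start]
        ok = run_len >= min_run and (
            ch != "C" or all(opposition[run_start:idx])
        )
        if ok:
            true_windows.append(
                Window(
                    kind=kind[ch],
                    start_len=start_len + run_start,
                    end_len=start_len + idx - 1,
                )
            )
        run_start = idx
    return labels, opposition, true_windows


def write_design(design: BistableDesign, fasta_path: str | Path, truth_path: str | Path) -> None:
    """Write a bistable design as FASTA plus a ground-truth JSON."""
    seq = design.sequence
    Path(fasta_path).write_text(f">{seq.id}\n{seq.residues}\n")
    truth = {
        "stem_len": design.stem_len,
        "loop_len": design.loop_len,
        "hairpin5": design.hairpin5.to_dotbracket(),
        "hairpin3": design.hairpin3.to_dotbracket(),
        "distance": base_pair_distance(design.hairpin5, design.hairpin3),
    }
    Path(truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
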