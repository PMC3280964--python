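"""Per-length landscape classification and folding-window segmentation.

Each elongation length's landscape is labeled:

* ``funnel``          — one significant basin (SC < 0.4) or a barrier
                        below 5 kcal/mol, or a 5-10 kcal/mol barrier whose
                        other barrier-limited criteria fail;
* ``barrier_limited`` — two significant clusters, basin minima within
                        2.0 kcal/mol of each other, a 5-10 kcal/mol barrier
                        between them, and funnel-shaped vicinities around
                        both minima;
* ``cluster``         — two significant clusters with a barrier above
                        10 kcal/mol.

Runs of at least 5 consecutive lengths with one label become windows:
barrier-limited runs are *sensing* windows, funnel runs are *downhill
folding* windows, and cluster runs whose two sets hold functionally opposing
structures (declared as motif pair sets) are *functional* windows.  A sensing
window reaching full length implies thermodynamic control; sensing windows
only before full length imply kinetic control; no sensing window is
ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .clustering import ClusterResult, significant_cluster_count
from .landscape import BarrierEstimate, EnergyEnvelope, Landscape
from .rna_core import BasePair, SecondaryStructure, parse_dotbracket

__all__ = [
    "ClassifierThresholds",
    "LandscapeLabel",
    "MotifSpec",
    "Window",
    "ControlCall",
    "classify_landscape",
    "label_from_features",
    "funnel_vicinity",
    "contains_motif",
    "functional_opposition",
    "segment_windows",
    "infer_control",
    "motif_from_dotbracket",
]

logger = logging.getLogger(__name__)

BARRIER_LIMITED = "barrier_limited"
FUNNEL = "funnel"
CLUSTER = "cluster"
LABELS = (BARRIER_LIMITED, FUNNEL, CLUSTER)

_LABEL_TO_WINDOW = {BARRIER_LIMITED: "sensing", FUNNEL: "downhill", CLUSTER: "functional"}


@dataclass(frozen=True)
class ClassifierThresholds:
    """The window-definition thresholds (defaults are the standard values)."""

    barrier_low: float = 5.0  # kcal/mol; funnel below, barrier-limited at/above
    barrier_high: float = 10.0  # kcal/mol; cluster above
    alt_energy: float = 2.0  # kcal/mol between the two basin minima
    sc_min: float = 0.4  # significant-cluster silhouette threshold
    vicinity_span: int = 3  # occupied bins checked on each side of a minimum
    min_run: int = 5  # consecutive lengths required for a window


@dataclass(frozen=True)
class LandscapeLabel:
    length: int
    label: str  # barrier_limited | funnel | cluster
    barrier: float | None  # kcal/mol, None when a single basin
    sc: float | None
    alt_low_energy: bool = False
    funnel_vicinity: bool = False


def label_from_features(
    sc: float | None,
    barrier: float | None,
    alt_low_energy: bool,
    vicinity: bool,
    thresholds: ClassifierThresholds | None = None,
) -> str:
    """Total label function of (SC, barrier, criteria flags).

    SC below the significance threshold gates out two-state labels entirely;
    the 5-10 kcal/mol band is closed on both ends (funnel is strictly < 5,
    cluster strictly > 10).
    """
    t = thresholds or ClassifierThresholds()
    if sc is None or sc < t.sc_min or barrier is None:
        return FUNNEL
    if barrier < t.barrier_low:
        return FUNNEL
    if barrier > t.barrier_high:
        return CLUSTER
    return BARRIER_LIMITED if (alt_low_energy and vicinity) else FUNNEL


def funnel_vicinity(
    env: EnergyEnvelope, basin_bin: int, span: int = 3
) -> bool:
    """True iff the envelope is non-increasing toward the basin minimum over
    the ``span`` nearest occupied bins on each side (vacuously true when no
    neighbors exist)."""
    if basin_bin not in env.env:
        raise ValueError(f"basin bin {basin_bin} is not occupied")
    occ = env.occupied
    left = [b for b in occ if b < basin_bin][-span:]
    right = [b for b in occ if b > basin_bin][:span]
    seq_left = [env.env[b] for b in left] + [env.env[basin_bin]]
    for prev, nxt in zip(seq_left, seq_left[1:]):  # approaching from the left
        if nxt > prev:
            return False
    seq_right = [env.env[basin_bin]] + [env.env[b] for b in right]
    for near, far in zip(seq_right, seq_right[1:]):  # receding to the right
        if near > far:
            return False
    return True


def classify_landscape(
    ls: Landscape,
    cr: ClusterResult | None,
    be: BarrierEstimate | None,
    env: EnergyEnvelope,
    thresholds: ClassifierThresholds | None = None,
) -> LandscapeLabel:
    """Label one landscape from its clustering and barrier estimate.

    ``cr`` may be None for degenerate landscapes (< 2 unique structures);
    ``be`` may be None when only one significant basin exists.
    """
    t = thresholds or ClassifierThresholds()
    sc = cr.sc if cr is not None else None
    if (
        cr is None
        or significant_cluster_count(cr, t.sc_min) < 2
        or be is None
    ):
        return LandscapeLabel(
            length=ls.length, label=FUNNEL, barrier=None, sc=sc
        )
    alt = abs(be.minA_energy - be.minB_energy) <= t.alt_energy
    vic = funnel_vicinity(env, be.minA_bin, t.vicinity_span) and funnel_vicinity(
        env, be.minB_bin, t.vicinity_span
    )
    return LandscapeLabel(
        length=ls.length,
        label=label_from_features(sc, be.barrier, alt, vic, t),
        barrier=be.barrier,
        sc=sc,
        alt_low_energy=alt,
        funnel_vicinity=vic,
    )


@dataclass(frozen=True)
class MotifSpec:
    """A functional element (e.g. terminator helix) as a required pair set."""

    name: str
    required_pairs: frozenset[BasePair]
    min_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.required_pairs:
            raise ValueError(f"motif {self.name!r} declares no pairs")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError(
                f"motif {self.name!r}: min_fraction {self.min_fraction} outside (0, 1]"
            )

    @property
    def max_position(self) -> int:
        return max(p.j for p in self.required_pairs)


def motif_from_dotbracket(
    name: str, fragment: str, offset: int = 0, min_fraction: float = 0.8
) -> MotifSpec:
    """Declare a motif from a dot-bracket fragment shifted by ``offset`` nt."""
    s = parse_dotbracket(fragment)
    pairs = frozenset(BasePair(p.i + offset, p.j + offset) for p in s.all_pairs)
    return MotifSpec(name=name, required_pairs=pairs, min_fraction=min_fraction)


def contains_motif(s: SecondaryStructure, m: MotifSpec) -> float:
    """Fraction of the motif's required pairs present in the nested layer."""
    if m.max_position > s.length:
        raise ValueError(
            f"motif {m.name!r} extends to position {m.max_position}, beyond "
            f"structure length {s.length}"
        )
    return len(m.required_pairs & s.nested_pairs) / len(m.required_pairs)


def functional_opposition(
    medoid_a: SecondaryStructure,
    medoid_b: SecondaryStructure,
    motifs: Sequence[MotifSpec],
) -> bool:
    """True iff the two cluster medoids match *different* motifs, each at its
    required coverage, and neither matches the other's motif.

    Motifs longer than the structures (mid-elongation) simply do not match.
    With no motifs declared, returns False with a warning: functional windows
    then cannot be called.
    """
    if not motifs:
        logger.warning(
            "no functional motifs declared; functional windows cannot be called"
        )
        return False

    def matches(s: SecondaryStructure, m: MotifSpec) -> bool:
        if m.max_position > s.length:
            return False
        return contains_motif(s, m) >= m.min_fraction

    for ma in motifs:
        for mb in motifs:
            if ma is mb:
                continue
            if (
                matches(medoid_a, ma)
                and matches(medoid_b, mb)
                and not matches(medoid_a, mb)
                and not matches(medoid_b, ma)
            ):
                return True
    return False


@dataclass(frozen=True)
class Window:
    kind: str  # sensing | downhill | functional
    start_len: int
    end_len: int  # inclusive

    def __post_init__(self) -> None:
        if self.kind not in ("sensing", "downhill", "functional"):
            raise ValueError(f"unknown window kind {self.kind!r}")

    @property
    def n_lengths(self) -> int:
        return self.end_len - self.start_len + 1


def segment_windows(
    labels: Sequence[LandscapeLabel],
    opposition: Sequence[bool] | None = None,
    min_run: int = 5,
) -> list[Window]:
    """Maximal same-label runs of >= ``min_run`` consecutive lengths.

    Runs are strictly consecutive: one interrupting length breaks a run.
    Cluster runs become functional windows only when opposition holds at
    every length of the run.
    """
    labels = list(labels)
    if not labels:
        return []
    lengths = [lab.length for lab in labels]
    if lengths != list(range(lengths[0], lengths[0] + len(lengths))):
        raise ValueError("labels must cover a contiguous, ascending length range")
    if opposition is None:
        opposition = [False] * len(labels)
    if len(opposition) != len(labels):
        raise ValueError("one opposition flag per label required")

    windows: list[Window] = []
    run_start = 0
    for idx in range(1, len(labels) + 1):
        if idx < len(labels) and labels[idx].label == labels[run_start].label:
            continue
        run = labels[run_start:idx]
        if len(run) >= min_run:
            kind = _LABEL_TO_WINDOW[run[0].label]
            if kind != "functional" or all(opposition[run_start:idx]):
                windows.append(
                    Window(kind=kind, start_len=run[0].length, end_len=run[-1].length)
                )
        run_start = idx
    return windows


@dataclass(frozen=True)
class ControlCall:
    mechanism: str  # kinetic | thermodynamic | ambiguous
    rationale: str
    window_order: tuple[str, ...]


def infer_control(windows: Sequence[Window], full_length: int) -> ControlCall:
    """Kinetic vs thermodynamic control from the window order.

    A sensing window ending at full length implies thermodynamic control
    (the riboswitch can still exchange states, and bind ligand reversibly,
    when fully transcribed); sensing windows only earlier imply kinetic
    control; with no sensing window the call is ambiguous.
    """
    order = tuple(w.kind for w in sorted(windows, key=lambda w: w.start_len))
    sensing = [w for w in windows if w.kind == "sensing"]
    if any(w.end_len == full_length for w in sensing):
        return ControlCall(
            mechanism="thermodynamic",
            rationale=(
                "a sensing window reaches the full-length transcript, so state "
                "exchange with ligand remains possible at equilibrium"
            ),
            window_order=order,
        )
    if sensing:
        return ControlCall(
            mechanism="kinetic",
            rationale=(
                "all sensing windows close before full length, so the state "
                "choice is made during transcription"
            ),
            window_order=order,
        )
    return ControlCall(
        mechanism="ambiguous",
        rationale="no sensing window detected",
        window_order=order,
    )
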