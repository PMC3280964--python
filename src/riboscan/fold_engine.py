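"""Built-in thermodynamic folding engine.

A reduced nearest-neighbor model over nested secondary structures:

* stacked pairs contribute ``dG(T) = dH - T*dS`` from a 6x6 canonical stack
  table (AU/UA/CG/GC/GU/UG),
* hairpin, bulge and interior loops carry temperature-independent
  free-energy penalties tabulated by size with logarithmic extrapolation,
* multiloops carry a flat penalty, and
* pseudoknot-layer pairs contribute a flat per-pair bonus (default 0);
  pseudoknot prediction itself is delegated to external backends.

On this substrate the engine provides exact minimum-free-energy folding,
exhaustive suboptimal enumeration (small sequences), the partition
function, Boltzmann sampling by stochastic backtracking, energy evaluation
at arbitrary temperature, and the melting temperature as the maximum of
the ensemble specific heat.  Energies are kcal/mol; engine-level
temperatures are Kelvin except where a Celsius grid is stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .rna_core import (
    BasePair,
    RnaSequence,
    SecondaryStructure,
    StructureError,
    write_dotbracket,
)

__all__ = [
    "CANONICAL_PAIRS",
    "CELSIUS_OFFSET",
    "T37_K",
    "EnergyModel",
    "FoldResult",
    "EnsembleSummary",
    "FoldingEngine",
    "EngineError",
    "NonCanonicalPairError",
    "EngineGuardError",
    "NoMeltingTransition",
    "default_model",
]

CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
CELSIUS_OFFSET = 273.15
T37_K = 37.0 + CELSIUS_OFFSET

#: Exhaustive enumeration guard for the built-in engine.
ENUMERATION_MAX_LEN = 40
#: Co-optimal traceback cap for the lexicographic MFE tie-break.
_COOPT_CAP = 4096
_TOL = 1e-7


class EngineError(RuntimeError):
    """Folding-engine failure."""


class NonCanonicalPairError(EngineError):
    """A structure pairs bases outside AU/UA/CG/GC/GU/UG."""


class EngineGuardError(EngineError):
    """Sequence exceeds the built-in engine's exhaustive-enumeration guard."""


class NoMeltingTransition(EngineError):
    """The sequence cannot form any canonical pair: no melting transition."""


def _flip(pair: str) -> str:
    return pair[1] + pair[0]


@dataclass
class EnergyModel:
    """Reduced nearest-neighbor parameter set (see the shipped YAML file)."""

    stacks: dict[tuple[str, str], tuple[float, float]]  # (dH, dS) kcal/mol, kcal/mol/K
    hairpin_table: dict[int, float]
    bulge_table: dict[int, float]
    internal_table: dict[int, float]
    multiloop_penalty: float = 3.4
    pk_bonus_per_pair: float = 0.0
    loop_extrapolation_coeff: float = 1.75
    R: float = 0.0019872  # gas constant, kcal/mol/K
    min_hairpin: int = 3
    max_interior_loop: int = 30

    # -- parameter file I/O ------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnergyModel":
        with open(path) as fh:
            return cls._from_dict(yaml.safe_load(fh))

    @classmethod
    def _from_dict(cls, raw: dict) -> "EnergyModel":
        stacks: dict[tuple[str, str], tuple[float, float]] = {}
        for key, (dg37, dh) in raw["stacks"].items():
            outer, inner = key.split(",")
            if outer not in CANONICAL_PAIRS or inner not in CANONICAL_PAIRS:
                raise EngineError(f"non-canonical stack key {key!r}")
            ds = (dh - dg37) / 310.15
            for o, i in ((outer, inner), (_flip(inner), _flip(outer))):
                if (o, i) in stacks and not math.isclose(stacks[(o, i)][0], dh):
                    raise EngineError(f"conflicting duplicate stack entry for {o},{i}")
                stacks[(o, i)] = (dh, ds)
        model = cls(
            stacks=stacks,
            hairpin_table={int(k): float(v) for k, v in raw["hairpin_loop"].items()},
            bulge_table={int(k): float(v) for k, v in raw["bulge_loop"].items()},
            internal_table={int(k): float(v) for k, v in raw["internal_loop"].items()},
            multiloop_penalty=float(raw.get("multiloop_penalty", 3.4)),
            pk_bonus_per_pair=float(raw.get("pk_bonus_per_pair", 0.0)),
            loop_extrapolation_coeff=float(raw.get("loop_extrapolation_coeff", 1.75)),
            R=float(raw.get("gas_constant", 0.0019872)),
            min_hairpin=int(raw.get("min_hairpin", 3)),
            max_interior_loop=int(raw.get("max_interior_loop", 30)),
        )
        for table, name in (
            (model.hairpin_table, "hairpin"),
            (model.bulge_table, "bulge"),
            (model.internal_table, "internal"),
        ):
            if any(v < 0 for v in table.values()):
                raise EngineError(f"negative {name} loop penalty in parameter file")
        return model

    def to_yaml(self, path: str | Path) -> None:
        seen: set[tuple[str, str]] = set()
        stacks = {}
        for (o, i), (dh, ds) in sorted(self.stacks.items()):
            if (o, i) in seen:
                continue
            seen.add((o, i))
            seen.add((_flip(i), _flip(o)))
            dg37 = dh - 310.15 * ds
            stacks[f"{o},{i}"] = [round(dg37, 4), round(dh, 4)]
        payload = {
            "gas_constant": self.R,
            "min_hairpin": self.min_hairpin,
            "max_interior_loop": self.max_interior_loop,
            "multiloop_penalty": self.multiloop_penalty,
            "pk_bonus_per_pair": self.pk_bonus_per_pair,
            "loop_extrapolation_coeff": self.loop_extrapolation_coeff,
            "stacks": stacks,
            "hairpin_loop": self.hairpin_table,
            "bulge_loop": self.bulge_table,
            "internal_loop": self.internal_table,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    # -- energy terms ------------------------------------------------------
    def stack_dg(self, outer: str, inner: str, T: float) -> float:
        dh, ds = self.stacks[(outer, inner)]
        return dh - T * ds

    def _loop(self, table: dict[int, float], size: int) -> float:
        if size in table:
            return table[size]
        nmax = max(table)
        if size < nmax:  # holes below the table maximum are not expected
            raise EngineError(f"loop size {size} missing from parameter table")
        return table[nmax] + self.loop_extrapolation_coeff * self.R * 310.15 * math.log(
            size / nmax
        )

    def hairpin_penalty(self, size: int) -> float:
        if size < self.min_hairpin:
            raise EngineError(f"hairpin loop of {size} nt below minimum")
        return self._loop(self.hairpin_table, size)

    def bulge_penalty(self, size: int) -> float:
        return self._loop(self.bulge_table, size)

    def internal_penalty(self, size: int) -> float:
        return self._loop(self.internal_table, size)


def default_model() -> EnergyModel:
    """The parameter set shipped with the package."""
    ref = resources.files("riboscan").joinpath("params/default_energy.yaml")
    with resources.as_file(ref) as path:
        return EnergyModel.from_yaml(path)


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    energy: float  # kcal/mol at `temperature`
    temperature: float  # Kelvin


@dataclass(frozen=True)
class EnsembleSummary:
    Z: float  # partition function, relative to the 0-energy open chain
    G: float  # ensemble free energy -RT ln Z, kcal/mol
    temperature: float  # Kelvin


def _residues(seq: RnaSequence | str) -> str:
    return seq.residues if isinstance(seq, RnaSequence) else seq


def _loop_decomposition(
    length: int, nested: frozenset[BasePair]
) -> list[tuple[tuple[int, int] | None, list[tuple[int, int]]]]:
    """Closing pair (1-based, None for the exterior loop) -> direct children."""
    partner = [0] * (length + 2)
    for p in nested:
        partner[p.i] = p.j
        partner[p.j] = p.i

    def children(lo: int, hi: int) -> list[tuple[int, int]]:
        out = []
        k = lo
        while k < hi:
            if partner[k] > k:
                out.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return out

    loops: list[tuple[tuple[int, int] | None, list[tuple[int, int]]]] = []
    stack: list[tuple[int, int]] = [*children(1, length + 1)]
    loops.append((None, list(stack)))
    while stack:
        i, j = stack.pop()
        kids = children(i + 1, j)
        loops.append(((i, j), kids))
        stack.extend(kids)
    return loops


class _DP:
    """DP tables for one (sequence, temperature); shared by MFE/PF/sampling."""

    __slots__ = ("res", "n", "T", "model", "can", "V", "WM", "WM2", "W", "ZB", "ZM",
                 "ZM2", "Z", "hp")

    def __init__(self, res: str, model: EnergyModel, T: float):
        self.res = res
        self.n = len(res)
        self.T = T
        self.model = model
        n = self.n
        can = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + model.min_hairpin + 1, n):
                can[i, j] = res[i] + res[j] in CANONICAL_PAIRS
        self.can = can
        self.hp = [math.inf] * (n + 1)
        for size in range(model.min_hairpin, n + 1):
            self.hp[size] = model.hairpin_penalty(size)
        self.V = self.WM = self.WM2 = self.W = None
        self.ZB = self.ZM = self.ZM2 = self.Z = None

    # 0-based pair helpers -------------------------------------------------
    def _pair(self, i: int, j: int) -> str:
        return self.res[i] + self.res[j]

    def _two_loop(self, i: int, j: int, k: int, l: int) -> float:
        """Energy of the loop closed by (i,j) with single interior pair (k,l)."""
        if k == i + 1 and l == j - 1:
            return self.model.stack_dg(self._pair(i, j), self._pair(k, l), self.T)
        size = (k - i - 1) + (j - l - 1)
        if k == i + 1 or l == j - 1:
            return self.model.bulge_penalty(size)
        return self.model.internal_penalty(size)

    def _interior_candidates(self, i: int, j: int) -> Iterator[tuple[int, int]]:
        maxloop = self.model.max_interior_loop
        mh = self.model.min_hairpin
        for k in range(i + 1, j - mh):
            left = k - i - 1
            if left > maxloop:
                break
            lmin = max(k + mh + 1, j - 1 - (maxloop - left))
            for l in range(j - 1, lmin - 1, -1):
                if self.can[k, l]:
                    yield k, l

    # ---- minimum free energy --------------------------------------------
    def fill_mfe(self) -> None:
        if self.V is not None:
            return
        n, mh = self.n, self.model.min_hairpin
        INF = math.inf
        V = [[INF] * n for _ in range(n)]
        WM = [[INF] * n for _ in range(n)]
        WM2 = [[INF] * n for _ in range(n)]
        mult = self.model.multiloop_penalty
        for span in range(mh + 1, n):
            for i in range(0, n - span):
                j = i + span
                if self.can[i, j]:
                    best = self.hp[span - 1]
                    for k, l in self._interior_candidates(i, j):
                        v = V[k][l]
                        if v < INF:
                            best = min(best, self._two_loop(i, j, k, l) + v)
                    if WM2[i + 1][j - 1] < INF:
                        best = min(best, mult + WM2[i + 1][j - 1])
                    V[i][j] = best
                wm = WM[i][j - 1]
                wm2 = WM2[i][j - 1]
                for k in range(i, j - mh):
                    v = V[k][j]
                    if v < INF:
                        wm = min(wm, v)
                        pre = WM[i][k - 1] if k - 1 >= i else INF
                        if pre < INF:
                            wm = min(wm, pre + v)
                            wm2 = min(wm2, pre + v)
                WM[i][j] = wm
                WM2[i][j] = wm2
        W = [0.0] * (n + 1)
        for t in range(1, n + 1):
            best = W[t - 1]
            for s in range(0, t - mh - 1):
                v = V[s][t - 1]
                if v < INF:
                    best = min(best, W[s] + v)
            W[t] = best
        self.V, self.WM, self.WM2, self.W = V, WM, WM2, W

    # co-optimal traceback (for the lexicographic tie-break) ---------------
    def _trace_V(self, i: int, j: int) -> Iterator[frozenset]:
        target = self.V[i][j]
        base = frozenset({(i, j)})
        if abs(self.hp[j - i - 1] - target) < _TOL:
            yield base
        for k, l in self._interior_candidates(i, j):
            if self.V[k][l] < math.inf and abs(
                self._two_loop(i, j, k, l) + self.V[k][l] - target
            ) < _TOL:
                for sub in self._trace_V(k, l):
                    yield base | sub
        wm2 = self.WM2[i + 1][j - 1]
        if wm2 < math.inf and abs(self.model.multiloop_penalty + wm2 - target) < _TOL:
            for sub in self._trace_WM(i + 1, j - 1, two=True):
                yield base | sub

    def _trace_WM(self, i: int, j: int, two: bool) -> Iterator[frozenset]:
        table = self.WM2 if two else self.WM
        target = table[i][j]
        if j - 1 >= i and table[i][j - 1] < math.inf and abs(
            table[i][j - 1] - target
        ) < _TOL:
            yield from self._trace_WM(i, j - 1, two)
        mh = self.model.min_hairpin
        for k in range(i, j - mh):
            v = self.V[k][j]
            if v >= math.inf:
                continue
            if not two and abs(v - target) < _TOL:
                yield from self._trace_V(k, j)
            pre = self.WM[i][k - 1] if k - 1 >= i else math.inf
            if pre < math.inf and abs(pre + v - target) < _TOL:
                for p in self._trace_WM(i, k - 1, two=False):
                    for s in self._trace_V(k, j):
                        yield p | s

    def _trace_ext(self, t: int) -> Iterator[frozenset]:
        if t == 0:
            yield frozenset()
            return
        target = self.W[t]
        if abs(self.W[t - 1] - target) < _TOL:
            yield from self._trace_ext(t - 1)
        for s in range(0, t - self.model.min_hairpin - 1):
            v = self.V[s][t - 1]
            if v < math.inf and abs(self.W[s] + v - target) < _TOL:
                for p in self._trace_ext(s):
                    for q in self._trace_V(s, t - 1):
                        yield p | q

    def cooptimal_pairsets(self, cap: int = _COOPT_CAP) -> list[frozenset]:
        out: list[frozenset] = []
        seen: set[frozenset] = set()
        for ps in self._trace_ext(self.n):
            if ps not in seen:
                seen.add(ps)
                out.append(ps)
                if len(out) >= cap:
                    break
        return out

    # ---- partition function ----------------------------------------------
    def fill_pf(self) -> None:
        if self.Z is not None:
            return
        n, mh = self.n, self.model.min_hairpin
        RT = self.model.R * self.T
        bf = lambda e: math.exp(-e / RT)
        ZB = [[0.0] * n for _ in range(n)]
        ZM = [[0.0] * n for _ in range(n)]
        ZM2 = [[0.0] * n for _ in range(n)]
        mult_bf = bf(self.model.multiloop_penalty)
        for span in range(mh + 1, n):
            for i in range(0, n - span):
                j = i + span
                if self.can[i, j]:
                    z = bf(self.hp[span - 1])
                    for k, l in self._interior_candidates(i, j):
                        if ZB[k][l] > 0.0:
                            z += bf(self._two_loop(i, j, k, l)) * ZB[k][l]
                    z += mult_bf * ZM2[i + 1][j - 1]
                    ZB[i][j] = z
                zm = ZM[i][j - 1]
                zm2 = ZM2[i][j - 1]
                for k in range(i, j - mh):
                    zb = ZB[k][j]
                    if zb > 0.0:
                        pre = ZM[i][k - 1] if k - 1 >= i else 0.0
                        zm += zb * (1.0 + pre)
                        zm2 += zb * pre
                ZM[i][j] = zm
                ZM2[i][j] = zm2
        Z = [1.0] * (n + 1)
        for t in range(1, n + 1):
            z = Z[t - 1]
            for s in range(0, t - mh - 1):
                if ZB[s][t - 1] > 0.0:
                    z += Z[s] * ZB[s][t - 1]
            Z[t] = z
        self.ZB, self.ZM, self.ZM2, self.Z = ZB, ZM, ZM2, Z

    # ---- stochastic backtracking ------------------------------------------
    @staticmethod
    def _choose(weights: list[float], rng: np.random.Generator) -> int:
        total = sum(weights)
        r = rng.random() * total
        acc = 0.0
        for idx, w in enumerate(weights):
            acc += w
            if r < acc:
                return idx
        return len(weights) - 1  # guard against float roundoff at the top edge

    def sample_pairset(self, rng: np.random.Generator) -> frozenset:
        self.fill_pf()
        pairs: set[tuple[int, int]] = set()
        self._sample_ext(self.n, rng, pairs)
        return frozenset(pairs)

    def _sample_ext(self, t: int, rng, pairs: set) -> None:
        mh = self.model.min_hairpin
        while t > 0:
            weights = [self.Z[t - 1]]
            branches: list[int] = []
            for s in range(0, t - mh - 1):
                zb = self.ZB[s][t - 1]
                if zb > 0.0:
                    weights.append(self.Z[s] * zb)
                    branches.append(s)
            idx = self._choose(weights, rng)
            if idx == 0:
                t -= 1
            else:
                s = branches[idx - 1]
                self._sample_B(s, t - 1, rng, pairs)
                t = s

    def _sample_B(self, i: int, j: int, rng, pairs: set) -> None:
        RT = self.model.R * self.T
        bf = lambda e: math.exp(-e / RT)
        pairs.add((i, j))
        weights = [bf(self.hp[j - i - 1])]
        interiors: list[tuple[int, int]] = []
        for k, l in self._interior_candidates(i, j):
            zb = self.ZB[k][l]
            if zb > 0.0:
                weights.append(bf(self._two_loop(i, j, k, l)) * zb)
                interiors.append((k, l))
        zm2 = self.ZM2[i + 1][j - 1]
        if zm2 > 0.0:
            weights.append(bf(self.model.multiloop_penalty) * zm2)
        idx = self._choose(weights, rng)
        if idx == 0:
            return
        if idx <= len(interiors):
            self._sample_B(*interiors[idx - 1], rng, pairs)
        else:
            self._sample_M(i + 1, j - 1, rng, pairs, two=True)

    def _sample_M(self, i: int, j: int, rng, pairs: set, two: bool) -> None:
        """Sample a multiloop-interior region holding >=1 (ZM) or >=2 (ZM2) branches."""
        mh = self.model.min_hairpin
        while True:
            table = self.ZM2 if two else self.ZM
            weights = [table[i][j - 1] if j - 1 >= i else 0.0]  # j unpaired
            options: list[tuple[int, bool]] = []  # (k, prefix_has_branches)
            for k in range(i, j - mh):
                zb = self.ZB[k][j]
                if zb <= 0.0:
                    continue
                pre = self.ZM[i][k - 1] if k - 1 >= i else 0.0
                if not two:
                    weights.append(zb)
                    options.append((k, False))
                if pre > 0.0:
                    weights.append(zb * pre)
                    options.append((k, True))
            idx = self._choose(weights, rng)
            if idx == 0:
                j -= 1
                continue
            k, has_prefix = options[idx - 1]
            self._sample_B(k, j, rng, pairs)
            if not has_prefix:
                return
            j, two = k - 1, False


class FoldingEngine:
    """Folding operations over one EnergyModel, with per-(sequence, T) caching."""

    def __init__(self, model: EnergyModel | None = None):
        self.model = model if model is not None else default_model()
        self._cache: dict[tuple[str, float], _DP] = {}

    def _dp(self, seq: RnaSequence | str, T: float) -> _DP:
        res = _residues(seq)
        key = (res, round(T, 6))
        dp = self._cache.get(key)
        if dp is None:
            dp = _DP(res, self.model, T)
            self._cache[key] = dp
        return dp

    def clear_cache(self) -> None:
        self._cache.clear()

    # ---- operations -------------------------------------------------------
    def eval_energy(
        self, seq: RnaSequence | str, s: SecondaryStructure, T: float = T37_K
    ) -> float:
        """Free energy (kcal/mol) of a structure on a sequence at T (Kelvin)."""
        res = _residues(seq)
        if len(res) != s.length:
            raise StructureError(
                f"structure length {s.length} != sequence length {len(res)}"
            )
        for p in sorted(s.all_pairs):
            bases = res[p.i - 1] + res[p.j - 1]
            if bases not in CANONICAL_PAIRS:
                raise NonCanonicalPairError(
                    f"pair ({p.i},{p.j}) = {bases} is not canonical"
                )
        m = self.model
        energy = 0.0
        pairset = {(p.i, p.j) for p in s.nested_pairs}
        for closing, kids in _loop_decomposition(s.length, s.nested_pairs):
            if closing is None:
                continue
            i, j = closing
            if not kids:
                energy += m.hairpin_penalty(j - i - 1)
            elif len(kids) == 1:
                k, l = kids[0]
                if k == i + 1 and l == j - 1:
                    energy += m.stack_dg(
                        res[i - 1] + res[j - 1], res[k - 1] + res[l - 1], T
                    )
                else:
                    size = (k - i - 1) + (j - l - 1)
                    if k == i + 1 or l == j - 1:
                        energy += m.bulge_penalty(size)
                    else:
                        energy += m.internal_penalty(size)
            else:
                energy += m.multiloop_penalty
        energy += m.pk_bonus_per_pair * s.pk_pair_count
        return energy

    def mfe_fold(self, seq: RnaSequence | str, T: float = T37_K) -> FoldResult:
        """Minimum-free-energy nested structure; co-optimal ties resolved to
        the lexicographically smallest dot-bracket string."""
        res = _residues(seq)
        dp = self._dp(res, T)
        dp.fill_mfe()
        pairsets = dp.cooptimal_pairsets()
        best_struct = None
        best_db = None
        for ps in pairsets:
            s = SecondaryStructure.from_pairs(
                len(res), [(i + 1, j + 1) for i, j in ps]
            )
            db = write_dotbracket(s)
            if best_db is None or db < best_db:
                best_db, best_struct = db, s
        assert best_struct is not None
        return FoldResult(structure=best_struct, energy=dp.W[dp.n], temperature=T)

    def enumerate_structures(
        self, seq: RnaSequence | str, delta_e_max: float, T: float = T37_K
    ) -> list[FoldResult]:
        """All nested structures within ``delta_e_max`` of the MFE, complete,
        sorted by (energy, dot-bracket).  Guarded to short sequences."""
        res = _residues(seq)
        n = len(res)
        if n > ENUMERATION_MAX_LEN:
            raise EngineGuardError(
                f"exhaustive enumeration limited to {ENUMERATION_MAX_LEN} nt "
                f"(got {n}); use an external backend for longer sequences"
            )
        mh = self.model.min_hairpin
        can = self._dp(res, T).can

        def gen(i: int, j: int) -> Iterator[frozenset]:
            # all pair sets over the half-open region [i, j)
            if j - i < mh + 2:
                yield frozenset()
                return
            yield from gen(i + 1, j)
            for k in range(i + mh + 1, j):
                if can[i, k]:
                    for inner in gen(i + 1, k):
                        base = frozenset({(i, k)}) | inner
                        for outer in gen(k + 1, j):
                            yield base | outer

        results = []
        for ps in gen(0, n):
            s = SecondaryStructure.from_pairs(n, [(i + 1, j + 1) for i, j in ps])
            results.append(
                FoldResult(structure=s, energy=self.eval_energy(res, s, T), temperature=T)
            )
        e_min = min(r.energy for r in results)
        kept = [r for r in results if r.energy <= e_min + delta_e_max + _TOL]
        kept.sort(key=lambda r: (r.energy, write_dotbracket(r.structure)))
        return kept

    def partition_function(
        self, seq: RnaSequence | str, T: float = T37_K
    ) -> EnsembleSummary:
        """McCaskill-style partition function relative to the open chain."""
        dp = self._dp(seq, T)
        dp.fill_pf()
        Z = dp.Z[dp.n]
        RT = self.model.R * T
        return EnsembleSummary(Z=Z, G=-RT * math.log(Z), temperature=T)

    def sample_boltzmann(
        self,
        seq: RnaSequence | str,
        T: float = T37_K,
        n: int = 100,
        seed: int | np.random.Generator = 0,
    ) -> list[SecondaryStructure]:
        """n i.i.d. Boltzmann draws by stochastic backtracking (seeded)."""
        if n <= 0:
            raise EngineError(f"sample size must be positive (got {n})")
        res = _residues(seq)
        dp = self._dp(res, T)
        dp.fill_pf()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = []
        for _ in range(n):
            ps = dp.sample_pairset(rng)
            out.append(
                SecondaryStructure.from_pairs(len(res), [(i + 1, j + 1) for i, j in ps])
            )
        return out

    def melting_temperature(
        self,
        seq: RnaSequence | str,
        t_min_c: float = 0.0,
        t_max_c: float = 150.0,
        step_c: float = 1.0,
    ) -> float:
        """Melting temperature (Celsius): the grid temperature maximizing the
        specific heat C(T) = -T d2G/dT2 (central finite differences of the
        ensemble free energy)."""
        res = _residues(seq)
        dp = self._dp(res, T37_K)
        if not dp.can.any():
            raise NoMeltingTransition(
                f"sequence {res!r} cannot form a canonical pair"
            )
        ts = np.arange(t_min_c, t_max_c + step_c / 2, step_c)
        G = np.array([self.partition_function(res, t + CELSIUS_OFFSET).G for t in ts])
        d2 = (G[2:] - 2 * G[1:-1] + G[:-2]) / step_c**2
        C = -(ts[1:-1] + CELSIUS_OFFSET) * d2
        idx = int(np.argmax(C))
        return float(round(ts[1:-1][idx]))
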