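"""Folding backends: the built-in engine and an external-tool adapter.

Both expose the same Celsius-level surface the sampling protocol consumes:

* ``mfe_fold(seq, t_c)``
* ``sample_boltzmann(seq, t_c, n, seed)``
* ``eval_energy(seq, structure, t_c)``
* ``melting_temperature(seq)`` (Celsius)

The external adapter shells out to RNAfold / RNAsubopt / RNAeval / RNAheat
compatible executables (plain-text dot-bracket I/O, temperature passed per
call) and, for pseudoknotted prediction, to a pknotsRG-compatible program in
complete-suboptimal mode within 10 kcal/mol (``pknotsRG -m -s -e 10``).
Whatever bracket dialect a tool emits is normalized through
:func:`riboscan.rna_core.parse_dotbracket`.  A missing executable raises a
clear error; there is never a silent fallback to the built-in engine.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .fold_engine import (
    CELSIUS_OFFSET,
    EnergyModel,
    FoldResult,
    FoldingEngine,
    NoMeltingTransition,
)
from .rna_core import RnaSequence, SecondaryStructure, parse_dotbracket

__all__ = [
    "FoldingBackend",
    "BackendError",
    "BuiltinBackend",
    "ExternalBackend",
    "get_backend",
]


class BackendError(RuntimeError):
    """An external folding program is missing or misbehaved."""


@runtime_checkable
class FoldingBackend(Protocol):
    def mfe_fold(self, seq: RnaSequence, t_c: float = 37.0) -> FoldResult: ...

    def sample_boltzmann(
        self, seq: RnaSequence, t_c: float, n: int, seed: int
    ) -> list[SecondaryStructure]: ...

    def eval_energy(
        self, seq: RnaSequence, s: SecondaryStructure, t_c: float = 37.0
    ) -> float: ...

    def melting_temperature(self, seq: RnaSequence) -> float: ...


class BuiltinBackend:
    """The reduced nearest-neighbor engine behind the backend surface."""

    name = "builtin"

    def __init__(self, model: EnergyModel | None = None):
        self.engine = FoldingEngine(model)

    def mfe_fold(self, seq: RnaSequence, t_c: float = 37.0) -> FoldResult:
        return self.engine.mfe_fold(seq, t_c + CELSIUS_OFFSET)

    def sample_boltzmann(
        self, seq: RnaSequence, t_c: float, n: int, seed: int
    ) -> list[SecondaryStructure]:
        return self.engine.sample_boltzmann(seq, t_c + CELSIUS_OFFSET, n, seed)

    def eval_energy(
        self, seq: RnaSequence, s: SecondaryStructure, t_c: float = 37.0
    ) -> float:
        return self.engine.eval_energy(seq, s, t_c + CELSIUS_OFFSET)

    def melting_temperature(self, seq: RnaSequence) -> float:
        return self.engine.melting_temperature(seq)


# --------------------------------------------------------------------------
# External adapter


@dataclass
class ExternalBackend:
    """Subprocess adapter for ViennaRNA-style executables.

    Command names are configurable so drop-in replacements can be used.
    ``RNAsubopt -p n`` performs its own stochastic backtracking and exposes
    no random seed, so external sampling is not reproducible run-to-run;
    the ``seed`` argument is accepted for interface compatibility.
    """

    rnafold: str = "RNAfold"
    rnasubopt: str = "RNAsubopt"
    rnaeval: str = "RNAeval"
    rnaheat: str = "RNAheat"
    pknotsrg: str = "pknotsRG"
    name: str = "external"

    def _require(self, exe: str) -> str:
        path = shutil.which(exe)
        if path is None:
            raise BackendError(
                f"external folding program {exe!r} not found on PATH; install it "
                "or select the builtin backend explicitly"
            )
        return path

    def _run(self, argv: list[str], stdin: str) -> str:
        exe = self._require(argv[0])
        proc = subprocess.run(
            [exe, *argv[1:]],
            input=stdin,
            text=True,
            capture_output=True,
        )
        if proc.returncode != 0:
            raise BackendError(
                f"{argv[0]} exited with status {proc.returncode}: "
                f"{proc.stderr.strip()[:500]}"
            )
        return proc.stdout

    @staticmethod
    def _parse_struct_energy(line: str, length: int) -> tuple[SecondaryStructure, float]:
        m = re.match(r"([.()\[\]{}<>]+)\s+\(\s*(-?\d+\.?\d*)\s*\)", line.strip())
        if not m:
            raise BackendError(f"cannot parse structure line: {line!r}")
        db = m.group(1)
        if len(db) != length:
            raise BackendError(
                f"structure length {len(db)} != sequence length {length}"
            )
        return parse_dotbracket(db), float(m.group(2))

    def mfe_fold(self, seq: RnaSequence, t_c: float = 37.0) -> FoldResult:
        out = self._run(
            [self.rnafold, "--noPS", "-T", f"{t_c:g}"], seq.residues + "\n"
        )
        lines = [ln for ln in out.splitlines() if ln.strip()]
        struct, energy = self._parse_struct_energy(lines[-1], seq.length)
        return FoldResult(structure=struct, energy=energy, temperature=t_c + CELSIUS_OFFSET)

    def sample_boltzmann(
        self, seq: RnaSequence, t_c: float, n: int, seed: int = 0
    ) -> list[SecondaryStructure]:
        if n <= 0:
            raise BackendError(f"sample size must be positive (got {n})")
        out = self._run(
            [self.rnasubopt, "-p", str(n), "-T", f"{t_c:g}"], seq.residues + "\n"
        )
        structs = []
        for line in out.splitlines():
            line = line.strip()
            if line and set(line) <= set(".()[]{}<>"):
                structs.append(parse_dotbracket(line))
        if len(structs) != n:
            raise BackendError(
                f"{self.rnasubopt} returned {len(structs)} structures, expected {n}"
            )
        return structs

    def eval_energy(
        self, seq: RnaSequence, s: SecondaryStructure, t_c: float = 37.0
    ) -> float:
        from .rna_core import strip_pseudoknots, write_dotbracket

        nested, _ = strip_pseudoknots(s)  # RNAeval understands one bracket layer
        out = self._run(
            [self.rnaeval, "-T", f"{t_c:g}"],
            seq.residues + "\n" + write_dotbracket(nested) + "\n",
        )
        lines = [ln for ln in out.splitlines() if ln.strip()]
        _, energy = self._parse_struct_energy(lines[-1], seq.length)
        return energy

    def melting_temperature(self, seq: RnaSequence) -> float:
        out = self._run(
            [self.rnaheat, "--Tmin", "0", "--Tmax", "150"], seq.residues + "\n"
        )
        best_t, best_c = None, -np.inf
        for line in out.splitlines():
            parts = line.split()
            if len(parts) >= 2:
                try:
                    t, c = float(parts[0]), float(parts[1])
                except ValueError:
                    continue
                if c > best_c:
                    best_t, best_c = t, c
        if best_t is None:
            raise NoMeltingTransition(f"{self.rnaheat} produced no heat curve")
        return float(round(best_t))

    def pknots_suboptimals(
        self, seq: RnaSequence, delta_e: float = 10.0
    ) -> list[FoldResult]:
        """Complete pseudoknot suboptimals within ``delta_e`` of the MFE
        (``pknotsRG -m -s -e <delta_e>``); output brackets are normalized to
        this package's layer convention."""
        out = self._run(
            [self.pknotsrg, "-m", "-s", "-e", f"{delta_e:g}"], seq.residues + "\n"
        )
        results = []
        for line in out.splitlines():
            m = re.match(r"([.()\[\]{}<>]+)\s+\(?\s*(-?\d+\.?\d*)", line.strip())
            if m and len(m.group(1)) == seq.length:
                results.append(
                    FoldResult(
                        structure=parse_dotbracket(m.group(1)),
                        energy=float(m.group(2)),
                        temperature=37.0 + CELSIUS_OFFSET,
                    )
                )
        if not results:
            raise BackendError(f"{self.pknotsrg} produced no parseable structures")
        return results


def get_backend(name: str, model: EnergyModel | None = None) -> FoldingBackend:
    if name == "builtin":
        return BuiltinBackend(model)
    if name == "external":
        return ExternalBackend()
    raise ValueError(f"unknown backend {name!r} (expected 'builtin' or 'external')")
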