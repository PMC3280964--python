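"""RNA sequences and secondary structures.

A secondary structure is a set of base pairs over a sequence, split into a
*nested* layer (mutually non-crossing pairs, the ordinary dot-bracket layer)
and zero or more *pseudoknot* layers, each internally non-crossing but
crossing the layers below it.  Structures serialize to multi-bracket
dot-bracket text: ``()`` for the nested layer, then ``[]``, ``{}``, ``<>``
for successive pseudoknot layers.

Positions are 1-based and inclusive throughout, matching dot-bracket
convention.  The minimum hairpin loop is 3 unpaired nucleotides, so every
pair satisfies ``j - i >= 4``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "RNA_ALPHABET",
    "BRACKET_ALPHABETS",
    "StructureError",
    "DotBracketParseError",
    "RnaSequence",
    "BasePair",
    "SecondaryStructure",
    "parse_dotbracket",
    "write_dotbracket",
    "strip_pseudoknots",
    "read_fasta",
]

RNA_ALPHABET = frozenset("ACGU")

#: Bracket pairs, in layer order: nested layer first, then pseudoknot layers.
BRACKET_ALPHABETS: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
)

MIN_HAIRPIN_LOOP = 3


class StructureError(ValueError):
    """Invalid sequence or structure."""


class DotBracketParseError(StructureError):
    """Malformed dot-bracket text."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with an identifier.

    ``residues`` must be uppercase over {A, C, G, U}; use :meth:`from_string`
    to normalize raw text (case folding, T -> U).
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise StructureError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise StructureError(
                f"sequence {self.id!r} contains non-RNA characters: {sorted(bad)}"
            )

    @classmethod
    def from_string(cls, id: str, text: str) -> "RnaSequence":
        return cls(id=id, residues=text.upper().replace("T", "U"))

    @property
    def length(self) -> int:
        return len(self.residues)

    def prefix(self, length: int) -> "RnaSequence":
        """5'-anchored truncation to the first ``length`` nucleotides."""
        if not 1 <= length <= self.length:
            raise StructureError(f"prefix length {length} outside 1..{self.length}")
        return RnaSequence(id=f"{self.id}:1-{length}", residues=self.residues[:length])

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length


@dataclass(frozen=True, order=True)
class BasePair:
    """A base pair (i, j), 1-based, i < j, with the minimum hairpin loop."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i < 1:
            raise StructureError(f"pair ({self.i},{self.j}): i must be >= 1")
        if self.j - self.i < MIN_HAIRPIN_LOOP + 1:
            raise StructureError(
                f"pair ({self.i},{self.j}) closes a loop shorter than "
                f"{MIN_HAIRPIN_LOOP} nt"
            )


def _crossing(p: BasePair, q: BasePair) -> bool:
    a, b = (p, q) if p.i < q.i else (q, p)
    return a.i < b.i < a.j < b.j


def _check_layer_noncrossing(pairs: Iterable[BasePair], layer_name: str) -> None:
    ordered = sorted(pairs)
    for idx, p in enumerate(ordered):
        for q in ordered[idx + 1 :]:
            if q.i >= p.j:
                break
            if _crossing(p, q):
                raise StructureError(
                    f"{layer_name} contains crossing pairs "
                    f"({p.i},{p.j}) and ({q.i},{q.j})"
                )


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairs split into a nested layer and pseudoknot layers.

    No position may participate in more than one pair (across all layers),
    and each layer is internally non-crossing.
    """

    length: int
    nested_pairs: frozenset[BasePair] = frozenset()
    pk_layers: tuple[frozenset[BasePair], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise StructureError("structure length must be >= 1")
        seen: set[int] = set()
        for layer_idx, layer in enumerate((self.nested_pairs, *self.pk_layers)):
            for p in layer:
                if p.j > self.length:
                    raise StructureError(
                        f"pair ({p.i},{p.j}) outside structure of length {self.length}"
                    )
                for pos in (p.i, p.j):
                    if pos in seen:
                        raise StructureError(f"position {pos} paired more than once")
                    seen.add(pos)
            name = "nested layer" if layer_idx == 0 else f"pseudoknot layer {layer_idx}"
            _check_layer_noncrossing(layer, name)

    @classmethod
    def from_pairs(
        cls, length: int, pairs: Iterable[BasePair] | Iterable[tuple[int, int]]
    ) -> "SecondaryStructure":
        """Build a structure from an unlayered pair collection.

        Pairs are assigned greedily (in (i, j) order) to the lowest layer in
        which they cross nothing, so a pair set that is globally non-crossing
        lands entirely in the nested layer.  This is also the normalization
        applied to parsed multi-bracket text and to external-tool output.
        """
        bps = sorted(p if isinstance(p, BasePair) else BasePair(*p) for p in pairs)
        layers: list[list[BasePair]] = []
        for p in bps:
            for layer in layers:
                if not any(_crossing(p, q) for q in layer):
                    layer.append(p)
                    break
            else:
                layers.append([p])
        nested = frozenset(layers[0]) if layers else frozenset()
        pk = tuple(frozenset(layer) for layer in layers[1:])
        return cls(length=length, nested_pairs=nested, pk_layers=pk)

    @property
    def all_pairs(self) -> frozenset[BasePair]:
        out = set(self.nested_pairs)
        for layer in self.pk_layers:
            out |= layer
        return frozenset(out)

    @property
    def pk_pair_count(self) -> int:
        return sum(len(layer) for layer in self.pk_layers)

    @property
    def n_pairs(self) -> int:
        return len(self.nested_pairs) + self.pk_pair_count

    def partner_array(self) -> list[int]:
        """0 for unpaired, else the 1-based partner; nested layer only."""
        partner = [0] * (self.length + 1)
        for p in self.nested_pairs:
            partner[p.i] = p.j
            partner[p.j] = p.i
        return partner

    def to_dotbracket(self) -> str:
        return write_dotbracket(self)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.to_dotbracket()


_OPEN = {o: idx for idx, (o, _) in enumerate(BRACKET_ALPHABETS)}
_CLOSE = {c: idx for idx, (_, c) in enumerate(BRACKET_ALPHABETS)}


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse (multi-bracket) dot-bracket text into a SecondaryStructure.

    ``()`` maps to the nested layer, ``[]``/``{}``/``<>`` to successive
    pseudoknot layers; layer assignment is then normalized so that the
    nested layer is the first greedily non-crossing layer (a structure whose
    only brackets are e.g. ``[]`` is nested by convention).
    """
    stacks: list[list[int]] = [[] for _ in BRACKET_ALPHABETS]
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise DotBracketParseError(
                    f"unbalanced {ch!r} at position {pos}: no matching opener"
                )
            pairs.append((stack.pop(), pos))
        else:
            raise DotBracketParseError(f"illegal character {ch!r} at position {pos}")
    for idx, stack in enumerate(stacks):
        if stack:
            raise DotBracketParseError(
                f"unbalanced {BRACKET_ALPHABETS[idx][0]!r} opened at position {stack[-1]}"
            )
    try:
        return SecondaryStructure.from_pairs(len(text), pairs)
    except StructureError as exc:
        raise DotBracketParseError(str(exc)) from exc


def write_dotbracket(s: SecondaryStructure) -> str:
    """Serialize to multi-bracket dot-bracket; round-trips through parsing."""
    if len(s.pk_layers) > len(BRACKET_ALPHABETS) - 1:
        raise StructureError(
            f"{len(s.pk_layers)} pseudoknot layers exceed the "
            f"{len(BRACKET_ALPHABETS) - 1} available bracket alphabets"
        )
    chars = ["."] * s.length
    for layer_idx, layer in enumerate((s.nested_pairs, *s.pk_layers)):
        op, cl = BRACKET_ALPHABETS[layer_idx]
        for p in layer:
            chars[p.i - 1] = op
            chars[p.j - 1] = cl
    return "".join(chars)


def strip_pseudoknots(s: SecondaryStructure) -> tuple[SecondaryStructure, int]:
    """Remove all pseudoknot layers; return (nested-only structure, count removed).

    The original structure is untouched; callers keep it so pseudoknots can be
    restored after nested-layer comparisons.
    """
    count = s.pk_pair_count
    if count == 0 and not s.pk_layers:
        return s, 0
    return (
        SecondaryStructure(length=s.length, nested_pairs=s.nested_pairs, pk_layers=()),
        count,
    )


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read FASTA records as RnaSequences (uppercased, T -> U)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureError(f"no FASTA records in {path}")
    return [RnaSequence.from_string(rec.id, str(rec.seq)) for rec in records]
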