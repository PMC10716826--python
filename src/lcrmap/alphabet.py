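"""Finite alphabets for sequence modelling.

An :class:`Alphabet` is the symbol set Θ over which context models operate.
DNA carries the Watson–Crick complement bijection (A↔T, C↔G) used by the
inverted-repeat model and the simulator's inversion transform; protein has no
complement, so inversion degrades to plain reversal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional


@dataclass(frozen=True)
class Alphabet:
    """Ordered finite symbol set, optionally with a complement bijection."""

    symbols: tuple[str, ...]
    complement: Optional[Mapping[str, str]] = None
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        if len(self.symbols) < 1:
            raise ValueError("alphabet must be nonempty")
        if self.complement is not None:
            comp = dict(self.complement)
            for s, c in comp.items():
                if comp.get(c) != s:
                    raise ValueError(f"complement is not an involution at {s!r}")
            object.__setattr__(self, "complement", MappingProxyType(comp))
        object.__setattr__(
            self, "_index", MappingProxyType({s: i for i, s in enumerate(self.symbols)})
        )

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._index

    def index(self, symbol: str) -> int:
        return self._index[symbol]

    def reverse_complement(self, seq: str) -> str:
        """Reverse complement for complemented alphabets, plain reversal otherwise."""
        if self.complement is None:
            return seq[::-1]
        comp = self.complement
        return "".join(comp[s] for s in reversed(seq))


DNA = Alphabet(("A", "C", "G", "T"), {"A": "T", "T": "A", "C": "G", "G": "C"})
PROTEIN = Alphabet(tuple("ACDEFGHIKLMNPQRSTVWY"))

#: IUPAC codes tolerated in DNA input; anything outside the core four symbols
#: is treated as ambiguous by the models (uniform prediction, context break).
_DNA_CHARS = set("ACGTUNRYSWKMBDHV")


def detect_alphabet(sequence: str) -> Alphabet:
    """Guess DNA vs protein from symbol content (case-insensitive).

    A sequence is called DNA when at least 90% of its symbols are drawn from
    the IUPAC nucleotide codes; empty sequences default to DNA.
    """
    seq = sequence.upper()
    if not seq:
        return DNA
    hits = sum(1 for s in seq if s in _DNA_CHARS)
    return DNA if hits / len(seq) >= 0.9 else PROTEIN
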