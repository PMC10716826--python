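"""Benchmark sequence simulation from concatenated blocks.

A simulated FASTA record is the concatenation of blocks, each realized from
one of three sources — extraction of coordinates from an existing FASTA
file, pseudo-random generation from a linear congruential generator (LCG),
or generation from a finite-context model trained on a FASTA file — and then
optionally transformed by inversion (reverse complement for DNA, reversal
otherwise) and by per-symbol substitution / deletion / insertion mutations.
Everything is driven by explicit seeds, so identical block lists yield
byte-identical output, and the ground-truth interval of every block in the
final coordinates is returned for benchmarking the mapper.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

from .alphabet import Alphabet, DNA
from .models import CountTable, estimate_probability
from .seqio import SequenceRecord, extract_subsequence, read_fasta

# 64-bit LCG constants (the multiplier/increment pair popularized by PCG);
# fixed and documented so simulated bytes are reproducible across runs.
LCG_A = 6364136223846793005
LCG_C = 1442695040888963407
LCG_MASK = (1 << 64) - 1


def lcg_next(state: int) -> int:
    """One raw LCG transition on 64-bit state."""
    return (LCG_A * state + LCG_C) & LCG_MASK


def lcg_uniform(state: int) -> Tuple[float, int]:
    """Advance the LCG; return a uniform draw in [0, 1) and the new state."""
    state = lcg_next(state)
    return (state >> 11) / float(1 << 53), state


class Lcg:
    """Stateful wrapper around the raw LCG stream."""

    def __init__(self, seed: int):
        # one warm-up step decorrelates small consecutive seeds
        self.state = lcg_next(seed & LCG_MASK)

    def uniform(self) -> float:
        value, self.state = lcg_uniform(self.state)
        return value

    def randint(self, n: int) -> int:
        """Uniform integer in [0, n)."""
        return min(int(self.uniform() * n), n - 1)

    def choice(self, items: Sequence[str]) -> str:
        return items[self.randint(len(items))]


def generate_random(
    n: int,
    seed: int,
    alphabet: Alphabet = DNA,
    weights: Optional[Sequence[float]] = None,
) -> str:
    """Length-n pseudo-random string, uniform or with per-symbol weights."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = Lcg(seed)
    if weights is None:
        return "".join(rng.choice(alphabet.symbols) for _ in range(n))
    if len(weights) != alphabet.size:
        raise ValueError("weights length must match alphabet size")
    total = float(sum(weights))
    cumulative = []
    acc = 0.0
    for w in weights:
        acc += w / total
        cumulative.append(acc)
    out = []
    for _ in range(n):
        u = rng.uniform()
        for idx, edge in enumerate(cumulative):
            if u < edge:
                out.append(alphabet.symbols[idx])
                break
        else:
            out.append(alphabet.symbols[-1])
    return "".join(out)


@dataclass
class TrainedGenerator:
    """Frozen order-k count table learned from training sequences."""

    table: CountTable
    contexts: dict  # context -> number of times observed (for burn-in sampling)
    order: int
    bet: float
    alphabet: Alphabet


def train_model_generator(
    training: Sequence[SequenceRecord],
    k: int,
    b: float,
    alphabet: Alphabet = DNA,
) -> TrainedGenerator:
    """Count (k+1)-mers of the training records; counts are then frozen.

    Symbols outside the alphabet are deleted from the training input (the
    reduced-alphabet filter); contexts do not bridge record boundaries.
    """
    if k < 1:
        raise ValueError(f"order must be >= 1, got {k}")
    table = CountTable(alphabet.size)
    contexts: dict = {}
    trained = 0
    for record in training:
        seq = "".join(s for s in record.sequence.upper() if s in alphabet)
        for i in range(k, len(seq)):
            ctx = seq[i - k:i]
            table.increment(ctx, alphabet.index(seq[i]))
            contexts[ctx] = contexts.get(ctx, 0) + 1
            trained += 1
    if trained == 0:
        raise ValueError(f"training shorter than order {k} + 1")
    return TrainedGenerator(table, contexts, k, b, alphabet)


def generate_from_model(state: TrainedGenerator, n: int, seed: int) -> str:
    """Sample n symbols from the frozen model.

    The first k symbols are drawn from the training table's context marginal
    distribution; afterwards each symbol is sampled from the bet-estimator
    distribution conditioned on the last k generated symbols.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = Lcg(seed)
    alphabet = state.alphabet
    size = alphabet.size
    # burn-in: one context sampled proportionally to its training frequency
    ctx_items = list(state.contexts.items())
    total = sum(count for _, count in ctx_items)
    u = rng.uniform() * total
    acc = 0
    context = ctx_items[-1][0]
    for ctx, count in ctx_items:
        acc += count
        if u < acc:
            context = ctx
            break
    out = list(context[:n])
    while len(out) < n:
        row, ctx_total = state.table.counts(context)
        counts = row if row is not None else [0] * size
        probs = [estimate_probability(c, ctx_total, state.bet, size) for c in counts]
        u = rng.uniform()
        acc_p = 0.0
        idx = size - 1
        for j, p in enumerate(probs):
            acc_p += p
            if u < acc_p:
                idx = j
                break
        symbol = alphabet.symbols[idx]
        out.append(symbol)
        context = (context + symbol)[-state.order:]
    return "".join(out)


def apply_inversion(seq: str, alphabet: Alphabet = DNA) -> str:
    """Reverse complement when the alphabet defines one, plain reversal otherwise."""
    return alphabet.reverse_complement(seq)


def apply_mutations(
    seq: str,
    p_sub: float,
    p_del: float,
    p_ins: float,
    seed: int,
    alphabet: Alphabet = DNA,
) -> str:
    """Per-symbol Bernoulli mutations from one seeded LCG stream.

    Per input position, in fixed order: deletion (rate ``p_del``); if kept,
    substitution by a uniformly chosen *different* symbol (rate ``p_sub``);
    independently, insertion of one uniform symbol after the position
    (rate ``p_ins``).
    """
    for name, rate in (("p_sub", p_sub), ("p_del", p_del), ("p_ins", p_ins)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {rate}")
    rng = Lcg(seed)
    symbols = alphabet.symbols
    out = []
    for s in seq:
        if rng.uniform() < p_del:
            pass
        elif rng.uniform() < p_sub and s in alphabet:
            others = [c for c in symbols if c != s]
            out.append(others[rng.randint(len(others))])
        else:
            out.append(s)
        if rng.uniform() < p_ins:
            out.append(symbols[rng.randint(len(symbols))])
    return "".join(out)


@dataclass(frozen=True)
class ExtractSource:
    """Coordinates ``start..end`` (1-based inclusive) of a FASTA record."""

    path: Union[str, Path]
    start: int
    end: int
    record_id: Optional[str] = None  # None: first record


@dataclass(frozen=True)
class RandomSource:
    n: int
    seed: int


@dataclass(frozen=True)
class ModelSource:
    training_path: Union[str, Path]
    k: int
    b: float
    n: int
    seed: int


Source = Union[ExtractSource, RandomSource, ModelSource]


@dataclass(frozen=True)
class SimulationBlock:
    """One simulator segment: a source plus its transforms."""

    source: Source
    invert: bool = False
    p_sub: float = 0.0
    p_del: float = 0.0
    p_ins: float = 0.0
    mutation_seed: int = 0
    label: str = ""


@dataclass(frozen=True)
class BlockInterval:
    """Ground-truth placement of one block in the final coordinates."""

    index: int
    label: str
    start: int  # 1-based inclusive; start > end marks a fully deleted block
    end: int


def _realize_source(source: Source, alphabet: Alphabet) -> str:
    if isinstance(source, RandomSource):
        return generate_random(source.n, source.seed, alphabet)
    if isinstance(source, ExtractSource):
        records = read_fasta(source.path)
        if not records:
            raise ValueError(f"{source.path}: no records to extract from")
        if source.record_id is None:
            record = records[0]
        else:
            try:
                record = next(r for r in records if r.id == source.record_id)
            except StopIteration:
                raise ValueError(f"{source.path}: no record {source.record_id!r}")
        sub = extract_subsequence(record, source.start, source.end)
        return "".join(s for s in sub.sequence.upper() if s in alphabet)
    if isinstance(source, ModelSource):
        training = read_fasta(source.training_path)
        state = train_model_generator(training, source.k, source.b, alphabet)
        return generate_from_model(state, source.n, source.seed)
    raise TypeError(f"unknown source type: {type(source).__name__}")


def simulate_fasta(
    blocks: Sequence[SimulationBlock],
    out_id: str = "sim",
    alphabet: Alphabet = DNA,
) -> Tuple[SequenceRecord, List[BlockInterval]]:
    """Realize, transform and concatenate blocks into one FASTA record.

    Returns the record and the ground-truth interval of every block in the
    final coordinates (mutations shift downstream intervals consistently).
    """
    if not blocks:
        raise ValueError("at least one block is required")
    pieces = []
    truth = []
    position = 0
    for index, block in enumerate(blocks):
        try:
            seq = _realize_source(block.source, alphabet)
            if block.invert:
                seq = apply_inversion(seq, alphabet)
            if block.p_sub or block.p_del or block.p_ins:
                seq = apply_mutations(
                    seq, block.p_sub, block.p_del, block.p_ins,
                    block.mutation_seed, alphabet,
                )
        except Exception as exc:
            raise type(exc)(f"block {index}: {exc}") from exc
        pieces.append(seq)
        truth.append(
            BlockInterval(index, block.label, position + 1, position + len(seq))
        )
        position += len(seq)
    return SequenceRecord(out_id, "".join(pieces)), truth
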