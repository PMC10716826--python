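"""Context-model probability machinery.

The compressor behind the low-complexity mapper blends several fixed-order
Markov models ("finite-context models", FCMs). Each model predicts the next
symbol from the preceding k-mer with the smoothed count estimator

    P(s | ctx) = (n(ctx, s) + 1/b) / (n(ctx, ·) + |Θ|/b),

where b ≥ 1 is the *bet*: b = 1 is the Laplace estimator, and as b → ∞ the
estimate approaches the relative frequency. Three refinements are supported:

* inverted repeats (IR): every observed (k+1)-mer also updates the counts of
  its reverse complement, so an inversion of earlier material is predicted;
* a bounded cache history of p symbols: updates older than p positions are
  evicted, restricting the model's memory to *local* repetition;
* substitution tolerance (STCM): the conditioning context may deviate from
  the literal history in up to t positions, tracked through the model's own
  top-1 predictions, making scattered point substitutions cheap.

Model probabilities for the actual symbol are combined by soft blending:
P = Σ_m w_m p_m with per-step weight update w_m ∝ w_m^{γ_m} · p_m; the
emitted information content is −log₂(P) bits.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .alphabet import Alphabet, DNA

#: Unbounded cache sentinel (a cache covering the whole sequence).
UNBOUNDED: Optional[int] = None


def estimate_probability(
    symbol_count: int, context_total: int, b: float, alphabet_size: int
) -> float:
    """Smoothed conditional probability estimate (the bet estimator)."""
    if b < 1:
        raise ValueError(f"bet must be >= 1, got {b}")
    if alphabet_size < 2:
        raise ValueError(f"alphabet size must be >= 2, got {alphabet_size}")
    if symbol_count > context_total:
        raise ValueError("symbol count exceeds context total")
    return (symbol_count + 1.0 / b) / (context_total + alphabet_size / b)


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of one context model.

    ``cache=None`` means unbounded history. ``tolerance`` > 0 (with
    ``kind='stcm'``) enables substitution tolerance; ``gamma`` is the
    forgetting weight of this model inside the mixture.
    """

    order: int
    bet: float = 1.0
    ir: bool = False
    cache: Optional[int] = None
    gamma: float = 0.9
    tolerance: int = 0
    kind: str = "fcm"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if self.bet < 1:
            raise ValueError(f"bet must be >= 1, got {self.bet}")
        if self.cache is not None and self.cache < 1:
            raise ValueError(f"cache must be >= 1 or None, got {self.cache}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.kind not in ("fcm", "stcm"):
            raise ValueError(f"kind must be 'fcm' or 'stcm', got {self.kind!r}")
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")
        if self.kind == "stcm" and self.tolerance > self.order:
            raise ValueError("tolerance cannot exceed the context order")
        if self.kind == "fcm" and self.tolerance != 0:
            raise ValueError("plain FCMs have tolerance 0")


@dataclass(frozen=True)
class CompressorConfig:
    """The blended model set driving one compression run."""

    models: Tuple[ModelSpec, ...]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("config needs at least one model")

    @classmethod
    def from_strings(cls, *texts: str) -> "CompressorConfig":
        specs: List[ModelSpec] = []
        for text in texts:
            specs.extend(parse_model_string(text))
        return cls(tuple(specs))

    def with_cache(self, cache: Optional[int]) -> "CompressorConfig":
        """Same model set with every model's cache replaced."""
        return CompressorConfig(tuple(replace(m, cache=cache) for m in self.models))


def parse_model_string(text: str) -> List[ModelSpec]:
    """Parse ``order:bet:ir:cache:gamma[/tolerance:gamma]``.

    The optional ``/t:g`` suffix adds a substitution-tolerant companion model
    of the same order, bet, IR flag and cache. Cache 0 denotes unbounded.
    Example: ``"13:50:1:0:0.9/5:0.9"``.
    """
    main, _, stcm_part = text.partition("/")
    fields = main.split(":")
    if len(fields) != 5:
        raise ValueError(
            f"model string {text!r}: expected order:bet:ir:cache:gamma"
        )
    order = int(fields[0])
    bet = float(fields[1])
    ir = bool(int(fields[2]))
    cache_raw = int(fields[3])
    cache = None if cache_raw == 0 else cache_raw
    gamma = float(fields[4])
    specs = [ModelSpec(order=order, bet=bet, ir=ir, cache=cache, gamma=gamma)]
    if stcm_part:
        sub = stcm_part.split(":")
        if len(sub) != 2:
            raise ValueError(f"model string {text!r}: expected /tolerance:gamma")
        specs.append(
            ModelSpec(
                order=order,
                bet=bet,
                ir=ir,
                cache=cache,
                gamma=float(sub[1]),
                tolerance=int(sub[0]),
                kind="stcm",
            )
        )
    return specs


class CountTable:
    """Counts of (context, symbol) pairs with O(1) increment/decrement."""

    __slots__ = ("_size", "_counts", "_totals")

    def __init__(self, alphabet_size: int):
        self._size = alphabet_size
        self._counts: dict = {}
        self._totals: dict = {}

    def counts(self, context: str) -> Tuple[Optional[list], int]:
        return self._counts.get(context), self._totals.get(context, 0)

    def increment(self, context: str, symbol_index: int) -> None:
        row = self._counts.get(context)
        if row is None:
            row = [0] * self._size
            self._counts[context] = row
        row[symbol_index] += 1
        self._totals[context] = self._totals.get(context, 0) + 1

    def decrement(self, context: str, symbol_index: int) -> None:
        row = self._counts[context]
        row[symbol_index] -= 1
        total = self._totals[context] - 1
        if total == 0:
            del self._counts[context]
            del self._totals[context]
        else:
            self._totals[context] = total

    def total_updates(self) -> int:
        return sum(self._totals.values())


class FiniteContextModel:
    """Order-k Markov model with bet smoothing, optional IR counts and cache."""

    def __init__(self, spec: ModelSpec, alphabet: Alphabet = DNA):
        self.spec = spec
        self.alphabet = alphabet
        self.table = CountTable(alphabet.size)
        self.ir_table = CountTable(alphabet.size) if spec.ir else None
        self._ctx = ""
        self._history: deque = deque()  # per-step update lists for eviction

    def _distribution(self, context: str) -> List[float]:
        size = self.alphabet.size
        b = self.spec.bet
        row, total = self.table.counts(context)
        counts = list(row) if row is not None else [0] * size
        if self.ir_table is not None:
            ir_row, ir_total = self.ir_table.counts(context)
            if ir_row is not None:
                counts = [c + i for c, i in zip(counts, ir_row)]
                total += ir_total
        return [estimate_probability(c, total, b, size) for c in counts]

    def predict(self) -> List[float]:
        """Probability vector for the next symbol given the current context."""
        if len(self._ctx) < self.spec.order:
            return [1.0 / self.alphabet.size] * self.alphabet.size
        return self._distribution(self._ctx)

    def _count(self, context: str, symbol: str, updates: list) -> None:
        idx = self.alphabet.index(symbol)
        self.table.increment(context, idx)
        updates.append((self.table, context, idx))
        if self.ir_table is not None:
            mer = context + symbol
            rc = self.alphabet.reverse_complement(mer)
            ir_idx = self.alphabet.index(rc[-1])
            self.ir_table.increment(rc[:-1], ir_idx)
            updates.append((self.ir_table, rc[:-1], ir_idx))

    def observe(self, symbol: str) -> None:
        """Consume one stream symbol: update counts and advance the context.

        Ambiguous symbols (outside the alphabet) never update counts and
        break the context buffer, but still age the cache.
        """
        k = self.spec.order
        updates: list = []
        if symbol not in self.alphabet:
            self._ctx = ""
        else:
            if len(self._ctx) == k:
                self._count(self._ctx, symbol, updates)
            self._ctx = (self._ctx + symbol)[-k:]
        self._age_cache(updates)

    def _age_cache(self, updates: list) -> None:
        cache = self.spec.cache
        if cache is None:
            return
        self._history.append(updates)
        if len(self._history) > cache:
            for table, context, idx in self._history.popleft():
                table.decrement(context, idx)


class SubstitutionTolerantModel(FiniteContextModel):
    """Context model whose conditioning context tolerates ≤ t substitutions.

    The model predicts from a *hypothesis* context assembled from its own
    past top-1 predictions. A mismatch between the real symbol and the top-1
    prediction marks a substitution; while at most t substitutions remain
    inside the current k-symbol window the predicted symbol (not the real
    one) extends the hypothesis and is counted, so isolated substitutions do
    not derail the context. Marks expire as they slide out of the window
    ("t substitutions in a context of k"); once a new mark would exceed t,
    the hypothesis resets to the true recent history and the marks clear.
    An unseen hypothesis context carries no prediction, so the real symbol
    extends it unmarked. With t = 0 the model is bitwise identical to the
    plain FCM.
    """

    def __init__(self, spec: ModelSpec, alphabet: Alphabet = DNA):
        if spec.kind != "stcm":
            raise ValueError("SubstitutionTolerantModel requires kind='stcm'")
        super().__init__(spec, alphabet)
        self._true = ""
        self._marks: deque = deque(maxlen=spec.order)  # substitution flags in window

    @property
    def substitutions_in_window(self) -> int:
        return sum(self._marks)

    def _extend(self, symbol: str, mark: int) -> None:
        self._ctx = (self._ctx + symbol)[-self.spec.order:]
        self._marks.append(mark)

    def observe(self, symbol: str) -> None:
        k = self.spec.order
        updates: list = []
        if symbol not in self.alphabet:
            self._ctx = ""
            self._true = ""
            self._marks.clear()
        else:
            if len(self._ctx) == k:
                probs = self._distribution(self._ctx)
                _, total = self.table.counts(self._ctx)
                if self.ir_table is not None:
                    total += self.ir_table.counts(self._ctx)[1]
                top = self.alphabet.symbols[probs.index(max(probs))]
                if total == 0 or symbol == top:
                    self._count(self._ctx, symbol, updates)
                    self._extend(symbol, 0)
                elif sum(self._marks) < self.spec.tolerance:
                    self._count(self._ctx, top, updates)
                    self._extend(top, 1)
                else:
                    self._count(self._ctx, symbol, updates)
                    self._ctx = (self._true + symbol)[-k:]
                    self._marks.clear()
            else:
                self._extend(symbol, 0)
            self._true = (self._true + symbol)[-k:]
        self._age_cache(updates)


def build_model(spec: ModelSpec, alphabet: Alphabet = DNA) -> FiniteContextModel:
    if spec.kind == "stcm":
        return SubstitutionTolerantModel(spec, alphabet)
    return FiniteContextModel(spec, alphabet)


def mixture_step(
    weights: Sequence[float], model_probs: Sequence[float], gammas: Sequence[float]
) -> Tuple[float, List[float]]:
    """One soft-blending step.

    Returns the information content −log₂(Σ w_m p_m) in bits and the updated,
    renormalized weight vector w_m ∝ w_m^{γ_m} · p_m.
    """
    blended = sum(w * p for w, p in zip(weights, model_probs))
    assert blended > 0.0, "smoothed estimators cannot assign zero probability"
    new = [(w ** g) * p for w, p, g in zip(weights, model_probs, gammas)]
    norm = sum(new)
    return -math.log2(blended), [w / norm for w in new]


class Mixture:
    """Blend several context models into a per-symbol bit stream."""

    def __init__(self, config: CompressorConfig, alphabet: Alphabet = DNA):
        self.alphabet = alphabet
        self.models = [build_model(spec, alphabet) for spec in config.models]
        self.gammas = [spec.gamma for spec in config.models]
        self.weights = [1.0 / len(self.models)] * len(self.models)

    def step(self, symbol: str) -> float:
        """Bits to encode ``symbol``; updates weights and all model states.

        Ambiguous symbols cost log₂|Θ| bits and leave the weights untouched.
        """
        if symbol not in self.alphabet:
            for model in self.models:
                model.observe(symbol)
            return math.log2(self.alphabet.size)
        idx = self.alphabet.index(symbol)
        probs = [model.predict()[idx] for model in self.models]
        bits, self.weights = mixture_step(self.weights, probs, self.gammas)
        for model in self.models:
            model.observe(symbol)
        return bits
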