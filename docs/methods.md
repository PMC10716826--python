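# Methods

## Model

`lcrmap` treats low-complexity detection as a compression problem: the
information content a lossless compressor assigns to each symbol is an
upper-bound proxy for its algorithmic (Kolmogorov) complexity, so
sub-threshold stretches of the per-position bit profile are, without risk of
underestimation, redundant. The compressor is a soft-blended mixture of
fixed-order context models over the sequence alphabet Θ.

**Estimator.** Each model predicts P(s|ctx) = (n(ctx,s) + 1/b) /
(n(ctx,·) + |Θ|/b). The bet b interpolates between the Laplace estimator
(b = 1) and the maximum-likelihood relative frequency (b → ∞). Because the
estimator is strictly positive, no symbol ever costs infinite bits.

**Mixture.** With per-model probabilities pₘ for the observed symbol, the
emitted value is −log₂ Σₘ wₘ pₘ bits and the weights update as
wₘ ∝ wₘ^{γₘ}·pₘ (renormalized). γₘ ∈ (0,1] is a forgetting factor: smaller
values let the blend switch faster between models. Weights start uniform.

**Bidirectional minimum.** The same (freshly initialized) compressor runs
left→right and, over the reversed symbol string, right→left; the
right-to-left pass does *not* complement — conditioning on following symbols
is a causal-direction change, while complementation is the IR model's job.
The pointwise minimum 𝒩 of the two directional profiles makes the original
and the copy of a duplicated segment both score low; a single pass would
only flag the second occurrence. The two passes are independent, so the
result is identical however they are scheduled.

**Smoothing and segmentation.** 𝒩 is averaged with a forward window,
F(i) = mean(𝒩[i .. i+w−1]), truncating at the right edge (the equation's
forward window leaves truncation at the boundary unspecified; truncation
keeps the profile length equal to n and is the documented choice). Maximal
runs *strictly* below the threshold T become regions; runs shorter than s
are discarded after extraction and never merged into neighbours. Strictness
matters at exact equality: on the 24-nt worked example the left-to-right
profile touches exactly 1.0 bits at position 12, and a non-strict rule would
change the mapped region. Smoothing is applied after the minimum, not
before. An optional `join_gap` merges nearby runs; it defaults to 0 (off).

Multi-record input is mapped independently per record by default. An
optional concatenation mode maps all records as one sequence — exposing
repeats shared *between* records — with sentinel runs of k ambiguity
symbols at the joins (so contexts never bleed across records) and
re-projects region coordinates into the originating records.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| k (order) | context depth, symbols | 13 (CLI) | ≥ 12 needed for unique contexts in Mb-scale DNA |
| b (bet) | estimator confidence, ≥ 1 | 50 (CLI) | high b rewards already-seen contexts sharply |
| ir | inverted-repeat counting | on (CLI) | DNA only; protein alphabets have no complement |
| p (cache) | memory, symbols; 0/None = unbounded | unbounded | bounds the distance over which repeats are recognized |
| t (tolerance) | substitutions allowed in the context window | 5 (CLI companion) | STCM only; t ≤ k |
| γ | mixture forgetting, (0,1] | 0.9 | per model |
| w | smoothing window, positions | 10 | larger w = fewer, coarser regions |
| T | threshold, bits | log₂\|Θ\|/2 (1.0 for DNA) | strictly-below semantics |
| s | minimum region size, positions | 1 | raise (≥ 30–50) to suppress chance dips |

**Cache semantics.** p counts *sequence positions*: all count updates made
at one position (the forward update and, with IR, its reverse-complement
twin) are enqueued together and evicted together once they are more than p
positions old. Ambiguous positions still age the queue. Eviction is exact
(FIFO with decrement), so a run with p = n is bit-identical to unbounded.

**Ambiguity policy.** Symbols outside the alphabet (N, X, …) are predicted
uniformly (log₂|Θ| bits), never update counts, and reset the context
buffer. This prevents N-runs from registering as low complexity while
keeping profile length equal to sequence length. Positions with fewer than
k preceding valid symbols also receive the uniform prediction — there is no
fallback to shorter orders, which keeps the contract testable and affects
only k positions per direction per context break.

**STCM state machine.** The substitution-tolerant model predicts from a
hypothesis context built from its own past top-1 predictions. A mismatch
between the real symbol and the top-1 prediction is marked as a
substitution and the *predicted* symbol extends the hypothesis (and is
counted); marks expire as they slide out of the k-symbol window, so the
invariant is "at most t substitutions in a context of k". A mark that would
exceed t instead counts the real symbol and resets the hypothesis to the
true recent history. An unseen hypothesis context (zero total counts)
carries no usable prediction, so the real symbol extends it unmarked. Two
design consequences, both verified by tests: t = 0 is bitwise identical to
the plain FCM, and 10%-substituted copies of a 1 kb block stay well below
1 bit on average (a non-expiring counter permanently derails instead). The
STCM keeps a private count table, isolating its contribution from the
paired FCM in the mixture.

**Normalized compression.** NC = Σᵢ bits(xᵢ) / (n·log₂|Θ|), computed from
the left-to-right pass only (matching a single compression of the file).
NC ≈ 0 marks heavy redundancy, NC ≈ 1 incompressibility; values slightly
above 1 are possible because the mixture pays a model-switching overhead.
`minimum_normalized_compression` minimizes NC over a grid of single-model
configurations (orders 1–14, bets 1/5/50, IR on/off) to give a sequence the
best chance of revealing structure before declaring it non-redundant.

## Simulator

The simulator emulates benchmark sequences as concatenations of blocks:
uniform pseudo-random stretches, coordinate extractions from existing FASTA
files, and samples from an order-k model trained on a FASTA file (counts
frozen after training; the first k symbols are drawn from the training
context marginals — the burn-in is otherwise unspecified and this choice is
documented here). Blocks may be inverted (reverse complement for DNA,
reversal otherwise) and mutated per symbol: delete with p_del; if kept,
substitute with p_sub by a uniformly chosen *different* symbol;
independently insert one uniform symbol after the position with p_ins. All
randomness comes from a 64-bit linear congruential generator
(a = 6364136223846793005, c = 1442695040888963407, m = 2⁶⁴, one warm-up
step) — constants fixed here so output bytes are reproducible; per-symbol
Bernoulli mutation (rather than fixed per-block counts) is the documented
interpretation of "mutation probability". Ground-truth block intervals in
final coordinates are returned for benchmarking.

What the simulator does *not* emulate: nonstationary base composition,
sequencing error profiles, long-range correlations of natural chromatin, or
rearrangements beyond inversion. Passing the simulated benchmarks therefore
demonstrates that the mapper recovers *planted* copies, inversions,
substituted copies and distance-stratified duplicates under controlled
noise — not that every biological LCR class is recovered; natural-sequence
behaviour should be spot-checked (e.g. with the NC grid on known
non-repetitive regions).

## Benchmark configurations used by the test suite

The planted-copy benchmark uses eleven 1 kb blocks (a fixed random block A;
exact, inverted, 3%- and 10%-substituted copies; six unique random blocks)
mapped with `13:50:1:0:0.9/5:0.9`, w = 10, s = 30, at T = 1.0 and 1.5. The
memory benchmark plants a 1.5 kb duplicate behind 1 kb and 20 kb random
spacers and maps with the same FCM at cache ∈ {unbounded, 500}. Sizes were
chosen as the smallest at which context-depth-13 statistics are meaningful
(≥ 4k symbols per block) while the whole suite stays interactive; the
estimator cross-check recounts k-mers by brute force on 500 strings of
20–200 nt.

## Known limitations

* Pure-Python inner loop: throughput is roughly 10⁵ symbols·model/s, ample
  for desk-scale analysis (viral genomes, benchmark sets), not for whole
  mammalian genomes.
* Profiles are held in memory per record; streaming is out of scope.
* The mixture can briefly exceed log₂|Θ| bits after context breaks; region
  boundaries within w−1 positions of a sharp complexity edge inherit the
  smoothing window's blur.
* The ideogram renders rectangles only (no centromere/stalk glyphs) and
  clips enlarged regions at bar ends (enlargement is center-anchored).
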