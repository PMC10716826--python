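# lcrmap

Alignment-free mapping, masking, simulation and visualization of
**low-complexity regions (LCRs)** in FASTA sequences (DNA or protein).

LCRs — homopolymer runs, tandem and inverted repeats, duplicated segments,
GC-biased stretches — matter because they concentrate assembly errors,
ambiguous read mappings, and regulatory/structural signals. `lcrmap` finds
them without a reference and without alignment, by asking a lossless
compressor how many bits each symbol costs: regions that compress well are,
by construction, redundant.

## The method

For a sequence x₀ … x_{n−1} over alphabet Θ, a blend of finite-context
(Markov) models of order k estimates

  P(xᵢ | context) = (n(ctx, xᵢ) + 1/b) / (n(ctx, ·) + |Θ|/b),

where b ≥ 1 is the *bet* (b = 1 ⇒ Laplace estimator, b → ∞ ⇒ relative
frequency). Model probabilities are soft-blended, wₘ ∝ wₘ^{γₘ}·pₘ, and the
per-position information content is −log₂ Σₘ wₘ pₘ bits. Three refinements:

* **inverted repeats (IR):** each observed (k+1)-mer also counts its reverse
  complement, so inversions are predicted;
* **cache history p:** updates older than p symbols are evicted, splitting
  *local* from *distant* redundancy;
* **substitution tolerance (STCM):** the conditioning context may deviate
  from the literal history in up to t of k positions, so scattered point
  substitutions do not break the context.

The mapper computes the profile in both causal directions (left→right and
right→left), takes the pointwise minimum 𝒩(xᵢ) — so *both* copies of a
duplication score low, not just the second — smooths it with a forward
moving average of window w, and reports maximal runs strictly below a
threshold T (default log₂|Θ|/2), discarding runs shorter than s. Regions can
be soft-masked (lowercased) in the FASTA and drawn to scale as a multi-track
SVG ideogram. A block-based simulator (LCG pseudo-random, FCM-trained
generation, file extraction; inversion and substitution/deletion/insertion
mutations) produces benchmark sequences with known ground truth.

## Worked example

The 24-nt sequence `ATGCTCGAAAAAAAAAACGAGCAT` contains a 10-A homopolymer at
positions 8–17 and an inverted repeat (positions 1–7 are the reverse
complement of 18–24).

```console
$ printf '>example\nATGCTCGAAAAAAAAAACGAGCAT\n' > ex.fa
$ lcrmap info ex.fa
example	24	33.3
$ lcrmap mapper ex.fa --model 2:1:0:0:0.9 --window 1 --threshold 1.0 --min-size 1
example	7	17	lcr	0.6089
$ lcrmap mapper ex.fa --model 2:1:0:0:0.9 --window 1 --threshold 1.0 --mask-out masked.fa
example	7	17	lcr	0.6089
$ cat masked.fa
>example
ATGCTCGaaaaaaaaaaCGAGCAT
```

`info` prints id, length and GC% (24 nt, 33.3% GC). The mapper line is
BED-style (0-based half-open on disk): `7 17` is the homopolymer at 1-based
positions **8–17**, found with a single order-2 Laplace model at threshold
1.0 bits; its mean smoothed complexity is 0.61 bits. The soft-masked FASTA
lowercases exactly those positions. An IR-enabled model string (third field
1, e.g. `13:50:1:0:0.9/5:0.9`: order 13, bet 50, IR on, unbounded cache,
γ = 0.9, plus a tolerance-5 substitution-tolerant companion) additionally
exposes the inverted repeat in longer sequences.

Model strings follow `order:bet:ir:cache:gamma[/tolerance:gamma]` with
cache 0 meaning unbounded. The other subcommands: `lcrmap simulation
--block random:1000:7 --block extract:ref.fa:1:500,inv,sub=0.03,mseed=5 -o
sim.fa` builds benchmark sequences (with `--truth-out` ground truth), and
`lcrmap visual --regions a.bed --regions b.bed --fasta sim.fa -o map.svg`
renders stacked region tracks to scale.

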