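# Methods

## Coding-sequence preprocessing

Inputs are filtered by four rules applied in a fixed, observable order:
length divisible by three; first codon among the translation table's
start codons; last codon among its stop codons; exactly one in-frame
stop, at the terminal position. A fifth rule ("alphabet") rejects any
sequence containing characters outside A/C/G/T — ambiguity codes are
rejected explicitly rather than silently skipped — and is checked first.
A sequence violating several rules is logged under the first violated
rule only, and kept + rejected always equals the input count.

Translation uses NCBI translation tables (via Biopython). Alternative
start codons (GTG/TTG in table 11, pervasive in bacteria and archaea)
are accepted by the start-codon rule and rendered as methionine, per
NCBI CDS convention; `translate_cds(..., recode_start=False)` disables
the re-coding. Input is case-insensitive and RNA `U` is transliterated
to `T` on read; storage is uppercase DNA.

## Usage tables and scalar metrics

A usage table aggregates codon counts over an organism's validated
genes. Zero-count codons receive a pseudocount of 0.5 before relative
adaptiveness w = x/x_max is formed, the standard device that keeps the
geometric mean defined. Within-family frequencies sum to one and each
family's maximal codon has w = 1 exactly; the rare set is {w < 0.30},
with the boundary value 0.30 itself not rare (strict inequality).

CSI is the geometric mean of w over a gene's codons. Codons of
single-synonym amino acids (ATG, TGG under the standard code) and stop
codons are excluded by default, following the classical CAI
implementations — including them only dilutes the index toward 1 —
with `include_all=True` available for the all-codon variant. These two
conventions (pseudocount, eligibility) are package choices where the
field itself varies; both are explicit parameters.

CFD counts all codons, including the stop, in its denominator. The
fine-tuning selection rule keeps the top ⌊fraction·N⌋ genes by CSI
(default fraction 0.10), with deterministic ties broken by record id.

## STREAM tokenization and corruption

The vocabulary is rebuilt from the translation table rather than stored:
5 special tokens (`[UNK] [CLS] [SEP] [PAD] [MASK]`), then 21
residue-unknown tokens sorted by residue symbol (the stop symbol `_`
sorts last, giving `[__UNK]`), then 64 pair tokens sorted by
(amino acid, codon) — 90 ids, deterministic and stable across
save/load. Encoded sequences are `[CLS] body [SEP] [PAD]*` with a
0/1 attention mask; truncation keeps the first max_len − 2 sequence
tokens so the start-codon context always survives; the organism's
token-type id fills the whole sequence.

MLM corruption selects each pair-token position independently with
probability 0.15 (special tokens are never touched — corrupting
`[CLS]`/`[SEP]` would destroy sequence structure). Selected positions
are masked to their residue-unknown token with probability 0.8,
replaced by a pair token drawn uniformly from all 64 with probability
0.1 (so random replacement may break amino-acid agreement, as in
generic masked-LM practice), and left unchanged otherwise; labels carry
the original ids at selected positions and −100 elsewhere. Because
selection is per-position Bernoulli, the empirical selection rate over
N pair tokens has standard deviation √(0.15·0.85/N) — about 0.06
percentage points at N ≈ 3·10⁵, which is the corpus size the rate
checks use.

A record whose alternative start codon was re-coded to M is encoded at
position 0 with the codon's own elongation pair token (e.g. `[V_GTG]`),
the only token that preserves the codon; decoding such a sequence
therefore returns the elongation-sense protein.

## Model

The trainable backend is a compact transformer encoder implemented in
numpy with hand-written gradients: embeddings are the sum of token,
organism-type and absolute-position embeddings followed by layer norm;
each block is post-layer-norm multi-head self-attention plus a GELU
feed-forward; a linear head yields per-position logits over the 90
tokens. Attention is dense — at the lengths this package targets
(≤ 2048 tokens) dense attention is exact, and block-sparse patterns are
purely an efficiency device — but the published full-scale shape
(12 layers, 12 heads, hidden 768, intermediate 3072, block size 64,
max length 2048, ~90M parameters) is recorded as a preset for
reference. The desk-scale default is 2 layers, 2 heads, hidden 64,
intermediate 128, max length 256: small enough to train on a single
CPU in well under five minutes on a 500-gene corpus, large enough to
recover the generating codon distributions (see below).

Training minimizes cross-entropy at labeled positions only, with fresh
corruption every epoch, Adam, and a piecewise-linear learning-rate
ramp: lr_start → lr_peak over the first 10% of steps, then linear decay
to lr_end (published values 5e-7 → 5e-5 → 5e-7 with batch 6; desk-scale
defaults 1e-4 → 2e-3 → 1e-4 with batch 16, 30 epochs). Gradients are
verified against central finite differences in the test suite.
Checkpoints (config, vocabulary, registry, weights) reload to
bit-identical predictions. Training is deterministic given seed and
thread count; BLAS reduction order can perturb the last bits across
machines, which is why reproducibility is asserted for evaluation, not
for training traces.

## Inference, decoding and mutation scoring

Two input modes: protein-only (all residue-unknown tokens) and
protein+DNA (pair tokens of a seed sequence, every position then
re-predicted). Decoding restricts each position's distribution to the
pair tokens of the target residue, renormalizes, and takes argmax
(default; ties broken toward the lexicographically first codon, making
runs reproducible) or a seeded sample. The decoded DNA therefore always
translates to the input protein, whatever the backend.

Synonymous mutations are scored zero-shot as
ln p(mutant token) − ln p(wild-type token) at the queried position,
with the wild-type sequence presented unmasked in protein+DNA mode; a
`mask_position` option hides the queried codon first. The choice of
greedy decoding and of not masking the queried position are
conventions where the underlying method is agnostic; both have
switches. Under the BFC baseline the score collapses to the closed
form ln(f_mut/f_wt), which the tests exploit as an exact oracle.

## Profiles and design comparison

%MinMax uses family-relative frequencies from the usage table
(consistent with the w < 0.30 rarity semantics, not per-1000 global
frequencies) and a window of 18 codons sliding by one. Two variants:

* `paper` (default): per window, 100·(f_max − f_min)/(f_max + f_min)
  over the frequencies observed in the window; range [0, 100].
* `canonical` (Clarke–Clark): X_actual = mean used frequency;
  X_max/X_min/X_avg = means of per-residue family max/min/average;
  score = 100·(X_actual − X_avg)/(X_max − X_avg) when X_actual ≥ X_avg,
  else −100·(X_avg − X_actual)/(X_avg − X_min); range [−100, 100].

Both are shipped because the two formulas are genuinely different
statistics; reports name the variant used, and no claim is made that
either reproduces any specific published figure.

DTW is an exact dynamic program with the optimal path recovered by
backtracking; its equality with exhaustive monotone-path enumeration on
short profiles is part of the test suite. Variants: `tool_compatible`
(default) uses the symmetric2 step pattern — |x−y| local cost, diagonal
steps paying the cost twice — normalized by n + m, matching the
convention of the standard dtw packages; `paper` uses squared local
cost, unit step weights, distance √(accumulated cost), normalized by
path length. DTW is not a metric (no triangle inequality); symmetry
holds for both variants.

## Synthetic data

Each synthetic organism draws within-family codon frequencies from a
symmetric Dirichlet(α) and materializes counts by a multinomial draw of
10,000 codons per family. The default α = 0.3 produces strong, varied
bias (typical families have one or two dominant codons and several rare
ones), comparable to strongly biased microbial genomes; α → ∞
approaches uniform usage. Mirrored pairs reverse each family's
frequency ranking — maximally different hosts over the same alphabet —
to probe organism conditioning. Proteins start with M (first codon
ATG) and end with a single stop drawn per policy, so every generated
record passes preprocessing; gene lengths are log-normal over codon
counts (median 100, σ = 0.5) clipped to [25, 500] so every gene
supports an 18-codon window.

What the generator emulates: organism-specific codon bias, mixed-length
multi-organism corpora, valid CDS structure. What it does not: GC-skew
gradients along genes, codon-pair and dinucleotide effects, positional
autocorrelation of rarity (natural rare-codon clusters), selection on
mRNA structure. Passing tests therefore demonstrate that the machinery
learns and measures codon-usage structure correctly, not that any
particular biological claim about real genomes holds.

## Problem sizes and numerical choices

The test suite trains the desk-scale model on 500-gene corpora (single
organism, and a 250+250 mirrored pair) and evaluates recovery as the
mean Kullback–Leibler divergence KL(table ‖ predicted), computed from
predictions at fully masked input averaged over 30 random 80-codon
proteins; single-organism recovery reaches KL ≈ 0.004 against a 0.05
bound, and each mirrored organism stays under 0.1 while the
cross-organism KL is an order of magnitude larger. Corruption-rate
checks use ≈ 3·10⁵ pair tokens. Probability vectors are normalized to
1 ± 1e-6; layer norm uses ε = 1e-12; degenerate inputs (empty
sequences, zero synonymous mass, unregistered organisms, non-synonymous
mutants) raise errors naming the offending position or key rather than
propagating NaNs.

## Known limitations

* The neural backend is CPU-oriented; no GPU path, no sparse attention.
* Organism conditioning is a single categorical embedding; no
  taxonomic sharing between related hosts.
* CSI eligibility and pseudocount conventions follow the CAI
  literature; published tools differ, so absolute CSI values are
  comparable only within one convention.
* RNA secondary-structure energy and host regulatory-motif scanning
  are out of scope (external engines); the evaluation suite covers
  codon-usage statistics only.
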