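# Methods

## The relative compressor

`paleocomp` measures how much information a reference genome shares with a
sequenced sample by *relative compression*: an ensemble of finite-context
(Markov) models is trained on the sample's reads, the accumulated counts are
frozen, and each reference is then coded left-to-right under the frozen
ensemble.  The code length, normalized by the 2 bits/base of the DNA
alphabet, is the Normalized Relative Compression,

    NRC(x | model) = bits(x) / (2 |x|),

and its percent complement, `NRS = 100 (1 − min(NRC, 1))`, is the Normalized
Relative Similarity.  Because the coder never adapts its counts to the
target, NRS is a conservative estimate: it can under- but not over-state
shared information.  An unrelated random genome codes at ≈ 2 bits/base
(NRC ≥ 1, NRS 0); a genome whose k-mers were all seen during training codes
at a few hundredths of a bit per base (NRS in the high 90s).

### Model ensemble

The default ensemble mixes four regular context models and one
substitution-tolerant model:

| model     | depth k | alpha | inverted repeats |
|-----------|---------|-------|------------------|
| regular   | 20      | 0.005 | yes              |
| regular   | 14      | 0.01  | yes              |
| regular   | 11      | 0.1   | no               |
| regular   | 6       | 1     | no               |
| tolerant  | 20      | 0.1   | tolerance 5      |

A regular model estimates `P(s|c) = (n(c,s) + α) / (Σ_s' n(c,s') + 4α)`.
With *inverted repeats* enabled, every observed k+1 window is counted twice:
once as seen and once as its reverse-complement twin (for window `w`, symbol
`complement(w[0])` under context `rc(w[1:])`).  This makes the count store
strand-symmetric — training on a sequence and on its reverse complement
yields byte-identical stores — which matters because shotgun reads sample
both strands and organelle/plastid genomes carry large inverted repeats.

The tolerant model shares the depth-20 count store but maintains an *edited*
context: after each symbol, a miss (observed ≠ the store's argmax
prediction, ties broken A<C<G<T) substitutes the predicted symbol into the
history and increments a miss counter (hits decay it, floor 0); when misses
exceed the tolerance the history resets to the literal past.  This lets a
deep context survive isolated substitutions — the dominant mutation mode in
both evolutionary divergence and ancient-DNA damage — instead of losing all
k symbols of context at every mismatch.  The exact repair schedule (argmax
substitution, decay-on-hit, reset-on-overflow) is this package's concrete
design; it is deliberately config-isolated so alternative schedules can be
swapped in.

Per-model probabilities are soft-blended: `P(s) = Σ_m w_m P_m(s)`, with
weights updated as `w_m ← normalize(w_m^γ · P_m(s_observed))` under a
decaying forgetting factor γ = 0.95.  γ < 1 flattens the weight history so
the mixture tracks which model predicts well *locally*, switching within a
few symbols when the data change character.  Weights reset to uniform at
the start of every evaluated sequence (references are compressed
independently; reads are scored independently).

### Coding conventions and numerics

* Contexts never span read boundaries; an N breaks the context for all
  models (internally, reads are concatenated with sentinel separators that
  invalidate any window crossing them).
* A position is mixture-coded only when the symbol is not N and the
  preceding k_max symbols are clean.  All other positions cost a flat
  2 bits and trigger no weight or tolerant-state update — the well-defined,
  alphabet-uniform fallback.  An all-N sequence therefore costs exactly
  2 bits/base, and the empty sequence 0 bits.
* Counts are exact integers in hash-backed tables (packed 2-bit context
  codes, sorted for batched lookup).  A per-model memory budget (`cache_mb`,
  default 250 MB) prunes lowest-count contexts deterministically (ties by
  context code) if ever exceeded; at the scales in this repository it never
  triggers, so results are exact.
* Evaluation is read-only and bit-deterministic: repeated runs give
  identical code lengths, and a `--threads` flag on the CLI is accepted but
  semantically inert.
* An adaptive single-model coder (counts updated after each coded symbol)
  is included for diagnostics; its arithmetic is hand-checkable — an
  order-1 model coding `AAAA` from nothing costs
  2 + 2 + log2(5/2) + 1 ≈ 6.32193 bits.

### Per-read similarity

Whole-genome NRC uses `bits/(2L)`: the k_max-position startup edge is
negligible against tens of kilobases.  Inside a 101 bp read it is not — the
first k_max positions *must* cost ~2 bits each (locating a read start in a
genome of size G costs ≈ log2(2G) bits under any honest model), which caps
naive read NRS at `100 (1 − k_max/101)` regardless of how perfectly the
read matches.  Per-read similarity therefore normalizes over the
mixture-coded positions only:

    read NRC = informative_bits / (2 · n_informative),

so an error-free read scores in the high 90s and a random read ≈ 0, and the
conventional 0.95 acceptance threshold separates them cleanly.  Reads too
short to contain any full-depth context score NRC 1 (NRS 0).

Read scoring uses a reduced ensemble — depths 11 and 6, both with inverted
repeats, no tolerant model — because a depth-20 context barely fires inside
a 101-mer.  Its alphas are small (0.01 at k=11): a single training pass
over a reference leaves count-1 contexts, where heavy smoothing would waste
~0.35 bits on every correctly predicted base.  The full ensemble remains
available behind a flag.

## Workflow components

**Read QC** trims terminal N runs (with matching quality trim) and rejects
reads shorter than 25 bases or with mean Phred below 20.  Both thresholds
are configurable; the quality rule is a mean over the read, chosen as the
simplest monotone statistic given that per-base trimming windows and
adapter handling are out of scope (the simulator emits insert-only reads).
QC is idempotent and order-preserving.

**Reference ranking** scores every database genome under the sample model,
sorts by NRS (ties by id, stable), and truncates to a top list (default
500).  **Database intra-similarity** re-runs the same machinery pairwise —
entry (i, j) scores reference j under a model trained only on reference i —
to distinguish near-duplicate references (one organism detected through
many similar genomes) from independent detections, in place of competitive
read assignment.

**Complexity profiles** record the per-position code length of a reference
under the sample model; dips mark represented regions.  Profiles are turned
into segment maps by bounding similarity as `s = 1 − min(bits, 2)/2`,
smoothing with a centered circular moving average (default window 500), and
extracting maximal runs with `s ≥ 0.5`; runs closer than the window merge,
and merged runs shorter than 100 bases drop.  The circular kernel was
chosen over shrink-to-fit edges because it preserves the profile mean
exactly (segmentation neither creates nor destroys similarity mass) and
because the typical references — plastids, mitochondria, bacterial
chromosomes — are circular molecules.  Segments are 0-based half-open
internally and 1-based closed in TSV; the SVG map colours segments by
similarity quartile.

**Damage profiling** counts reference→read substitutions from SAM
alignments by distance (default 25 positions) from each read end, after
strand correction: reverse-strand records are complemented and mirrored so
position 1 is always the biological 5′ terminus.  Frequencies are
conditioned on the reference base (C→T frequency = C→T events / aligned
reference Cs at that distance).  Only substitutions are profiled; cigars
are restricted to M/S/=/X and indel alignments are rejected.  The
ancient-vs-contaminant call formalizes "visible terminal damage" as a
two-condition rule on the mean 5′ C→T frequency over positions 1–3:
it must clear an absolute floor (default 0.05) *and* a fold change (default
2×) over the interior baseline (positions 11–25 of the 5′ C→T and 3′ G→A
curves).  The floor rejects sparse-coverage artifacts; the fold change
rejects uniformly noisy mappings.  With zero terminal coverage the call is
reported as undetermined rather than false.

## The synthetic-data generator

`adnasim` emulates a nonamplified shotgun sample of an ancient specimen:

* **Genomes** — i.i.d.-uniform by default (order-2 Markov optional);
  contaminants may be independent, user-supplied, or substitution-mutated
  copies of a named ancestor (for intra-similarity scenarios).
* **Fragments** — truncated log-normal lengths (μ = ln 70, σ = 0.35,
  floor 25, cap read length + 50), uniform starts, uniform strand; minus
  fragments are reverse-complemented.
* **Damage** — C at 5′ offset i deaminates with probability
  `baseline + (d5 − baseline)·λ^i`, G at 3′ offset j with the mirrored
  rule; defaults d5 = d3 = 0.30, λ = 0.5, baseline = 0.01.  This is a
  simplified exponential-decay model, not a nick-based chemistry model: it
  reproduces the terminal C→T / G→A signature the classifier keys on, with
  closed-form per-position expectations that make recovery testable.
  Damage applies to the endogenous source only by default — contaminants
  model modern DNA, which is exactly the contrast the damage call exists to
  detect — and is settable per contaminant.
* **Sequencing** — fragments truncated to 101 bp reads, per-base
  substitution error (default 10⁻³), Gaussian Phred qualities
  (mean 36, sd 3, clipped to [2, 41]).
* **Truth** — every read carries its source, 0-based start, strand and
  pre-damage fragment; the truth SAM stores reverse reads
  reference-oriented with the 0x10 flag; the manifest reconciles per-source
  read counts with the total.  All outputs are pure functions of the
  configuration.

What the generator does *not* emulate — indel damage, GC bias, chimeras,
platform quality drift, repetitive genome structure, real taxonomic
divergence patterns — bounds what passing tests show: they validate the
estimator's arithmetic, its discrimination on known ground truth, and its
damage-recovery calibration, not performance on real archives.

## Validation problem sizes

The test suite exercises the pipeline at desk scale, sizes chosen once as
representative of a small simulation study: self-vs-null discrimination at
50 kb genomes with 20× error-free coverage (5 seeds); divergence
monotonicity at 20 kb / 10× across substitution rates 0–0.30 (10 seeds);
contaminant detection at 5% contaminant reads against 10 decoys (20
seeds); read filtering with 400 + 400 reads per seed; damage recovery from
30,000 fragments (the ±0.02 check band is ~3.8σ of the estimator's
binomial noise at that depth); inverted-repeat segment detection with two
reverse-complement copies of a 5 kb block.  `scripts/acceptance.py` re-runs
the same measurements end-to-end from a single seed.

## Known limitations

* Per-read scoring direction is a choice: the model trains on the reference
  and scores reads (one training pass, many cheap evaluations); the
  opposite direction (sample-trained model scoring the reference
  windows) is not implemented.
* The tolerant-model repair schedule and the cache-bound eviction rule
  (frequency-based, not LRU) are this package's concrete readings of
  under-specified mechanisms; both are isolated behind their configs.
* NRS clipping is applied to NRC before the percent complement, so
  anti-similar sequences (NRC > 1) are indistinguishable from unrelated
  ones.
* No abundance estimation, taxonomic aggregation, or competitive read
  assignment: intra-similarity analysis is the intended disambiguation
  tool.
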