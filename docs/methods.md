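# Methods

This note documents the models and procedures implemented in `comotif`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Gene classification

Genes are split by the knockout/wild-type signal ratio: down-regulated
when `ko/wt < 0.5`, non-regulated when `|ko/wt − 1.0| ≤ nonreg_tol`.
`nonreg_tol` defaults to 0 (an exact ratio of 1), which only synthetic
or pre-filtered tables satisfy; real array data needs a small positive
tolerance. A `manual_down` list forces known-misassayed genes into the
down-regulated set. Promoter windows are 0-based half-open
`[tss−upstream, tss+downstream)` with defaults 2000/300, so a complete
window is 2300 nt and the TSS base is the first downstream position;
windows are clipped at sequence bounds rather than erroring.

## Conservation masking

Pairwise alignment is local Smith–Waterman–Gotoh with affine gaps: a
gap of length L costs `gap_open + (L−1)·gap_extend`. Defaults follow
EMBOSS-water conventions — match +5, mismatch −4, gap open −10, gap
extend −0.5 — because the original programs' "default parameters" are
not recoverable; all four are configurable. `N` mismatches everything,
including `N`. The implementation is a three-matrix DP (numba-compiled
when available, exact pure-Python fallback otherwise) and is tested
against an independent brute-force DP and Biopython's `PairwiseAligner`.

Species are retained when their alignment to the mouse promoter scores
strictly above 200 over 500–1000 alignment columns (inclusive bounds;
"consensus length" is the number of local-alignment columns). The
multiple alignment is a mouse-centred star: each retained species'
local alignment is merged into a master alignment ("once a gap, always
a gap"); the unaligned flanks of non-reference species are dropped.
With at most seven mammalian species per group, a full guide-tree
progressive alignment adds nothing a star alignment does not.

Refinement is iterative leave-one-out: each row is realigned against
the profile of the others by an exact linear-gap DP, and a realignment
is kept only when the sum-of-pairs (SP) score improves, so SP is
non-decreasing and the procedure terminates at a fixed point or after
`max_rounds` (default 10; the pipeline uses 2). SP uses **linear** gap
costs (gap-vs-base = `gap_open`, gap-vs-gap = 0): a single well-defined
objective keeps the monotonicity guarantee exact and lets small
alignment optima be verified by an exhaustive three-sequence DP in the
test suite. Pairwise alignment itself stays affine.

Masking: a reference position survives when at least `min_agree_frac`
(default 0.5) of the covering non-reference rows carry the same base
(`N` counts as coverage but never as agreement), and surviving runs
shorter than `min_run` (default 6, a typical core-motif width) are
masked too. "Non-conserved" has no published operational definition
here, so both knobs are explicit configuration. Masked output always
has exactly the reference promoter's length.

## ZOOPS motif discovery

The finder is a zero-or-one-occurrence-per-sequence mixture: with
probability `1−γ` a sequence is pure background; otherwise one site,
uniform over N-free start positions on both strands, is emitted by the
PWM. EM alternates exact site posteriors with PWM/γ re-estimation.
Columns carry a pseudocount of 0.25 per letter (Dirichlet-MAP M-step),
so the monotone EM objective is the penalized likelihood — asserted
non-decreasing at every iteration. Convergence: relative objective
change < 1e-6 or 200 iterations. Background frequencies are estimated
from the input unless supplied.

Seeding is deterministic rather than randomized so results reproduce
without a seed: candidate width-mers are ranked by exact occurrence
count on both strands, the top `seed_pool` (default 100) are scored by
a single EM iteration, and the best `n_refine` (default 5) run to
convergence; ties break lexicographically on the consensus. Exhaustive
seeding from *every* distinct width-mer (`seed_pool=None`) is used for
small inputs such as the nine binding sequences, but is quadratic in
input size and impractical at 2300-nt promoters — the two-stage ranking
is the scalable approximation of the same idea. The final model is
reported in the orientation of the majority site strand (lexicographic
tie-break), which reproduces the printed width-8 consensus `CTGCTGAC`
from the bundled binding sequences.

Multi-width discovery (widths 6–18, ten per width → up to 70 motifs)
masks each motif's called sites with `N` before the next rank, a
stand-in for how a batch motif finder separates its top-ten reports.
The ranking statistic is the ZOOPS log-likelihood ratio against
background. The degenerate consensus lists, per column, every letter
with probability ≥ 0.2 (bracketed when more than one); 0.2 reproduces
the 1–3-letter brackets of the reference motif table.

## Scanning

*PWM mode*: per sequence, the best log-odds score over both strands is
converted to a p-value from the **exact** null distribution of the
single-window score, computed by DP over a discretized score lattice
(1000 bins across the log-odds range) under the background model, then
corrected for `m` scanned windows as `1−(1−p₁)^m`; the E-value is
`p × n_sequences`. Windows containing `N` are skipped. The lattice DP
matches exhaustive enumeration over all 4^w words in tests. The
product-of-p-values combination used by multi-motif search suites is
deliberately not reproduced: the pipeline filters on one motif family
at a time, so the single-motif best-hit E-value is the relevant score.

*String mode*: plain or bracketed consensi match with at most
`substitution_budget(width)` mismatches — 1 for widths 6–8, 2 for
10–12, 3 for 14–16, 4 for 18+, unlisted widths inheriting the nearest
lower width's budget. The "90% minimum match" convention conflicts
with this schedule at short widths; the explicit schedule is binding.
`N` in the sequence never matches. Minus-strand hits are reported in
forward coordinates; overlapping hits are all reported.

Target-gene selection keeps a gene when its minimum E-value over the
binding-motif family is strictly below 21 in mouse **and** a hit exists
in both mouse and human promoters. The unusual threshold of 21 is
treated as a plain numeric cutoff on our E-value; its original meaning
cannot be reconstructed.

## ORI

The published equation for the over-representation score survives only
as its variable definitions, so the implemented formula is a
reconstruction consistent with every stated property (scores > 1
meaningful; high score = even presence across the target group;
group-size normalization):

    ORI = ((Patt_p / S_p) / (max(Patt_np, 1) / S_np)) · (N_p / N_promoter)

It is strictly increasing in `Patt_p` and `N_p` and non-increasing in
`Patt_np`. The `max(·,1)` pseudocount keeps motifs absent from the
non-regulated group finite; a `+1` smoothing variant is selectable, and
the formula lives in one function so it can be swapped. The {1,2}
absence/presence coding is preserved in all I/O files.

Occurrence-matrix columns merge when their presence vectors are
identical **and** the consensi are reverse complements or substrings of
one another (or of the reverse complement) — the same signal read
through related sequences. Binding-family (MafB-tagged) motifs are
never merged so their column stays interpretable on its own.

## Log-linear graphical model

The k candidate motifs define a 2^k binary contingency table (variable
0 is the least significant bit of the cell index; k ≤ 16). A
hierarchical model's generating class is the clique set of its
independence graph; fitting is classical IPF, converged when every
generator marginal matches within `tol` (1e-8, max 2000 cycles).
Deviance is G² with zero-observed cells contributing zero (random
zeros only; structural zeros are out of scope). Residual degrees of
freedom are `(2^k−1) − rank` of the centered ±1 indicator design;
distinct interaction terms are characters of Z₂^k and hence orthogonal
over the full lattice, so the rank equals the number of distinct terms
(verified numerically in tests).

Backward elimination starts from the complete graph. Each remaining
edge is tested by fitting the graphical model without it and comparing
against the **current** model (stepwise single-edge test); the
largest-p edge is removed while p ≥ α (default 0.001). The trace also
records the cumulative deviance of each reduced model against the full
model — both views are reported because either stopping convention is
defensible; the stepwise rule is binding. The full model defaults to
saturated (an all-two-way full model is selectable): with 10 binary
variables the saturated model has 2^10−1 = 1023 parameters, consistent
with the ~1001-df final-model tests this style of analysis reports.
Star tables mark a gene × combination cell when **both** motifs of the
edge are present in that gene's promoter; this pairwise rule reproduces
the 15-gene GATA-1 count on the bundled star-matrix fixture. Non-convergent
candidate fits are skipped with a warning.

## Synthetic data

The generator's defaults are the emulated study's conditions: 18
down-regulated versus 211 non-regulated genes, 4 species, 2300-nt
windows. Down-group presence vectors are sampled from the exact
enumeration of `P(x) ∝ exp(Σ mainᵢxᵢ + Σ coefᵢⱼxᵢxⱼ)` (k ≤ 12) — exact
enumeration rather than Gibbs sampling so tests carry no MCMC
convergence caveats. Non-regulated genes draw presences independently
(default rate 0.2) to keep the group contrast controllable. Promoters
are i.i.d. background (GC fraction 0.5) with a centred conserved core
(default 800 nt, inside the 500–1000 column filter band); one site per
present motif is sampled from its PWM at a non-overlapping offset in
the core; orthologues copy the reference with substitution probability
0.3 outside the core and the site-mutation rate (default 0.05) inside
it. Planted PWMs put `1−μ` on the consensus base. Expression ratios
are U(0.05, 0.5) for the down group and exactly 1.0 otherwise, with
signal magnitudes in the emulated study's bands.

What the generator does **not** model: phylogenetic (tree-structured)
substitution, indels between orthologues, GC heterogeneity and repeats,
microarray noise, and motif positional preference. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real promoter data, where
alignment and background-model violations will matter.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at reduced sizes
(promoters of a few hundred nt, 2–3 widths, tens of genes) and the
statistical components at their natural sizes (k = 6, n = 400, 20
replicates for structure recovery; 200 random pairs for the alignment
oracle; 50 sites for PWM recovery) — large enough for the measured
properties to be stable across seeds while keeping a full run in
seconds. All randomness flows from a single integer seed
(`numpy.random.default_rng`); discovery and elimination are themselves
deterministic with documented tie-breaks, and a pipeline rerun with the
same inputs and seed is byte-identical.

## Known limitations

- Star-alignment flanks: only the locally aligned region of each
  non-reference species contributes to the MSA, so conservation outside
  the reference-anchored alignment is invisible.
- The exact-null scan p-value discretizes the score lattice; p-values
  are exact to the lattice (≲0.1% of the score range), not to machine
  precision.
- Backward elimination re-fits every candidate edge per step; beyond
  k ≈ 12 variables the 2^k tables and clique enumeration grow quickly.
- The ORI formula is a reconstruction (flagged above), not a verified
  transcription of the published equation.
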