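# Methods

## Model

The package models the length distribution of open reading frames (ORFs)
in a double-stranded DNA sequence as a six-component mixture of geometric
distributions, one per relative reading frame i ∈ {+1, +2, +3, −1, −2,
−3}. The frame of an annotated gene is +1 by convention; −1 is the
antiparallel in-register frame whose codons occupy the same forward
triplets read on the other strand.

The only fitted quantity is the codon usage π: per-codon frequencies in
the concatenation of all annotated ORFs on their coding strands,
**including each gene's terminal stop codon**. Including the stop makes
ρ₊₁ = 1/(mean gene length in codons + 1) an exact structural identity
(each gene contributes exactly one stop), which is what ties the frame
+1 component to the annotated gene-length scale.

Frame distributions:

* +1: π itself. −1: q(c) = π(rc(c)).
* ±2/±3: the frame-shifted triplet process over an IID codon stream is a
  64-state Markov chain with memory one. For +2, a frame codon is the
  last two nucleotides of codon k followed by the first nucleotide of
  codon k+1, giving

      Q((a,b,c) → (d,e,f)) = [π(c,d,e) / m₁(c)] · m₁(f),

  with m₁ the first-position nucleotide marginal of π; +3 analogously
  with the first-two-position marginal m₁₂. −2/−3 apply the same
  construction to q. These are the unique memory-one laws of the shifted
  process; their stationary distributions have the closed forms m₂₃⊗m₁
  (+2) and m₃⊗m₁₂ (+3), which we use both as an independent cross-check
  of the linear-solve stationary distribution and to fill unreachable
  rows (below). ρ_i and τ_i are the stop-set and start-set masses of the
  frame-i distribution.

Counting: with a two-state occupancy chain (enter an ORF on a start
codon, leave on a stop), the in-ORF fraction is α_i = τ_i/(τ_i+ρ_i), the
expected dwell is 1/ρ_i codons, and the expected ORF count per frame is
N_i = n_i τ_i ρ_i/(τ_i+ρ_i) with n_i = ⌊genome bp/3⌋ for every frame
(the ±1-position differences between frames are negligible at genome
scale). Mixture weights are w_i = N_i/ΣN_j.

Length support: L counts codons from the start codon inclusive to the
stop exclusive, so the minimum ORF (start immediately followed by stop)
has L = 1 and P(L = l) = Σ w_i (1−ρ_i)^(l−1) ρ_i on l ∈ {1, 2, …}, with
E[L] = Σ w_i/ρ_i. The constrained gene-count prediction uses the frame
+1 tail with exponent (min_len − 1); the serialized model records this
convention as `tail_exponent_offset = 0`.

Survival: S(l) = 1 − (1 − P(L ≥ l))^N with N the model's expected total
ORF count rounded to the nearest integer (a flag allows fractional-trial
exponentiation). Per-frame variants use N_i and the frame-i geometric
tail; they drive the shadow-candidate report. The p-value length limit
is the smallest l with S(l) ≤ p, found by bisection (S is monotone
non-increasing in l). The limit is reported in codons; the CLI also
prints bp as 3·(l+1).

## Assumptions and their consequences

* Codons in frame +1 are IID. Real genomes have neighbour correlations;
  the stationarity/average-case treatment of frames ±2/±3 makes the
  frame probabilities exact for the IID stream (verified against
  simulation) but the *count* formula N_i is an approximation there:
  stop occurrences in shifted frames are weakly autocorrelated, which
  moves realized per-frame counts a few percent from N_i. The effect
  vanishes for product-form usages and grows with codon-level bias.
* The chromosome is treated as linear even when circular; ORFs spanning
  the origin (a handful per genome) are not emitted. ORFs truncated by
  the sequence end without a stop are discarded; only stop-terminated
  ORFs are counted, matching the geometric support.
* Intergenic sequence is ignored by the model: the usage comes from
  annotated ORFs only, and every codon position is treated as eligible
  for every frame.

## ORF definition and scanning

An ORF is the longest run of in-frame triplets from a start codon (NTG
set {ATG, GTG, TTG, CTG} by default) to the next in-frame stop: one ORF
per (frame, stop), starting at the first start codon after the previous
in-frame stop. Annotated ORFs instead begin at the annotated start,
ignoring upstream starts; a scanned ORF is identified with a gene when
it shares the gene's stop codon. Minus-strand frames are labelled by the
forward phase of the codon grid so that −1 is in-register with +1; for
relative-frame assignment of non-annotated ORFs the label is derived
from d = (phase_na − phase_a) mod 3 in the annotated ORF's orientation,
mapping d = 0→−1, 1→−3, 2→−2 on the opposite strand (one-nucleotide
shifts along the minus strand's 5'→3' direction lower the forward
phase). Overlap ties are broken by largest overlap in bp, then longer
aORF, then lower start coordinate.

## Numerical choices

* Stationary distributions: direct least-squares solve of (Qᵀ−I)d = 0
  with a normalization row, restricted to the unique closed
  communicating class; residual tolerance 10⁻¹⁰ with power iteration
  (tol 10⁻¹⁴, ≤10⁵ iterations) as fallback. Multiple closed classes
  raise an error (the ergodicity premise fails).
* Zero-probability codons (common in small gene subsets) leave some
  chain states unreachable; their rows are filled with the frame's
  unconditional (closed-form) codon distribution so the matrix stays
  stochastic without affecting the stationary law on the reachable
  class.
* Degenerate toy usages may give ρ_i = 0 or τ_i = 0 in some frame; the
  model builds with a warning (survival quantities are then degenerate
  in that frame) and errors only when τ_i + ρ_i = 0.
* Quantiles of observed ORF lengths use the lower nearest-rank rule
  (ceil(q·n)-th smallest), appropriate for integer codon lengths; the
  model quantile inverts the mixture CDF by bisection.
* IUPAC ambiguity codes are resolved uniformly at random over the
  symbol's substitution set with a caller-supplied seed (default 0):
  this preserves expected base composition and is reproducible.
  Genes whose span is not a multiple of 3 or whose terminal codon
  regions contained ambiguity symbols in the raw sequence are filtered
  out before usage estimation.

## Synthetic data

`rcodon.simulate` draws ⌊length/3⌋ IID codons from a usage — the model's
defining null. `rcodon.synthetic_usage(gc_content, bias, seed)` supplies
bacterial-like usages for simulation studies: a product of per-position
nucleotide frequencies (overall GC set by `gc_content`, purine-rich
first positions) times log-normal codon-level noise of scale `bias`
(default 0.4, giving codon-preference ratios typical of bacteria;
0 yields an exact product form where all six frames collapse to one
distribution). What this emulates: the composition-dominated structure
of real codon usage across the GC spectrum. What it does not: amino-acid
constraints, gene-length distributions (real genes are far longer than
geometric frame +1 ORFs, so annotated-gene counts are over-predicted for
real genomes below ~80 codons), operon structure, or strand asymmetries.
Passing simulation tests therefore validates the probabilistic machinery
and its internal consistency, not annotation-level accuracy on real
chromosomes.

`rcodon.make_fixture` writes minimal valid GenBank files (CDS features
on either strand with spacers) for round-trip tests.

## Test problem sizes

End-to-end consistency checks run three usages (GC 35/50/65%, bias 0.4)
by three seeds at 3 Mb — bacterial chromosome scale — expecting total
counts within 3%, per-frame counts within 5%, the 75% quantile within ±1
codon and the mean within 2%. Markov-chain validation uses 10⁶-codon
simulations; because the largest of thousands of per-codon z-scores
exceeds 4σ with appreciable probability even for an exact model, the 4σ
rule is applied in replicated form (a deviation must recur with the same
sign in two independent realizations) with a 6σ single-run cap.
Survival-limit calibration uses 50 realizations at 1 Mb against the 95%
binomial band around p = 0.05. The acceptance script runs one 5 Mb study
plus 25 calibration realizations at 1 Mb.

## Known limitations

* Real-genome headline numbers require local GenBank files; nothing is
  downloaded.
* Annotated-gene count predictions inherit the model's geometric frame
  +1 length law, which real gene-length distributions violate below
  ~80 codons; minimum-length constraints partially compensate.
* Re-estimating a usage from an Rcodon realization's frame +1 ORFs
  carries an O(ρ) conditioning bias (interior codons are stop-free), so
  parameter-level round trips agree only to ~10–15% for short-ORF
  usages, while count-level predictions close the loop to a few
  percent.
* No multiple-testing correction is applied to shadow-candidate
  survival p-values (per-frame trial counts are reported so users can
  apply their own), and no confidence intervals are attached to model
  parameters, which are treated as plug-in quantities.
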