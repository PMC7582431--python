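# Methods

## Problem and model

`lncloc` predicts which of four subcellular compartments — cytoplasm,
nucleus, ribosome, exosome — a long non-coding RNA (lncRNA, > 200 nt)
predominantly occupies, from sequence alone. The task is a small-sample,
strongly imbalanced multi-class problem: experimentally annotated corpora
have a few hundred sequences, with the smallest compartment an order of
magnitude rarer than the largest. The approach is multi-source feature
fusion: several complementary views of the sequence are extracted,
aggressively filtered, and fed to a kernel classifier.

### Feature blocks

**fea.Tuple — raw 8-mer counts (65,536 columns, sparse).** Overlapping
8-mer occurrence counts, lexicographic order A < C < G < U. Stored as a
CSR matrix: a transcript of length m touches at most m − 7 of the 65,536
words, so densifying the block would waste memory and the binomial filter
operates directly on counts.

**fea.Bio — 70 named columns.** The registry is pinned so the block width
is always exactly 70:

| group | width | definition |
|---|---|---|
| dinucleotide EDP | 16 | S_i = −(1/H) f_i ln f_i of 2-mer frequencies, H the Shannon entropy; components sum to 1 |
| ORF length, coverage | 2 | longest forward-frame AUG…stop span (stop included); coverage = ORF/length |
| amino-acid EDP of the ORF | 20 | EDP of translated codon (amino-acid) frequencies, stop excluded; zeros when no ORF |
| hexamer usage bias | 4 | per class j: mean over in-frame ORF hexamers of ln(F_j/F), F the pooled other-class table |
| hexamer log-distances | 3 | (1/n) Σ ln(freq_seq/freq_class) over observed whole-sequence hexamers, against the cytoplasm and nucleus profiles, plus their ratio |
| UTR / GC | 5 | 5′/3′ coverage and GC of the regions flanking the ORF, plus pooled non-ORF GC |
| Fickett | 8 | per base: max/min(+1) of the three codon-phase counts; composition percentage |
| EIIP spectrum | 7 | s[round(N/3)], mean energy, SNR, Q1, Q2, max, min of the DFT power spectrum of the EIIP signal |
| MFE | 2 | (pseudo-)minimum free energy, raw and per nucleotide |
| structure log-distances | 3 | log-distances of the acguD derived sequence (k = 1) to the cytoplasm/nucleus profiles, plus ratio |

Natural logarithms are used everywhere; the EDP is base-invariant because
the base cancels in the ratio.

### Design choices in the feature definitions

- **ORF scan**: forward strand, all three frames, first in-frame stop per
  AUG, longest span wins, ties to the smallest start. Matches the common
  CPAT/LncFinder convention and is deterministic.
- **In-frame hexamers** step 3 from the ORF start over the coding part
  (the stop codon contributes no hexamer); **log-distance hexamers** step 1
  over the whole sequence, normalized by the total window count, summing
  over observed words only.
- **Hexamer pseudocount**: 1/4096 added per cell before normalizing (total
  pseudomass one count), a scale-free floor ≈ 1/(4096·T) that vanishes as
  the table total T grows. A class with no ORFs falls back to a uniform
  table with a warning.
- **Fickett**: the 8 raw position/composition values are used directly; the
  original lookup-table TESTCODE score is deliberately not computed.
- **Spectrum**: the period-3 bin is k = round(N/3) (N/3 is rarely an
  integer). Quartiles are linear-interpolation quantiles computed excluding
  the DC bin, whose magnitude dwarfs the rest and only restates base
  composition; Q3 is available but not in the default registry. Both
  choices are configurable.
- **SSE rules**: paired → stem `s`; an unpaired run whose two paired
  neighbours pair with each other → hairpin `h`; a run whose flanking
  partners are adjacent (partner(left) = partner(right)+1, a one-sided
  helix interruption) → bulge `b`; everything else (interior loops,
  multiloops, exterior) → loop `l`. The four letters are standard; the
  decision rules are frozen here as the package's definition and
  unit-tested as such.
- **Structure featurization**: each of the six derived sequences gets
  (logDistCyto, logDistNuc, ratio) at k = 1 and k = 4 — six values per
  derived type — plus raw and length-normalized MFE. The default fea.Bio
  registry takes the acguD/k=1 triple, which keeps the block at 70 columns;
  the full vector is available from `structure_feature_vector`.
- **Ratio guards**: a zero nucleus distance makes the cyto/nucleus ratio 1
  (with a warning); degenerate EDP inputs (zero entropy) return the uniform
  profile with a warning.
- **Alphabet**: internal alphabet is RNA {A,C,G,U}; T maps silently to U;
  ambiguity codes are dropped by default (k-mer and EDP formulas assume a
  4-letter alphabet), with seeded-random and strict-error policies
  available. Coordinates are 0-based half-open internally.

### Folding engines

`external_mfe` shells out to ViennaRNA's `RNAfold` and parses the
dot-bracket and energy; `nussinov` is a built-in base-pair maximization
(Watson–Crick + GU wobble, minimum hairpin loop 3, pseudo-MFE −1 per pair,
traceback ties toward the smaller 5′ index). The Nussinov engine is the
default because it is deterministic and dependency-free; it is validated
against exhaustive enumeration of nested pairings at small lengths.
Folding cost grows cubically with length, so by default only the 5′-most
`fold_window = 500` nt are folded and the remainder is reported unpaired;
set `fold_window=None` for full-length folding. Pseudoknots are rejected.

### Feature selection

**Binomial confidence (fea.Tuple).** With q_j = m_j/M the prior share of
class j in the total 8-mer mass, an 8-mer seen N_i times overall and n_ij
times in class j gets the upper binomial tail
p = P(X ≥ n_ij), X ~ Binomial(N_i, q_j), computed with the numerically
stable survival function, confidence C_ij = 1 − p, and C_i = max_j C_ij.
Features are ordered by ascending minimum tail probability (ties by index)
rather than by C_i directly, so the ranking stays stable when many
confidences round to 1.0 in double precision. Counts are token
occurrences pooled over sequences, not per-sequence presence.

**IFS.** Features are added along the ranking in batches (default 50 at
the 65,536-column scale), each prefix scored by stratified-CV accuracy of
a linear-kernel SVM on the training split only; selection stops after
max(1, patience) consecutive non-improving steps (patience default 3) and
returns the best prefix. Batch size, patience, fold count, and the
evaluator are configurable; the candidate pool is capped at 1000 by
default for tractability.

**Autoencoders + RFE (fea.Bio).** The 70 columns are standardized, then
re-encoded by two independently trained symmetric autoencoders —
70→64→32→64→70 and 70→64→64→70 — giving a 32- and a 64-dimensional code,
concatenated to 96 features. Implementation: `MLPRegressor` fitted to
reconstruct its input (ReLU hidden units, linear output, Adam, fixed seed,
plateau stopping at 500 epochs max), with the bottleneck read off by a
manual forward pass. Recursive feature elimination then removes one
feature per round under an XGBoost ranker (learning rate 0.1, 50 trees)
until 32 remain; the elimination sequence is a full permutation of the 96
columns, ordered least- to most-important.

### Classifier and evaluation

The selected tuple and bio features are concatenated, standardized, and
fed to an RBF SVM (libsvm's native one-vs-one multi-class training;
per-class scores are reported on the one-vs-rest scale). C and γ are
grid-searched over powers of two, C ∈ [2⁻⁵, 2¹⁰] and γ ∈ [2⁻¹⁵, 2⁰],
selecting by stratified-CV accuracy. Metrics: accuracy, per-class
precision/recall (0/0 defined as 0 and flagged — the smallest class easily
has empty prediction sets), and macro F1 (mean of per-class F1, n = number
of classes). Outer cross-validation is stratified, and *all* fitting —
hexamer and structure profiles, binomial/IFS, scalers, encoders, RFE,
SVM — happens inside each training fold; only per-sequence, label-free
folding is shared across folds, so no label information can leak.

## Synthetic data

The generator emulates the statistical structure of an annotated lncRNA
localization corpus, not its sequences: four imbalanced classes (defaults
424/156/43/30, the benchmark shape), lengths uniform in [200, 3000] nt,
per-class nucleotide composition (GC shifts of −0.05/+0.05/+0.10/−0.10
around uniform for cytoplasm/nucleus/ribosome/exosome), planted complete
ORFs (AUG + sense codons + stop, 90–300 nt, per-class probability
0.9/0.5/0.8/0.5), and three fixed class-specific 8-mer motifs planted with
probability 0.9 each. It is exactly seed-deterministic and honors class
counts exactly.

What it does **not** emulate: phylogenetic correlation and shared repeat
families, genuine localization signals (zipcode elements), realistic
length/GC joint distributions, sequencing artifacts, or residual redundancy
(the 80% CD-HIT cutoff used for real corpora is documented but external).
Passing recovery tests therefore demonstrates that the machinery recovers
planted signal under controlled conditions, not field performance on real
transcripts.

## Problem sizes used in tests and acceptance

Corpora of 46–72 sequences of 200–400 nt, 3 outer CV folds and 3-fold
inner CV (a training fold holds only 4 exosome members, so 5 inner folds
would be infeasible at this scale); 20 seeds for the binomial-rank
recovery, 10 for RFE recovery, 3 for end-to-end CV. These sizes are the
package's choice of a desk-scale experiment; the pipeline defaults (5-fold
inner CV, 10-fold comparison CV, full grid) remain the full-scale
protocol. Evaluating against a real annotated corpus requires an
RNALocate-derived download (with CD-HIT redundancy removal at 80%) and is
out of scope for this package's test suite.

## Known limitations

- The Nussinov pseudo-MFE is a pair count, not a thermodynamic energy; use
  `external_mfe` when ViennaRNA is available and energies matter.
- Hexamer-bias features are emitted once per class (4 columns); at predict
  time the sequence's own class is unknown, so all four are provided and
  the classifier weighs them.
- With ≤ 6 sequences in the smallest class, grid-searched SVMs frequently
  collapse the smallest compartments into the majority class; class-weighted
  scoring is available in the config as the imbalance lever (oversampling
  is deliberately not implemented).
- The autoencoders are trained per fold on few samples; their encodings
  are reproducible (fixed seed) but not transferable across corpora.
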