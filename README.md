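# lncloc

Sequence-based prediction of the subcellular localization of long
non-coding RNAs (lncRNAs): cytoplasm, nucleus, ribosome, or exosome.

Where a lncRNA accumulates constrains what it can do — nuclear transcripts
act in chromatin regulation, cytoplasmic ones can titrate miRNAs or be
targeted by RNA inhibitors — but experimentally annotated localization data
are scarce and heavily imbalanced across compartments. `lncloc` is a
desk-scale tool for this small-sample multi-class problem: it extracts
multi-source features from the sequence, filters them hard, and classifies
with a kernel machine. It is aimed at computational biologists who want
either the end-to-end predictor or the individual feature extractors.

## Method

Two feature blocks are built from each transcript S = N₁N₂…N_m over
{A,C,G,U}:

- **fea.Tuple** — sparse raw 8-mer occurrence counts (4⁸ = 65,536 columns).
- **fea.Bio** — 70 named features: the entropy density profile (EDP)
  S_i = −(1/H)·f_i·ln f_i of dinucleotide frequencies (16); longest-ORF
  length and coverage ORF(S)/l(S) (2); amino-acid EDP of the translated ORF
  (20); per-class in-frame hexamer usage bias μ(s) = mean ln(F_j/F) (4);
  whole-sequence hexamer log-distances to the cytoplasm/nucleus profiles
  and their ratio (3); UTR coverage/GC (5); Fickett position and
  composition values (8); EIIP power-spectrum summaries including the
  codon-periodicity SNR = s[N/3]/Ē (7); minimum free energy raw and per
  nucleotide (2); and log-distances of the structure-derived acguD sequence
  (3).

fea.Tuple is filtered by binomial-distribution confidence — for 8-mer i and
class j with prior q_j = m_j/M, the upper tail p(n_ij) = P(X ≥ n_ij),
X ~ B(N_i, q_j), gives C_ij = 1 − p and C_i = max_j C_ij — followed by
incremental feature selection (IFS) until cross-validated accuracy stops
improving. fea.Bio is standardized, re-encoded by two symmetric
autoencoders (bottlenecks 32 and 64, concatenated to 96), and reduced to 32
features by recursive feature elimination under an XGBoost ranker. The
concatenated features feed an RBF SVM (one-vs-one) grid-searched over
C ∈ [2⁻⁵, 2¹⁰], γ ∈ [2⁻¹⁵, 2⁰], evaluated by stratified cross-validation
with accuracy, per-class precision/recall, and macro F1.

Secondary structures come from ViennaRNA's `RNAfold` (`external_mfe`) or a
built-in Nussinov base-pair-maximization engine (default); structures are
annotated with stem/bulge/loop/hairpin labels and expanded into six derived
sequences (SSE full/abbreviated, paired–unpaired, acguD, acguS, acgu-ACGU).
See `docs/methods.md` for definitions, defaults, and limitations.

A synthetic-corpus generator (`lncloc.seq_io.generate_synthetic_dataset`)
emulates the benchmark's statistical shape — imbalanced classes, 200–3000 nt
lengths, class GC shifts, planted ORFs and class-specific 8-mer motifs — so
the whole pipeline is exercisable without any external download.

## Worked example

```python
from lncloc import (PipelineConfig, SyntheticConfig, cross_validate,
                    generate_synthetic_dataset)

corpus = generate_synthetic_dataset(SyntheticConfig(
    n_per_class={"cytoplasm": 42, "nucleus": 16, "ribosome": 8, "exosome": 6},
    length_range=(200, 400),
    seed=1,
))
config = PipelineConfig(seed=1, grid_cv_folds=3, ifs_cv_folds=3)
result = cross_validate(corpus, config, folds=3)

print(f"pooled accuracy : {result.pooled.accuracy:.3f}")
print(f"mean macro F1   : {result.mean_macro_f1:.3f}")
print("recall by class :", {c: round(r, 2) for c, r in result.pooled.recall.items()})
print(result.pooled.confusion)
```

prints

```
pooled accuracy : 0.806
mean macro F1   : 0.543
recall by class : {'cytoplasm': 1.0, 'exosome': 0.0, 'nucleus': 0.88, 'ribosome': 0.25}
           cytoplasm  exosome  nucleus  ribosome
cytoplasm         42        0        0         0
exosome            6        0        0         0
nucleus            2        0       14         0
ribosome           6        0        0         2
```

The pooled 3-fold accuracy (0.806) is well above the majority-class rate
(42/72 ≈ 0.583) because the selection machinery recovers the planted
class-specific 8-mers and composition shifts; the low macro F1 shows the
flip side of hard imbalance — with only 4 exosome training sequences per
fold, the smallest compartments collapse into cytoplasm, exactly the regime
the method's filtering is designed to mitigate at realistic corpus sizes.

The same pipeline is available from a shell:

```bash
lncloc synth --seed 1 --n cytoplasm 42 --n nucleus 16 --n ribosome 8 --n exosome 6 \
       --length-range 200 400 --out-fasta corpus.fa --out-labels corpus.tsv
lncloc train corpus.fa corpus.tsv --seed 1 --folds 3 --out-bundle model.joblib
lncloc predict model.joblib corpus.fa --out predictions.tsv
lncloc evaluate corpus.tsv predictions.tsv --out report.json
```

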