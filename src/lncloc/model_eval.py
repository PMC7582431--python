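"""Feature assembly, pipeline training, prediction, and evaluation.

Features form two blocks.  ``fea.Tuple`` is the sparse raw 8-mer count
matrix (65,536 columns).  ``fea.Bio`` is a pinned 70-column registry:
dinucleotide EDP (16), ORF length and coverage (2), amino-acid EDP of the
ORF (20), per-class hexamer usage bias (4), whole-sequence hexamer
log-distances (3), UTR coverage/GC (5), Fickett (8), EIIP spectral
summaries (7), MFE raw and per nucleotide (2), and acguD structure
log-distances at k = 1 (3).

Training fits, in order: hexamer and structure profiles on the training
data; binomial confidence + IFS on the tuple block; standardization, the
32/64 autoencoder pair, and RFE down to 32 features on the bio block; and a
grid-searched RBF SVM (one-vs-one multi-class, C in 2^-5..2^10, gamma in
2^-15..2^0) on the concatenated selected features.  Prediction replays the
stored transformations in the same order.  Cross-validation refits
everything inside each training fold; only per-sequence, label-free folding
is shared across folds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import kmer_features, orf_features, physchem_features, structure_features
from .errors import NotFittedError, StratificationError
from .feature_selection import (
    BinomialRanking,
    EncoderPair,
    FeatureScaler,
    SelectionResult,
    binomial_confidence,
    ifs_select,
    rfe_select,
    train_autoencoders,
)
from .kmer_features import all_kmers, kmer_count_matrix
from .orf_features import AA20, HexamerTable, build_hexamer_tables
from .seq_io import CLASSES, LabeledDataset, NucleotideSequence
from .structure_features import (
    DerivedSequences,
    SecondaryStructure,
    StructureProfiles,
    derive_sequences,
    fold,
)

#: Shortest sequence the predictor will featurize; shorter records are
#: skipped per-record with a reason rather than failing the batch.
MIN_PREDICT_LENGTH = 10

BIO_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"EDP2_{w}" for w in all_kmers(2)]
    + ["ORF_LENGTH", "ORF_COVERAGE"]
    + [f"EDPORF_{a}" for a in AA20]
    + [f"HEXBIAS_{c}" for c in CLASSES]
    + ["HEX_LOGDIST_CYTO", "HEX_LOGDIST_NUC", "HEX_RATIODIST"]
    + ["COV_5UTR", "COV_3UTR", "GC_5UTR", "GC_3UTR", "GC_NONORF"]
    + [f"FICKETT_{b}_POS" for b in "ACGU"]
    + [f"FICKETT_{b}_PCT" for b in "ACGU"]
    + ["SPEC_S13", "SPEC_MEAN_ENERGY", "SPEC_SNR", "SPEC_Q1", "SPEC_Q2",
       "SPEC_MAX", "SPEC_MIN"]
    + ["MFE", "MFE_PER_NT"]
    + ["STRUCT_ACGUD_LOGDIST_CYTO", "STRUCT_ACGUD_LOGDIST_NUC",
       "STRUCT_ACGUD_RATIODIST"]
)
assert len(BIO_FEATURE_NAMES) == 70


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end pipeline (defaults are the protocol)."""

    k_tuple: int = 8
    engine: str = "nussinov"
    fold_window: int | None = 500
    struct_ks: tuple[int, ...] = (1, 4)
    struct_registry_kind: str = "acguD"
    struct_registry_k: int = 1
    ifs_batch_size: int = 50
    ifs_patience: int = 3
    ifs_cv_folds: int = 5
    ifs_max_features: int | None = 1000
    n_keep_bio: int = 32
    ae_max_iter: int = 500
    rfe_learning_rate: float = 0.1
    rfe_n_estimators: int = 50
    svm_log2_c: tuple[int, ...] = tuple(range(-5, 11))
    svm_log2_gamma: tuple[int, ...] = tuple(range(-15, 1))
    grid_cv_folds: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """Assembled features: sparse tuple block + named dense bio block."""

    ids: list[str]
    tuple_block: sparse.csr_matrix
    bio: pd.DataFrame

    def __post_init__(self) -> None:
        if self.bio.isna().any().any():
            raise ValueError("bio block contains missing values after assembly")


def compute_structures(
    seqs: Sequence[NucleotideSequence], config: PipelineConfig
) -> dict[str, tuple[SecondaryStructure, DerivedSequences]]:
    """Fold every sequence and build its derived sequences (label-free)."""
    out = {}
    for s in seqs:
        ss = fold(s, engine=config.engine, fold_window=config.fold_window)
        out[s.id] = (ss, derive_sequences(s, ss))
    return out


def _bio_row(
    seq: NucleotideSequence,
    tables: HexamerTable,
    profiles: StructureProfiles,
    ss: SecondaryStructure,
    derived: DerivedSequences,
    config: PipelineConfig,
) -> np.ndarray:
    orf = orf_features.find_longest_orf(seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        edp2 = kmer_features.edp_2mer(seq)
        edporf = orf_features.edp_orf(seq, orf)
        spec = physchem_features.power_spectrum(physchem_features.eiip_encode(seq))
        spectral = physchem_features.spectral_features(spec)
        logdists = orf_features.hexamer_log_distances(seq, tables)
        struct_triple = profiles.logdist_triple(
            derived.get(config.struct_registry_kind),
            config.struct_registry_kind,
            config.struct_registry_k,
        )
    hexbias = [
        orf_features.hexamer_bias(seq, orf, tables, c) if c in tables.classes else 0.0
        for c in CLASSES
    ]
    return np.concatenate([
        edp2,
        [float(orf.length), orf_features.orf_coverage(seq, orf)],
        edporf,
        hexbias,
        logdists,
        orf_features.utr_features(seq, orf),
        orf_features.fickett_vector(seq),
        spectral,
        [ss.mfe, ss.mfe / seq.length],
        struct_triple,
    ])


def assemble_features(
    seqs: Sequence[NucleotideSequence],
    tables: HexamerTable,
    profiles: StructureProfiles,
    structures: Mapping[str, tuple[SecondaryStructure, DerivedSequences]],
    config: PipelineConfig,
) -> FeatureMatrix:
    """Build the fea.Tuple / fea.Bio blocks for a batch of sequences.

    Deterministic given identical inputs and config; the bio block carries
    the pinned 70-name registry as its columns.
    """
    tuple_block = kmer_count_matrix(seqs, config.k_tuple)
    rows = [
        _bio_row(s, tables, profiles, *structures[s.id], config) for s in seqs
    ]
    bio = pd.DataFrame(rows, columns=list(BIO_FEATURE_NAMES), index=[s.id for s in seqs])
    return FeatureMatrix([s.id for s in seqs], tuple_block, bio)


@dataclass
class ModelBundle:
    """Everything needed to replay training-time transformations at predict time."""

    config: PipelineConfig
    classes: tuple[str, ...]
    hexamer_tables: HexamerTable
    structure_profiles: StructureProfiles
    ranking: BinomialRanking
    tuple_selection: SelectionResult
    bio_scaler: FeatureScaler
    encoders: EncoderPair
    bio_selected: np.ndarray
    final_scaler: FeatureScaler
    classifier: SVC
    best_params: dict
    cv_accuracy: float
    schema_version: int = 1

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(Path(path))
        if not isinstance(bundle, ModelBundle):
            raise ValueError(f"{path} is not a model bundle")
        return bundle


def _transform(bundle: ModelBundle, fm: FeatureMatrix) -> np.ndarray:
    x_tuple = fm.tuple_block[:, bundle.tuple_selection.selected].toarray()
    z = bundle.encoders.encode(bundle.bio_scaler.transform(fm.bio.to_numpy()))
    x = np.hstack([x_tuple, z[:, bundle.bio_selected]])
    return bundle.final_scaler.transform(x)


def _check_min_counts(y: np.ndarray, folds: int, what: str) -> int:
    classes, counts = np.unique(y, return_counts=True)
    smallest = int(counts.min())
    if smallest < folds:
        cls = classes[int(np.argmin(counts))]
        raise StratificationError(
            f"class {cls!r} has {smallest} samples, fewer than the {folds} "
            f"folds required for {what}"
        )
    return smallest


def train(
    dataset: LabeledDataset,
    config: PipelineConfig | None = None,
    structures: Mapping[str, tuple[SecondaryStructure, DerivedSequences]] | None = None,
) -> ModelBundle:
    """Fit the full pipeline on a labeled dataset and return the bundle."""
    config = config or PipelineConfig()
    y = dataset.y
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes")
    _check_min_counts(y, config.grid_cv_folds, "hyperparameter grid search")
    _check_min_counts(y, config.ifs_cv_folds, "IFS evaluation")
    if structures is None:
        structures = compute_structures(dataset.sequences, config)
    tables = build_hexamer_tables(dataset)
    profiles = StructureProfiles(ks=config.struct_ks).fit(
        {sid: structures[sid][1] for sid in dataset.ids}, dataset.labels
    )
    fm = assemble_features(dataset.sequences, tables, profiles, structures, config)

    # fea.Tuple: binomial confidence ranking + IFS over the count matrix.
    class_order = sorted(set(y))
    counts_fc = np.vstack([
        np.asarray(fm.tuple_block[y == c].sum(axis=0)).ravel() for c in class_order
    ]).T
    ranking = binomial_confidence(counts_fc)
    selection = ifs_select(
        ranking,
        fm.tuple_block,
        y,
        batch_size=config.ifs_batch_size,
        patience=config.ifs_patience,
        cv_folds=config.ifs_cv_folds,
        seed=config.seed,
        max_features=config.ifs_max_features,
    )

    # fea.Bio: standardize -> autoencode to 96 -> RFE down to n_keep.
    bio_scaler = FeatureScaler().fit(fm.bio.to_numpy())
    xb = bio_scaler.transform(fm.bio.to_numpy())
    encoders = train_autoencoders(xb, seed=config.seed, max_iter=config.ae_max_iter)
    z = encoders.encode(xb)
    bio_selected, _ = rfe_select(
        z,
        y,
        n_keep=config.n_keep_bio,
        learning_rate=config.rfe_learning_rate,
        n_estimators=config.rfe_n_estimators,
        seed=config.seed,
    )

    x = np.hstack([
        fm.tuple_block[:, selection.selected].toarray(), z[:, bio_selected]
    ])
    final_scaler = FeatureScaler().fit(x)
    xs = final_scaler.transform(x)

    grid = {
        "C": [2.0 ** e for e in config.svm_log2_c],
        "gamma": [2.0 ** e for e in config.svm_log2_gamma],
    }
    cv = StratifiedKFold(
        n_splits=config.grid_cv_folds, shuffle=True, random_state=config.seed
    )
    search = GridSearchCV(
        SVC(kernel="rbf", decision_function_shape="ovr"),
        grid,
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
    )
    search.fit(xs, y)
    return ModelBundle(
        config=config,
        classes=tuple(search.best_estimator_.classes_),
        hexamer_tables=tables,
        structure_profiles=profiles,
        ranking=ranking,
        tuple_selection=selection,
        bio_scaler=bio_scaler,
        encoders=encoders,
        bio_selected=bio_selected,
        final_scaler=final_scaler,
        classifier=search.best_estimator_,
        best_params=search.best_params_,
        cv_accuracy=float(search.best_score_),
    )


def predict(
    bundle: ModelBundle,
    seqs: Sequence[NucleotideSequence],
    structures: Mapping[str, tuple[SecondaryStructure, DerivedSequences]] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Predict classes and per-class decision scores for a batch.

    Returns (predictions, skipped): sequences shorter than
    ``MIN_PREDICT_LENGTH`` are skipped with a reason instead of failing the
    whole batch.  Row order follows the input minus skips.
    """
    usable, skipped = [], []
    for s in seqs:
        if s.length < MIN_PREDICT_LENGTH:
            skipped.append((s.id, f"length {s.length} < {MIN_PREDICT_LENGTH}"))
        else:
            usable.append(s)
    if not usable:
        empty = pd.DataFrame(columns=["id", "predicted"])
        return empty, skipped
    if structures is None:
        structures = compute_structures(usable, bundle.config)
    fm = assemble_features(
        usable, bundle.hexamer_tables, bundle.structure_profiles, structures,
        bundle.config,
    )
    xs = _transform(bundle, fm)
    pred = bundle.classifier.predict(xs)
    scores = bundle.classifier.decision_function(xs)
    if scores.ndim == 1:  # binary: expand to one column per class
        scores = np.column_stack([-scores, scores])
    out = pd.DataFrame({"id": fm.ids, "predicted": pred})
    for i, c in enumerate(bundle.classifier.classes_):
        out[f"score_{c}"] = scores[:, i]
    return out, skipped


@dataclass
class EvaluationReport:
    """Confusion matrix plus accuracy / per-class precision, recall, F1."""

    labels: tuple[str, ...]
    confusion: pd.DataFrame
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.to_dict(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "undefined": list(self.undefined),
        }


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str] | None = None,
) -> EvaluationReport:
    """Accuracy, per-class precision/recall, and macro F1.

    Precision or recall with an empty denominator is defined as 0 and the
    affected class is flagged in ``undefined`` — small compartments easily
    produce empty prediction sets under cross-validation.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot evaluate empty inputs")
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred length mismatch")
    if labels is not None:
        labels = [str(l) for l in labels]
    else:
        labels = sorted({str(l) for l in y_true} | {str(l) for l in y_pred})
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0
        )
    undefined = tuple(
        lab
        for i, lab in enumerate(labels)
        if cm[:, i].sum() == 0 or cm[i, :].sum() == 0
    )
    return EvaluationReport(
        labels=tuple(labels),
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        accuracy=float(np.trace(cm) / cm.sum()),
        precision={lab: float(p) for lab, p in zip(labels, prec)},
        recall={lab: float(r) for lab, r in zip(labels, rec)},
        f1={lab: float(v) for lab, v in zip(labels, f1)},
        macro_f1=float(np.mean(f1)),
        undefined=undefined,
    )


@dataclass
class CrossValidationResult:
    fold_reports: list[EvaluationReport]
    pooled: EvaluationReport
    mean_accuracy: float
    mean_macro_f1: float


def cross_validate(
    dataset: LabeledDataset,
    config: PipelineConfig | None = None,
    folds: int = 10,
    structures: Mapping[str, tuple[SecondaryStructure, DerivedSequences]] | None = None,
) -> CrossValidationResult:
    """Stratified k-fold evaluation of the full pipeline.

    All fitting (profiles, selection, encoders, scalers, SVM) happens inside
    each training fold; the held-out fold only ever passes through stored
    transformations.  Folding is per-sequence and label-free, so structures
    may be shared across folds.
    """
    config = config or PipelineConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = dataset.y
    _check_min_counts(y, folds, "outer cross-validation")
    if structures is None:
        structures = compute_structures(dataset.sequences, config)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    reports: list[EvaluationReport] = []
    pooled_true: list[str] = []
    pooled_pred: list[str] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        bundle = train(dataset.subset(train_idx), config, structures)
        test_seqs = [dataset.sequences[i] for i in test_idx]
        pred_df, skipped = predict(bundle, test_seqs, structures)
        if skipped:
            warnings.warn(f"skipped during CV: {skipped}", stacklevel=2)
        truth = [dataset.labels[i] for i in pred_df["id"]]
        reports.append(evaluate(truth, pred_df["predicted"]))
        pooled_true.extend(truth)
        pooled_pred.extend(pred_df["predicted"])
    pooled = evaluate(pooled_true, pooled_pred)
    return CrossValidationResult(
        fold_reports=reports,
        pooled=pooled,
        mean_accuracy=float(np.mean([r.accuracy for r in reports])),
        mean_macro_f1=float(np.mean([r.macro_f1 for r in reports])),
    )
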