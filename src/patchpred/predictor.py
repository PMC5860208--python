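"""Random-forest classification of patches and the patch->residue mapping.

The classifier is a 100-tree random forest sampling 3 features per split.
Unlabelled rim (U) patches are excluded from training.  Missing conservation
features are imputed with the training-set column means, which are frozen
inside the model file together with the feature schema, the propensity table,
the patch radius and the seed, so a saved model is self-contained and
reproducible.

A patch prediction is the majority vote of the trees; the score is the
fraction of trees voting interface, with an exact 50/50 tie resolved to
non-interface (favouring specificity).  Residue-level predictions copy each
patch's label to its centre residue; surface residues (isolated RASA >= 10%)
that are not patch centres are always predicted non-interface with score 0,
and buried residues get no prediction at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import DEFAULT_CONFIG, RunConfig
from .evaluation import ConfusionCounts, MetricsReport, confusion, metrics
from .patches import Patch
from .pipeline import FEATURE_COLUMNS
from .sequence_features import PropensityTable
from .structure import ChainStructure, ResidueId

MODEL_FORMAT_VERSION = "patchpred-model-1"


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    feature_schema: list[str]
    imputation_means: dict[str, float]
    propensity_table: PropensityTable | None
    patch_radius: float
    seed: int
    version: str = MODEL_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(
            {
                "version": self.version,
                "forest": self.forest,
                "feature_schema": self.feature_schema,
                "imputation_means": self.imputation_means,
                "propensity_table": (
                    self.propensity_table.to_tsv() if self.propensity_table else None
                ),
                "patch_radius": self.patch_radius,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model version {blob.get('version')!r} does not match "
                f"{MODEL_FORMAT_VERSION!r}; refusing to load"
            )
        table = blob["propensity_table"]
        return cls(
            forest=blob["forest"],
            feature_schema=blob["feature_schema"],
            imputation_means=blob["imputation_means"],
            propensity_table=PropensityTable.from_tsv(table) if table else None,
            patch_radius=blob["patch_radius"],
            seed=blob["seed"],
        )


@dataclass
class ResiduePrediction:
    residue_id: ResidueId
    predicted_label: str  # interface | non-interface
    score: float          # interface vote fraction
    provenance: str       # patch-mapped | forced-non-interface


def assemble_training_set(matrix: pd.DataFrame):
    """Keep I/S rows only (U patches are excluded from training).

    Expects the ``intf`` column: 1 for I, 0 for S, NaN for U.  Missing
    homology/FEP values stay as NaN markers for the imputer.
    """
    if "intf" not in matrix.columns:
        raise ValueError("matrix has no 'intf' label column")
    keep = matrix[matrix["intf"].notna()]
    X = keep[FEATURE_COLUMNS].copy()
    y = keep["intf"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: need both I and S patches")
    return X, y


def train(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 100,
    m_try: int = 3,
    seed: int = 0,
    propensity_table: PropensityTable | None = None,
    patch_radius: float = DEFAULT_CONFIG.patch_radius,
) -> TrainedModel:
    """Fit the forest with training-mean imputation, deterministically."""
    X = X[FEATURE_COLUMNS]
    finite_or_nan = np.isfinite(X.to_numpy(dtype=float)) | np.isnan(X.to_numpy(dtype=float))
    if not finite_or_nan.all():
        raise ValueError("non-finite feature values that are not declared missings")
    means = {
        c: (float(X[c].mean()) if np.isfinite(X[c].mean()) else 0.0)
        for c in FEATURE_COLUMNS
    }
    X_imp = X.fillna(means)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=m_try,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_imp.to_numpy(dtype=float), y)
    return TrainedModel(
        forest=forest,
        feature_schema=list(FEATURE_COLUMNS),
        imputation_means=means,
        propensity_table=propensity_table,
        patch_radius=patch_radius,
        seed=seed,
    )


def predict_patches(model: TrainedModel, X: pd.DataFrame):
    """Per-patch labels and interface vote fractions.

    Score = fraction of trees voting interface; label I when score > 0.5
    (an exact tie goes to non-interface).
    """
    missing = [c for c in model.feature_schema if c not in X.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}")
    X = X[model.feature_schema].fillna(model.imputation_means)
    arr = X.to_numpy(dtype=float)
    votes = np.zeros(len(X))
    # per-tree hard votes (not averaged leaf probabilities)
    interface_class_index = list(model.forest.classes_).index(1)
    for tree in model.forest.estimators_:
        votes += (tree.predict(arr) == model.forest.classes_[interface_class_index])
    scores = votes / len(model.forest.estimators_)
    labels = np.where(scores > 0.5, "I", "S")
    return labels.tolist(), scores


def map_to_residues(
    patches: list[Patch],
    labels: list[str],
    scores: np.ndarray,
    chain: ChainStructure,
    config: RunConfig = DEFAULT_CONFIG,
) -> list[ResiduePrediction]:
    """Patch predictions -> residue predictions over all surface residues.

    Patch centres inherit their patch's label and score; every other surface
    residue (isolated RASA >= 10%) is forced non-interface with score 0;
    buried residues are absent from the output.
    """
    by_centre = {
        p.centre_residue_id: (lab, float(s))
        for p, lab, s in zip(patches, labels, scores)
    }
    out = []
    for r in chain.residues:
        if r.rasa_isolated is None or r.rasa_isolated < config.surface_rasa_threshold:
            continue
        if r.residue_id in by_centre:
            lab, s = by_centre[r.residue_id]
            out.append(
                ResiduePrediction(
                    residue_id=r.residue_id,
                    predicted_label="interface" if lab == "I" else "non-interface",
                    score=s,
                    provenance="patch-mapped",
                )
            )
        else:
            out.append(
                ResiduePrediction(
                    residue_id=r.residue_id,
                    predicted_label="non-interface",
                    score=0.0,
                    provenance="forced-non-interface",
                )
            )
    return out


def residue_predictions_to_tsv(
    predictions: list[ResiduePrediction], chain: ChainStructure
) -> str:
    """Deterministic TSV serialisation of residue-level predictions."""
    by_id = {r.residue_id: r for r in chain.residues}
    lines = ["chain\tresnum\ticode\tresidue\trasa\tlabel\tscore\tprovenance"]
    for p in predictions:
        r = by_id[p.residue_id]
        c, num, icode = p.residue_id
        lab = "I" if p.predicted_label == "interface" else "NI"
        lines.append(
            f"{c}\t{num}\t{icode}\t{r.residue_type}\t{r.rasa_isolated:.4f}"
            f"\t{lab}\t{p.score:.4f}\t{p.provenance}"
        )
    return "\n".join(lines) + "\n"


@dataclass
class CrossValidationResult:
    fold_metrics: list[MetricsReport]
    fold_counts: list[ConfusionCounts]
    mean: MetricsReport


def _mean_report(fold_metrics: list[MetricsReport]) -> MetricsReport:
    def nanmean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        **{
            key: nanmean([getattr(m, key) for m in fold_metrics])
            for key in ("acc", "prec", "spec", "sens", "mcc", "f")
        }
    )


def cross_validate_corpus(
    data,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    m_try: int = 3,
) -> CrossValidationResult:
    """k-fold cross-validation grouped by complex, with per-fold propensity.

    Whole complexes are held out together and the propensity table is rebuilt
    from the training complexes of each fold before the ``prop`` column is
    re-evaluated, so no statistic of a test complex leaks into training.
    ``data`` is the CorpusData from :func:`patchpred.pipeline.build_corpus_matrix`.
    """
    from .pipeline import recompute_propensity_column
    from .sequence_features import build_propensity_table

    matrix = data.matrix
    complexes = sorted(data.residues_by_complex)
    if k < 2 or k > len(complexes):
        raise ValueError(f"need 2 <= k <= number of complexes ({len(complexes)})")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(complexes)))
    folds = [[complexes[i] for i in order[f::k]] for f in range(k)]

    fold_metrics, fold_counts = [], []
    for held_out in folds:
        train_cpx = [c for c in complexes if c not in held_out]
        table = build_propensity_table(
            [r for c in train_cpx for r in data.residues_by_complex[c]],
            provenance="fold",
        )
        mat = matrix.copy()
        mat["prop"] = recompute_propensity_column(mat, table)
        is_test = mat["complex"].isin(held_out)
        train_rows = mat[~is_test & mat["intf"].notna()]
        test_rows = mat[is_test & mat["intf"].notna()]
        model = train(
            train_rows[FEATURE_COLUMNS],
            train_rows["intf"].astype(int).to_numpy(),
            n_trees, m_try, seed,
        )
        labels, _ = predict_patches(model, test_rows[FEATURE_COLUMNS])
        pred = {i: lab for i, lab in zip(test_rows.index, labels)}
        truth = {
            i: ("I" if v == 1 else "S")
            for i, v in zip(test_rows.index, test_rows["intf"].astype(int))
        }
        counts = confusion(pred, truth, level="patch")
        fold_counts.append(counts)
        fold_metrics.append(metrics(counts))
    return CrossValidationResult(fold_metrics, fold_counts, _mean_report(fold_metrics))


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 100,
    m_try: int = 3,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation at patch level.

    Folds are stratified by class and fixed by the seed.  Folds whose test
    split holds a single class give undefined metrics and are excluded from
    the unweighted mean, with a warning.
    """
    if k < 2:
        raise ValueError("k-fold cross-validation needs k >= 2")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics, fold_counts = [], []
    for train_idx, test_idx in skf.split(X, y):
        model = train(X.iloc[train_idx], y[train_idx], n_trees, m_try, seed)
        labels, _ = predict_patches(model, X.iloc[test_idx])
        pred = {i: lab for i, lab in zip(test_idx, labels)}
        truth = {i: ("I" if y[i] == 1 else "S") for i in test_idx}
        counts = confusion(pred, truth, level="patch")
        if len(set(truth.values())) < 2:
            warnings.warn("fold with a single class: metrics undefined, excluded")
        fold_counts.append(counts)
        fold_metrics.append(metrics(counts))
    return CrossValidationResult(fold_metrics, fold_counts, _mean_report(fold_metrics))
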