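"""Survival-class prediction from subnetwork states.

A feed-forward neural network consumes the per-gene binary H/L states of
the union of the top-k mined subnetworks and predicts STS vs LTS.
Performance is tracked *cumulatively*: the classifier is retrained as each
subnetwork is added (k = 1, 2, ...), reporting accuracy (S + L)/T — S and L
the correctly predicted short- and long-term survivors, T the number of
test samples — and the per-class positive predictive value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .io import LTS, STS, BinarizedMatrix, PhenotypeLabels
from .mining import SignatureSet

log = logging.getLogger(__name__)


def encode_features(
    binarized: BinarizedMatrix, signature: SignatureSet, k: int | None = None
) -> pd.DataFrame:
    """Binary design matrix (samples x genes): H -> 1, L -> 0, columns are
    the concatenated gene lists of the top-k subnetworks in signature
    order."""
    if len(signature) == 0:
        raise ValueError("signature contains no subnetworks")
    k = len(signature) if k is None else k
    if not 1 <= k <= len(signature):
        raise ValueError(f"k must be in 1..{len(signature)}, got {k}")
    genes: list[str] = []
    for sub in signature.subnetworks[:k]:
        genes.extend(sub.genes)
    missing = [g for g in genes if g not in binarized.states.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    return binarized.states.loc[genes].T.astype(int)


@dataclass
class TrainedClassifier:
    """A fitted model mapping binary state features to {STS, LTS}."""

    model: object
    feature_genes: list[str]

    def predict(self, features: pd.DataFrame) -> pd.Series:
        X = features[self.feature_genes].to_numpy()
        pred = self.model.predict(X)
        return pd.Series(pred, index=features.index, name="predicted")


def train_classifier(
    features: pd.DataFrame,
    labels: PhenotypeLabels,
    seed: int = 0,
    model: str = "mlp",
) -> TrainedClassifier:
    """Train the survival-class predictor.

    ``model="mlp"``: one hidden layer as wide as the feature vector,
    logistic-loss output, fixed seed; early stopping on a 20% validation
    split when the cohort is large enough for the split to contain both
    classes reliably.  ``model="logistic"``: a deterministic
    logistic-regression fallback for exact reproducibility in tests.
    """
    samples = [s for s in features.index if s in labels.labels.index]
    if len(samples) < len(features.index):
        features = features.loc[samples]
    y = labels.labels.loc[features.index]
    counts = y.value_counts()
    if len(counts) < 2:
        raise ValueError("training set contains a single phenotype class")
    if counts.min() < 5:
        raise ValueError(f"need >= 5 samples per class, got {counts.to_dict()}")
    X = features.to_numpy()
    if model == "mlp":
        # early stopping monitors accuracy on a 20% validation split; that
        # score is too coarse to be a stopping signal on small cohorts, so
        # it is enabled only when the split holds >= 40 samples
        clf = MLPClassifier(
            hidden_layer_sizes=(X.shape[1],),
            activation="logistic",
            solver="adam",
            learning_rate_init=0.01,
            max_iter=1000,
            random_state=int(seed),
            early_stopping=len(features) >= 200,
            validation_fraction=0.2,
            n_iter_no_change=25,
        )
    elif model == "logistic":
        clf = LogisticRegression(max_iter=2000, random_state=int(seed))
    else:
        raise ValueError(f"unknown classifier model: {model!r}")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(X, y.to_numpy())
    return TrainedClassifier(model=clf, feature_genes=list(features.columns))


def classification_accuracy(predictions: pd.Series, labels: PhenotypeLabels) -> float:
    """(S + L)/T: correctly predicted short- plus long-term survivors over
    the number of test samples."""
    truth = labels.labels
    common = predictions.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between predictions and labels")
    return float((predictions.loc[common] == truth.loc[common]).mean())


def positive_predictive_value(
    predictions: pd.Series, labels: PhenotypeLabels, target_class: str
) -> float:
    """True positives over all predictions of ``target_class``; NaN (with a
    warning) when the class was never predicted."""
    if target_class not in (STS, LTS):
        raise ValueError(f"target_class must be STS or LTS, got {target_class!r}")
    truth = labels.labels
    common = predictions.index.intersection(truth.index)
    pred = predictions.loc[common]
    predicted_pos = pred == target_class
    if predicted_pos.sum() == 0:
        warnings.warn(f"no predictions of class {target_class}; PPV undefined")
        return float("nan")
    return float((truth.loc[common][predicted_pos] == target_class).mean())


def confusion_counts(predictions: pd.Series, labels: PhenotypeLabels) -> dict:
    """S, L, T and per-class predicted/false-positive counts."""
    truth = labels.labels
    common = predictions.index.intersection(truth.index)
    pred = predictions.loc[common]
    tr = truth.loc[common]
    S = int(((pred == STS) & (tr == STS)).sum())
    L = int(((pred == LTS) & (tr == LTS)).sum())
    return {
        "S": S,
        "L": L,
        "T": int(len(common)),
        "pred_sts": int((pred == STS).sum()),
        "pred_lts": int((pred == LTS).sum()),
        "fp_sts": int(((pred == STS) & (tr == LTS)).sum()),
        "fp_lts": int(((pred == LTS) & (tr == STS)).sum()),
    }


def cumulative_evaluation(
    train_binarized: BinarizedMatrix,
    train_labels: PhenotypeLabels,
    test_binarized: BinarizedMatrix,
    test_labels: PhenotypeLabels,
    signature: SignatureSet,
    k_max: int = 10,
    seed: int = 0,
    model: str = "mlp",
) -> pd.DataFrame:
    """Cumulative classification report: for each k = 1..k_max, retrain on
    the training cohort using the top-k subnetworks and evaluate on the
    test cohort.  Columns: k, accuracy, ppv_sts, ppv_lts, S, L, T,
    pred_sts, pred_lts."""
    if k_max > len(signature):
        warnings.warn(
            f"k_max={k_max} exceeds signature size {len(signature)}; truncating"
        )
        k_max = len(signature)
    rows = []
    for k in range(1, k_max + 1):
        feats_train = encode_features(train_binarized, signature, k)
        feats_test = encode_features(test_binarized, signature, k)
        clf = train_classifier(feats_train, train_labels, seed=seed, model=model)
        pred = clf.predict(feats_test.loc[[s for s in feats_test.index if s in test_labels.labels.index]])
        counts = confusion_counts(pred, test_labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "k": k,
                    "accuracy": classification_accuracy(pred, test_labels),
                    "ppv_sts": positive_predictive_value(pred, test_labels, STS),
                    "ppv_lts": positive_predictive_value(pred, test_labels, LTS),
                    **counts,
                }
            )
    return pd.DataFrame(rows)
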