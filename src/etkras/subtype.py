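"""PDAC subtype signature scoring.

The procedure mirrors proteomic subtype mapping: select the most variable
proteins, train (or load) a PLS-DA model against one-hot class targets,
project samples into component space, score each of the four classes
(Proliferative, Inflammatory, Metabolic, Progenitor-like by default) along
its discriminant direction, and calibrate a per-class score cutoff at the
ROC point maximizing Youden's J (sensitivity + specificity - 1).

The published patient-cohort model weights are not reproduced here; the
contract is the procedure, exercised on reference or synthetic cohorts,
with JSON (de)serialization for externally supplied weights.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_curve

from .iokit import OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_CLASSES = ("Proliferative", "Inflammatory", "Metabolic", "Progenitor-like")


@dataclass
class SignatureModel:
    """Serializable PLS-DA signature: feature space, projection, cutoffs."""

    feature_ids: list[str]
    center: np.ndarray                  # per-feature mean (training)
    scale: np.ndarray                   # per-feature sd (training)
    weights: np.ndarray                 # feature x component NIPALS weights (orthonormal)
    rotations: np.ndarray               # feature x component projection (scores = Xs @ rotations)
    class_directions: np.ndarray        # class x component discriminant vectors
    classes: list[str]
    cutoffs: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_ids": self.feature_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "rotations": self.rotations.tolist(),
            "class_directions": self.class_directions.tolist(),
            "classes": self.classes,
            "cutoffs": self.cutoffs,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_ids=list(d["feature_ids"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            rotations=np.asarray(d["rotations"], dtype=float),
            class_directions=np.asarray(d["class_directions"], dtype=float),
            classes=list(d["classes"]),
            cutoffs={k: float(v) for k, v in d["cutoffs"].items()},
        )


@dataclass
class SubtypeScore:
    sample: str
    scores: dict[str, float]
    calls: dict[str, bool]
    top_class: str


def select_variable_features(matrix: OmicsMatrix, k: int = 60) -> list[str]:
    """Top-k features by variance across samples; ties break lexicographically."""
    n = len(matrix.feature_ids)
    if k > n:
        raise ValueError(f"k ({k}) exceeds the feature count ({n})")
    var = matrix.values.var(axis=1, ddof=1, skipna=True)
    order = sorted(matrix.feature_ids, key=lambda f: (-float(var[f]), f))
    return order[:k]


def plsda_train(
    train: OmicsMatrix,
    labels: Mapping[str, str],
    n_components: int = 2,
    classes: Sequence[str] | None = None,
) -> SignatureModel:
    """Fit a PLS-DA signature on labelled samples.

    Features are centered and unit-variance scaled; the NIPALS PLS2
    decomposition regresses them onto one-hot class targets.  Class
    discriminant directions are the target loadings in component space, so
    a sample's class score is its component-score vector dotted with that
    class's direction (the centered regression prediction).
    """
    vals = train.values
    if vals.isna().any().any():
        raise ValueError("training matrix may not contain missing values")
    sample_ids = list(vals.columns)
    y_labels = [labels[s] for s in sample_ids]
    classes = list(classes) if classes is not None else sorted(set(y_labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if y_labels.count(cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")

    X = vals.to_numpy(dtype=float).T          # samples x features
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale
    Y = np.array([[1.0 if lab == c else 0.0 for c in classes] for lab in y_labels])

    pls = PLSRegression(n_components=n_components, scale=False, max_iter=2000)
    pls.fit(Xs, Y)
    return SignatureModel(
        feature_ids=list(vals.index),
        center=center,
        scale=scale,
        weights=pls.x_weights_,
        rotations=pls.x_rotations_,
        class_directions=pls.y_loadings_,
        classes=classes,
    )


def youden_cutoff(scores: np.ndarray, positive: np.ndarray) -> float:
    """Score threshold maximizing Youden's J for the call ``score >= cutoff``.

    Ties in J resolve to the lowest qualifying threshold (most sensitive).
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if positive.all() or (~positive).all():
        raise ValueError("calibration needs both positive and negative samples")
    fpr, tpr, thr = roc_curve(positive.astype(int), scores, drop_intermediate=False)
    j = tpr - fpr
    best = j.max()
    # roc_curve thresholds descend; the last index with max J is the lowest one
    idx = np.where(np.isclose(j, best))[0][-1]
    cutoff = thr[idx]
    if np.isinf(cutoff):  # the "predict none" point; fall back to the max score
        cutoff = float(scores.max())
    return float(cutoff)


def project_scores(model: SignatureModel, samples: OmicsMatrix) -> pd.DataFrame:
    """Per-class scores (samples x classes) under a fitted model.

    Model features absent from ``samples`` are imputed at the training
    center (zero after standardization) with a warning.
    """
    vals = samples.values
    present = [f for f in model.feature_ids if f in vals.index]
    if len(present) < len(model.feature_ids):
        logger.warning(
            "%d of %d model features absent from the scoring matrix; "
            "imputed at the training center",
            len(model.feature_ids) - len(present), len(model.feature_ids),
        )
    X = vals.reindex(model.feature_ids).to_numpy(dtype=float).T
    Xs = (X - model.center) / model.scale
    Xs[:, ~np.isin(model.feature_ids, vals.index.to_numpy())] = 0.0
    Xs = np.nan_to_num(Xs, nan=0.0)  # missing cells also impute at the center
    T = Xs @ model.rotations
    S = T @ model.class_directions.T
    return pd.DataFrame(S, index=list(vals.columns), columns=model.classes)


def score_subtypes(
    model: SignatureModel,
    samples: OmicsMatrix,
    calibration_labels: Mapping[str, str] | None = None,
) -> list[SubtypeScore]:
    """Score samples per class and call subtypes against ROC cutoffs.

    With ``calibration_labels`` (sample -> true class) the per-class cutoff
    is (re)calibrated at the Youden-optimal ROC point and stored on the
    model; otherwise previously stored cutoffs are required.
    """
    score_df = project_scores(model, samples)
    if calibration_labels is not None:
        for cls in model.classes:
            truth = np.array(
                [calibration_labels.get(s) == cls for s in score_df.index]
            )
            model.cutoffs[cls] = youden_cutoff(score_df[cls].to_numpy(), truth)
    elif not model.cutoffs:
        raise ValueError("no stored cutoffs and no calibration labels supplied")
    out = []
    for sample, row in score_df.iterrows():
        scores = {c: float(row[c]) for c in model.classes}
        calls = {c: scores[c] >= model.cutoffs[c] for c in model.classes
                 if c in model.cutoffs}
        out.append(
            SubtypeScore(
                sample=str(sample),
                scores=scores,
                calls=calls,
                top_class=max(model.classes, key=lambda c: scores[c]),
            )
        )
    return out


def resubstitution_accuracy(
    model: SignatureModel, train: OmicsMatrix, labels: Mapping[str, str]
) -> float:
    """Fraction of training samples whose top-scoring class is their label."""
    score_df = project_scores(model, train)
    correct = sum(
        max(model.classes, key=lambda c: score_df.loc[s, c]) == labels[s]
        for s in score_df.index
    )
    return correct / len(score_df)
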