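"""Point-level diagnostic classification of palpation features.

Each probed point is summarised by an eight-element mechanical feature
vector -- quasi-static modulus, dynamic modulus, phase difference and time
lag, at each of firm and light contact pressure -- and classified C (cancer
in the tissue column under the point) vs NC with a small two-layer
feed-forward network: one hidden layer of sigmoid units and a softmax
output, trained with a batch gradient method under early stopping on a
held-out validation fold.  The evaluation protocol is repeated random
stratified 70/15/15 train/validation/test splits; the headline report is
the pooled test-fold confusion matrix over the repeats (an all-data pooled
matrix is emitted alongside), from which the five standard diagnostic
indicators are computed:

    sensitivity = 100 TP / (TP + FN)      specificity = 100 TN / (TN + FP)
    NPV         = 100 TN / (TN + FN)      PPV         = 100 TP / (TP + FP)
    accuracy    = 100 (TP + TN) / (TP + FP + FN + TN)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

log = logging.getLogger(__name__)

#: Fixed ordering of the 8 mechanical features (pressure, column).
FEATURE_ORDER: tuple[tuple[str, str], ...] = (
    ("firm", "e_static_kpa"), ("firm", "e_dynamic_kpa"),
    ("firm", "pd_rad"), ("firm", "dt_s"),
    ("light", "e_static_kpa"), ("light", "e_dynamic_kpa"),
    ("light", "pd_rad"), ("light", "dt_s"),
)
FEATURE_NAMES = tuple(f"{p}_{c}" for p, c in FEATURE_ORDER)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts with class 1 = C (cancer)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_true == 1) & (y_pred == 1))),
                   fp=int(np.sum((y_true == 0) & (y_pred == 1))),
                   fn=int(np.sum((y_true == 1) & (y_pred == 0))),
                   tn=int(np.sum((y_true == 0) & (y_pred == 0))))


@dataclass(frozen=True)
class DiagnosticIndicators:
    """The five diagnostic percentages; an indicator whose denominator is
    zero is reported as None (absent), never as 0."""

    sensitivity: float | None
    specificity: float | None
    npv: float | None
    ppv: float | None
    accuracy: float

    def as_dict(self) -> dict[str, float | None]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "npv": self.npv, "ppv": self.ppv, "accuracy": self.accuracy}


def diagnostic_indicators(cm: ConfusionMatrix) -> DiagnosticIndicators:
    """Compute the five indicators (percent) from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("cannot compute indicators of an empty confusion matrix")

    def ratio(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return DiagnosticIndicators(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
    )


@dataclass(frozen=True)
class CVConfig:
    """Repeated-random-split training protocol."""

    n_repeats: int = 10
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    hidden_units: int = 10
    max_epochs: int = 400
    patience: int = 25
    learning_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class FeatureMatrix:
    X: np.ndarray
    y: np.ndarray            # 1 = C, 0 = NC
    ids: pd.DataFrame        # patient_id, point_id, label per row
    feature_names: tuple[str, ...] = FEATURE_NAMES


def assemble_feature_vectors(features: pd.DataFrame, mode: str = "strict",
                             frequency: float | None = None) -> FeatureMatrix:
    """Build one 8-feature vector per probed point from a feature table.

    Rows are combined per (patient, point) across the two pressure levels in
    the fixed :data:`FEATURE_ORDER`; the result is independent of input row
    order.  Points are taken at their own actuation frequency (each point in
    a default cohort is measured at a single frequency); pass ``frequency``
    to restrict a multi-frequency table to one block.  ``mode="strict"``
    excludes points missing a pressure level (with a logged reason);
    ``mode="impute"`` fills missing entries with the cohort median of that
    feature.
    """
    if mode not in ("strict", "impute"):
        raise ValueError(f"mode must be 'strict' or 'impute', got {mode!r}")
    if "label" not in features.columns or features["label"].isna().any():
        raise ValueError("feature table must carry C/NC labels")
    df = features
    if frequency is not None:
        df = df[df["frequency_hz"] == frequency]
    dup = df.duplicated(subset=["patient_id", "point_id", "pressure"])
    if dup.any():
        raise ValueError(
            "multiple frequency rows per (point, pressure); pass `frequency` "
            "to select one actuation block"
        )

    wide = df.pivot_table(index=["patient_id", "point_id", "label"],
                          columns="pressure",
                          values=list(dict.fromkeys(c for _, c in FEATURE_ORDER)),
                          aggfunc="first")
    cols = []
    for pressure, column in FEATURE_ORDER:
        key = (column, pressure)
        cols.append(wide[key] if key in wide.columns
                    else pd.Series(np.nan, index=wide.index))
    mat = pd.concat(cols, axis=1)
    mat.columns = list(FEATURE_NAMES)
    mat = mat.sort_index()

    if mode == "strict":
        complete = mat.notna().all(axis=1)
        for pid, point, _ in mat.index[~complete]:
            log.warning("excluding point %s/%s: missing pressure level", pid, point)
        mat = mat[complete]
    else:
        mat = mat.fillna(mat.median())

    ids = mat.index.to_frame(index=False)
    y = (ids["label"] == "C").to_numpy(dtype=int)
    return FeatureMatrix(X=mat.to_numpy(dtype=float), y=y, ids=ids)


@dataclass(frozen=True)
class RepeatResult:
    train_cm: ConfusionMatrix
    val_cm: ConfusionMatrix
    test_cm: ConfusionMatrix
    alldata_cm: ConfusionMatrix


@dataclass(frozen=True)
class CVResult:
    repeats: tuple[RepeatResult, ...]
    pooled_test_cm: ConfusionMatrix
    pooled_alldata_cm: ConfusionMatrix

    @property
    def pooled_test_indicators(self) -> DiagnosticIndicators:
        return diagnostic_indicators(self.pooled_test_cm)


def _fit_early_stopped(X_train, y_train, X_val, y_val, cfg: CVConfig,
                       random_state: int) -> MLPClassifier:
    """Train the two-layer network one epoch at a time, early-stopping on
    validation cross-entropy and restoring the best weights."""
    clf = MLPClassifier(hidden_layer_sizes=(cfg.hidden_units,),
                        activation="logistic", solver="adam",
                        learning_rate_init=cfg.learning_rate,
                        batch_size=min(200, len(y_train)),
                        max_iter=1, warm_start=True, random_state=random_state)
    best_loss = np.inf
    best_weights = None
    stale = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(cfg.max_epochs):
            clf.fit(X_train, y_train)
            val_loss = log_loss(y_val, clf.predict_proba(X_val), labels=[0, 1])
            if val_loss < best_loss - 1e-7:
                best_loss = val_loss
                best_weights = ([c.copy() for c in clf.coefs_],
                                [b.copy() for b in clf.intercepts_])
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if best_weights is not None:
        clf.coefs_, clf.intercepts_ = best_weights
    return clf


def train_eval(fm: FeatureMatrix, cfg: CVConfig) -> CVResult:
    """Repeated stratified random-split training and evaluation.

    For each repeat the data are split 70/15/15 (stratified by class), the
    network is trained with early stopping on the validation fold, and
    confusion matrices are recorded for every fold plus the full data set.
    Deterministic under ``cfg.seed``.
    """
    X, y = fm.X, fm.y
    if len(y) < 20:
        raise ValueError(f"need at least 20 feature vectors, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train a classifier")

    rng = np.random.default_rng(cfg.seed)
    repeats: list[RepeatResult] = []
    for _ in range(cfg.n_repeats):
        rs = int(rng.integers(2**31 - 1))
        idx = np.arange(len(y))
        idx_train, idx_rest = train_test_split(
            idx, train_size=cfg.train_frac, stratify=y, random_state=rs)
        rel_val = cfg.val_frac / (cfg.val_frac + cfg.test_frac)
        idx_val, idx_test = train_test_split(
            idx_rest, train_size=rel_val, stratify=y[idx_rest],
            random_state=rs + 1)

        scaler = StandardScaler().fit(X[idx_train])
        Xs = scaler.transform(X)
        clf = _fit_early_stopped(Xs[idx_train], y[idx_train],
                                 Xs[idx_val], y[idx_val], cfg, random_state=rs)
        pred = clf.predict(Xs)
        repeats.append(RepeatResult(
            train_cm=ConfusionMatrix.from_predictions(y[idx_train], pred[idx_train]),
            val_cm=ConfusionMatrix.from_predictions(y[idx_val], pred[idx_val]),
            test_cm=ConfusionMatrix.from_predictions(y[idx_test], pred[idx_test]),
            alldata_cm=ConfusionMatrix.from_predictions(y, pred),
        ))

    pooled_test = repeats[0].test_cm
    pooled_all = repeats[0].alldata_cm
    for r in repeats[1:]:
        pooled_test = pooled_test + r.test_cm
        pooled_all = pooled_all + r.alldata_cm
    return CVResult(repeats=tuple(repeats), pooled_test_cm=pooled_test,
                    pooled_alldata_cm=pooled_all)
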