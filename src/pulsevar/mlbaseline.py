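"""Multi-classifier baseline: eight supervised models, threefold CV.

Features are the 40 harmonic indices per recording (``pulse40``) or the
per-subject M1-vs-M0 contrasts (``delta40``). Standardisation is fitted
fold-wise on the training split only; metrics go through the evalmetrics
module so threshold and ML arms share one metric code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .errors import InvalidParameterError, MissingSessionError, StratificationError
from .evalmetrics import confusion, rank_auc
from .harmonics import feature_names
from .score import NEGATIVE, POSITIVE
from .simulate import N_HARMONICS, wrap_degrees

MODEL_NAMES = ("SVM", "MLP", "GNB", "DT", "RF", "LR", "LDA", "KNN")


@dataclass
class FeatureTable:
    """Subject rows x named feature columns with a binary target."""

    X: pd.DataFrame
    y: pd.Series
    target_name: str

    def __post_init__(self):
        if self.X.isna().any().any() or self.y.isna().any():
            raise InvalidParameterError("feature table contains missing values")
        if len(self.X) != len(self.y):
            raise InvalidParameterError("X and y length mismatch")


def make_models(seed: int) -> dict[str, object]:
    """The eight model families, library defaults, seeded where stochastic."""
    return {
        "SVM": SVC(random_state=seed),
        "MLP": MLPClassifier(random_state=seed, max_iter=800),
        "GNB": GaussianNB(),
        "DT": DecisionTreeClassifier(random_state=seed),
        "RF": RandomForestClassifier(random_state=seed),
        "LR": LogisticRegression(max_iter=2000),
        "LDA": LinearDiscriminantAnalysis(),
        "KNN": KNeighborsClassifier(),
    }


def assemble_features(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    mode: str = "pulse40",
    target: str = "cv_flag",
    session: str = "M1",
) -> FeatureTable:
    """Build the model-ready table from per-recording index rows.

    ``pulse40`` takes the 40 indices of one session per subject; ``delta40``
    takes per-subject M1/M0 log-ratios for the positive-valued families and
    wrapped phase differences (degrees) for P_n.
    """
    if mode not in ("pulse40", "delta40"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    cols = feature_names()
    missing_cols = [c for c in cols if c not in features.columns]
    if missing_cols:
        raise InvalidParameterError(f"feature table lacks columns {missing_cols}")
    label_map = labels.set_index("subject")[target]

    needed = (session,) if mode == "pulse40" else ("M0", "M1")
    by_subject = features.groupby("subject")
    missing = sorted(
        subj for subj, grp in by_subject
        if not set(needed).issubset(set(grp["session"]))
    )
    if missing:
        raise MissingSessionError(missing)

    rows = []
    subjects = []
    for subj, grp in by_subject:
        grp = grp.set_index("session")
        if mode == "pulse40":
            rows.append(grp.loc[session, cols].astype(float).to_numpy())
        else:
            pre = grp.loc["M0", cols].astype(float)
            post = grp.loc["M1", cols].astype(float)
            vals = []
            for c in cols:
                is_plain_phase = c.startswith("P") and not c.endswith("_SD")
                if is_plain_phase:  # circular: wrapped difference in degrees
                    vals.append(float(wrap_degrees(post[c] - pre[c])))
                else:  # positive-valued families: log-ratio
                    vals.append(np.log(post[c] / pre[c]))
            rows.append(np.asarray(vals))
        subjects.append(subj)

    X = pd.DataFrame(rows, columns=cols, index=subjects)
    y = label_map.reindex(subjects).astype(int)
    if y.isna().any():
        raise InvalidParameterError("labels missing for some subjects")
    return FeatureTable(X=X, y=y, target_name=target)


def crossval_models(
    ft: FeatureTable,
    seed: int = 0,
    folds: int = 3,
    models: dict[str, object] | None = None,
) -> pd.DataFrame:
    """Stratified k-fold CV for every model; mean metrics per model.

    Returns a DataFrame indexed by model name with columns
    accuracy (%), auc, specificity, sensitivity.
    """
    y = ft.y.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"minority class has {counts.min()} < {folds} members"
        )
    X = ft.X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for _, test_idx in splits:
        if len(np.unique(y[test_idx])) < 2:
            raise StratificationError("a fold lost one of the classes")

    models = models if models is not None else make_models(seed)
    records = []
    for name, model in models.items():
        fold_metrics = []
        for train_idx, test_idx in splits:
            scaler = StandardScaler().fit(X[train_idx])
            x_train = scaler.transform(X[train_idx])
            x_test = scaler.transform(X[test_idx])
            model.fit(x_train, y[train_idx])
            pred = model.predict(x_test)
            decisions = [POSITIVE if p == 1 else NEGATIVE for p in pred]
            report = confusion(decisions, y[test_idx])
            if hasattr(model, "predict_proba"):
                s = model.predict_proba(x_test)[:, 1]
            else:
                s = model.decision_function(x_test)
            fold_metrics.append(
                (
                    report.accuracy,
                    rank_auc(s, y[test_idx]),
                    report.specificity,
                    report.sensitivity,
                )
            )
        mean = np.mean(fold_metrics, axis=0)
        records.append(
            {
                "model": name,
                "accuracy": mean[0],
                "auc": mean[1],
                "specificity": mean[2],
                "sensitivity": mean[3],
            }
        )
    return pd.DataFrame(records).set_index("model")
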