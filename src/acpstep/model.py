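"""The two-step RBF-SVM classifier over peptide sequences.

Step one assigns every peptide to a subtype (C+, N+ or Other) by the
terminal positive-charge rule; step two applies a subtype-specific support
vector machine with an RBF kernel, trained on min-max-scaled hybrid
features (composition blocks plus physicochemical descriptors).  Each
subtype model selects its own (C, γ) by exhaustive grid search with
internal stratified cross-validation, the combination with the highest CV
accuracy winning (ties broken toward smaller C, then smaller γ), and is
then refit on all of that subtype's rows — the LIBSVM ``grid.py``
protocol.  Setting ``two_step=False`` trains a single undivided SVM, the
one-step baseline the two-step design is compared against.

The estimator follows scikit-learn conventions (``fit``/``predict``/
``get_params``) with raw sequences as samples, so it composes with
pipelines and model-selection utilities that do not require numeric X.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .encoders import FeatureSpec, encode
from .grouping import SubtypeGroup, assign_group

# LIBSVM grid.py defaults: C = 2^-5, 2^-3, ..., 2^15; gamma = 2^-15, ..., 2^3
DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    scoring: str = "accuracy",
    class_weight=None,
):
    """Exhaustive (C, γ) grid search for an RBF SVC.

    Returns ``(fitted_svm, C, gamma, cv_score)``.  The grid is scanned with
    stratified ``cv_folds``-fold CV; the highest mean score wins, ties
    resolved toward the smallest C then the smallest γ (the scan order), and
    the winning configuration is refit on all rows.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs both classes present in y")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= cv_folds={cv_folds}"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf", class_weight=class_weight, random_state=seed),
        param_grid={"C": sorted(C_grid), "gamma": sorted(gamma_grid)},
        scoring=scoring,
        cv=cv,
        n_jobs=None,
        refit=True,
    )
    search.fit(X, y)
    best = search.best_params_
    return search.best_estimator_, best["C"], best["gamma"], float(search.best_score_)


class ACPClassifier(ClassifierMixin, BaseEstimator):
    """Two-step (or one-step) anticancer-peptide classifier.

    Parameters
    ----------
    features : str or FeatureSpec, default "aac+dpc+pcp"
        Feature blocks, e.g. ``"aac+dpc+cksaap:k=1,2,3+pcp"``.
    two_step : bool, default True
        Partition by subtype and train one SVM per subtype; ``False`` trains
        a single SVM on the undivided data.
    window : int, default 5
        Terminal window length for the subtype rule.
    pH : float, default 7.0
        pH for the charge-dependent physicochemical descriptors.
    C_grid, gamma_grid : sequences of float
        Candidate SVM penalty and RBF width values.
    cv : int, default 5
        Folds of the internal grid-search cross-validation.
    scoring : str, default "accuracy"
        Grid-search selection criterion ("accuracy" or "balanced_accuracy").
    probability : bool, default False
        Enable Platt-calibrated class probabilities.
    class_weight : None or "balanced"
        Optional inverse-frequency class weighting.
    pos_label : str or None
        Label treated as the positive (active) class; default picks "ACP"
        when present, else the lexicographically largest label.
    random_state : int, default 0
        Seed for all internal randomness.

    Attributes
    ----------
    classes_ : ndarray of shape (2,), ``[negative, positive]``.
    feature_spec_ : resolved :class:`FeatureSpec`.
    models_ : dict mapping subtype (or None for one-step) to a dict with
        keys ``scaler``, ``svm``, ``C``, ``gamma``, ``cv_score``, ``n``.
    meta_ : training metadata (sizes, seed, feature spec string).
    """

    def __init__(
        self,
        features="aac+dpc+pcp",
        two_step: bool = True,
        window: int = 5,
        pH: float = 7.0,
        C_grid=DEFAULT_C_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        cv: int = 5,
        scoring: str = "accuracy",
        probability: bool = False,
        class_weight=None,
        pos_label=None,
        random_state: int = 0,
    ):
        self.features = features
        self.two_step = two_step
        self.window = window
        self.pH = pH
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv = cv
        self.scoring = scoring
        self.probability = probability
        self.class_weight = class_weight
        self.pos_label = pos_label
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _sequences(X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            if "sequence" not in X.columns:
                raise ValueError("DataFrame X must have a 'sequence' column")
            return X["sequence"].tolist()
        seqs = list(X)
        if not all(isinstance(s, str) for s in seqs):
            raise ValueError("X must be sequence strings")
        return seqs

    def _spec(self) -> FeatureSpec:
        if isinstance(self.features, FeatureSpec):
            return self.features
        return FeatureSpec.parse(self.features)

    def _encode(self, seqs: list[str]) -> np.ndarray:
        ds = pd.DataFrame({"id": [str(i) for i in range(len(seqs))], "sequence": seqs})
        return encode(ds, self.feature_spec_, pH=self.pH).to_numpy()

    def _group_keys(self, seqs: list[str]):
        if not self.two_step:
            return np.array([None] * len(seqs), dtype=object)
        return np.array(
            [assign_group(s, self.window).group for s in seqs], dtype=object
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        seqs = self._sequences(X)
        y = np.asarray(y)
        if len(y) != len(seqs):
            raise ValueError("X and y length mismatch")
        uniques = np.unique(y)
        if len(uniques) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(uniques)}")
        pos = self.pos_label
        if pos is None:
            pos = "ACP" if "ACP" in uniques else uniques[-1]
        if pos not in uniques:
            raise ValueError(f"pos_label {pos!r} not found in y")
        neg = uniques[uniques != pos][0]
        self.classes_ = np.array([neg, pos])
        self.feature_spec_ = self._spec()

        y_bin = (y == pos).astype(int)
        keys = self._group_keys(seqs)
        features = self._encode(seqs)

        self.models_ = {}
        group_order = list(SubtypeGroup) if self.two_step else [None]
        for gi, g in enumerate(group_order):
            mask = keys == g
            name = g.value if g is not None else "all"
            if mask.sum() == 0:
                raise ValueError(f"group {name!r} has no training rows")
            yg = y_bin[mask]
            if len(np.unique(yg)) < 2:
                raise ValueError(f"group {name!r} is missing one of the classes")
            Xg = features[mask]
            scaler = MinMaxScaler().fit(Xg)
            svm, C, gamma, cv_score = grid_search_train(
                scaler.transform(Xg),
                yg,
                C_grid=self.C_grid,
                gamma_grid=self.gamma_grid,
                cv_folds=self.cv,
                seed=self.random_state + gi,
                scoring=self.scoring,
                class_weight=self.class_weight,
            )
            calibrator = None
            if self.probability:
                # Platt-style sigmoid calibration on the group's own rows
                calibrator = CalibratedClassifierCV(
                    SVC(kernel="rbf", C=C, gamma=gamma,
                        class_weight=self.class_weight,
                        random_state=self.random_state + gi),
                    method="sigmoid",
                    cv=StratifiedKFold(
                        n_splits=self.cv, shuffle=True,
                        random_state=self.random_state + gi,
                    ),
                    ensemble=False,
                ).fit(scaler.transform(Xg), yg)
            self.models_[g] = {
                "scaler": scaler,
                "svm": svm,
                "calibrator": calibrator,
                "C": C,
                "gamma": gamma,
                "cv_score": cv_score,
                "n": int(mask.sum()),
                "n_pos": int(yg.sum()),
                "n_neg": int(len(yg) - yg.sum()),
            }
        self.meta_ = {
            "features": str(self.feature_spec_),
            "dimension": self.feature_spec_.dimension,
            "two_step": self.two_step,
            "window": self.window,
            "pH": self.pH,
            "random_state": self.random_state,
            "n_train": len(seqs),
            "classes": [str(c) for c in self.classes_],
            "per_group": {
                (g.value if g is not None else "all"): {
                    k: m[k] for k in ("C", "gamma", "cv_score", "n", "n_pos", "n_neg")
                }
                for g, m in self.models_.items()
            },
        }
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "models_"):
            raise RuntimeError("classifier is not fitted")

    def _per_group_apply(self, seqs: list[str], fn) -> np.ndarray:
        """Route each sequence through its group's model; fn(model_dict, X)."""
        self._check_fitted()
        keys = self._group_keys(seqs)
        features = self._encode(seqs)
        out = None
        for g, m in self.models_.items():
            mask = keys == g
            if not mask.any():
                continue
            vals = fn(m, m["scaler"].transform(features[mask]))
            if out is None:
                out = np.empty((len(seqs),) + vals.shape[1:], dtype=vals.dtype)
            out[mask] = vals
        if out is None:
            return np.empty(0)
        return out

    def decision_function(self, X) -> np.ndarray:
        """Signed distance to the margin; positive favors the positive class."""
        return self._per_group_apply(self._sequences(X), lambda m, Z: m["svm"].decision_function(Z))

    def predict(self, X) -> np.ndarray:
        seqs = self._sequences(X)
        if not seqs:
            return np.array([], dtype=object)
        pred = self._per_group_apply(seqs, lambda m, Z: m["svm"].predict(Z))
        return self.classes_[pred.astype(int)]

    def predict_proba(self, X) -> np.ndarray:
        """Platt-calibrated probabilities, columns ordered as ``classes_``."""
        if not self.probability:
            raise AttributeError("probability=False; refit with probability=True")
        seqs = self._sequences(X)
        if not seqs:
            return np.empty((0, 2))
        return self._per_group_apply(seqs, lambda m, Z: m["calibrator"].predict_proba(Z))

    def predict_table(self, ds: pd.DataFrame) -> pd.DataFrame:
        """Predict a dataset frame → table (id, group, label, score[, probability])."""
        seqs = ds["sequence"].tolist()
        keys = self._group_keys(seqs)
        out = pd.DataFrame(
            {
                "id": ds["id"].values,
                "group": [k.value if k is not None else "all" for k in keys],
                "label": self.predict(seqs),
                "score": self.decision_function(seqs),
            }
        )
        if self.probability:
            out["probability"] = self.predict_proba(seqs)[:, 1]
        return out


BUNDLE_SCHEMA_VERSION = 1


def save_model(clf: ACPClassifier, path) -> None:
    """Persist a fitted classifier plus a JSON-serializable metadata manifest."""
    import joblib

    clf._check_fitted()
    joblib.dump(
        {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "meta": clf.meta_,
            "model": clf,
        },
        path,
    )


def load_model(path) -> ACPClassifier:
    """Load a model bundle, refusing schema versions this code cannot read."""
    import joblib

    bundle = joblib.load(path)
    version = bundle.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"model bundle schema version {version!r} is not supported "
            f"(expected {BUNDLE_SCHEMA_VERSION})"
        )
    return bundle["model"]
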