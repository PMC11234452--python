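"""Virtual screening of candidate hydrogelators.

A probabilistic RBF-kernel SVM on 2048-bit ECFP vectors, trained on a
labeled set of self-assembling (positive) and non-assembling (negative)
molecules.  Class imbalance is handled by random oversampling of the
minority class to parity before fitting; probabilities come from Platt
sigmoid calibration with internal cross-validation; a molecule scoring
strictly above 0.5 is called a candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .chem import MoleculeRecord, parse_and_standardize
from .descriptors import EcfpFeaturizer

#: decision threshold on the calibrated self-assembly probability
ACTIVE_THRESHOLD = 0.5

_MODEL_VERSION = "gelgen-svm-v1"


@dataclass
class ScreeningResult:
    """Per-molecule screening outcome.

    ``probability`` is NaN and ``active`` False for molecules whose SMILES
    did not parse (flagged in ``valid``); screening never silently drops
    input rows.
    """

    smiles: list[str]
    probability: np.ndarray
    valid: np.ndarray
    threshold: float = ACTIVE_THRESHOLD
    fingerprint_radius: int = 2
    fingerprint_bits: int = 2048

    @property
    def active(self) -> np.ndarray:
        # strict inequality: a score of exactly 0.5 is not a candidate
        with np.errstate(invalid="ignore"):
            return np.where(self.valid, self.probability > self.threshold, False)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "smiles": self.smiles,
                "probability": self.probability,
                "active": self.active,
                "valid": self.valid,
            }
        )


def oversample_to_balance(
    records: list, labels: list[int] | np.ndarray, seed: int = 0
) -> tuple[list, np.ndarray]:
    """Duplicate minority-class items (sampling with replacement) to parity.

    The majority class is untouched; the set of distinct items never
    changes, only multiplicities.  Deterministic for a given seed.
    """
    labels = np.asarray(labels, dtype=int)
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to oversample")
    n_by_class = {c: int((labels == c).sum()) for c in classes}
    majority = max(n_by_class, key=n_by_class.get)
    minority = min(n_by_class, key=n_by_class.get)
    gap = n_by_class[majority] - n_by_class[minority]
    if gap == 0:
        return list(records), labels.copy()
    rng = np.random.default_rng(seed)
    minority_idx = np.flatnonzero(labels == minority)
    extra = rng.choice(minority_idx, size=gap, replace=True)
    out_records = list(records) + [records[i] for i in extra]
    out_labels = np.concatenate([labels, labels[extra]])
    return out_records, out_labels


class GelationClassifier(BaseEstimator, ClassifierMixin):
    """Probabilistic SVM screen for self-assembly propensity.

    sklearn-style classifier over SMILES strings (or MoleculeRecords):
    featurization to ECFP bits, minority oversampling, then
    ``SVC(kernel='rbf', C=10, gamma=0.01, probability=True)``.

    Fitted attributes: ``svm_``, ``featurizer_``, ``classes_``,
    ``n_features_in_``.
    """

    def __init__(
        self,
        C: float = 10.0,
        gamma: float = 0.01,
        kernel: str = "rbf",
        radius: int = 2,
        n_bits: int = 2048,
        oversample: bool = True,
        threshold: float = ACTIVE_THRESHOLD,
        seed: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel
        self.radius = radius
        self.n_bits = n_bits
        self.oversample = oversample
        self.threshold = threshold
        self.seed = seed

    # ------------------------------------------------------------------

    def _featurize(self, X, on_invalid="raise") -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 2 and X.shape[1] == self.n_bits:
            return X  # already fingerprints
        feat = EcfpFeaturizer(radius=self.radius, n_bits=self.n_bits, on_invalid=on_invalid)
        return feat.fit_transform(X)

    def fit(self, X, y) -> "GelationClassifier":
        """Fit on molecules ``X`` with binary labels ``y`` (1 = gel-forming)."""
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        for c in np.unique(y):
            if (y == c).sum() < 2:
                raise ValueError("need at least 2 examples per class")
        items = list(X)
        if self.oversample:
            items, y = oversample_to_balance(items, y, seed=self.seed)
        F = self._featurize(items)
        self.featurizer_ = EcfpFeaturizer(radius=self.radius, n_bits=self.n_bits)
        self.svm_ = SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            probability=True,
            random_state=self.seed,
        )
        self.svm_.fit(F, y)
        self.classes_ = self.svm_.classes_
        self.n_features_in_ = self.n_bits
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.predict_proba(self._featurize(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, list(self.classes_).index(1)]
        return (proba > self.threshold).astype(int)

    def screen(self, smiles: list[str]) -> ScreeningResult:
        """Score a list of SMILES; unparseable entries are flagged, not dropped."""
        check_is_fitted(self, "svm_")
        records = [
            s if isinstance(s, MoleculeRecord) else parse_and_standardize(str(s))
            for s in smiles
        ]
        valid = np.array([r.is_valid for r in records], dtype=bool)
        prob = np.full(len(records), np.nan)
        ok = [r for r in records if r.is_valid]
        if ok:
            pos_col = list(self.classes_).index(1)
            prob[valid] = self.predict_proba(ok)[:, pos_col]
        return ScreeningResult(
            smiles=[r.raw_smiles for r in records],
            probability=prob,
            valid=valid,
            threshold=self.threshold,
            fingerprint_radius=self.radius,
            fingerprint_bits=self.n_bits,
        )

    # ------------------------------------------------------------------
    # persistence

    def save(self, path: str) -> None:
        check_is_fitted(self, "svm_")
        import pickle, base64

        blob = base64.b64encode(pickle.dumps(self.svm_)).decode()
        meta = {
            "version": _MODEL_VERSION,
            "config": self.get_params(),
            "svm": blob,
        }
        with open(path, "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path: str, radius: int | None = None, n_bits: int | None = None):
        import pickle, base64

        with open(path) as fh:
            meta = json.load(fh)
        if meta.get("version") != _MODEL_VERSION:
            raise ValueError(f"model version mismatch: {meta.get('version')!r}")
        cfg = meta["config"]
        if radius is not None and radius != cfg["radius"]:
            raise ValueError(
                f"model was trained with fingerprint radius {cfg['radius']}, requested {radius}"
            )
        if n_bits is not None and n_bits != cfg["n_bits"]:
            raise ValueError(
                f"model was trained with {cfg['n_bits']}-bit fingerprints, requested {n_bits}"
            )
        clf = cls(**cfg)
        clf.svm_ = pickle.loads(base64.b64decode(meta["svm"]))
        clf.classes_ = clf.svm_.classes_
        clf.n_features_in_ = clf.n_bits
        return clf


def evaluate_auroc(classifier: GelationClassifier, X, y) -> float:
    """Rank-based area under the ROC curve on a labeled test set.

    Equals the Mann-Whitney concordance probability; ties get midranks.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes")
    pos_col = list(classifier.classes_).index(1)
    scores = classifier.predict_proba(X)[:, pos_col]
    return float(roc_auc_score(y, scores))


def grid_search_svm(
    X,
    y,
    C_grid=(0.1, 1.0, 10.0, 100.0),
    gamma_grid=(0.001, 0.01, 0.1),
    cv: int = 3,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUROC-scored grid search over (C, gamma); returns (C, gamma, auroc)."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    feats = EcfpFeaturizer().fit_transform(list(X))
    y = np.asarray(y, dtype=int)
    best = (None, None, -np.inf)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    for C in C_grid:
        for gamma in gamma_grid:
            svm = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
            score = cross_val_score(svm, feats, y, cv=skf, scoring="roc_auc").mean()
            if score > best[2]:
                best = (C, gamma, float(score))
    return best
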