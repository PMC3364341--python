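"""Pair classifiers: random forest and RBF-SVM, statsmodels-style.

:class:`DTIModel` is built from a training :class:`~dtiforge.pairs.PairDataset`
and a learner configuration; ``fit()`` returns a :class:`DTIResults` carrying
the fitted ensemble/solver state, the feature-scaling ranges, the training
entity-id sets (for known/new bookkeeping), and evaluation helpers.

The random forest's *binding score* of a pair is the fraction of trees voting
"interaction": a confidence in [0, 1] on a 1/ntree grid, with majority vote
recovered at the 0.5 threshold. The literal vote ratio votes(+1)/votes(-1) is
also exposed for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import __version__ as _pkg_version
from .exceptions import DtiforgeError
from .pairs import FeatureScaler, PairDataset


@dataclass
class RFConfig:
    """Random-forest settings: 500 unpruned trees, mtry = floor(sqrt(M))."""

    ntree: int = 500
    mtry: int | None = None  # None -> floor(sqrt(n_features))
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise DtiforgeError("ntree must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else int(math.isqrt(n_features))
        if not 1 <= m <= n_features:
            raise DtiforgeError(f"mtry {m} outside [1, {n_features}]")
        return m


def default_c_grid() -> list[float]:
    return [2.0**e for e in range(-5, 16, 2)]


def default_gamma_grid() -> list[float]:
    return [2.0**e for e in range(-15, 4, 2)]


@dataclass
class SVMConfig:
    """Soft-margin RBF-SVM with (C, gamma) chosen by 5-fold CV accuracy."""

    C_grid: list[float] = field(default_factory=default_c_grid)
    gamma_grid: list[float] = field(default_factory=default_gamma_grid)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise DtiforgeError("C and gamma grids must be nonempty")
        if min(self.C_grid) <= 0 or min(self.gamma_grid) <= 0:
            raise DtiforgeError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise DtiforgeError("cv_folds must be >= 2")


class DTIModel:
    """A drug-target pair classifier specification bound to training data.

    Parameters
    ----------
    train : PairDataset
        Labelled, (usually) scaled pair vectors; must contain both classes.
    method : {'rf', 'svm'}
    config : RFConfig or SVMConfig, optional
    """

    def __init__(self, train: PairDataset, method: str = "rf",
                 config: RFConfig | SVMConfig | None = None):
        if method not in ("rf", "svm"):
            raise DtiforgeError(f"unknown method {method!r}")
        classes = set(np.unique(train.y))
        if classes != {-1, 1}:
            raise DtiforgeError(
                f"training set must contain both classes, found {sorted(classes)}"
            )
        self.train = train
        self.method = method
        if config is None:
            config = RFConfig() if method == "rf" else SVMConfig()
        self.config = config

    @classmethod
    def from_catalog(cls, catalog, method: str = "rf", config=None, seed: int = 0):
        """Convenience constructor: balanced dataset straight from a catalog."""
        from .pairs import build_pair_dataset, scale_features

        dataset = build_pair_dataset(catalog, seed=seed)
        scaled, _, _ = scale_features(dataset)
        return cls(scaled, method=method, config=config)

    def fit(self) -> "DTIResults":
        X, y = self.train.X, self.train.y
        if self.method == "rf":
            cfg: RFConfig = self.config
            est = RandomForestClassifier(
                n_estimators=cfg.ntree,
                max_features=cfg.resolved_mtry(X.shape[1]),
                bootstrap=True,
                random_state=cfg.seed,
                n_jobs=1,
            )
            est.fit(X, y)
            return DTIResults(self, est)
        return self._fit_svm_grid()

    def _fit_svm_grid(self) -> "DTIResults":
        cfg: SVMConfig = self.config
        X, y = self.train.X, self.train.y
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        folds = list(skf.split(X, y))
        rows = []
        best = None  # (accuracy, -C, -gamma) maximization with smallest-C/gamma ties
        for C in sorted(cfg.C_grid):
            for gamma in sorted(cfg.gamma_grid):
                correct = 0
                for tr, te in folds:
                    svc = SVC(C=C, gamma=gamma, kernel="rbf")
                    svc.fit(X[tr], y[tr])
                    correct += int((svc.predict(X[te]) == y[te]).sum())
                acc = correct / len(y)
                rows.append({"C": C, "gamma": gamma, "cv_accuracy": acc})
                if best is None or acc > best[0]:
                    best = (acc, C, gamma)
        _, C, gamma = best
        est = SVC(C=C, gamma=gamma, kernel="rbf")
        est.fit(X, y)
        return DTIResults(self, est, chosen_params={"C": C, "gamma": gamma},
                          grid_table=pd.DataFrame(rows))


class DTIResults:
    """Fitted pair classifier plus its provenance and evaluation helpers."""

    def __init__(self, model: DTIModel, estimator, chosen_params: dict | None = None,
                 grid_table: pd.DataFrame | None = None):
        self.model = model
        self.kind = model.method
        self.config = model.config
        self.estimator = estimator
        self.chosen_params = chosen_params or {}
        self.grid_table = grid_table
        self.scaling: FeatureScaler | None = model.train.scaling
        self.train_drug_ids, self.train_target_ids = model.train.entity_sets()
        self.n_features = model.train.X.shape[1]

    # -- scoring ------------------------------------------------------------
    def _check_dims(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise DtiforgeError(
                f"pair vectors have {X.shape[1]} features; model expects {self.n_features}"
            )
        return X

    def tree_votes(self, X: np.ndarray) -> np.ndarray:
        """Number of trees voting +1 per pair (random forest only)."""
        if self.kind != "rf":
            raise DtiforgeError("tree votes are defined for random-forest results only")
        X = self._check_dims(X)
        votes = np.zeros(X.shape[0], dtype=int)
        for tree in self.estimator.estimators_:
            votes += (tree.predict(X) == 1).astype(int)
        return votes

    def binding_score(self, X: np.ndarray) -> np.ndarray:
        """Per-pair confidence in [0, 1].

        Random forest: fraction of trees voting interaction (granularity
        1/ntree). SVM: logistic squash of the decision value, so screening
        works with either learner on a common scale.
        """
        X = self._check_dims(X)
        if self.kind == "rf":
            return self.tree_votes(X) / self.config.ntree
        return 1.0 / (1.0 + np.exp(-self.estimator.decision_function(X)))

    def vote_ratio(self, X: np.ndarray) -> np.ndarray:
        """The literal votes(+1)/votes(-1) ratio (inf when unanimous)."""
        votes = self.tree_votes(X)
        ntree = self.config.ntree
        with np.errstate(divide="ignore"):
            return np.where(votes == ntree, np.inf, votes / (ntree - votes))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous ranking score: vote fraction (RF) or decision value (SVM)."""
        X = self._check_dims(X)
        if self.kind == "rf":
            return self.binding_score(X)
        return self.estimator.decision_function(X)

    def classify(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Labels in {+1, -1}; ties at the threshold go to +1.

        For the RF the threshold applies to the binding score (0.5 = majority
        vote); for the SVM the sign of the decision function is used, with the
        threshold applied to the logistic-calibrated score when it differs
        from 0.5.
        """
        X = self._check_dims(X)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=int)
        if self.kind == "rf":
            scores = self.binding_score(X)
            return np.where(scores >= threshold, 1, -1)
        if threshold == 0.5:
            f = self.estimator.decision_function(X)
            return np.where(f >= 0, 1, -1)
        return np.where(self.binding_score(X) >= threshold, 1, -1)

    def oob_error(self) -> float | None:
        """Out-of-bag error of the forest (None for SVM results)."""
        if self.kind != "rf":
            return None
        est = RandomForestClassifier(
            n_estimators=self.config.ntree,
            max_features=self.config.resolved_mtry(self.n_features),
            bootstrap=True,
            oob_score=True,
            random_state=self.config.seed,
            n_jobs=1,
        )
        est.fit(self.model.train.X, self.model.train.y)
        return 1.0 - est.oob_score_

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, dataset: PairDataset, threshold: float = 0.5):
        """SE/SP/CO and ROC-AUC of this classifier on a labelled dataset."""
        from .evaluation import evaluate_classifier

        return evaluate_classifier(self, dataset, threshold=threshold)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Drug-target pair classifier",
            "=" * 42,
            f"method:            {self.kind}",
            f"training pairs:    {len(self.model.train)} "
            f"({int((self.model.train.y == 1).sum())} +, "
            f"{int((self.model.train.y == -1).sum())} -)",
            f"pair dimension:    {self.n_features}",
            f"training drugs:    {len(self.train_drug_ids)}",
            f"training targets:  {len(self.train_target_ids)}",
        ]
        if self.kind == "rf":
            lines.append(f"trees:             {self.config.ntree}")
            lines.append(f"mtry:              {self.config.resolved_mtry(self.n_features)}")
        else:
            lines.append(f"chosen C:          {self.chosen_params.get('C')}")
            lines.append(f"chosen gamma:      {self.chosen_params.get('gamma')}")
            if self.grid_table is not None:
                lines.append(f"grid points:       {len(self.grid_table)}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Serialize the fitted bundle (model, config, scaling, id sets)."""
        import sklearn

        bundle = {
            "kind": self.kind,
            "config": asdict(self.config),
            "estimator": self.estimator,
            "chosen_params": self.chosen_params,
            "scaling": self.scaling,
            "train_drug_ids": sorted(self.train_drug_ids),
            "train_target_ids": sorted(self.train_target_ids),
            "n_features": self.n_features,
            "versions": {"dtiforge": _pkg_version, "sklearn": sklearn.__version__},
        }
        joblib.dump(bundle, path)

    @classmethod
    def load(cls, path) -> "DTIResults":
        bundle = joblib.load(path)
        obj = cls.__new__(cls)
        obj.model = None
        obj.kind = bundle["kind"]
        obj.config = (RFConfig if bundle["kind"] == "rf" else SVMConfig)(**bundle["config"])
        obj.estimator = bundle["estimator"]
        obj.chosen_params = bundle["chosen_params"]
        obj.grid_table = None
        obj.scaling = bundle["scaling"]
        obj.train_drug_ids = set(bundle["train_drug_ids"])
        obj.train_target_ids = set(bundle["train_target_ids"])
        obj.n_features = bundle["n_features"]
        return obj


# ---------------------------------------------------------------------------
# spec-surface wrappers
# ---------------------------------------------------------------------------

def train_random_forest(train: PairDataset, cfg: RFConfig | None = None) -> DTIResults:
    return DTIModel(train, method="rf", config=cfg or RFConfig()).fit()


def train_svm_grid(train: PairDataset, cfg: SVMConfig | None = None) -> DTIResults:
    return DTIModel(train, method="svm", config=cfg or SVMConfig()).fit()


def binding_score(results: DTIResults, pairs: np.ndarray) -> np.ndarray:
    return results.binding_score(pairs)


def classify_pairs(results: DTIResults, pairs: np.ndarray, threshold: float = 0.5
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Labels and ranking scores for a list of pair vectors."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    labels = results.classify(pairs, threshold=threshold)
    return labels, results.decision_scores(pairs)
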