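"""Stacked ensemble cancer classifier.

Each feature family (cnv / fsd / fragma) is fed to six base learner
families — GLM (L2 logistic regression), XRT (extremely randomized
trees), DRF (random forest), DeepLearning (small feed-forward net), GBM
(gradient-boosted trees) and XGBoost — with stratified 5-fold
cross-validation producing an out-of-fold cancer score per sample per
base model. The stacked score is the unweighted mean of the base scores
(a second-layer logistic meta-learner is available via
``combination="meta_glm"``); the best non-empty subset of feature blocks
is chosen by out-of-fold AUC. The decision cutoff is fixed on the
training cohort at 95% specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureMatrix",
    "BaseModelSpec",
    "TrainedEnsemble",
    "FAMILIES",
    "default_specs",
    "train_base_models",
    "stack",
    "fix_cutoff",
    "auc_score",
]

FAMILIES = ("GLM", "XRT", "DRF", "DeepLearning", "GBM", "XGBoost")


@dataclass
class FeatureMatrix:
    """Per-sample feature blocks with labels and split assignment."""

    sample_ids: list
    labels: np.ndarray  # bool, True = cancer
    split: np.ndarray  # "train" | "validation"
    blocks: dict  # name -> (n_samples, width) float array
    feature_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name, mat in self.blocks.items():
            if mat.shape[0] != n:
                raise ValueError(f"block {name!r} has {mat.shape[0]} rows, expected {n}")
            if np.isnan(mat).any():
                raise ValueError(f"block {name!r} contains NaN")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def total_width(self) -> int:
        return int(sum(m.shape[1] for m in self.blocks.values()))

    def block_widths(self) -> dict:
        return {k: int(v.shape[1]) for k, v in self.blocks.items()}

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(mask)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            split=self.split[idx],
            blocks={k: v[idx] for k, v in self.blocks.items()},
            feature_names=self.feature_names,
        )

    def training(self) -> "FeatureMatrix":
        return self.subset(self.split == "train")

    def validation(self) -> "FeatureMatrix":
        return self.subset(self.split == "validation")


@dataclass(frozen=True)
class BaseModelSpec:
    family: str
    feature_block: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def _estimator(spec: BaseModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.family == "GLM":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(C=hp.get("C", 1.0), max_iter=2000, random_state=seed),
        )
    if spec.family == "XRT":
        return ExtraTreesClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "DRF":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth"),
            max_features=hp.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "DeepLearning":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=hp.get("hidden_layer_sizes", (32, 16)),
                alpha=hp.get("alpha", 1e-3),
                max_iter=hp.get("max_iter", 400),
                random_state=seed,
            ),
        )
    if spec.family == "GBM":
        return GradientBoostingClassifier(
            n_estimators=hp.get("n_estimators", 100),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 3),
            random_state=seed,
        )
    if spec.family == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=hp.get("n_estimators", 150),
            learning_rate=hp.get("learning_rate", 0.1),
            max_depth=hp.get("max_depth", 4),
            reg_alpha=hp.get("reg_alpha", 0.0),
            reg_lambda=hp.get("reg_lambda", 1.0),
            subsample=hp.get("subsample", 1.0),
            colsample_bytree=hp.get("colsample_bytree", 1.0),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    raise AssertionError(spec.family)


_GRIDS = {
    "GLM": {"C": [0.01, 0.1, 1.0, 10.0]},
    "XRT": {"n_estimators": [200, 300, 500], "max_depth": [None, 6, 12]},
    "DRF": {"n_estimators": [200, 300, 500], "max_depth": [None, 6, 12]},
    "DeepLearning": {"hidden_layer_sizes": [(32, 16), (64, 32), (16,)], "alpha": [1e-4, 1e-3, 1e-2]},
    "GBM": {"n_estimators": [100, 150, 250], "max_depth": [2, 3, 4], "learning_rate": [0.05, 0.1]},
    "XGBoost": {
        "n_estimators": [100, 150, 250],
        "max_depth": [3, 4, 6],
        "learning_rate": [0.05, 0.1],
        "reg_lambda": [0.5, 1.0, 2.0],
    },
}


def default_specs(
    blocks: Sequence[str], seed: int = 0, grid_budget: int = 1
) -> list[BaseModelSpec]:
    """One spec per (feature block x learner family). ``grid_budget`` > 1
    draws that many random hyperparameter candidates per family (the best
    by out-of-fold AUC wins in :func:`train_base_models`); the default
    budget of 1 uses the fixed defaults."""
    rng = np.random.default_rng(seed)
    specs = []
    for block in blocks:
        for family in FAMILIES:
            for draw in range(grid_budget):
                if draw == 0:
                    hp = {}
                else:
                    hp = {k: v[rng.integers(len(v))] for k, v in _GRIDS[family].items()}
                specs.append(
                    BaseModelSpec(family=family, feature_block=block, hyperparameters=hp, seed=seed)
                )
    return specs


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (ties count 1/2)."""
    from scipy.stats import rankdata

    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required")
    ranks = rankdata(np.asarray(scores, dtype=float))
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _proba(model, X: np.ndarray) -> np.ndarray:
    return np.clip(model.predict_proba(X)[:, 1], 0.0, 1.0)


def train_base_models(
    train: FeatureMatrix,
    specs: Sequence[BaseModelSpec],
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Fit every base model with stratified k-fold CV.

    Returns (fitted models keyed by (block, family), out-of-fold score
    matrix with one column per key). When several specs share a (block,
    family) key — a hyperparameter grid — the candidate with the best
    out-of-fold AUC is kept. Each model is refit on the full training
    split for deployment after its out-of-fold scores are assembled.
    """
    y = train.labels.astype(int)
    if y.sum() < k or (len(y) - y.sum()) < k:
        raise ValueError(f"stratification error: need >= {k} samples per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(y)), y))
    best: dict[tuple, tuple] = {}  # key -> (auc, oof, spec)
    for spec in specs:
        X = train.blocks[spec.feature_block]
        oof = np.empty(len(y), dtype=float)
        for tr_idx, te_idx in folds:
            m = _estimator(spec)
            m.fit(X[tr_idx], y[tr_idx])
            oof[te_idx] = _proba(m, X[te_idx])
        a = auc_score(oof, y)
        key = (spec.feature_block, spec.family)
        if key not in best or a > best[key][0]:
            best[key] = (a, oof, spec)
    models: dict[tuple, object] = {}
    oof_cols = {}
    for key, (_, oof, spec) in best.items():
        X = train.blocks[spec.feature_block]
        final = _estimator(spec)
        final.fit(X, y)
        models[key] = final
        oof_cols[key] = oof
    oof_df = pd.DataFrame(oof_cols, index=train.sample_ids)
    return models, oof_df


def stack(
    scores: pd.DataFrame | np.ndarray,
    combination: str = "mean",
    meta=None,
) -> np.ndarray:
    """Combine base scores into the stacked cancer score, clipped to [0,1].

    ``mean`` averages the base scores; ``meta_glm`` applies a fitted
    second-layer logistic model (pass the model via ``meta``).
    """
    mat = scores.to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)
    if combination == "mean":
        return np.clip(mat.mean(axis=1), 0.0, 1.0)
    if combination == "meta_glm":
        if meta is None:
            raise ValueError("meta_glm stacking requires a fitted meta model")
        return np.clip(meta.predict_proba(mat)[:, 1], 0.0, 1.0)
    raise ValueError(f"unknown combination {combination!r}")


def fit_meta_glm(oof: pd.DataFrame, labels: np.ndarray, seed: int = 0):
    m = LogisticRegression(max_iter=2000, random_state=seed)
    m.fit(oof.to_numpy(), np.asarray(labels).astype(int))
    return m


def fix_cutoff(
    healthy_scores: np.ndarray, target_specificity: float = 0.95
) -> tuple[float, float]:
    """Smallest threshold t with frac(healthy < t) >= target.

    Candidates are the observed healthy scores themselves; when even the
    largest score leaves too few healthy below, t is the smallest
    representable value above the maximum. Returns (cutoff, achieved
    specificity). Prediction convention everywhere: score >= t => cancer.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target specificity must be in (0, 1)")
    s = np.sort(np.asarray(healthy_scores, dtype=float))
    n = len(s)
    if n == 0:
        raise ValueError("no healthy samples to set the cutoff")
    need = int(np.ceil(target_specificity * n))
    for t in np.unique(s):
        below = int((s < t).sum())
        if below >= need:
            return float(t), below / n
    t = float(np.nextafter(s[-1], np.inf))
    return t, 1.0


@dataclass
class TrainedEnsemble:
    """Fitted base models, selected feature blocks, combination rule and
    the training-derived decision cutoff."""

    models: dict  # (block, family) -> fitted estimator
    selected_blocks: tuple
    combination: str
    cutoff: float
    achieved_specificity: float
    oof: pd.DataFrame
    block_widths: dict
    meta: object = None
    seed: int = 0

    def base_scores(self, fm: FeatureMatrix) -> pd.DataFrame:
        cols = {}
        for (block, family), model in self.models.items():
            if block not in self.selected_blocks:
                continue
            if block not in fm.blocks:
                raise ValueError(f"missing feature block {block!r}")
            if fm.blocks[block].shape[1] != self.block_widths[block]:
                raise ValueError(
                    f"block {block!r} width {fm.blocks[block].shape[1]} != "
                    f"training width {self.block_widths[block]}"
                )
            cols[(block, family)] = _proba(model, fm.blocks[block])
        return pd.DataFrame(cols, index=fm.sample_ids)

    def scores(self, fm: FeatureMatrix) -> np.ndarray:
        return stack(self.base_scores(fm), self.combination, meta=self.meta)

    def predict(self, fm: FeatureMatrix) -> pd.DataFrame:
        """ScoreTable: per-sample cancer score in [0,1] and cutoff call."""
        s = self.scores(fm)
        return pd.DataFrame(
            {
                "sample_id": fm.sample_ids,
                "cancer_score": s,
                "predicted_label": np.where(s >= self.cutoff, "cancer", "healthy"),
                "true_label": np.where(fm.labels, "cancer", "healthy"),
            }
        )


def train_ensemble(
    train: FeatureMatrix,
    k: int = 5,
    seed: int = 0,
    combination: str = "mean",
    target_specificity: float = 0.95,
    grid_budget: int = 1,
    block_search: bool = True,
) -> TrainedEnsemble:
    """Full training procedure: base models with k-fold CV, block-subset
    selection by out-of-fold AUC (all 7 non-empty subsets of the 3 feature
    families), stacking, and the 95%-specificity training cutoff."""
    specs = default_specs(sorted(train.blocks), seed=seed, grid_budget=grid_budget)
    models, oof = train_base_models(train, specs, k=k, seed=seed)
    y = train.labels
    block_names = sorted(train.blocks)
    if block_search:
        from itertools import combinations

        candidates = [
            subset
            for r in range(1, len(block_names) + 1)
            for subset in combinations(block_names, r)
        ]
    else:
        candidates = [tuple(block_names)]
    best_subset, best_auc, best_meta = None, -1.0, None
    for subset in candidates:
        cols = [c for c in oof.columns if c[0] in subset]
        meta = fit_meta_glm(oof[cols], y, seed=seed) if combination == "meta_glm" else None
        s = stack(oof[cols], combination, meta=meta)
        a = auc_score(s, y)
        # ties break toward the larger subset (more signal axes retained)
        if a > best_auc or (a == best_auc and len(subset) > len(best_subset)):
            best_subset, best_auc, best_meta = subset, a, meta
    cols = [c for c in oof.columns if c[0] in best_subset]
    train_scores = stack(oof[cols], combination, meta=best_meta)
    cutoff, achieved = fix_cutoff(train_scores[~y], target_specificity)
    return TrainedEnsemble(
        models=models,
        selected_blocks=best_subset,
        combination=combination,
        cutoff=cutoff,
        achieved_specificity=achieved,
        oof=oof,
        block_widths=train.block_widths(),
        meta=best_meta,
        seed=seed,
    )
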