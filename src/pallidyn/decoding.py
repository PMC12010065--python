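"""Neural decoding of gene labels from neuron features (OVO and OVR).

Three models — a random-forest ensemble, a gradient-boosted ensemble, and
their soft-voting combination — are evaluated with stratified 5-fold
cross-validation. Standardization and imputation are fit inside each
training fold only (no leakage). Performance is the class-prevalence
weighted AUC averaged over folds (for two balanced classes this reduces to
the ordinary AUC); OVR contrasts additionally report balanced accuracy,
weighted F1 and the fold-summed confusion matrix. Chance level is the 95th
percentile of the AUC distribution over label-shuffle bootstrap iterations
in which new models are trained per shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier, VotingClassifier
from sklearn.metrics import balanced_accuracy_score, confusion_matrix, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .embedding import design_matrix

MODEL_NAMES = ("random_forest", "gradient_boost", "voting")


@dataclass
class DecodeConfig:
    """Model and CV hyperparameters (unstated upstream; fixed here, all exposed)."""

    n_folds: int = 5
    n_trees: int = 500
    max_depth: int | None = None
    gb_learning_rate: float = 0.1
    gb_n_estimators: int = 100
    models: tuple[str, ...] = MODEL_NAMES
    n_jobs: int = 1


@dataclass
class DecodeReport:
    contrast: str
    auc: dict[str, float]                      # model -> weighted AUC mean over folds
    balanced_accuracy: dict[str, float] = field(default_factory=dict)
    f1_weighted: dict[str, float] = field(default_factory=dict)
    confusion: np.ndarray | None = None        # summed over folds (random forest)
    chance_threshold: float | None = None
    above_chance: bool | None = None


def _make_models(cfg: DecodeConfig, seed: int) -> dict[str, object]:
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees, max_depth=cfg.max_depth,
        class_weight="balanced", random_state=seed, n_jobs=cfg.n_jobs,
    )
    gb = GradientBoostingClassifier(
        learning_rate=cfg.gb_learning_rate, n_estimators=cfg.gb_n_estimators,
        random_state=seed,
    )
    members = {"random_forest": rf, "gradient_boost": gb}
    models: dict[str, object] = {name: members[name] for name in cfg.models if name in members}
    if "voting" in cfg.models:
        import copy

        models["voting"] = VotingClassifier(
            estimators=[(k, copy.deepcopy(members[k])) for k in ("random_forest", "gradient_boost")],
            voting="soft",
        )
    return {name: Pipeline([("scale", StandardScaler()), ("clf", m)]) for name, m in models.items()}


def _sample_weights(y: np.ndarray) -> np.ndarray:
    """Inverse-prevalence weights (class balance for models without class_weight)."""
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[c] for c in y])


def _cv_evaluate(X: np.ndarray, y: np.ndarray, cfg: DecodeConfig, seed: int,
                 want_confusion: bool = False) -> DecodeReport:
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    aucs: dict[str, list[float]] = {m: [] for m in cfg.models}
    baccs: dict[str, list[float]] = {m: [] for m in cfg.models}
    f1s: dict[str, list[float]] = {m: [] for m in cfg.models}
    conf = np.zeros((2, 2), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        models = _make_models(cfg, seed + 1000 * fold)
        sw = _sample_weights(y[tr])
        for name, pipe in models.items():
            if name == "gradient_boost":
                pipe.fit(X[tr], y[tr], clf__sample_weight=sw)
            else:
                pipe.fit(X[tr], y[tr])
            prob = pipe.predict_proba(X[te])[:, 1]
            pred = (prob >= 0.5).astype(int)
            aucs[name].append(roc_auc_score(y[te], prob, average="weighted"))
            baccs[name].append(balanced_accuracy_score(y[te], pred))
            f1s[name].append(f1_score(y[te], pred, average="weighted"))
            if want_confusion and name == "random_forest":
                conf += confusion_matrix(y[te], pred, labels=[0, 1])
    return DecodeReport(
        contrast="",
        auc={m: float(np.mean(v)) for m, v in aucs.items()},
        balanced_accuracy={m: float(np.mean(v)) for m, v in baccs.items()},
        f1_weighted={m: float(np.mean(v)) for m, v in f1s.items()},
        confusion=conf if want_confusion else None,
    )


def _xy(table: pd.DataFrame, pos_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = design_matrix(table).to_numpy(dtype=float)
    y = pos_mask.astype(int)
    return X, y


def ovo_decode(table: pd.DataFrame, gene_a: str, gene_b: str,
               cfg: DecodeConfig | None = None, seed: int = 0) -> DecodeReport:
    """One-vs-one decoding of two genes from the feature table."""
    cfg = cfg or DecodeConfig()
    sub = table[table["gene"].isin([gene_a, gene_b])].reset_index(drop=True)
    for g in (gene_a, gene_b):
        n = int((sub["gene"] == g).sum())
        if n < 2 * cfg.n_folds:
            raise ValueError(f"gene {g} has {n} neurons; needs >= {2 * cfg.n_folds}")
    X, y = _xy(sub, (sub["gene"] == gene_b).to_numpy())
    rep = _cv_evaluate(X, y, cfg, seed)
    rep.contrast = f"{gene_a} vs {gene_b}"
    return rep


def ovr_decode(table: pd.DataFrame, gene: str,
               cfg: DecodeConfig | None = None, seed: int = 0) -> DecodeReport:
    """One-vs-rest decoding of one gene against the pooled remainder."""
    cfg = cfg or DecodeConfig()
    n = int((table["gene"] == gene).sum())
    if n < 2 * cfg.n_folds:
        raise ValueError(f"gene {gene} has {n} neurons; needs >= {2 * cfg.n_folds}")
    sub = table.reset_index(drop=True)
    X, y = _xy(sub, (sub["gene"] == gene).to_numpy())
    rep = _cv_evaluate(X, y, cfg, seed, want_confusion=True)
    rep.contrast = f"{gene} vs rest"
    return rep


def bootstrap_chance(table: pd.DataFrame, contrast: tuple[str, str] | str,
                     n_iter: int = 100, cfg: DecodeConfig | None = None,
                     seed: int = 0, model: str = "random_forest") -> float:
    """95th percentile of the weighted AUC over ``n_iter`` label shuffles.

    Gene labels are shuffled across neurons and the full CV pipeline is
    retrained per iteration; the 95th percentile of the resulting AUC
    distribution is the upper threshold of chance performance.
    """
    cfg = cfg or DecodeConfig()
    rng = np.random.default_rng(seed)
    if isinstance(contrast, tuple):
        sub = table[table["gene"].isin(contrast)].reset_index(drop=True)
        pos = (sub["gene"] == contrast[1]).to_numpy()
    else:
        sub = table.reset_index(drop=True)
        pos = (sub["gene"] == contrast).to_numpy()
    X, y = _xy(sub, pos)
    one_cfg = DecodeConfig(**{**cfg.__dict__, "models": (model,)})
    aucs = np.empty(n_iter)
    for i in range(n_iter):
        y_shuf = rng.permutation(y)
        rep = _cv_evaluate(X, y_shuf, one_cfg, seed=int(rng.integers(0, 2**31 - 1)))
        aucs[i] = rep.auc[model]
    return float(np.percentile(aucs, 95))
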