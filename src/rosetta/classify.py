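"""Two-stage gradient-boosted assessment with iterative pruning.

Stage 1 (the *gate*) decides whether any target condition — autism or
ADHD — is present; stage 2 (the *discriminator*) separates autism from
ADHD and is consulted only for rows the gate flags as positive.  Both
stages are gradient-boosted decision trees.  Feature/row selection uses an
iterative loop that removes the single worst row or feature per step —
features scored by tree importance weighted by post-imputation coverage,
rows by their fraction of unimputable cells — until cross-validated
performance stops improving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .impute import FAILED, ImputedMatrix

__all__ = [
    "ClassifierConfig",
    "TwoStageModel",
    "CVResult",
    "train_two_stage",
    "iterative_prune",
    "predict",
    "cross_validate",
]

POSITIVE_CLASSES = ("autism", "adhd")


@dataclass
class ClassifierConfig:
    k_folds: int = 20
    gate_threshold: float = 0.5
    max_depth: int = 3
    n_rounds: int = 200
    learning_rate: float = 0.1
    prune: bool = True
    prune_patience: int = 3
    prune_objective: str = "mean"  # "stage1" | "stage2" | "mean"
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.gate_threshold < 1:
            raise ValueError("gate_threshold must lie in (0, 1)")
        if self.prune_objective not in ("stage1", "stage2", "mean"):
            raise ValueError(f"unknown prune objective {self.prune_objective!r}")


@dataclass
class TwoStageModel:
    stage1: XGBClassifier
    stage2: XGBClassifier
    selected_features: list[str]
    gate_threshold: float
    prune_trace: pd.DataFrame | None = None
    stage2_invocations: int = field(default=0)


@dataclass
class CVResult:
    stage1_auc: float
    stage2_auc: float
    per_fold: pd.DataFrame
    fold_assignments: pd.Series


def _as_frame(data) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Accept an ImputedMatrix (values + provenance) or a bare DataFrame
    (provenance inferred: NaN cells count as failed)."""
    if isinstance(data, ImputedMatrix):
        return data.values, data.provenance
    frame = pd.DataFrame(data)
    return frame, None


def _align_labels(values: pd.DataFrame, labels) -> pd.Series:
    """Align labels to the matrix rows by index when both carry the same
    index set; otherwise pair them positionally."""
    s = pd.Series(labels)
    if set(s.index) == set(values.index):
        return s.reindex(values.index)
    if len(s) != len(values):
        raise ValueError("labels must cover every matrix row")
    return pd.Series(s.to_numpy(), index=values.index)


def _booster(config: ClassifierConfig, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=config.n_rounds,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
    )


def _fit_stages(
    X: pd.DataFrame, labels: pd.Series, config: ClassifierConfig, seed: int
) -> tuple[XGBClassifier, XGBClassifier]:
    y = np.asarray(labels)
    pos = np.isin(y, POSITIVE_CLASSES)
    if len(np.unique(pos)) < 2:
        raise ValueError("gate stage needs both positive and negative rows")
    y2 = y[pos]
    if len(np.unique(y2)) < 2:
        raise ValueError("discriminator stage needs both autism and ADHD rows")
    Xv = X.to_numpy(dtype=float)
    stage1 = _booster(config, seed)
    stage1.fit(Xv, pos.astype(int))
    stage2 = _booster(config, seed + 1)
    # positive class of the discriminator = autism
    stage2.fit(Xv[pos], (y2 == "autism").astype(int))
    return stage1, stage2


def train_two_stage(imputed, labels: pd.Series, config: ClassifierConfig) -> TwoStageModel:
    """Fit the gate and discriminator, optionally preceded by the pruning
    loop.  The discriminator is trained on truly condition-positive rows;
    gate filtering applies only at prediction time."""
    values, _ = _as_frame(imputed)
    labels = _align_labels(values, labels)
    trace = None
    rows, feats = list(values.index), list(values.columns)
    if config.prune:
        rows, feats, trace = iterative_prune(imputed, labels, config)
    stage1, stage2 = _fit_stages(
        values.loc[rows, feats], labels.loc[rows], config, config.seed
    )
    return TwoStageModel(
        stage1=stage1, stage2=stage2, selected_features=list(feats),
        gate_threshold=config.gate_threshold, prune_trace=trace,
    )


def predict(model: TwoStageModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-row label plus stage probabilities.

    Rows with gate probability below the threshold are labelled
    ``neither`` and never reach the discriminator; for them ``p_autism``
    is NaN.
    """
    missing = [f for f in model.selected_features if f not in rows.columns]
    if missing:
        raise ValueError(f"rows lack selected features: {missing}")
    X = rows[model.selected_features].to_numpy(dtype=float)
    p_cond = model.stage1.predict_proba(X)[:, 1]
    gated = p_cond >= model.gate_threshold
    p_autism = np.full(len(rows), np.nan)
    labels = np.array(["neither"] * len(rows), dtype=object)
    if gated.any():
        model.stage2_invocations += int(gated.sum())
        p2 = model.stage2.predict_proba(X[gated])[:, 1]
        p_autism[gated] = p2
        labels[gated] = np.where(p2 >= 0.5, "autism", "adhd")
    return pd.DataFrame(
        {"label": labels, "p_condition": p_cond, "p_autism": p_autism},
        index=rows.index,
    )


def cross_validate(imputed, labels: pd.Series, config: ClassifierConfig) -> CVResult:
    """Stratified k-fold cross-validation of both stages.

    Folds stratify on the three-way label.  The gate AUC pools
    out-of-fold gate probabilities over all rows (positive union vs
    neither); the discriminator AUC pools out-of-fold discriminator
    probabilities over the truly condition-positive rows (autism vs ADHD).
    """
    values, _ = _as_frame(imputed)
    y = _align_labels(values, labels).to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < config.k_folds).any():
        raise ValueError(
            f"every class needs >= k_folds={config.k_folds} rows for "
            f"stratification; got {counts.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=config.seed)
    Xv = values.to_numpy(dtype=float)
    pos = np.isin(y, POSITIVE_CLASSES)
    oof_gate = np.full(len(y), np.nan)
    oof_disc = np.full(len(y), np.nan)
    fold_of = np.zeros(len(y), dtype=int)
    fold_rows = []
    for f, (tr, te) in enumerate(skf.split(Xv, y)):
        fold_of[te] = f
        cfg = config
        s1, s2 = _fit_stages(values.iloc[tr], pd.Series(y[tr]), cfg,
                             cfg.seed + 101 * f)
        oof_gate[te] = s1.predict_proba(Xv[te])[:, 1]
        te_pos = te[pos[te]]
        if len(te_pos):
            oof_disc[te_pos] = s2.predict_proba(Xv[te_pos])[:, 1]
        f_gate = (roc_auc_score(pos[te], oof_gate[te])
                  if len(np.unique(pos[te])) == 2 else np.nan)
        y2 = (y[te_pos] == "autism").astype(int)
        f_disc = (roc_auc_score(y2, oof_disc[te_pos])
                  if len(np.unique(y2)) == 2 else np.nan)
        fold_rows.append((f, f_gate, f_disc, len(te)))
    stage1_auc = float(roc_auc_score(pos, oof_gate))
    y2_all = (y[pos] == "autism").astype(int)
    stage2_auc = (float(roc_auc_score(y2_all, oof_disc[pos]))
                  if len(np.unique(y2_all)) == 2 else float("nan"))
    per_fold = pd.DataFrame(
        fold_rows, columns=["fold", "stage1_auc", "stage2_auc", "n"]
    )
    return CVResult(
        stage1_auc=stage1_auc, stage2_auc=stage2_auc, per_fold=per_fold,
        fold_assignments=pd.Series(fold_of, index=values.index, name="fold"),
    )


def _objective(cv: CVResult, objective: str) -> float:
    if objective == "stage1":
        return cv.stage1_auc
    if objective == "stage2":
        return cv.stage2_auc
    return float(np.nanmean([cv.stage1_auc, cv.stage2_auc]))


def iterative_prune(
    imputed, labels: pd.Series, config: ClassifierConfig
) -> tuple[list, list[str], pd.DataFrame]:
    """Remove the single worst row or feature per iteration until the
    cross-validated objective stops improving.

    Feature badness is ``1 - normalized_importance x coverage`` (importance
    averaged over the two stages, coverage = fraction of valid cells after
    imputation); row badness is the row's failed-cell fraction.  The
    candidate with the higher badness is removed (ties favour the feature).
    Stops after ``prune_patience`` non-improving steps, or when further
    removal would leave fewer than two features or break stratification.
    Returns the best-scoring (rows, features, trace).
    """
    values, provenance = _as_frame(imputed)
    labels = _align_labels(values, labels)
    if provenance is None:
        failed = values.isna()
    else:
        failed = provenance == FAILED

    rows = list(values.index)
    feats = list(values.columns)

    def cv_score(r, f):
        cv = cross_validate(values.loc[r, f], labels.loc[r], config)
        return _objective(cv, config.prune_objective)

    trace_rows: list[tuple] = []
    best_score = cv_score(rows, feats)
    best_state = (list(rows), list(feats))
    trace_rows.append((0, "initial", "", best_score))
    stall = 0
    step = 0
    eps = 1e-9
    while len(feats) > 2 and stall < config.prune_patience:
        step += 1
        sub_vals = values.loc[rows, feats]
        sub_labels = labels.loc[rows]
        # feature scores from a fit on the current state
        try:
            s1, s2 = _fit_stages(sub_vals, sub_labels, config,
                                 config.seed + 7919 * step)
            imp = (s1.feature_importances_ + s2.feature_importances_) / 2.0
        except ValueError:
            break
        imp_max = imp.max()
        norm_imp = imp / imp_max if imp_max > 0 else np.zeros_like(imp)
        cov = 1.0 - failed.loc[rows, feats].mean(axis=0).to_numpy()
        feat_bad = 1.0 - norm_imp * cov
        worst_feat_idx = int(np.argmax(feat_bad))

        row_bad = failed.loc[rows, feats].mean(axis=1).to_numpy()
        worst_row_idx = int(np.argmax(row_bad))

        remove_feature = feat_bad[worst_feat_idx] >= row_bad[worst_row_idx]
        if not remove_feature:
            # do not break stratification by dropping a scarce class
            cls = sub_labels.iloc[worst_row_idx]
            if (sub_labels == cls).sum() - 1 < config.k_folds:
                remove_feature = True
        if remove_feature:
            removed = feats[worst_feat_idx]
            feats = [f for f in feats if f != removed]
            kind = "feature"
        else:
            removed = rows[worst_row_idx]
            rows = [r for r in rows if r != removed]
            kind = "row"

        score = cv_score(rows, feats)
        trace_rows.append((step, kind, str(removed), score))
        if score > best_score + eps:
            best_score = score
            best_state = (list(rows), list(feats))
            stall = 0
        else:
            stall += 1

    trace = pd.DataFrame(
        trace_rows, columns=["step", "removed_kind", "removed_id", "cv_score"]
    )
    return best_state[0], best_state[1], trace
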