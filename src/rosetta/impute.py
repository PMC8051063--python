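"""Constraint-based ensemble random-forest imputation.

For each question (feature) with missing codes, an ensemble of random
forests is grown: every ensemble member draws a random subset of candidate
predictor features and trains only on rows with complete coverage of that
subset in the *original* observed mask — imputed values never feed later
predictions, which avoids the cascading errors of chained multiple
imputation.  A draw is discarded when any labeled class contributes fewer
than ``min_class_samples`` training rows.  Draws repeat until every target
row has accumulated at least ``min_predictions`` predictions (or the draw
cap is reached); accumulated predictions are averaged and clamped to the
question's code range.  Target rows that never reach the minimum remain
missing and are flagged ``failed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .crosswalk import RosettaMatrix

__all__ = [
    "ImputationConfig",
    "ImputedMatrix",
    "impute",
    "coverage_profile",
]

OBSERVED, IMPUTED, FAILED = "observed", "imputed", "failed"


@dataclass
class ImputationConfig:
    min_class_samples: int = 50
    min_predictions: int = 10
    subset_size_range: tuple[int, int] = (3, 20)
    trees_per_forest: int = 100
    max_draws_per_feature: int = 200
    mode: str = "regression"  # or "classification"
    round_values: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.min_class_samples < 1:
            raise ValueError("min_class_samples must be >= 1")
        if self.min_predictions < 1:
            raise ValueError("min_predictions must be >= 1")
        lo, hi = self.subset_size_range
        if lo < 1 or hi < lo:
            raise ValueError("subset_size_range must satisfy 1 <= lo <= hi")
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ImputedMatrix:
    """Imputation result: values, per-cell provenance and per-cell
    prediction counts.

    Provenance holds ``observed`` / ``imputed`` / ``failed`` per cell
    (cells of fully observed questions are all ``observed``).  Values of
    failed cells are NaN.
    """

    values: pd.DataFrame
    provenance: pd.DataFrame
    prediction_counts: pd.DataFrame
    code_ranges: dict[str, int]

    @property
    def n_imputed(self) -> int:
        return int((self.provenance == IMPUTED).to_numpy().sum())

    @property
    def n_failed(self) -> int:
        return int((self.provenance == FAILED).to_numpy().sum())

    def valid_mask(self) -> pd.DataFrame:
        return self.provenance != FAILED

    def to_csv(self, path, provenance_path=None) -> None:
        self.values.to_csv(path, index_label="child_id")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, index_label="child_id")


def impute(
    matrix: RosettaMatrix, labels: pd.Series, config: ImputationConfig
) -> ImputedMatrix:
    """Run the ensemble imputation over every feature with missing values.

    ``labels`` (indexed like the matrix rows, or positionally aligned)
    enters only through the class-size guard: candidate draws whose
    training pool under-represents any labeled class are discarded, so
    imputations are never extrapolated from a pool that a class is absent
    from.
    """
    codes = matrix.codes
    labels = pd.Series(labels)
    if len(labels) != len(codes):
        raise ValueError("labels must cover every matrix row")
    y_class = labels.to_numpy()

    X = codes.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    n, p = X.shape
    if observed.sum() == 0 or p < 2:
        raise ValueError("matrix has no usable observed structure to impute from")

    rng = np.random.default_rng(config.seed)
    lo, hi = config.subset_size_range
    hi = min(hi, p - 1)
    lo = min(lo, hi)

    values = X.copy()
    provenance = np.full((n, p), OBSERVED, dtype=object)
    provenance[~observed] = FAILED  # upgraded to IMPUTED on success
    counts = np.zeros((n, p), dtype=int)

    classes = np.unique(y_class)
    columns = list(codes.columns)

    for j in range(p):
        target_rows = np.nonzero(~observed[:, j])[0]
        if len(target_rows) == 0:
            continue
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n, dtype=int)
        hopeless = np.zeros(n, dtype=bool)
        candidates = np.array([c for c in range(p) if c != j])
        for _ in range(config.max_draws_per_feature):
            short = pred_cnt[target_rows] < config.min_predictions
            need = target_rows[short & ~hopeless[target_rows]]
            if len(need) == 0:
                break
            # anchor the draw on a row still short of predictions: sample
            # the candidate subset from features observed for that row, so
            # every draw can serve at least one under-covered sample
            anchor = int(need[rng.integers(len(need))])
            avail = candidates[observed[anchor, candidates]]
            if len(avail) < lo:
                hopeless[anchor] = True
                continue
            size = int(rng.integers(lo, min(hi, len(avail)) + 1))
            subset = rng.choice(avail, size=size, replace=False)
            full_cov = observed[:, subset].all(axis=1)
            train = full_cov & observed[:, j]
            if not train.any():
                continue
            # class-size guard on the training pool
            train_classes = y_class[train]
            if any((train_classes == c).sum() < config.min_class_samples
                   for c in classes):
                continue
            infer = full_cov & ~observed[:, j]
            if not infer.any():
                continue
            forest_seed = int(rng.integers(0, 2**31 - 1))
            if config.mode == "regression":
                forest = RandomForestRegressor(
                    n_estimators=config.trees_per_forest,
                    random_state=forest_seed, n_jobs=1,
                )
            else:
                forest = RandomForestClassifier(
                    n_estimators=config.trees_per_forest,
                    random_state=forest_seed, n_jobs=1,
                )
            forest.fit(X[np.ix_(train.nonzero()[0], subset)], X[train, j])
            preds = forest.predict(X[np.ix_(infer.nonzero()[0], subset)])
            idx = infer.nonzero()[0]
            pred_sum[idx] += preds.astype(float)
            pred_cnt[idx] += 1

        m = matrix.code_ranges.get(columns[j])
        done = target_rows[pred_cnt[target_rows] >= config.min_predictions]
        for i in done:
            val = pred_sum[i] / pred_cnt[i]
            if config.round_values:
                val = float(np.floor(val + 0.5))
            if m is not None:
                val = float(np.clip(val, 1.0, m))
            values[i, j] = val
            provenance[i, j] = IMPUTED
            counts[i, j] = pred_cnt[i]

    idx, cols = codes.index, codes.columns
    return ImputedMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        provenance=pd.DataFrame(provenance, index=idx, columns=cols),
        prediction_counts=pd.DataFrame(counts, index=idx, columns=cols),
        code_ranges=dict(matrix.code_ranges),
    )


def coverage_profile(
    matrix: RosettaMatrix | ImputedMatrix,
) -> tuple[pd.Series, pd.Series]:
    """Observed (or valid, for an imputed matrix) fractions per row and per
    feature: ``(row_coverage, feature_coverage)``."""
    if isinstance(matrix, ImputedMatrix):
        mask = matrix.valid_mask()
    else:
        mask = matrix.mask
    row = mask.mean(axis=1)
    col = mask.mean(axis=0)
    row.name, col.name = "row_coverage", "feature_coverage"
    return row, col
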