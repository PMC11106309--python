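"""Disentanglement scoring of latent representations.

Random forests predict each generative factor (V gene, J gene, mean insert
physicochemistry) from the latent vectors; the per-latent-dimension feature
importances form a relative-importance matrix R.  The disentanglement score
normalizes each latent dimension's row of R to a probability vector P_i,
scores the dimension by one minus its entropy (logarithm base K = number of
factors), and averages with weights proportional to the dimension's total
importance:

    D_i   = 1 - H_K(P_i)
    rho_i = sum_j R_ij / sum_ij R_ij
    score = sum_i rho_i D_i in [0, 1].

A score of 1 means every informative dimension encodes exactly one factor;
0 means every dimension spreads its importance uniformly over all factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score

DEFAULT_GRID = {"n_estimators": [100], "max_depth": [None, 8, 16]}


class FactorError(ValueError):
    pass


@dataclass
class ImportanceMatrix:
    R: np.ndarray                       # n_latent x n_factors, >= 0
    factor_names: tuple[str, ...]
    predictive_scores: dict[str, float]  # AUROC (categorical) / R2 (continuous)

    def normalized_frame(self) -> pd.DataFrame:
        """Row-normalized importances for Hinton-style plotting."""
        row_sums = self.R.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            norm = np.where(row_sums > 0, self.R / row_sums, 0.0)
        return pd.DataFrame(norm, columns=list(self.factor_names))

    def report(self) -> dict:
        """JSON-serializable summary: R, scores, D_i, rho_i, total."""
        d, total = disentanglement_score(self)
        rho = self.R.sum(axis=1) / self.R.sum()
        return {
            "R": self.R.tolist(),
            "factor_names": list(self.factor_names),
            "predictive_scores": self.predictive_scores,
            "per_dimension_score": d.tolist(),
            "dimension_weights": rho.tolist(),
            "disentanglement_score": total,
        }


def _fit_one(latents: np.ndarray, y, categorical: bool, cv_folds: int,
             seed: int) -> tuple[np.ndarray, float]:
    if categorical:
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise FactorError("categorical factor has a single class")
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scoring = "roc_auc_ovr_weighted" if len(np.unique(y)) > 2 else "roc_auc"
    else:
        est = RandomForestRegressor(random_state=seed, n_jobs=1)
        cv = cv_folds
        scoring = "r2"
    search = GridSearchCV(est, DEFAULT_GRID, cv=cv, scoring=scoring, n_jobs=1)
    search.fit(latents, y)
    best = search.best_estimator_  # refit on the full sample
    return best.feature_importances_, float(search.best_score_)


def fit_factor_predictors(latents: np.ndarray, factors: pd.DataFrame,
                          cv_folds: int = 5, sample_cap: int = 100_000,
                          seed: int = 0) -> ImportanceMatrix:
    """Fit one forest per factor and collect importances.

    ``factors`` columns: ``v_gene`` and ``j_gene`` (categorical) and
    ``mean_insert`` (array-valued 7-vectors, or scalar; rows with missing
    insert are excluded from the regression).  Hyperparameters are chosen
    by cross-validation, then each forest is refit on the full (capped)
    sample; column j of R holds the refit importances for factor j.
    """
    latents = np.asarray(latents)
    if len(latents) != len(factors):
        raise ValueError("latents and factors are misaligned")
    rng = np.random.default_rng(seed)
    if len(latents) > sample_cap:
        idx = rng.choice(len(latents), size=sample_cap, replace=False)
        latents = latents[idx]
        factors = factors.iloc[idx].reset_index(drop=True)

    columns: list[np.ndarray] = []
    names: list[str] = []
    scores: dict[str, float] = {}
    for name in ("v_gene", "j_gene"):
        if name in factors:
            imp, score = _fit_one(latents, factors[name], True, cv_folds, seed)
            columns.append(imp)
            names.append(name)
            scores[name] = score
    if "mean_insert" in factors:
        mask = factors["mean_insert"].notna()
        y = np.stack([np.atleast_1d(np.asarray(v, dtype=float))
                      for v in factors.loc[mask, "mean_insert"]])
        if y.shape[1] == 1:
            y = y[:, 0]
        imp, score = _fit_one(latents[mask.to_numpy()], y, False, cv_folds, seed)
        columns.append(imp)
        names.append("mean_insert")
        scores["mean_insert"] = score
    if not columns:
        raise FactorError("no recognized factor columns")
    return ImportanceMatrix(R=np.column_stack(columns),
                            factor_names=tuple(names),
                            predictive_scores=scores)


def disentanglement_score(R: ImportanceMatrix | np.ndarray
                          ) -> tuple[np.ndarray, float]:
    """Per-dimension scores D_i and importance-weighted total."""
    mat = R.R if isinstance(R, ImportanceMatrix) else np.asarray(R, dtype=float)
    if mat.ndim != 2 or (mat < 0).any():
        raise ValueError("importance matrix must be 2-D and non-negative")
    total_mass = mat.sum()
    if total_mass == 0:
        raise ValueError("all-zero importance matrix")
    n_factors = mat.shape[1]
    row_sums = mat.sum(axis=1)
    d = np.zeros(len(mat))
    nz = row_sums > 0
    p = mat[nz] / row_sums[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=1) / np.log(n_factors)
    d[nz] = 1.0 - entropy
    rho = row_sums / total_mass
    return d, float((rho * d).sum())


def shuffled_baseline(latents: np.ndarray, factors: pd.DataFrame,
                      seed: int = 0, **kwargs) -> ImportanceMatrix:
    """Permutation null: factor labels shuffled independently of latents."""
    rng = np.random.default_rng(seed)
    shuffled = factors.sample(frac=1.0, random_state=int(rng.integers(2**31))
                              ).reset_index(drop=True)
    return fit_factor_predictors(latents, shuffled, seed=seed, **kwargs)
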