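"""Random-forest attribution of F-IBI variation to environmental drivers.

The response (a site's F-IBI total, or one metric's score) is regressed
on human-pressure covariates (GDP, land-use ratio LUR, cumulative
connectivity-time effect CTP) and environmental-filtering covariates
(water area WA, runoff VR, air temperature TEM, precipitation PRE,
free-flowing reach length NRAD, habitat type HT, drainage density DWN,
elevation ALT) with a bootstrap regression forest.  Variable importance
is reported two ways, mirroring the randomForest convention:

* permutation importance (%IncMSE-style): mean increase in out-of-bag
  MSE when a covariate is permuted among each tree's OOB rows, expressed
  as a percentage of the overall OOB MSE;
* node-purity importance: total impurity (SSE) decrease contributed by
  the covariate's splits, summed over trees.

The forest is authored here as a bootstrap ensemble of scikit-learn
decision trees with explicit out-of-bag bookkeeping, because the OOB
permutation scheme needs per-tree OOB indices.  Explained variance is
the OOB pseudo-R^2 (1 - MSE_oob / Var(y)); a leave-one-out R^2 from
refitted forests is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.tree import DecisionTreeRegressor

from .core_data import ValidationError

__all__ = [
    "ORDINAL_COVARIATES",
    "DriverModelResult",
    "prepare_covariates",
    "fit_driver_model",
    "fit_response_curves",
    "per_metric_models",
]

#: Covariates passed through untransformed (ordinal categories).
ORDINAL_COVARIATES = ("HT", "CTP")


def prepare_covariates(
    metadata: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    ordinal: Sequence[str] = ORDINAL_COVARIATES,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """log10(x + 1)-transform continuous covariates; pass ordinals through.

    Returns the model matrix and a per-column transform log.  Negative
    continuous values are an error (the transform is undefined there).
    """
    if covariates is None:
        standard = ("WA", "VR", "TEM", "PRE", "NRAD", "LUR", "HT", "GDP", "DWN", "CTP", "ALT")
        present = [c for c in standard if c in metadata.columns]
        covariates = present if present else list(metadata.columns)
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise ValidationError(f"covariates missing from metadata: {missing}")
    x = metadata[list(covariates)].astype(float).copy()
    transforms: dict[str, str] = {}
    for col in x.columns:
        if col in ordinal:
            transforms[col] = "identity (ordinal)"
            continue
        if (x[col] < 0).any():
            raise ValidationError(
                f"covariate {col!r} has negative values; log10(x+1) undefined"
            )
        x[col] = np.log10(x[col] + 1.0)
        transforms[col] = "log10(x+1)"
    return x, transforms


class _BootstrapForest:
    """Regression forest with explicit bootstrap/OOB bookkeeping."""

    def __init__(
        self,
        n_trees: int = 1000,
        max_features: float = 1 / 3,
        min_samples_leaf: int = 2,
        seed: int | np.random.Generator | None = None,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.rng = np.random.default_rng(seed)
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_indices: list[np.ndarray] = []

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_BootstrapForest":
        n, p = x.shape
        mtry = max(1, int(round(self.max_features * p)))
        for _ in range(self.n_trees):
            boot = self.rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(self.rng.integers(0, 2**31 - 1)),
            )
            tree.fit(x[boot], y[boot])
            self.trees.append(tree)
            self.oob_indices.append(oob)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        pred = np.zeros(len(x))
        for tree in self.trees:
            pred += tree.predict(x)
        return pred / len(self.trees)

    def oob_predict(self, x: np.ndarray) -> np.ndarray:
        n = len(x)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if len(oob) == 0:
                continue
            total[oob] += tree.predict(x[oob])
            count[oob] += 1
        if (count == 0).any():
            # essentially impossible for any realistic tree count; fall back
            # to the in-forest prediction for never-OOB rows
            never = count == 0
            total[never] = self.predict(x[never]) * 1.0
            count[never] = 1
        return total / count

    def permutation_importance(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Mean per-tree increase in OOB MSE after permuting each feature."""
        n, p = x.shape
        increases = np.zeros(p)
        counts = np.zeros(p)
        for tree, oob in zip(self.trees, self.oob_indices):
            if len(oob) < 2:
                continue
            x_oob, y_oob = x[oob], y[oob]
            base = np.mean((tree.predict(x_oob) - y_oob) ** 2)
            for j in range(p):
                perm = x_oob.copy()
                perm[:, j] = self.rng.permutation(perm[:, j])
                err = np.mean((tree.predict(perm) - y_oob) ** 2)
                increases[j] += err - base
                counts[j] += 1
        counts[counts == 0] = 1
        return increases / counts

    def node_purity(self, p: int) -> np.ndarray:
        """Summed impurity (SSE) decrease per feature across trees."""
        purity = np.zeros(p)
        for tree in self.trees:
            purity += tree.tree_.compute_feature_importances(normalize=False)
        return purity


@dataclass
class DriverModelResult:
    """One forest fit: importances, explained variance, validation."""

    response: str
    var_explained_oob: float       # OOB pseudo-R^2, percent
    loo_r2: float                  # leave-one-out R^2, percent
    importance: pd.DataFrame       # covariates x (inc_mse_pct, node_purity)
    top4: list[str]
    loo_predictions: pd.Series
    residuals: pd.Series
    n_trees: int
    seed: int | None = None


def _top_four(importance: pd.DataFrame) -> list[str]:
    """Covariates in the top 4 on *both* importance measures.

    Conflicts (fewer than four in the intersection) are filled from the
    permutation-importance ranking.
    """
    by_perm = list(importance.sort_values("inc_mse_pct", ascending=False).index)
    by_purity = set(importance.sort_values("node_purity", ascending=False).index[:4])
    agreed = [c for c in by_perm[:4] if c in by_purity]
    for c in by_perm:
        if len(agreed) >= 4:
            break
        if c not in agreed:
            agreed.append(c)
    return agreed[:4]


def fit_driver_model(
    response: pd.Series,
    model_matrix: pd.DataFrame,
    seed: int | None = None,
    n_trees: int = 1000,
    max_features: float = 1 / 3,
    compute_loo: bool = True,
    name: str | None = None,
) -> DriverModelResult:
    """Fit a seeded regression forest of ``response`` on the covariates.

    Requires at least 8 sites and a non-constant response.  With a fixed
    seed all outputs are bit-reproducible.
    """
    y = response.to_numpy(dtype=float)
    x = model_matrix.loc[response.index].to_numpy(dtype=float)
    if len(y) < 8:
        raise ValidationError("need at least 8 sites to fit a driver model")
    if np.allclose(y, y[0]):
        raise ValidationError(
            f"response {name or response.name!r} is constant across sites"
        )

    forest = _BootstrapForest(n_trees=n_trees, max_features=max_features, seed=seed)
    forest.fit(x, y)

    var_y = y.var()  # population variance, matching the OOB pseudo-R^2 convention
    oob_pred = forest.oob_predict(x)
    mse_oob = float(np.mean((oob_pred - y) ** 2))
    var_explained = 100.0 * (1.0 - mse_oob / var_y)

    inc = forest.permutation_importance(x, y)
    importance = pd.DataFrame(
        {
            "inc_mse_pct": 100.0 * inc / mse_oob if mse_oob > 0 else inc,
            "node_purity": forest.node_purity(x.shape[1]),
        },
        index=model_matrix.columns,
    )

    if compute_loo:
        loo_pred = np.empty(len(y))
        for i in range(len(y)):
            mask = np.arange(len(y)) != i
            sub = _BootstrapForest(
                n_trees=n_trees, max_features=max_features,
                seed=None if seed is None else seed + 1000 + i,
            )
            sub.fit(x[mask], y[mask])
            loo_pred[i] = sub.predict(x[i : i + 1])[0]
        loo_r2 = 100.0 * (1.0 - np.mean((loo_pred - y) ** 2) / var_y)
    else:
        loo_pred = np.full(len(y), np.nan)
        loo_r2 = float("nan")

    loo_series = pd.Series(loo_pred, index=response.index, name="loo_prediction")
    return DriverModelResult(
        response=name or str(response.name),
        var_explained_oob=float(var_explained),
        loo_r2=float(loo_r2),
        importance=importance,
        top4=_top_four(importance),
        loo_predictions=loo_series,
        residuals=(response - loo_series).rename("loo_residual"),
        n_trees=n_trees,
        seed=seed,
    )


def fit_response_curves(
    response: pd.Series,
    covariates: pd.DataFrame,
    max_degree: int = 3,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Linear/polynomial least-squares response fits per covariate.

    Starting from a straight line, the polynomial degree is raised while
    the incremental term is significant at ``alpha`` (nested-model F
    test), capped at ``max_degree``.  Each entry reports the selected
    degree, coefficients (ascending powers), R^2, the incremental-term
    p-values, and whether the linear slope itself is significant.
    """
    y = response.to_numpy(dtype=float)
    results: dict[str, dict] = {}
    for col in covariates.columns:
        xv = covariates.loc[response.index, col].to_numpy(dtype=float)
        degree = 1
        models = {}
        for d in range(1, max_degree + 1):
            if len(y) <= d + 1:
                break
            design = sm.add_constant(np.vander(xv, d + 1, increasing=True)[:, 1:])
            models[d] = sm.OLS(y, design).fit()
        increment_p: dict[int, float] = {}
        for d in range(2, max_degree + 1):
            if d not in models:
                break
            f_p = float(models[d].compare_f_test(models[d - 1])[1])
            increment_p[d] = f_p
            if np.isnan(f_p) or f_p >= alpha:
                break
            degree = d
        chosen = models[degree]
        slope_p = float(chosen.pvalues[1]) if degree >= 1 else float("nan")
        results[col] = {
            "degree": degree,
            "coefficients": list(np.asarray(chosen.params, dtype=float)),
            "r2": float(chosen.rsquared),
            "increment_p": increment_p,
            "slope_significant": bool(slope_p < alpha),
            "slope_p": slope_p,
        }
    return results


def per_metric_models(
    scores: pd.DataFrame,
    model_matrix: pd.DataFrame,
    seed: int | None = None,
    n_trees: int = 1000,
    compute_loo: bool = True,
) -> tuple[dict[str, DriverModelResult], dict[str, str]]:
    """One driver model per sensitive-metric score column.

    A metric whose scores are constant across sites cannot be modelled;
    it is reported in the failures map without affecting the others.
    """
    results: dict[str, DriverModelResult] = {}
    failures: dict[str, str] = {}
    for i, metric in enumerate(scores.columns):
        try:
            results[metric] = fit_driver_model(
                scores[metric], model_matrix,
                seed=None if seed is None else seed + i,
                n_trees=n_trees, compute_loo=compute_loo, name=metric,
            )
        except ValidationError as exc:
            failures[metric] = str(exc)
    return results, failures
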