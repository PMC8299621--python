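"""L1/L2 penalized linear models of the site-level cleavage score.

Objective (paper-scale): sum of squared residuals plus ``lam * sum(|beta|)``
(L1) or ``lam * sum(beta**2)`` (L2), intercept unpenalized.

Penalty scaling against scikit-learn solvers
--------------------------------------------
* L1: sklearn's :class:`~sklearn.linear_model.Lasso` minimizes
  ``(1/(2n)) * RSS + alpha * ||w||_1``, so ``alpha = lam / (2n)``.
* L2: sklearn's :class:`~sklearn.linear_model.Ridge` minimizes
  ``RSS + alpha * ||w||_2^2``, so ``alpha = lam`` exactly.

Both conventions are covered by closed-form oracle tests.

The objective variable defaults to log10 of the cleavage score (a
heavy-tailed ratio of counts); ``y_transform="raw"`` fits the untransformed
score.  Features are z-scored on training statistics so coefficients are
comparable across categories.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from .transcript_io import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-10, -1, 10))
SEQUENCE_CATEGORIES = ("nucleotide", "codon", "amino_acid")


@dataclass
class ModelConfig:
    penalty: str = "l1"  # "l1" or "l2"
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 10
    seed: int = 0
    feature_mode: str = "all"  # or "sequence_only"
    y_transform: str = "log10"  # or "raw"
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.penalty not in ("l1", "l2"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if any(lam < 0 for lam in self.lambda_grid):
            raise ValueError("lambda must be non-negative")
        if self.y_transform not in ("log10", "raw"):
            raise ValueError(f"unknown y transform {self.y_transform!r}")


@dataclass
class FittedModel:
    penalty: str
    lam: float
    intercept: float
    coef: np.ndarray
    feature_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_transform: str = "log10"
    n_train: int = 0

    @property
    def nonzero(self) -> dict[str, float]:
        return {
            name: float(c)
            for name, c in zip(self.feature_names, self.coef)
            if c != 0.0
        }

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return self.intercept + Xs @ self.coef

    def to_json(self, path: str | Path) -> None:
        payload = {
            "penalty": self.penalty,
            "lambda": self.lam,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "feature_names": self.feature_names,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_transform": self.y_transform,
            "n_train": self.n_train,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            penalty=d["penalty"],
            lam=d["lambda"],
            intercept=d["intercept"],
            coef=np.asarray(d["coef"], dtype=float),
            feature_names=list(d["feature_names"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_transform=d["y_transform"],
            n_train=d["n_train"],
        )


@dataclass
class EvalReport:
    mse: float
    r: float
    n: int
    r_defined: bool = True

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise ValueError("MSE must be non-negative")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def transform_y(y: np.ndarray, mode: str) -> np.ndarray:
    if mode == "raw":
        return np.asarray(y, dtype=float)
    if mode == "log10":
        y = np.asarray(y, dtype=float)
        if (y <= 0).any():
            raise ValueError("log10 transform requires strictly positive scores")
        return np.log10(y)
    raise ValueError(f"unknown y transform {mode!r}")


def select_feature_mode(matrix: FeatureMatrix, mode: str) -> FeatureMatrix:
    """``all`` keeps everything; ``sequence_only`` drops structure and
    occupancy features."""
    if mode == "all":
        return matrix
    if mode == "sequence_only":
        keep = [
            j
            for j, s in enumerate(matrix.specs)
            if s.category in SEQUENCE_CATEGORIES
        ]
        return matrix.select_features(keep)
    raise ValueError(f"unknown feature mode {mode!r}")


def _standardize(
    X: np.ndarray, standardize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not standardize:
        return X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def fit_penalized(
    matrix: FeatureMatrix, config: ModelConfig, lam: float
) -> FittedModel:
    """Fit the penalized least-squares model on the rows of ``matrix``.

    The caller supplies training rows (see :meth:`FeatureMatrix.rows`).
    ``lam`` is on the paper objective scale; 0 reduces to ordinary least
    squares.  Non-convergence of the coordinate-descent solver raises with
    diagnostics rather than returning a bad fit.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = matrix.X
    y = transform_y(matrix.y, config.y_transform)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in design or objective")
    n = len(y)
    if n == 0:
        raise ValueError("no rows to fit")
    Xs, mean, scale = _standardize(X, config.standardize)

    if lam == 0:
        est = LinearRegression()
        est.fit(Xs, y)
    elif config.penalty == "l2":
        est = Ridge(alpha=lam, fit_intercept=True, solver="cholesky", tol=1e-10)
        est.fit(Xs, y)
    else:
        alpha = lam / (2 * n)
        est = Lasso(alpha=alpha, fit_intercept=True, tol=1e-6, max_iter=500_000)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                est.fit(Xs, y)
            except ConvergenceWarning as exc:  # pragma: no cover - diagnostics
                raise RuntimeError(
                    f"L1 solver failed to converge (lam={lam}, alpha={alpha}, "
                    f"n={n}, p={X.shape[1]}): {exc}"
                ) from exc
    return FittedModel(
        penalty=config.penalty,
        lam=float(lam),
        intercept=float(est.intercept_),
        coef=np.asarray(est.coef_, dtype=float),
        feature_names=matrix.feature_names,
        x_mean=mean,
        x_scale=scale,
        y_transform=config.y_transform,
        n_train=n,
    )


def _gene_folds(genes: np.ndarray, n_folds: int, seed: int) -> dict[str, int]:
    uniq = np.array(sorted(set(genes)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    return {uniq[g]: int(i % n_folds) for i, g in enumerate(order)}


def cv_lambda(matrix: FeatureMatrix, config: ModelConfig) -> pd.DataFrame:
    """Cross-validated MSE and nonzero-count per grid lambda.

    Folds are gene-grouped (all sites of a gene share a fold) and assigned
    by the config seed; the nonzero count comes from the fit on all supplied
    rows.  Returns a DataFrame with columns lam, mean_mse, n_nonzero.
    """
    if matrix.n_sites < 2 * config.cv_folds:
        raise ValueError("too few rows for the requested fold count")
    genes = matrix.site_info["gene_id"].to_numpy()
    fold_of = _gene_folds(genes, config.cv_folds, config.seed)
    fold_ids = np.array([fold_of[g] for g in genes])
    y_all = transform_y(matrix.y, config.y_transform)

    records = []
    for lam in config.lambda_grid:
        mses = []
        for f in range(config.cv_folds):
            test_mask = fold_ids == f
            train_mask = ~test_mask
            if not test_mask.any() or not train_mask.any():
                continue
            y_train = y_all[train_mask]
            if np.ptp(y_train) == 0:
                logger.warning("fold %d skipped: constant objective", f)
                continue
            sub_train = FeatureMatrix(
                matrix.site_info.loc[train_mask].reset_index(drop=True),
                matrix.X[train_mask],
                list(matrix.specs),
            )
            model = fit_penalized(sub_train, config, lam)
            pred = model.predict(matrix.X[test_mask])
            mses.append(float(np.mean((pred - y_all[test_mask]) ** 2)))
        full = fit_penalized(matrix, config, lam)
        records.append(
            {
                "lam": float(lam),
                "mean_mse": float(np.mean(mses)) if mses else np.nan,
                "n_nonzero": int(np.count_nonzero(full.coef)),
            }
        )
    return pd.DataFrame(records)


def select_lambda(
    cv_table: pd.DataFrame,
    tolerance: float = 0.05,
    override: float | None = None,
) -> float:
    """Largest lambda whose mean CV MSE is within ``(1 + tolerance)`` of the
    minimum; an explicit ``override`` bypasses selection entirely."""
    if override is not None:
        return float(override)
    if len(cv_table) == 0:
        raise ValueError("empty CV table")
    ok = cv_table.dropna(subset=["mean_mse"])
    best = ok["mean_mse"].min()
    eligible = ok.loc[ok["mean_mse"] <= (1 + tolerance) * best, "lam"]
    return float(eligible.max())


def predict_and_evaluate(model: FittedModel, matrix: FeatureMatrix) -> EvalReport:
    """MSE and Pearson r between predicted and measured objective on the
    supplied rows (typically the test split)."""
    if matrix.feature_names != model.feature_names:
        raise ValueError("feature columns do not match the trained model")
    y = transform_y(matrix.y, model.y_transform)
    pred = model.predict(matrix.X)
    mse = float(np.mean((pred - y) ** 2))
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        logger.warning("degenerate prediction or objective; correlation set to 0")
        return EvalReport(mse=mse, r=0.0, n=len(y), r_defined=False)
    r, _ = stats.pearsonr(pred, y)
    return EvalReport(mse=mse, r=float(r), n=len(y))


@dataclass
class CoefficientReport:
    """Nonzero coefficients grouped by sign, with scope/category breakdowns."""

    table: pd.DataFrame  # feature, category, scope, coefficient
    positive: dict = field(default_factory=dict)
    negative: dict = field(default_factory=dict)
    top_positive: pd.DataFrame | None = None
    top_negative: pd.DataFrame | None = None


def _group_summary(sub: pd.DataFrame) -> dict:
    total = float(sub["coefficient"].sum())
    out: dict = {"total": total, "by_scope": {}, "by_category": {}}
    for scope, grp in sub.groupby("scope"):
        s = float(grp["coefficient"].sum())
        out["by_scope"][scope] = {
            "sum": s,
            "proportion": s / total if total != 0 else 0.0,
        }
        by_cat = {}
        for cat, cgrp in grp.groupby("category"):
            cs = float(cgrp["coefficient"].sum())
            by_cat[cat] = {"sum": cs, "proportion": cs / s if s != 0 else 0.0}
        out["by_category"][scope] = by_cat
    return out


def coefficient_report(
    model: FittedModel, specs: list, top_k: int = 5
) -> CoefficientReport:
    """Signed coefficient groups with per-scope and per-category sums and
    proportions of the group total, plus top-k tables by magnitude."""
    if len(specs) != len(model.coef):
        raise ValueError("spec metadata does not match coefficient vector")
    rows = [
        {
            "feature": s.name,
            "category": s.category,
            "scope": s.scope,
            "coefficient": float(c),
        }
        for s, c in zip(specs, model.coef)
        if c != 0.0
    ]
    table = pd.DataFrame(rows, columns=["feature", "category", "scope", "coefficient"])
    report = CoefficientReport(table=table)
    if len(table) == 0:
        return report
    pos = table[table["coefficient"] > 0]
    neg = table[table["coefficient"] < 0]
    if len(pos):
        report.positive = _group_summary(pos)
        report.top_positive = (
            pos.sort_values("coefficient", ascending=False).head(top_k).reset_index(drop=True)
        )
    if len(neg):
        report.negative = _group_summary(neg)
        report.top_negative = (
            neg.sort_values("coefficient").head(top_k).reset_index(drop=True)
        )
    return report
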