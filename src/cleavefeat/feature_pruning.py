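"""Rank-correlation feature pruning.

Two rules, both on absolute Spearman correlations computed over training
rows: features with |r| to the objective below a threshold (default 0.1)
are removed; then features are visited in descending order of |r| to the
objective and kept only if their pairwise correlation with every feature
already kept stays below a second threshold (default 0.6), so that of any
collinear group the member most correlated with the objective survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transcript_io import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_TARGET_THRESHOLD = 0.1
DEFAULT_PAIR_THRESHOLD = 0.6


@dataclass
class PruneReport:
    n_input: int
    n_after_target_filter: int
    n_after_decorrelation: int
    table: pd.DataFrame  # feature, r_target, kept, reason

    def __post_init__(self) -> None:
        if not (
            self.n_after_decorrelation
            <= self.n_after_target_filter
            <= self.n_input
        ):
            raise ValueError("inconsistent pruning counts")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# n_input={self.n_input}\t"
                f"n_after_target_filter={self.n_after_target_filter}\t"
                f"n_after_decorrelation={self.n_after_decorrelation}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def _training_rows(matrix: FeatureMatrix, train_only: bool) -> np.ndarray:
    if train_only and (matrix.site_info["split"] == "train").any():
        return (matrix.site_info["split"] == "train").to_numpy()
    return np.ones(matrix.n_sites, dtype=bool)


def _rank_standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-tie ranks per column, centered and scaled to unit norm.

    Returns (Z, constant_mask); constant columns get all-zero Z columns so
    any correlation against them is 0.
    """
    ranks = stats.rankdata(M, axis=0)
    ranks = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=0))
    constant = norms == 0
    norms[constant] = 1.0
    return ranks / norms, constant


def target_correlations(
    matrix: FeatureMatrix, train_only: bool = True
) -> pd.DataFrame:
    """Spearman correlation of every feature column with the objective.

    Ties are handled by average ranks.  Constant columns are reported with
    r = 0 and ``constant = True``.  Returns a DataFrame with columns
    feature, r, constant.
    """
    rows = _training_rows(matrix, train_only)
    if rows.sum() < 3:
        raise ValueError("need at least 3 rows to compute correlations")
    Z, constant = _rank_standardize(matrix.X[rows])
    zy, y_const = _rank_standardize(matrix.y[rows][:, None])
    if y_const[0]:
        logger.warning("objective is constant on the correlation rows")
    r = Z.T @ zy[:, 0]
    r[constant] = 0.0
    return pd.DataFrame(
        {"feature": matrix.feature_names, "r": r, "constant": constant}
    )


def drop_uncorrelated(
    matrix: FeatureMatrix,
    correlations: pd.DataFrame,
    threshold: float = DEFAULT_TARGET_THRESHOLD,
) -> FeatureMatrix:
    """Keep features whose |r| with the objective is >= ``threshold``."""
    r = correlations["r"].to_numpy()
    keep = np.flatnonzero(np.abs(r) >= threshold)
    return matrix.select_features(keep)


def decorrelate(
    matrix: FeatureMatrix,
    correlations: pd.DataFrame,
    pair_threshold: float = DEFAULT_PAIR_THRESHOLD,
    train_only: bool = True,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Greedy collapse of collinear feature groups.

    Features are visited by descending |r| to the objective (ties broken by
    column order); a feature is accepted iff its absolute pairwise Spearman
    correlation with every already-accepted feature is < ``pair_threshold``.
    Returns (pruned matrix, per-feature table with kept flags and reasons).
    """
    name_to_r = dict(zip(correlations["feature"], correlations["r"]))
    r = np.array([name_to_r[n] for n in matrix.feature_names])
    rows = _training_rows(matrix, train_only)
    Z, _ = _rank_standardize(matrix.X[rows])

    order = sorted(range(matrix.p), key=lambda j: (-abs(r[j]), j))
    accepted: list[int] = []
    kept = np.zeros(matrix.p, dtype=bool)
    reason = np.array(["" for _ in range(matrix.p)], dtype=object)
    for j in order:
        if accepted:
            corr = np.abs(Z[:, accepted].T @ Z[:, j])
            if (corr >= pair_threshold).any():
                worst = accepted[int(np.argmax(corr))]
                reason[j] = f"collinear_with:{matrix.feature_names[worst]}"
                continue
        accepted.append(j)
        kept[j] = True
        reason[j] = "kept"
    accepted_sorted = sorted(accepted)
    table = pd.DataFrame(
        {
            "feature": matrix.feature_names,
            "r_target": r,
            "kept": kept,
            "reason": reason,
        }
    )
    return matrix.select_features(accepted_sorted), table


def prune(
    matrix: FeatureMatrix,
    target_threshold: float = DEFAULT_TARGET_THRESHOLD,
    pair_threshold: float = DEFAULT_PAIR_THRESHOLD,
    train_only: bool = True,
) -> tuple[FeatureMatrix, PruneReport]:
    """Target-correlation filter followed by greedy decorrelation."""
    corrs = target_correlations(matrix, train_only=train_only)
    filtered = drop_uncorrelated(matrix, corrs, target_threshold)
    sub_corrs = corrs[corrs["feature"].isin(set(filtered.feature_names))]
    pruned, table = decorrelate(filtered, sub_corrs, pair_threshold, train_only)

    dropped_early = corrs.loc[
        ~corrs["feature"].isin(set(filtered.feature_names)),
        ["feature", "r"],
    ].rename(columns={"r": "r_target"})
    dropped_early["kept"] = False
    dropped_early["reason"] = "target_correlation_below_threshold"
    full = pd.concat([table, dropped_early], ignore_index=True)
    full = full.set_index("feature").loc[matrix.feature_names].reset_index()
    report = PruneReport(
        n_input=matrix.p,
        n_after_target_filter=filtered.p,
        n_after_decorrelation=pruned.p,
        table=full,
    )
    logger.info(
        "prune: %d -> %d -> %d features",
        report.n_input,
        report.n_after_target_filter,
        report.n_after_decorrelation,
    )
    return pruned, report
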