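"""Clustered resampling statistics for eye-level cohort tables.

Eyes from the same patient are correlated, so ordinary bootstrap or
analytic AUROC variances are anticonservative.  The cluster bootstrap
resamples whole patients with replacement (2000 replicates by default),
recomputes the statistic of interest on the concatenated eyes of the
drawn patients, and reports percentile 95% confidence intervals.

AUROC is computed in the Mann–Whitney pair-counting form — the
probability that a random positive outscores a random negative, ties
counted one half — which equals trapezoidal ROC integration with proper
tie handling and is invariant under strictly increasing score transforms.

Statistics passed to the bootstrap are callables that receive a dict of
column-name → numpy array for the resampled rows (a plain-array view of
the table, kept cheap because the bootstrap calls it thousands of times);
:func:`auroc_stat` and :func:`mean_stat` build the common ones.
Randomness comes from one explicit seed: replicate ``r`` draws from the
``r``-th spawned child stream, so results do not depend on evaluation
order, and redraws triggered by an undefined statistic stay local to the
replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AnalysisError, FormatError, UndefinedStatisticError
from .phantom import COHORT_COLUMNS

__all__ = [
    "BootstrapResult",
    "auroc",
    "auroc_stat",
    "mean_stat",
    "cluster_bootstrap",
    "compare_predictors",
    "group_difference",
    "pearson_correlation",
    "one_eye_per_patient",
    "validate_cohort",
]

TableStat = Callable[[dict], float]


@dataclass
class BootstrapResult:
    """Point estimate with a percentile bootstrap confidence interval."""

    point_estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int
    n_clusters: int
    n_redraws: int = 0
    ci_contains_estimate: bool = True

    def to_dict(self) -> dict:
        return {
            "estimate": self.point_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_reps": self.n_replicates,
            "seed": self.seed,
            "n_clusters": self.n_clusters,
            "n_redraws": self.n_redraws,
        }


# ---------------------------------------------------------------------------
# estimators


def auroc(scores, labels) -> float:
    """Area under the ROC curve by pair counting (ties count one half).

    ``(concordant + 0.5 * tied) / (n_pos * n_neg)`` via midranks.  Raises
    :class:`UndefinedStatisticError` if only one outcome class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUROC undefined: only one outcome class present")
    ranks = rankdata(scores)  # midranks handle ties as half-concordant
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auroc_stat(predictor: str, outcome: str) -> TableStat:
    """Named estimator: AUROC of ``predictor`` for binary ``outcome``."""

    def stat(cols: dict) -> float:
        return auroc(cols[predictor], cols[outcome])

    stat.__name__ = f"auroc[{predictor}->{outcome}]"
    return stat


def mean_stat(column: str) -> TableStat:
    """Named estimator: mean of one column."""

    def stat(cols: dict) -> float:
        return float(np.mean(cols[column]))

    stat.__name__ = f"mean[{column}]"
    return stat


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; errors on <2 pairs or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise AnalysisError("Pearson correlation needs >= 2 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("Pearson correlation undefined for zero variance")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# cluster bootstrap core


def _columns_of(table: pd.DataFrame) -> dict:
    return {c: table[c].to_numpy() for c in table.columns}


def _cluster_indices(table: pd.DataFrame, cluster_col: str):
    codes, _ = pd.factorize(table[cluster_col])
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes)
    bounds = np.concatenate([[0], np.cumsum(counts)])
    return [order[bounds[i]:bounds[i + 1]] for i in range(len(counts))]


def _take(cols: dict, idx: np.ndarray) -> dict:
    return {c: v[idx] for c, v in cols.items()}


def _replicate_stats(
    stats: list[TableStat],
    cols: dict,
    clusters: list[np.ndarray],
    n_reps: int,
    seed: int,
    max_redraw_frac: float = 0.5,
):
    """Evaluate estimators on ``n_reps`` cluster-resampled replicates.

    Returns ``(values (n_reps, n_stats), n_redraws)``.  Replicates on
    which any estimator is undefined are redrawn from the same replicate's
    stream; if more than ``max_redraw_frac * n_reps`` redraws accumulate
    the analysis is abandoned as ill-posed.
    """
    n_clusters = len(clusters)
    if n_clusters < 2:
        raise AnalysisError("cluster bootstrap needs >= 2 clusters")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    values = np.empty((n_reps, len(stats)))
    n_redraws = 0
    max_redraws = int(max_redraw_frac * n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(streams[r])
        while True:
            draw = rng.integers(0, n_clusters, size=n_clusters)
            idx = np.concatenate([clusters[c] for c in draw])
            sub = _take(cols, idx)
            try:
                values[r] = [s(sub) for s in stats]
                break
            except UndefinedStatisticError:
                n_redraws += 1
                if n_redraws > max_redraws:
                    raise AnalysisError(
                        "statistic undefined in more than half of the "
                        "bootstrap replicates"
                    ) from None
    return values, n_redraws


def _percentile_result(
    point: float, reps: np.ndarray, n_reps: int, seed: int, n_clusters: int, n_redraws: int
) -> BootstrapResult:
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        point_estimate=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        n_replicates=n_reps,
        seed=seed,
        n_clusters=n_clusters,
        n_redraws=n_redraws,
        ci_contains_estimate=bool(lo <= point <= hi),
    )


def cluster_bootstrap(
    table: pd.DataFrame,
    statistic: TableStat,
    n_reps: int = 2000,
    seed: int = 0,
    cluster_col: str = "patient_id",
) -> BootstrapResult:
    """Patient-cluster bootstrap percentile CI for one statistic.

    Each replicate draws ``n_clusters`` patient ids with replacement and
    concatenates all their eyes before recomputing the statistic.  The
    point estimate is the statistic on the original table.
    """
    cols = _columns_of(table)
    clusters = _cluster_indices(table, cluster_col)
    point = statistic(cols)
    reps, n_redraws = _replicate_stats([statistic], cols, clusters, n_reps, seed)
    return _percentile_result(point, reps[:, 0], n_reps, seed, len(clusters), n_redraws)


def compare_predictors(
    table: pd.DataFrame,
    predictor_a: str,
    predictor_b: str,
    outcome: str,
    n_reps: int = 2000,
    seed: int = 0,
    cluster_col: str = "patient_id",
):
    """Paired AUROC difference (a - b) under the cluster bootstrap.

    Both AUROCs are computed on the *same* resampled eyes in each
    replicate, so the difference is properly paired.  Returns a
    :class:`BootstrapResult` for the difference plus a significance flag
    (the 95% CI excludes zero).
    """
    cols = _columns_of(table)
    clusters = _cluster_indices(table, cluster_col)
    sa, sb = auroc_stat(predictor_a, outcome), auroc_stat(predictor_b, outcome)
    point = sa(cols) - sb(cols)
    reps, n_redraws = _replicate_stats([sa, sb], cols, clusters, n_reps, seed)
    diffs = reps[:, 0] - reps[:, 1]
    res = _percentile_result(point, diffs, n_reps, seed, len(clusters), n_redraws)
    significant = bool(res.ci_low > 0 or res.ci_high < 0)
    return res, significant


def group_difference(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    group_col: str = "zone",
    n_reps: int = 0,
    seed: int = 0,
    cluster_col: str = "patient_id",
):
    """Mean difference ``mean(metric | group_b) - mean(metric | group_a)``.

    With ``n_reps > 0`` a cluster-bootstrap CI is attached (replicates
    missing either group are redrawn); otherwise the plain difference is
    returned as a float.
    """
    in_a = table[group_col] == group_a
    in_b = table[group_col] == group_b
    if not in_a.any() or not in_b.any():
        raise AnalysisError(f"empty group among ({group_a!r}, {group_b!r})")
    vals = table[metric].to_numpy(dtype=float)
    point = float(vals[in_b.to_numpy()].mean() - vals[in_a.to_numpy()].mean())
    if n_reps <= 0:
        return point

    def stat(cols: dict) -> float:
        g = cols[group_col]
        ma, mb = g == group_a, g == group_b
        if not ma.any() or not mb.any():
            raise UndefinedStatisticError("a group vanished in this replicate")
        v = cols[metric]
        return float(v[mb].mean() - v[ma].mean())

    cols = _columns_of(table)
    clusters = _cluster_indices(table, cluster_col)
    reps, n_redraws = _replicate_stats([stat], cols, clusters, n_reps, seed)
    return _percentile_result(point, reps[:, 0], n_reps, seed, len(clusters), n_redraws)


def one_eye_per_patient(table: pd.DataFrame, seed: int = 0,
                        cluster_col: str = "patient_id") -> pd.DataFrame:
    """Randomly keep one eye per patient (for patient-level analyses)."""
    rng = np.random.default_rng(seed)
    keep = []
    for idx in _cluster_indices(table, cluster_col):
        keep.append(idx[rng.integers(0, len(idx))])
    return table.iloc[np.sort(np.asarray(keep))].reset_index(drop=True)


def validate_cohort(table: pd.DataFrame, required=COHORT_COLUMNS) -> None:
    """Schema check: required columns present, <= 2 eyes per patient."""
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    sizes = table.groupby("patient_id").size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index[0]
        raise FormatError(f"patient {bad!r} has more than 2 eyes")
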