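"""Group comparison and diagnostic-accuracy statistics.

Implements the classical two-group workflow for the sensor features and
clinical covariates: Mann-Whitney U tests for location differences and
ROC/AUC analysis of each candidate predictor of the infectious class, with
the Hanley-McNeil standard error and a Wald 95% confidence interval.

Score orientation is fixed: the infectious class is positive and larger
values count as more positive.  The orientation is never flipped, so a
predictor that runs the "wrong" way yields an AUC below 0.5 and is reported
as such (the viscosity feature is the canonical example).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "GroupComparison",
    "RocResult",
    "mann_whitney_u",
    "roc_auc",
    "hanley_mcneil_se",
    "binormal_auc",
    "simulate_binormal_auc",
    "summary_table",
]


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of one feature between two groups."""

    feature: str
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    u_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n_1 * self.n_2):
            raise ValueError("U statistic outside [0, n1*n2]")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value outside (0, 1]")


@dataclass(frozen=True)
class RocResult:
    """AUC with Hanley-McNeil SE, Wald 95% CI and the ROC curve itself."""

    auc: float
    se: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("CI does not bracket the AUC")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs with x > y (ties at half weight).
    Uses exact enumeration for small samples (n1 + n2 <= 12, no ties) and the
    tie-corrected normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a nonparametric AUC estimate."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(scores, labels, positive) -> RocResult:
    """ROC curve and AUC of ``scores`` as a predictor of the ``positive`` class.

    Higher score means more positive; ties contribute half a concordant pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an ROC curve")
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    ci_low = max(0.0, auc - 1.96 * se)
    ci_high = min(1.0, auc + 1.96 * se)
    return RocResult(
        auc=auc, se=se, ci_low=ci_low, ci_high=ci_high,
        fpr=fpr, tpr=tpr, n_pos=n_pos, n_neg=n_neg,
    )


def binormal_auc(mean_neg: float, sd_neg: float, mean_pos: float, sd_pos: float) -> float:
    """Closed-form AUC of two Gaussian classes: Phi(dmu / sqrt(s1^2 + s2^2))."""
    return float(
        scipy.stats.norm.cdf((mean_pos - mean_neg) / np.hypot(sd_neg, sd_pos))
    )


def simulate_binormal_auc(
    mean_neg: float,
    sd_neg: float,
    mean_pos: float,
    sd_pos: float,
    n_per_class: int = 100_000,
    seed: int = 0,
) -> RocResult:
    """Monte-Carlo AUC of two Gaussian classes by explicit pairwise concordance."""
    rng = np.random.default_rng(seed)
    neg = rng.normal(mean_neg, sd_neg, n_per_class)
    pos = rng.normal(mean_pos, sd_pos, n_per_class)
    scores = np.concatenate([neg, pos])
    labels = np.array(["neg"] * n_per_class + ["pos"] * n_per_class)
    return roc_auc(scores, labels, positive="pos")


def summary_table(
    rows: pd.DataFrame,
    features: list[str] | None = None,
    *,
    group_col: str = "label",
    classes: tuple[str, str] = ("inflammatory", "infectious"),
    positive: str = "infectious",
    mode: str = "per_sample",
) -> pd.DataFrame:
    """Group-comparison summary: one row per feature.

    Means and SDs are computed from the measurement rows directly.  The
    Mann-Whitney U test and the ROC/AUC operate on per-sample means by default
    (``mode='per_sample'``): repeated points from one patient sample are not
    independent observations, and the published p-values and AUC standard
    errors are only consistent with sample-level group sizes.  Set
    ``mode='per_point'`` to treat every row as an observation.
    """
    if features is None:
        features = ["delta_f_hz", "delta_gamma_hz", "eta_mpas"]
    if mode not in ("per_sample", "per_point"):
        raise ValueError(f"mode must be 'per_sample' or 'per_point', got {mode!r}")
    missing = [c for c in features if c not in rows.columns]
    if missing:
        raise KeyError(f"feature column(s) not in table: {', '.join(missing)}")
    g1 = rows[rows[group_col] == classes[0]]
    g2 = rows[rows[group_col] == classes[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"both classes {classes} must be present in {group_col!r}")

    if mode == "per_sample":
        test_data = rows.groupby(["sample_id", group_col], sort=False, as_index=False)[
            features
        ].mean()
    else:
        test_data = rows

    records = []
    for feat in features:
        x = test_data.loc[test_data[group_col] == classes[0], feat].to_numpy()
        y = test_data.loc[test_data[group_col] == classes[1], feat].to_numpy()
        u, p = mann_whitney_u(x, y)
        roc = roc_auc(
            test_data[feat].to_numpy(), test_data[group_col].to_numpy(), positive
        )
        records.append(
            {
                "feature": feat,
                f"mean_{classes[0]}": g1[feat].mean(),
                f"sd_{classes[0]}": g1[feat].std(ddof=1),
                f"mean_{classes[1]}": g2[feat].mean(),
                f"sd_{classes[1]}": g2[feat].std(ddof=1),
                "u_statistic": u,
                "p_value": p,
                "auc": roc.auc,
                "auc_se": roc.se,
                "auc_ci_low": roc.ci_low,
                "auc_ci_high": roc.ci_high,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "mode": mode,
            }
        )
    return pd.DataFrame.from_records(records)
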