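"""Emotion-condition grouping and nonparametric group comparisons.

Trials carry either explicit emotion labels (e.g. positive / negative /
neutral) or continuous 1–9 valence and arousal self-assessment ratings.
Rated trials are split into high/low per dimension against a per-subject
threshold (subject mean by default, since rating ranges differ markedly
between people), giving the four quadrant classes HAHV, HALV, LAHV, LALV.
Group differences in microstate parameters are tested feature-wise with the
two-sided Wilcoxon rank-sum (Mann-Whitney) test at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["GroupingConfig", "assign_groups", "ranksum_compare"]

_EXACT_N_MAX = 12


@dataclass
class GroupingConfig:
    """How trials are split into emotion groups.

    ``mode``: ``explicit_labels`` passes labels through; ``rating_threshold``
    dichotomises arousal/valence ratings.  ``threshold_rule`` is ``fixed``
    (use ``fixed_value``), ``per_subject_mean`` or ``per_subject_median``.
    The per-subject rules stand in for adaptive-threshold schemes used with
    self-assessment data; a subject with constant ratings falls back to the
    fixed threshold.  A rating exactly at threshold counts as low.
    """

    mode: str = "rating_threshold"
    threshold_rule: str = "per_subject_mean"
    fixed_value: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("explicit_labels", "rating_threshold"):
            raise ValidationError(f"unknown grouping mode {self.mode!r}")
        if self.threshold_rule not in ("fixed", "per_subject_mean", "per_subject_median"):
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")


def _thresholds(values: np.ndarray, cfg: GroupingConfig, subject: object) -> float:
    if cfg.threshold_rule == "fixed":
        return cfg.fixed_value
    if np.ptp(values) == 0:
        logger.warning(
            "subject %r has constant ratings; falling back to fixed threshold %g",
            subject, cfg.fixed_value,
        )
        return cfg.fixed_value
    if cfg.threshold_rule == "per_subject_mean":
        return float(np.mean(values))
    return float(np.median(values))


def assign_groups(ratings: pd.DataFrame, cfg: GroupingConfig | None = None) -> pd.Series:
    """Quadrant labels {HAHV, HALV, LAHV, LALV} per trial.

    ``ratings`` needs columns ``subject``, ``arousal``, ``valence`` with
    ratings on the 1–9 scale.  High means strictly above the subject's
    threshold on that dimension.
    """
    cfg = cfg or GroupingConfig()
    required = {"subject", "arousal", "valence"}
    if not required.issubset(ratings.columns):
        raise ValidationError(f"ratings table needs columns {sorted(required)}")
    for dim in ("arousal", "valence"):
        vals = ratings[dim].to_numpy(dtype=float)
        if np.any((vals < 1) | (vals > 9)):
            raise ValidationError(f"{dim} ratings must lie in [1, 9]")
    labels = pd.Series(index=ratings.index, dtype=object)
    for subject, grp in ratings.groupby("subject"):
        thr_a = _thresholds(grp["arousal"].to_numpy(float), cfg, subject)
        thr_v = _thresholds(grp["valence"].to_numpy(float), cfg, subject)
        high_a = grp["arousal"].to_numpy(float) > thr_a
        high_v = grp["valence"].to_numpy(float) > thr_v
        lab = np.where(
            high_a,
            np.where(high_v, "HAHV", "HALV"),
            np.where(high_v, "LAHV", "LALV"),
        )
        labels.loc[grp.index] = lab
    return labels


def ranksum_compare(
    features: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Two-sided rank-sum test per feature column between two groups.

    ``groups`` is a per-row label sequence with exactly two distinct values
    (compared in sorted order: first vs second).  For small untied samples
    (both n <= 12) the exact null distribution is used; otherwise the
    normal approximation with tie correction.  Returns one row per feature
    with group medians, the rank-sum statistic W of the first group, the
    p-value and the significance flag; ``fdr=True`` adds
    Benjamini-Hochberg-adjusted p-values (flagging then uses those).
    """
    groups = np.asarray(groups)
    if groups.shape[0] != len(features):
        raise ValidationError("groups must align with feature rows")
    uniq = sorted(pd.unique(groups[pd.notna(groups)]))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    a_mask, b_mask = groups == uniq[0], groups == uniq[1]
    rows = []
    for col in features.columns:
        x = features.loc[a_mask, col].to_numpy(dtype=float)
        y = features.loc[b_mask, col].to_numpy(dtype=float)
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size == 0 or y.size == 0:
            logger.info("feature %s skipped: empty group", col)
            continue
        pooled = np.concatenate([x, y])
        ties = pooled.size != np.unique(pooled).size
        method = (
            "exact"
            if (x.size <= _EXACT_N_MAX and y.size <= _EXACT_N_MAX and not ties)
            else "asymptotic"
        )
        res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        w = res.statistic + x.size * (x.size + 1) / 2  # U -> Wilcoxon rank sum
        rows.append(
            {
                "feature": col,
                f"median_{uniq[0]}": float(np.median(x)),
                f"median_{uniq[1]}": float(np.median(y)),
                "statistic": float(w),
                "p": float(res.pvalue),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["p_adj"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
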