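"""Signature performance evaluation: one-vs-rest ROC/AUC and rank tests.

AUC is the Mann-Whitney U statistic normalized by n1*n0 (midranks for ties);
its p-value comes from the two-sided normal-approximated U test with tie
correction.  By default the per-group scores fed in should be
cross-validated, held-out scores rather than resubstitution scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class RocResult:
    group: object
    auc: float
    p_value: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_pos: int
    n_neg: int


def one_vs_rest_roc(scores: pd.DataFrame, labels: pd.Series) -> list[RocResult]:
    """One-vs-rest ROC per group from continuous per-group scores.

    ``scores`` has one column per group (higher = more group-like); positives
    for group g are the samples labelled g.  AUC below 0.5 is reported as-is.
    """
    labels = labels.loc[scores.index]
    results = []
    for g in scores.columns:
        pos = (labels == g).to_numpy()
        n1, n0 = int(pos.sum()), int((~pos).sum())
        if n1 == 0 or n0 == 0:
            raise ValueError(f"group {g!r} is degenerate: {n1} positives / {n0} negatives")
        s = scores[g].to_numpy(float)
        u = stats.mannwhitneyu(s[pos], s[~pos], alternative="two-sided",
                               method="asymptotic")
        auc = float(u.statistic) / (n1 * n0)
        fpr, tpr, thr = roc_curve(pos.astype(int), s)
        results.append(RocResult(group=g, auc=auc, p_value=float(u.pvalue),
                                 fpr=fpr, tpr=tpr, thresholds=thr,
                                 n_pos=n1, n_neg=n0))
    return results


def roc_table(results: list[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": r.group, "auc": r.auc, "p_value": r.p_value,
          "n_pos": r.n_pos, "n_neg": r.n_neg} for r in results]
    )


def kruskal_wallis(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Missing values are dropped pairwise.  All-tied data returns H=0, p=1.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = sorted(set(groups))
    if len(levels) < 2 or any((groups == g).sum() < 2 for g in levels):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if np.all(values == values[0]):
        return 0.0, 1.0
    samples = [values[groups == g] for g in levels]
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
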