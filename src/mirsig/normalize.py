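"""Adaptive delta-Ct normalization.

Instead of a fixed housekeeping gene, the normalizer set is learned from the
data: assays are clustered on their raw per-sample Ct profiles (Euclidean
distance, Ward's variance-minimizing linkage) and the most stable small
cluster — the one whose k tightest members minimize the summed distance to
their centroid — provides the k normalizing miRNAs.  Expression is then
reported as (−)ΔCt = −(Ct − mean normalizer Ct), a log2-scale proxy that
increases with abundance and is invariant to per-sample extraction-efficiency
offsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .datatypes import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizerAudit:
    """Ordered record of candidate clusters examined during selection."""

    candidates: list[dict] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    dispersion: float = float("nan")
    n_complete_assays: int = 0

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates,
            "selected": self.selected,
            "dispersion": self.dispersion,
            "n_complete_assays": self.n_complete_assays,
        }


@dataclass
class NormalizedExpression:
    values: pd.DataFrame            # samples x assays, (−)ΔCt
    normalizer_set: list[str]
    dispersion: float
    audit: NormalizerAudit
    dose_groups: pd.Series = None   # aligned with values.index when available


def _best_subset(profiles: np.ndarray, members: list[int], k: int) -> tuple[tuple[int, ...], float]:
    """Exhaustively pick the size-k subset of ``members`` minimizing the sum of
    Euclidean distances from the subset's own centroid.

    Candidates form the moment their size first reaches k, so they have at
    most 2(k-1) members and the enumeration is tiny.
    """
    best, best_disp = None, np.inf
    for subset in combinations(sorted(members), k):
        pts = profiles[list(subset)]
        centroid = pts.mean(axis=0)
        disp = float(np.linalg.norm(pts - centroid, axis=1).sum())
        if disp < best_disp - 1e-12:
            best, best_disp = subset, disp
    return best, best_disp


def candidate_clusters(link: np.ndarray, n_leaves: int, k: int) -> list[list[int]]:
    """Walk Ward merges bottom-up; report each cluster the first time its size
    reaches >= k (i.e. both children were still smaller than k)."""
    members: dict[int, list[int]] = {i: [i] for i in range(n_leaves)}
    out: list[list[int]] = []
    for step, (a, b, _dist, _size) in enumerate(link):
        a, b = int(a), int(b)
        merged = members[a] + members[b]
        members[n_leaves + step] = merged
        if len(merged) >= k and len(members[a]) < k and len(members[b]) < k:
            out.append(sorted(merged))
    return out


def find_normalizer_set(
    ct: CtMatrix, k: int = 3, assays: list[str] | None = None
) -> tuple[list[str], NormalizerAudit]:
    """Select the k normalizing assays via Ward clustering of Ct profiles.

    Only assays with a complete Ct profile across retained samples are
    candidates (a normalizer must be measurable in every sample for ΔCt to
    exist); control assays are never candidates.  Ties in dispersion break by
    lexicographic assay-name order for determinism.
    """
    retained = ct.retained()
    pool = assays if assays is not None else retained.feature_assays
    complete = [a for a in pool if retained.values[a].notna().all()]
    audit = NormalizerAudit(n_complete_assays=len(complete))
    if len(complete) < k:
        raise ValueError(
            f"only {len(complete)} assays have complete Ct across retained samples; "
            f"need >= {k}. Relax the completeness rule (impute or drop samples) "
            "or lower k."
        )
    profiles = retained.values[complete].to_numpy().T   # assays x samples
    if len(complete) == k:
        centroid = profiles.mean(axis=0)
        disp = float(np.linalg.norm(profiles - centroid, axis=1).sum())
        audit.candidates.append({"members": sorted(complete), "subset": sorted(complete),
                                 "dispersion": disp})
        audit.selected, audit.dispersion = sorted(complete), disp
        return sorted(complete), audit

    link = linkage(profiles, method="ward", metric="euclidean")
    best_names, best_disp = None, np.inf
    for cluster in candidate_clusters(link, len(complete), k):
        subset, disp = _best_subset(profiles, cluster, k)
        names = sorted(complete[i] for i in subset)
        audit.candidates.append({
            "members": sorted(complete[i] for i in cluster),
            "subset": names,
            "dispersion": disp,
        })
        if disp < best_disp - 1e-12 or (
            abs(disp - best_disp) <= 1e-12 and best_names is not None and names < best_names
        ):
            best_names, best_disp = names, disp
    audit.selected, audit.dispersion = best_names, float(best_disp)
    logger.info("normalizer set: %s (dispersion %.4g, %d candidates)",
                best_names, best_disp, len(audit.candidates))
    return best_names, audit


def to_neg_delta_ct(
    ct: CtMatrix, normalizer_set: list[str], audit: NormalizerAudit | None = None
) -> NormalizedExpression:
    """Convert Ct to (−)ΔCt against the mean of the normalizer set.

    value(s, i) = −(Ct(s, i) − mean_j Ct(s, j)) over normalizers j.  Missing
    Ct stays missing.  Samples missing any normalizer Ct are dropped with a
    log entry (ΔCt is undefined for them).
    """
    if not normalizer_set:
        raise ValueError("normalizer_set is empty")
    missing_cols = [a for a in normalizer_set if a not in ct.values.columns]
    if missing_cols:
        raise KeyError(f"normalizer assays absent from matrix: {missing_cols}")
    retained = ct.retained()
    norm_ct = retained.values[list(normalizer_set)]
    ok = norm_ct.notna().all(axis=1)
    if (~ok).any():
        logger.warning("dropping %d samples with missing normalizer Ct: %s",
                       int((~ok).sum()), list(norm_ct.index[~ok]))
    vals = retained.values.loc[ok.values]
    neg_dct = -(vals.sub(vals[list(normalizer_set)].mean(axis=1), axis=0))
    return NormalizedExpression(
        values=neg_dct,
        normalizer_set=list(normalizer_set),
        dispersion=audit.dispersion if audit else float("nan"),
        audit=audit or NormalizerAudit(selected=list(normalizer_set)),
        dose_groups=retained.meta.loc[neg_dct.index, "dose_gy"],
    )


def normalize(ct: CtMatrix, k: int = 3) -> NormalizedExpression:
    """Convenience: select normalizers, then compute (−)ΔCt."""
    normalizers, audit = find_normalizer_set(ct, k)
    return to_neg_delta_ct(ct, normalizers, audit)
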