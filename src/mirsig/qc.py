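"""Sample- and assay-level quality control for plasma miRNA Ct panels.

Three controls drive sample QC: a universally expressed endogenous reference
(miR-23a-3p), a hemolysis indicator enriched in red blood cells (miR-451a),
and an exogenous spike-in (cel-miR-39) added before extraction.  Hemolysis is
scored as Ct(reference) - Ct(hemolysis indicator): red-cell contamination
inflates miR-451a abundance, lowering its Ct and raising the delta.  Flags
never auto-exclude; exclusion is an explicit, logged decision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CtMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    samples: pd.DataFrame = None   # hemolysis_delta, hemolysis_flag, spikein_deviation, spikein_flag, excluded
    assays: pd.DataFrame = None    # detection_rate, retained
    n_discarded_high_ct: int = 0

    def summary(self) -> dict:
        out = {"n_discarded_high_ct": int(self.n_discarded_high_ct)}
        if self.samples is not None:
            out["n_hemolysis_flagged"] = int((self.samples["hemolysis_flag"] == True).sum())  # noqa: E712
            out["n_spikein_flagged"] = int((self.samples["spikein_flag"] == True).sum())  # noqa: E712
            out["n_excluded"] = int(self.samples["excluded"].sum())
        if self.assays is not None:
            out["n_assays_retained"] = int(self.assays["retained"].sum())
            out["n_assays_removed"] = int((~self.assays["retained"]).sum())
        return out


def discard_high_ct(ct: CtMatrix, limit: float = 37.0, report: QCReport | None = None) -> CtMatrix:
    """Set Ct values strictly above ``limit`` to missing (late amplification is noise)."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    out = ct.copy()
    mask = out.values > limit
    n = int(mask.sum().sum())
    out.values = out.values.mask(mask)
    if report is not None:
        report.n_discarded_high_ct += n
    logger.info("discarded %d Ct values above %.4g", n, limit)
    return out


def hemolysis_score(ct: CtMatrix, threshold: float = 7.0) -> pd.DataFrame:
    """Per-sample hemolysis delta and flag.

    delta = Ct(reference) - Ct(hemolysis indicator); flagged when delta >
    ``threshold`` cycles.  Samples missing either control Ct get a missing
    delta and an ``"indeterminate"`` flag.
    """
    ref, hem = ct.control("reference"), ct.control("hemolysis")
    if ref is None or hem is None:
        raise ValueError("hemolysis scoring needs both the reference and hemolysis control assays")
    delta = ct.values[ref] - ct.values[hem]
    flag = pd.Series(
        ["indeterminate" if np.isnan(d) else bool(d > threshold) for d in delta],
        index=delta.index,
        dtype=object,
    )
    return pd.DataFrame({"hemolysis_delta": delta, "hemolysis_flag": flag})


def spikein_check(ct: CtMatrix, max_dev: float = 2.0) -> pd.DataFrame:
    """Flag samples whose spike-in Ct deviates from the cohort median by > max_dev cycles.

    Median-relative, so a uniform extraction-efficiency shift never flags.
    If the spike-in assay is absent every flag is ``"indeterminate"``.
    """
    spike = ct.control("spikein")
    if spike is None:
        flags = pd.Series("indeterminate", index=ct.values.index, dtype=object)
        dev = pd.Series(np.nan, index=ct.values.index)
        return pd.DataFrame({"spikein_deviation": dev, "spikein_flag": flags})
    values = ct.values[spike]
    dev = values - values.median()
    flag = pd.Series(
        ["indeterminate" if np.isnan(d) else bool(abs(d) > max_dev) for d in dev],
        index=dev.index,
        dtype=object,
    )
    return pd.DataFrame({"spikein_deviation": dev, "spikein_flag": flag})


def assay_detection_filter(
    ct: CtMatrix, min_rate: float = 0.75, report: QCReport | None = None
) -> CtMatrix:
    """Remove assays detected in fewer than ``min_rate`` of (retained) samples.

    Control assays are kept in the matrix whatever their detection rate but
    are never treated as features downstream (``CtMatrix.feature_assays``).
    """
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    retained_rows = ~ct.meta["excluded"].astype(bool)
    rate = ct.values.loc[retained_rows.values].notna().mean(axis=0)
    controls = set(ct.control_assays)
    keep = [a for a in ct.assay_ids if a in controls or rate[a] >= min_rate]
    if not set(keep) - controls:
        raise ValueError(f"detection filter at min_rate={min_rate} removed every feature assay")
    removed = [a for a in ct.assay_ids if a not in keep]
    if report is not None:
        report.assays = pd.DataFrame({
            "detection_rate": rate,
            "retained": [a in keep for a in ct.assay_ids],
        }, index=ct.assay_ids)
    logger.info("detection filter (>= %.2f): kept %d / %d assays", min_rate, len(keep), len(ct.assay_ids))
    out = ct.copy()
    out.values = out.values[keep]
    return CtMatrix(out.values, out.meta, out.controls)


def run_sample_qc(
    ct: CtMatrix,
    ct_limit: float = 37.0,
    hemolysis_threshold: float = 7.0,
    spikein_max_dev: float = 2.0,
    min_detection_rate: float = 0.75,
    exclude_flagged: bool = True,
) -> tuple[CtMatrix, QCReport]:
    """Full QC chain: Ct ceiling, hemolysis + spike-in flags, detection filter.

    A sample is excluded when its hemolysis OR spike-in flag is True (an
    explicit, logged decision; ``"indeterminate"`` flags are logged but do not
    exclude).  Idempotent: re-applying the chain changes nothing.
    """
    report = QCReport()
    out = discard_high_ct(ct, ct_limit, report)

    try:
        hemo = hemolysis_score(out, hemolysis_threshold)
    except ValueError as err:
        logger.warning("hemolysis QC degraded: %s", err)
        hemo = pd.DataFrame({
            "hemolysis_delta": pd.Series(np.nan, index=out.values.index),
            "hemolysis_flag": pd.Series("indeterminate", index=out.values.index, dtype=object),
        })
    spike = spikein_check(out, spikein_max_dev)
    samples = pd.concat([hemo, spike], axis=1)
    samples["excluded"] = (samples["hemolysis_flag"] == True) | (samples["spikein_flag"] == True)  # noqa: E712

    if exclude_flagged:
        to_exclude = [
            sid for sid in samples.index[samples["excluded"]]
            if not out.meta.loc[sid, "excluded"]
        ]
        if to_exclude:
            out.exclude_samples(to_exclude, "failed QC (hemolysis or spike-in)")
            logger.info("excluded %d samples failing QC: %s", len(to_exclude), to_exclude)
    samples["excluded"] = out.meta["excluded"].astype(bool)
    report.samples = samples

    out = assay_detection_filter(out, min_detection_rate, report)
    return out, report


def write_qc_report(report: QCReport, sample_path, assay_path) -> None:
    if report.samples is not None:
        report.samples.to_csv(sample_path, index_label="sample_id")
    if report.assays is not None:
        report.assays.to_csv(assay_path, index_label="assay_id")
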