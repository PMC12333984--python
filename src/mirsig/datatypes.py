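"""Core in-memory containers for the Ct-panel analysis pipeline.

Everything tabular is held as pandas objects indexed by ``sample_id`` so the
blocks stay aligned by construction.  Ct values are qPCR cycle thresholds
(lower = more abundant, one cycle ~ 2-fold); missing entries represent
undetected assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

COHORTS = ("broad", "targeted")
TIMEPOINTS = ("D1", "D7", "D14")
DOSE_LEVELS = (0, 20, 40, 80)

#: canonical control roles -> conventional assay names
DEFAULT_CONTROL_MAP = {
    "reference": "miR-23a-3p",
    "hemolysis": "miR-451a",
    "spikein": "cel-miR-39",
}

META_COLUMNS = ["sample_id", "cohort", "timepoint", "dose_gy", "excluded", "exclusion_reason"]


@dataclass
class SampleMeta:
    """Per-animal metadata attached to every Ct row."""

    sample_id: str
    cohort: str
    timepoint: str
    dose_gy: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"unknown cohort {self.cohort!r}; expected one of {COHORTS}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}")
        if self.dose_gy not in DOSE_LEVELS:
            raise ValueError(f"dose {self.dose_gy} Gy not in the four-level design {DOSE_LEVELS}")


def meta_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    """Assemble a metadata DataFrame (indexed by sample_id) from SampleMeta records."""
    df = pd.DataFrame([vars(m) for m in metas])
    return df.set_index("sample_id")


class CtMatrix:
    """Raw Ct values (samples x assays) plus sample metadata and control-assay roles.

    Parameters
    ----------
    values:
        DataFrame of Ct cycles, rows indexed by ``sample_id``, columns are
        miRNA assay names (kept verbatim, case-sensitive).  NaN marks missing.
    meta:
        DataFrame indexed by ``sample_id`` with columns cohort, timepoint,
        dose_gy, excluded, exclusion_reason; one row per sample row.
    controls:
        Mapping role -> assay name for {reference, hemolysis, spikein}.
        Roles whose assay column is absent from ``values`` map to None.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        meta: pd.DataFrame,
        controls: Mapping[str, str | None] | None = None,
    ) -> None:
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate assay ids: {dupes}")
        missing_meta = values.index.difference(meta.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {missing_meta.tolist()}")
        with np.errstate(invalid="ignore"):
            if (values.to_numpy(dtype=float) <= 0).any():
                raise ValueError("non-missing Ct values must be positive")
        self.values = values.astype(float)
        self.meta = meta.loc[values.index]
        controls = dict(controls or {})
        self.controls: dict[str, str | None] = {
            role: (assay if assay in values.columns else None)
            for role, assay in controls.items()
        }

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def control_assays(self) -> list[str]:
        return [a for a in self.controls.values() if a is not None]

    def control(self, role: str) -> str | None:
        return self.controls.get(role)

    @property
    def feature_assays(self) -> list[str]:
        """Assay columns that are candidate biomarkers (controls excluded)."""
        ctrl = set(self.control_assays)
        return [a for a in self.assay_ids if a not in ctrl]

    @property
    def dose_groups(self) -> pd.Series:
        return self.meta["dose_gy"]

    def retained(self) -> "CtMatrix":
        """View restricted to samples not flagged excluded."""
        keep = ~self.meta["excluded"].astype(bool)
        return CtMatrix(self.values.loc[keep.values], self.meta, self.controls)

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.meta.copy(), dict(self.controls))

    def exclude_samples(self, sample_ids: list[str], reason: str) -> None:
        """Flag samples as excluded (metadata-level; rows are never deleted)."""
        for sid in sample_ids:
            if sid not in self.meta.index:
                raise KeyError(f"unknown sample id {sid!r}")
            self.meta.loc[sid, "excluded"] = True
            prev = self.meta.loc[sid, "exclusion_reason"]
            self.meta.loc[sid, "exclusion_reason"] = f"{prev}; {reason}" if prev else reason

    def __repr__(self) -> str:  # pragma: no cover
        n, p = self.values.shape
        return f"CtMatrix({n} samples x {p} assays, {int(self.values.isna().sum().sum())} missing)"


#: clinical column conventions (units in docs/methods.md)
CLINICAL_FIELDS = [
    "lymphocytes",      # 10^9/L
    "wbc",              # 10^9/L
    "neutrophils",      # 10^9/L
    "rbc",              # 10^12/L
    "hemoglobin",       # g/dL
    "hematocrit",       # %
    "platelets",        # 10^9/L
    "crp",              # ng/mL
    "tewl_diff",        # g/h/m^2, irradiated minus contralateral limb
    "perfusion_ratio",  # unitless, irradiated / contralateral limb blood flow
    "injury_score",     # ordinal >= 0; only present at D7/D14
]


def validate_clinical(table: pd.DataFrame, timepoint: str | None = None) -> pd.DataFrame:
    """Check clinical-table invariants; returns the table unchanged."""
    if "perfusion_ratio" in table.columns:
        pr = table["perfusion_ratio"].dropna()
        if (pr <= 0).any():
            raise ValueError("perfusion_ratio must be positive where present")
    if "injury_score" in table.columns and timepoint == "D1":
        if table["injury_score"].notna().any():
            raise ValueError("injury_score must be absent for D1 tables")
    return table


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, recorded with every run."""

    # quality control
    ct_limit: float = 37.0            # Ct above this are discarded as unreliable
    hemolysis_threshold: float = 7.0  # cycles; Ct(reference) - Ct(hemolysis) above -> flag
    spikein_max_dev: float = 2.0      # cycles from cohort median spike-in Ct
    min_detection_rate: float = 0.75  # assay kept if detected in >= this fraction of samples
    # normalization
    n_normalizers: int = 3
    # multiblock sPLS-DA
    ncomp_grid: tuple[int, ...] = (1, 2, 3)
    keepx_grid: tuple[int, ...] = (3, 5, 7, 10, 15, 20, 30)
    design_weight: float = 0.1        # miR <-> clinical connection strength
    outcome_weight: float = 1.0       # every block <-> outcome connection
    deflate_outcome: bool = True
    stability_cutoff: float = 0.5     # feature deemed "stably selected"
    similarity_cutoff: float = 0.5    # cross-block correlation-circle cutoff
    # Bayesian bridge MCMC
    chains: int = 2
    burn_in: int = 2000
    draws: int = 5000                 # kept draws, total over chains
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_limit", "hemolysis_threshold", "spikein_max_dev",
                     "min_detection_rate", "design_weight", "outcome_weight"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 < self.min_detection_rate <= 1:
            raise ValueError("min_detection_rate must be in (0, 1]")
        if self.n_normalizers < 1:
            raise ValueError("n_normalizers must be >= 1")

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["ncomp_grid"] = list(self.ncomp_grid)
        d["keepx_grid"] = list(self.keepx_grid)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        for key in ("ncomp_grid", "keepx_grid"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
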