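"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a four-arm hindlimb-irradiation design (0/20/40/80 Gy,
~15 animals per arm) profiled on a plasma miRNA RT-qPCR panel:

* additive effects on the Ct (log2-expression) scale — a planted subset of
  assays shifts monotonically with dose, linear in log2(dose+1), random sign;
* a tight housekeeping cluster (near-identical baselines, biological SD
  <= 0.05 cycles) that adaptive normalization should discover;
* per-sample extraction-efficiency offsets shared by every assay of a sample;
* hemolysis events that boost miR-451a by 4-8 cycles;
* right-truncation missingness at the detection limit;
* a clinical block with a dose-dependent lymphocyte decrease and, at D7,
  elevated perfusion in the 80 Gy arm;
* day-14 outcomes (ordinal injury score, perfusion ratio) driven by a latent
  severity variable that tracks dose noisily rather than deterministically.

Ground truth (planted assays, effect curves, latent severities, hemolysed
samples) is returned alongside every cohort for recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_CONTROL_MAP, DOSE_LEVELS, CtMatrix, SampleMeta, meta_frame

LOG_DOSE_MAX = np.log2(1 + DOSE_LEVELS[-1])  # log2(81)


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_per_group: int = 15
    n_assays: int = 300
    n_signature: int = 15
    max_abs_shift: float = 1.5       # |delta-Ct| of the strongest planted assay at 80 Gy
    min_abs_shift: float = 0.75      # weakest planted assay at 80 Gy
    housekeeping_size: int = 3
    housekeeping_bio_sd: float = 0.05
    sigma_tech: float = 0.25         # technical replicate noise, cycles
    sigma_bio: float = 0.5           # per-assay biological variation, cycles
    sample_offset_sd: float = 0.3    # extraction-efficiency offset, cycles
    p_hemolysis: float = 0.05
    detection_limit: float = 37.0
    baseline_range: tuple[float, float] = (22.0, 36.0)
    # clinical effect sizes
    lymphocyte_depression: float = 1.5   # 10^9/L drop at 80 Gy
    perfusion_increase_d7: float = 0.4   # added to IRR/NIR ratio at 80 Gy (D7 only)
    p_clinical_missing: float = 0.03
    # day-14 latent severity
    d14_severity_slope: float = 2.4      # latent severity mean at 80 Gy
    severity_sd: float = 0.5
    d14_group_sizes: tuple[int, ...] = (12, 10, 11, 9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.housekeeping_size < 3:
            raise ValueError("housekeeping cluster needs >= 3 assays")
        if self.n_signature + self.housekeeping_size > self.n_assays:
            raise ValueError("signature and housekeeping sets exceed the assay count")

    def null(self) -> "SimulationParams":
        """Copy with every planted effect switched off (calibration runs)."""
        return replace(
            self,
            max_abs_shift=0.0,
            min_abs_shift=0.0,
            lymphocyte_depression=0.0,
            perfusion_increase_d7=0.0,
            d14_severity_slope=0.0,
        )


@dataclass
class GroundTruth:
    """What was planted, for recovery tests."""

    signature_assays: list[str]
    housekeeping_assays: list[str]
    dose_effects: dict[str, dict[int, float]]   # assay -> dose -> delta-Ct shift
    sample_offsets: dict[str, float]
    latent_severity: dict[str, float]
    hemolysed_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "signature_assays": self.signature_assays,
            "housekeeping_assays": self.housekeeping_assays,
            "dose_effects": {a: {str(d): v for d, v in c.items()}
                             for a, c in self.dose_effects.items()},
            "sample_offsets": self.sample_offsets,
            "latent_severity": self.latent_severity,
            "hemolysed_samples": self.hemolysed_samples,
        }


def _dose_curve(sign: float, magnitude: float) -> dict[int, float]:
    return {d: float(sign * magnitude * np.log2(1 + d) / LOG_DOSE_MAX) for d in DOSE_LEVELS}


def simulate_cohort(
    params: SimulationParams, timepoint: str = "D1", cohort: str = "targeted"
) -> tuple[CtMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one cohort: Ct panel, clinical table and ground truth.

    Ct(s, i) = baseline_i + offset_s + effect_i(dose_s) + bio_(i,s) + tech noise,
    right-truncated to missing above the detection limit.
    """
    rng = np.random.default_rng(params.seed)
    doses = np.repeat(DOSE_LEVELS, params.n_per_group)
    n = len(doses)
    sample_ids = [f"{cohort}_{timepoint}_m{i:03d}" for i in range(n)]

    assay_ids = [f"miR-sim-{i:03d}" for i in range(params.n_assays)]
    sig_assays = assay_ids[: params.n_signature]
    hk_assays = assay_ids[params.n_signature: params.n_signature + params.housekeeping_size]

    baselines = rng.uniform(*params.baseline_range, size=params.n_assays)
    # housekeeping cluster: near-identical moderate baselines
    baselines[params.n_signature: params.n_signature + params.housekeeping_size] = (
        25.0 + rng.normal(0, 0.1, params.housekeeping_size)
    )

    magnitudes = rng.uniform(params.min_abs_shift, params.max_abs_shift, params.n_signature)
    if params.n_signature:
        magnitudes[int(rng.integers(params.n_signature))] = params.max_abs_shift
    signs = rng.choice([-1.0, 1.0], size=params.n_signature)
    dose_effects = {a: _dose_curve(s, m) for a, s, m in zip(sig_assays, signs, magnitudes)}

    offsets = rng.normal(0, params.sample_offset_sd, n)
    effect = np.zeros((n, params.n_assays))
    for j, assay in enumerate(sig_assays):
        effect[:, j] = [dose_effects[assay][int(d)] for d in doses]

    bio_sd = np.full(params.n_assays, params.sigma_bio)
    bio_sd[params.n_signature: params.n_signature + params.housekeeping_size] = (
        params.housekeeping_bio_sd
    )
    ct = (
        baselines[None, :]
        + offsets[:, None]
        + effect
        + rng.normal(0, 1, (n, params.n_assays)) * bio_sd[None, :]
        + rng.normal(0, params.sigma_tech, (n, params.n_assays))
    )

    # control assays: endogenous reference, hemolysis indicator, exogenous spike-in
    ref = 26.0 + offsets + rng.normal(0, 0.3, n) + rng.normal(0, params.sigma_tech, n)
    hem = 21.5 + offsets + rng.normal(0, 0.4, n) + rng.normal(0, params.sigma_tech, n)
    spike = 21.0 + offsets + rng.normal(0, params.sigma_tech, n)
    hemolysed = rng.random(n) < params.p_hemolysis
    hem[hemolysed] -= rng.uniform(4.0, 8.0, int(hemolysed.sum()))

    values = pd.DataFrame(ct, index=sample_ids, columns=assay_ids)
    for role, col in (("reference", ref), ("hemolysis", hem), ("spikein", spike)):
        values[DEFAULT_CONTROL_MAP[role]] = col
    values = values.mask(values > params.detection_limit)
    values.index.name = "sample_id"

    meta = meta_frame([
        SampleMeta(sid, cohort, timepoint, float(d)) for sid, d in zip(sample_ids, doses)
    ])
    ct_matrix = CtMatrix(values, meta, DEFAULT_CONTROL_MAP)

    severity = (
        params.d14_severity_slope * np.log2(1 + doses) / LOG_DOSE_MAX
        + rng.normal(0, params.severity_sd, n)
    )
    clinical = _clinical_block(rng, params, doses, severity, sample_ids, timepoint)

    truth = GroundTruth(
        signature_assays=list(sig_assays),
        housekeeping_assays=list(hk_assays),
        dose_effects=dose_effects,
        sample_offsets=dict(zip(sample_ids, map(float, offsets))),
        latent_severity=dict(zip(sample_ids, map(float, severity))),
        hemolysed_samples=[s for s, h in zip(sample_ids, hemolysed) if h],
    )
    return ct_matrix, clinical, truth


def _clinical_block(rng, params, doses, severity, sample_ids, timepoint) -> pd.DataFrame:
    n = len(doses)
    dose_frac = (doses / DOSE_LEVELS[-1]) ** 1.5   # gradual, dominated by the 80 Gy arm
    lym = rng.normal(4.5, 0.8, n) - params.lymphocyte_depression * dose_frac
    table = pd.DataFrame(
        {
            "lymphocytes": np.clip(lym, 0.1, None),
            "wbc": rng.normal(6.0, 1.0, n),
            "neutrophils": np.clip(rng.normal(1.2, 0.3, n), 0.05, None),
            "rbc": rng.normal(9.0, 0.5, n),
            "hemoglobin": rng.normal(14.0, 0.8, n),
            "hematocrit": rng.normal(45.0, 2.0, n),
            "platelets": rng.normal(900.0, 120.0, n),
            "crp": np.clip(rng.normal(12.0, 3.0, n), 0.5, None),
            "tewl_diff": rng.normal(0.0, 1.5, n),
            "perfusion_ratio": np.exp(rng.normal(0.0, 0.15, n)),
            "dose_gy": doses.astype(float),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if timepoint == "D7":
        table.loc[doses == 80, "perfusion_ratio"] += params.perfusion_increase_d7
        p_injury = np.where(doses == 80, 0.25, np.where(doses == 40, 0.12, 0.0))
        table["injury_score"] = (rng.random(n) < p_injury).astype(float)
    if params.p_clinical_missing > 0:
        measured = [c for c in table.columns if c not in ("dose_gy", "injury_score")]
        mask = rng.random((n, len(measured))) < params.p_clinical_missing
        table[measured] = table[measured].mask(mask)
    return table


def simulate_d14_cohort(
    params: SimulationParams, severity_link: dict[int, float] | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a day-14 outcomes cohort (injury score + perfusion ratio).

    ``severity_link`` maps dose (Gy) to the latent severity mean; the default
    is linear in log2(dose+1) with slope ``params.d14_severity_slope``.  The
    observed outcomes are noisy monotone functions of the latent severity, so
    dose and severity correlate without strictly overlapping.
    """
    rng = np.random.default_rng(params.seed + 1)
    if severity_link is None:
        severity_link = {
            d: params.d14_severity_slope * np.log2(1 + d) / LOG_DOSE_MAX for d in DOSE_LEVELS
        }
    link_vals = [severity_link[d] for d in sorted(severity_link)]
    if any(b < a for a, b in zip(link_vals, link_vals[1:])):
        warnings.warn("severity_link is not monotone in dose", stacklevel=2)

    doses = np.concatenate([
        np.full(size, dose) for dose, size in zip(DOSE_LEVELS, params.d14_group_sizes)
    ])
    n = len(doses)
    sample_ids = [f"d14_m{i:03d}" for i in range(n)]
    severity = np.array([severity_link[int(d)] for d in doses]) + rng.normal(
        0, params.severity_sd, n
    )
    injury = np.clip(np.rint(severity + rng.normal(0, 0.4, n)), 0, 5)
    perfusion = np.exp(0.25 * severity + rng.normal(0, 0.15, n))
    table = pd.DataFrame(
        {
            "dose_gy": doses.astype(float),
            "injury_score": injury,
            "perfusion_ratio": perfusion,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        signature_assays=[],
        housekeeping_assays=[],
        dose_effects={},
        sample_offsets={},
        latent_severity=dict(zip(sample_ids, map(float, severity))),
        hemolysed_samples=[],
    )
    return table, truth
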