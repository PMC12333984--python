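"""End-to-end orchestration: simulate -> qc -> normalize -> fit -> evaluate -> bridge.

Every run writes its artifacts into a run directory together with a JSON
manifest recording the config snapshot, seed, stage timings, SHA-256 digests
of every output file, and any warnings — enough to reproduce deterministic
stages bit for bit.  Stages can also start from prior artifacts on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import pandas as pd

from . import bridge as bridge_mod
from . import evaluate as eval_mod
from . import io as io_mod
from . import qc as qc_mod
from . import splsda as splsda_mod
from .normalize import NormalizedExpression, NormalizerAudit, find_normalizer_set, to_neg_delta_ct
from .datatypes import PipelineConfig
from .simulate import SimulationParams, simulate_cohort, simulate_d14_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "normalize", "fit", "evaluate", "bridge")


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return PipelineConfig.from_dict(data)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Run:
    """Stateful pipeline run over a run directory."""

    def __init__(self, run_dir: str | Path, config: PipelineConfig | None = None):
        self.dir = Path(run_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config = config or PipelineConfig()
        prior = self._out("manifest.json")
        if prior.exists():
            self.manifest = json.loads(prior.read_text())
            self.manifest["config"] = self.config.to_dict()
            self.manifest["seed"] = self.config.seed
        else:
            self.manifest = {
                "config": self.config.to_dict(),
                "seed": self.config.seed,
                "timings_s": {},
                "outputs": {},
                "warnings": [],
            }

    def _out(self, name: str) -> Path:
        return self.dir / name

    def _record(self, stage: str, t0: float, files: list[Path]) -> None:
        self.manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            self.manifest["outputs"][f.name] = _digest(f)
        io_mod.write_json(self.manifest, self._out("manifest.json"))

    # -- stages ----------------------------------------------------------
    def simulate(self, timepoint: str = "D1") -> None:
        t0 = time.perf_counter()
        params = SimulationParams(seed=self.config.seed)
        ct, clinical, truth = simulate_cohort(params, timepoint=timepoint)
        d14, d14_truth = simulate_d14_cohort(params)
        io_mod.write_ct_table(ct, self._out("ct_table.csv"))
        io_mod.write_clinical_table(clinical, self._out("clinical.csv"))
        io_mod.write_clinical_table(d14, self._out("d14.csv"))
        io_mod.write_json(truth.to_dict(), self._out("ground_truth.json"))
        self._record("simulate", t0, [self._out(n) for n in
                                      ("ct_table.csv", "clinical.csv", "d14.csv",
                                       "ground_truth.json")])

    def qc(self) -> None:
        t0 = time.perf_counter()
        ct = self._require_ct("ct_table.csv")
        cfg = self.config
        clean, report = qc_mod.run_sample_qc(
            ct, cfg.ct_limit, cfg.hemolysis_threshold,
            cfg.spikein_max_dev, cfg.min_detection_rate)
        io_mod.write_ct_table(clean, self._out("ct_qc.csv"))
        qc_mod.write_qc_report(report, self._out("qc_samples.csv"), self._out("qc_assays.csv"))
        io_mod.write_json(report.summary(), self._out("qc_summary.json"))
        self._record("qc", t0, [self._out(n) for n in
                                ("ct_qc.csv", "qc_samples.csv", "qc_assays.csv",
                                 "qc_summary.json")])

    def normalize(self) -> None:
        t0 = time.perf_counter()
        ct = self._require_ct("ct_qc.csv")
        normalizers, audit = find_normalizer_set(ct, self.config.n_normalizers)
        expr = to_neg_delta_ct(ct, normalizers, audit)
        out = expr.values.copy()
        out.insert(0, "dose_gy", expr.dose_groups)
        out.to_csv(self._out("expression.csv"), index_label="sample_id",
                   float_format="%.10g")
        io_mod.write_json(audit.to_dict(), self._out("normalizer_audit.json"))
        self._record("normalize", t0, [self._out("expression.csv"),
                                       self._out("normalizer_audit.json")])

    def fit(self) -> None:
        t0 = time.perf_counter()
        dataset = self._dataset()
        cfg = self.config
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = splsda_mod.fit_tuned(
                dataset, cfg.ncomp_grid, cfg.keepx_grid,
                deflate_outcome=cfg.deflate_outcome)
        self._model = model
        self._dataset_cache = dataset
        io_mod.write_signature_report(model, self._out("signature.csv"))
        model.tuning_trace.to_csv(self._out("tuning_trace.csv"), index=False)
        model.stability.to_csv(self._out("stability.csv"), index=False)
        files = [self._out(n) for n in ("signature.csv", "tuning_trace.csv", "stability.csv")]
        for b in model.block_names:
            lf, sf = self._out(f"loadings_{b}.csv"), self._out(f"scores_{b}.csv")
            model.loadings_frame(b).to_csv(lf)
            pd.DataFrame(model.scores[b], index=dataset.outcome.index,
                         columns=[f"comp{h+1}" for h in range(model.ncomp)]
                         ).to_csv(sf, index_label="sample_id")
            files += [lf, sf]
        self._record("fit", t0, files)

    def evaluate(self, resubstitution: bool = False) -> None:
        t0 = time.perf_counter()
        model, dataset = self._require_model()
        if resubstitution:
            _, scores = splsda_mod.predict_group(model, dataset.blocks)
            preds = pd.DataFrame({"true": dataset.outcome})
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                loo, _ = splsda_mod.loo_predictions(dataset, model.ncomp, model.keepX)
            loo = loo.set_index("sample_id")
            scores = loo[[f"score_{g}" for g in model.groups]]
            scores.columns = model.groups
            preds = loo
        roc = eval_mod.one_vs_rest_roc(scores, dataset.outcome)
        eval_mod.roc_table(roc).to_csv(self._out("roc.csv"), index=False)
        pairs, full = splsda_mod.cross_block_similarity(
            model, cutoff=self.config.similarity_cutoff)
        pairs.to_csv(self._out("similarity_pairs.csv"), index=False)
        full.to_csv(self._out("similarity.csv"))
        self._record("evaluate", t0, [self._out(n) for n in
                                      ("roc.csv", "similarity_pairs.csv", "similarity.csv")])

    def bridge(self, component: int = 1, outcome: str = "injury_score") -> None:
        t0 = time.perf_counter()
        model, dataset = self._require_model()
        bridge_mod.attach_labels(model, dataset.outcome)
        prior = bridge_mod.summarize_coordinates(model, component)
        d14 = io_mod.read_clinical_table(self._out("d14.csv"), timepoint="D14")
        cfg = self.config
        result = bridge_mod.fit_bridge(
            prior, d14, outcome=outcome, chains=cfg.chains,
            burn_in=cfg.burn_in, draws=cfg.draws, seed=cfg.seed)
        name = f"bridge_{outcome}_comp{component}.json"
        io_mod.write_json(result.to_dict(), self._out(name))
        self._record("bridge", t0, [self._out(name)])

    # -- helpers ----------------------------------------------------------
    def _require_ct(self, name: str):
        path = self._out(name)
        if not path.exists():
            raise FileNotFoundError(f"expected upstream artifact {path}")
        return io_mod.read_ct_table(path)

    def _dataset(self) -> splsda_mod.BlockDataset:
        path = self._out("expression.csv")
        if not path.exists():
            raise FileNotFoundError(f"expected upstream artifact {path}")
        tab = pd.read_csv(path, index_col=0)
        expr = NormalizedExpression(
            values=tab.drop(columns=["dose_gy"]),
            normalizer_set=[], dispersion=float("nan"),
            audit=NormalizerAudit(),
            dose_groups=tab["dose_gy"],
        )
        clin_path = self._out("clinical.csv")
        clinical = io_mod.read_clinical_table(clin_path) if clin_path.exists() else None
        if clinical is not None:
            clinical = clinical.loc[clinical.index.intersection(tab.index)]
        return splsda_mod.build_block_dataset(
            expr, clinical, self.config.design_weight, self.config.outcome_weight)

    def _require_model(self):
        if not hasattr(self, "_model"):
            self.fit()
        return self._model, self._dataset_cache


def run_pipeline(
    config: PipelineConfig | str | Path,
    run_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    timepoint: str = "D1",
) -> dict:
    """Execute the requested stages in order; returns the run manifest."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
    run = Run(run_dir, config)
    for stage in STAGES:
        if stage in stages:
            logger.info("stage %s", stage)
            getattr(run, stage)() if stage != "simulate" else run.simulate(timepoint)
    return run.manifest
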