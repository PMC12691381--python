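"""End-to-end orchestration of the synthetic study analogue.

Stages, each readable and re-runnable from the previous stage's files:

1. ``synth``       simulate a pooled multi-component training cohort and
                   an EV-only clinical cohort (HCC vs cirrhosis)
2. ``preprocess``  baseline -> normalize -> bin both cohorts to 375 bins
3. ``ae``          train the autoencoder on the pooled training matrix
4. ``encode``      latent features for both cohorts (clinical spectra
                   are encoded, never used to refit)
5. ``stats``       UMAP embedding of the training latents; Welch/BH
                   feature comparison of the clinical latents
6. ``clf``         screened elastic-net LOOCV with lambda.1se, ROC/AUC,
                   Youden point, optional permutation null
7. ``sensitivity`` latent-perturbation differential profile of the
                   top-ranked feature with band annotations

``run_pipeline`` executes the enabled stages in order, records a
manifest (file hashes, parameters, wall time per stage) and stops with
the manifest of completed stages intact if a stage fails.  Disabled
stages cause dependent stages to be skipped with a logged reason unless
their input files already exist from an earlier run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ae import (AEArchitecture, AEModel, TrainConfig, build_model, encode,
                 reconstruct, reconstruction_metrics, study_train_config, train)
from .clf import EnetSpec, evaluate_latent_classifier, permutation_auc, roc_curve_points
from .latentstats import compare_latent_features, embed_2d
from .preprocess import PreprocessConfig, preprocess_set
from .sensitivity import (DEFAULT_WINDOWS, PerturbationSpec, annotate_bands,
                          latent_perturbation_profile)
from .spectra import SpectrumSet
from .synth import (clinical_cohort_config, default_disease_effect,
                    generate_cohort, training_cohort_config)

logger = logging.getLogger("evlatent.pipeline")

STAGES = ("synth", "preprocess", "ae", "encode", "stats", "clf", "sensitivity")

_DEPENDENCIES: dict[str, list[str]] = {
    "synth": [],
    "preprocess": ["training_spectra.csv", "training_metadata.csv",
                   "clinical_spectra.csv", "clinical_metadata.csv"],
    "ae": ["training_matrix.csv", "clinical_matrix.csv"],
    "encode": ["ae_model.npz", "training_matrix.csv", "clinical_matrix.csv"],
    "stats": ["training_latent.csv", "clinical_latent.csv", "clinical_metadata.csv"],
    "clf": ["clinical_latent.csv", "clinical_metadata.csv"],
    "sensitivity": ["ae_model.npz", "clinical_latent.csv", "feature_tests.csv"],
}


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "evlatent_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_per_class: int = 20
    n_hcc: int = 9
    n_cirrhosis: int = 16
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    architecture: AEArchitecture = dataclasses.field(default_factory=AEArchitecture)
    train: TrainConfig = dataclasses.field(default_factory=study_train_config)
    enet: EnetSpec = dataclasses.field(default_factory=EnetSpec)
    perturbation: PerturbationSpec = dataclasses.field(default_factory=PerturbationSpec)
    n_permutations: int = 0  # 0 disables the permutation null

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = {
            "preprocess": PreprocessConfig, "architecture": AEArchitecture,
            "train": TrainConfig, "enet": EnetSpec, "perturbation": PerturbationSpec,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                if "encoder_units" in (value or {}):
                    value["encoder_units"] = tuple(value["encoder_units"])
                kwargs[key] = sub[key](**(value or {}))
            elif key == "stages":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str = __version__
    stages: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float,
               status: str = "completed", reason: str = "") -> None:
        self.stages[stage] = {
            "status": status,
            "reason": reason,
            "wall_time_s": round(seconds, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"version": self.version, "config": self.config, "stages": self.stages},
            indent=2, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    enet = d.get("enet", {})
    if isinstance(enet.get("lambda_grid"), np.ndarray):
        enet["lambda_grid"] = enet["lambda_grid"].tolist()
    return d


# ---------------------------------------------------------------------------
# stage implementations: read inputs from out_dir, write outputs to out_dir

def _stage_synth(cfg: PipelineConfig, out: Path) -> list[Path]:
    train_cfg = training_cohort_config(cfg.n_per_class, seed=cfg.seed)
    clin_cfg = clinical_cohort_config(cfg.n_hcc, cfg.n_cirrhosis, seed=cfg.seed + 1)
    effect = default_disease_effect()
    training = generate_cohort(train_cfg)
    clinical = generate_cohort(clin_cfg, effect=effect)
    training.to_csv(out / "training_spectra.csv", out / "training_metadata.csv")
    clinical.to_csv(out / "clinical_spectra.csv", out / "clinical_metadata.csv")
    return [out / f for f in ("training_spectra.csv", "training_metadata.csv",
                              "clinical_spectra.csv", "clinical_metadata.csv")]


def _stage_preprocess(cfg: PipelineConfig, out: Path) -> list[Path]:
    outputs = []
    provenance = {}
    for name in ("training", "clinical"):
        sset = SpectrumSet.from_csv(out / f"{name}_spectra.csv",
                                    out / f"{name}_metadata.csv")
        matrix, prov = preprocess_set(sset, cfg.preprocess)
        path = out / f"{name}_matrix.csv"
        matrix.to_csv(path)
        provenance[name] = prov
        outputs.append(path)
    prov_path = out / "preprocess_provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2))
    outputs.append(prov_path)
    return outputs


def _stage_ae(cfg: PipelineConfig, out: Path) -> list[Path]:
    # unsupervised training pool: multi-component cohort plus the clinical
    # EV spectra (labels unused); clinical latents still come from encoding
    matrix = pd.concat([
        pd.read_csv(out / "training_matrix.csv", index_col=0),
        pd.read_csv(out / "clinical_matrix.csv", index_col=0),
    ])
    tc = dataclasses.replace(cfg.train, seed=cfg.seed + 2)
    model = build_model(cfg.architecture, tc)
    train(model, matrix)
    model.save(out / "ae_model.npz")
    hist = pd.DataFrame({k: v for k, v in model.history.items()
                         if k in ("train_mae", "val_mae")})
    hist.index.name = "epoch"
    hist.to_csv(out / "training_history.csv")
    report = reconstruction_metrics(matrix.to_numpy(), reconstruct(model, matrix),
                                    final_training_mae=model.history["train_mae"][-1])
    (out / "reconstruction_report.json").write_text(json.dumps({
        "mean_rmse": report.mean_rmse, "sd_rmse": report.sd_rmse,
        "final_training_mae": report.final_training_mae,
    }, indent=2))
    return [out / "ae_model.npz", out / "training_history.csv",
            out / "reconstruction_report.json"]


def _stage_encode(cfg: PipelineConfig, out: Path) -> list[Path]:
    model = AEModel.load(out / "ae_model.npz")
    outputs = []
    for name in ("training", "clinical"):
        matrix = pd.read_csv(out / f"{name}_matrix.csv", index_col=0)
        latent = encode(model, matrix)
        path = out / f"{name}_latent.csv"
        latent.to_csv(path)
        outputs.append(path)
    return outputs


def _stage_stats(cfg: PipelineConfig, out: Path) -> list[Path]:
    training_latent = pd.read_csv(out / "training_latent.csv", index_col=0)
    training_meta = pd.read_csv(out / "training_metadata.csv")
    emb = embed_2d(training_latent, seed=cfg.seed + 3)
    emb_df = emb.to_frame(training_latent.index)
    emb_df["component"] = training_meta["component"].to_numpy()
    emb_df.to_csv(out / "embedding.csv", index=False)

    clinical_latent = pd.read_csv(out / "clinical_latent.csv", index_col=0)
    clinical_meta = pd.read_csv(out / "clinical_metadata.csv")
    table = compare_latent_features(clinical_latent, clinical_meta["group"],
                                    group_order=("HCC", "cirrhosis"))
    table.to_csv(out / "feature_tests.csv", index=False)
    return [out / "embedding.csv", out / "feature_tests.csv"]


def _stage_clf(cfg: PipelineConfig, out: Path) -> list[Path]:
    latent = pd.read_csv(out / "clinical_latent.csv", index_col=0)
    meta = pd.read_csv(out / "clinical_metadata.csv")
    labels = meta["group"].to_numpy()
    result = evaluate_latent_classifier(latent, labels, positive_group="HCC",
                                        spec=cfg.enet)
    summary: dict = {"screened_features": result["screened_features"]}
    outputs = []
    if result["cv"] is not None:
        cv, roc = result["cv"], result["roc"]
        y = (labels == "HCC").astype(int)
        pd.DataFrame({"lambda": cv.lambdas, "mean_deviance": cv.cv_deviance,
                      "se": cv.cv_se}).to_csv(out / "cv_curve.csv", index=False)
        pd.DataFrame({"sample_id": latent.index, "oof_score": cv.oof_scores,
                      "group": labels}).to_csv(out / "oof_scores.csv", index=False)
        roc_curve_points(cv.oof_scores, y).to_csv(out / "roc_points.csv", index=False)
        outputs += [out / "cv_curve.csv", out / "oof_scores.csv", out / "roc_points.csv"]
        summary.update({
            "lambda_min": cv.lambda_min, "lambda_1se": cv.lambda_1se,
            "selected_support": cv.selected_support,
            "auc": roc.auc, "ci_95": list(roc.ci_95),
            "youden_threshold": roc.youden_threshold,
            "confusion": roc.confusion, "accuracy": roc.accuracy,
        })
        if cfg.n_permutations > 0:
            X = latent[result["screened_features"]]
            null = permutation_auc(X, y.astype(float), cfg.enet,
                                   n_permutations=cfg.n_permutations,
                                   seed=cfg.seed + 4)
            summary["permutation_p"] = null.p_value
            summary["n_permutations"] = null.n_permutations
    else:
        summary["note"] = "no feature passed the FDR screen; classifier not fitted"
    path = out / "classifier_summary.json"
    path.write_text(json.dumps(summary, indent=2))
    outputs.append(path)
    return outputs


def _stage_sensitivity(cfg: PipelineConfig, out: Path) -> list[Path]:
    model = AEModel.load(out / "ae_model.npz")
    latent = pd.read_csv(out / "clinical_latent.csv", index_col=0)
    tests = pd.read_csv(out / "feature_tests.csv")
    feature = str(tests.iloc[0]["feature"])  # table is ranked by p
    matrix_cols = pd.read_csv(out / "clinical_matrix.csv", index_col=0, nrows=1).columns
    grid = np.asarray([float(c) for c in matrix_cols])
    spec = dataclasses.replace(cfg.perturbation, feature=feature)
    profile = latent_perturbation_profile(model, latent, spec, grid=grid)
    profile.to_frame().to_csv(out / "differential_profile.csv", index=False)
    annotations = annotate_bands(profile, DEFAULT_WINDOWS)
    (out / "band_annotations.json").write_text(json.dumps({
        "feature": profile.feature,
        "delta": profile.delta_used,
        "sign_convention": profile.sign_convention,
        "windows": [dataclasses.asdict(a) for a in annotations],
    }, indent=2))
    return [out / "differential_profile.csv", out / "band_annotations.json"]


_STAGE_FUNCS = {
    "synth": _stage_synth, "preprocess": _stage_preprocess, "ae": _stage_ae,
    "encode": _stage_encode, "stats": _stage_stats, "clf": _stage_clf,
    "sensitivity": _stage_sensitivity,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_jsonable_config(config))
    manifest_path = out / "manifest.json"

    for stage in STAGES:
        if stage not in config.stages:
            logger.info("stage %s disabled by config; skipping", stage)
            manifest.record(stage, [], 0.0, status="skipped", reason="disabled")
            manifest.write(manifest_path)
            continue
        missing = [f for f in _DEPENDENCIES[stage] if not (out / f).exists()]
        if missing:
            reason = f"missing upstream artifacts: {missing}"
            logger.warning("stage %s skipped: %s", stage, reason)
            manifest.record(stage, [], 0.0, status="skipped", reason=reason)
            manifest.write(manifest_path)
            continue
        logger.info("running stage %s", stage)
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception:
            manifest.record(stage, [], time.perf_counter() - t0, status="failed")
            manifest.write(manifest_path)
            raise
        manifest.record(stage, outputs, time.perf_counter() - t0)
        manifest.write(manifest_path)
    return manifest
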