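"""End-to-end pipeline orchestration and persisted run artifacts.

One :class:`PipelineConfig` drives the whole workflow: ingest (one of
three input modes) -> curation -> featurization -> activity scaling ->
75/25 partition -> min-max scaling -> modelability gate -> feature
ranking (both importance methods by default) -> stepwise selection ->
full-model and SF-model fitting -> external validation -> applicability
domain.  Every completed stage leaves its artifact in the working
directory and the manifest lists them all; a run is deterministic given
the base seed, from which each stochastic stage derives its own seed at
a fixed offset.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chembl import TargetQuery, fetch_bioactivities, parse_chembl_payload
from .curation import curate, parse_input
from .errors import ConfigurationError, EmptyDatasetError
from .featurize import (
    FeatureMatrix,
    FingerprintSpec,
    compute_descriptors,
    compute_fingerprints,
    merge_feature_blocks,
)
from .modelability import ModelabilityGateFailure, modelability_gate, modi
from .ranking import rank_by_forest, rank_features
from .stepwise import LearnerConfig, plot_trace, select_features, stepwise_trace
from .transform import (
    apply_minmax,
    fit_minmax,
    partition_data,
    scale_activities,
)
from .validation import (
    ADReport,
    ModelBundle,
    ValidationReport,
    applicability_domain,
    fit_and_validate,
)

logger = logging.getLogger(__name__)

MODES = ("fully_automated", "customized_structures", "customized_features")

# fixed per-stage seed offsets off the base seed
SEED_PARTITION = 1
SEED_RANKING = 100
SEED_STEPWISE = 200
SEED_MODEL = 300


@dataclass
class PipelineConfig:
    mode: str = "customized_structures"
    target_name: str = ""
    uniprot_id: str = ""
    activity_type: str = "Ki"
    endpoint: str = ""  # URL or fixture path (fully_automated mode)
    input_path: str = ""  # customized modes
    input_format: str = "csv"
    fingerprints: list[dict] = field(default_factory=lambda: [{"kind": "morgan"}])
    nfold: int = 10
    ntree: int = 500
    learner: str = "svm"
    svm_C: float = 1.0
    svm_epsilon: float = 0.1
    ranking_methods: list[str] = field(default_factory=lambda: ["scaled", "unscaled"])
    step_size: int = 1
    selection_tolerance: float = 0.0
    train_fraction: float = 0.75
    modi_threshold: float = 0.45
    modi_mode: str = "halt"
    modi_k: int = 5
    ad_z: float = 0.5
    activity_prescaled: bool = False
    seed: int = 0
    workdir: str = "qsarflow_run"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.mode == "fully_automated":
            if not (self.uniprot_id and self.activity_type and self.endpoint):
                raise ConfigurationError(
                    "fully_automated mode requires uniprot_id, activity_type and endpoint"
                )
        elif not self.input_path:
            raise ConfigurationError(f"{self.mode} mode requires input_path")
        if self.modi_mode not in ("warn", "halt"):
            raise ConfigurationError("modi_mode must be 'warn' or 'halt'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def learner_config(self) -> LearnerConfig:
        return LearnerConfig(
            learner=self.learner, C=self.svm_C, epsilon=self.svm_epsilon, ntree=self.ntree
        )


@dataclass
class RunArtifacts:
    """Everything a finished (or halted) run produced."""

    workdir: Path
    manifest: dict
    halted_at: str | None = None
    modi_results: list = field(default_factory=list)
    validation: ValidationReport | None = None
    ad_reports: dict = field(default_factory=dict)
    selected: dict = field(default_factory=dict)
    bundles: dict = field(default_factory=dict)

    @property
    def files(self) -> list[str]:
        return self.manifest.get("artifacts", [])


def _read_feature_table(path: str | Path) -> tuple[FeatureMatrix, pd.Series]:
    """Customized-features mode input: compound_id, activity, numeric columns."""
    df = pd.read_csv(path)
    for col in ("compound_id", "activity"):
        if col not in df.columns:
            raise ConfigurationError(f"feature table lacks required column {col!r}")
    df = df.set_index("compound_id")
    y = df.pop("activity").astype(float)
    fm = FeatureMatrix(df.astype(float), pd.Series("descriptor", index=df.columns), {})
    return fm, y


def _ingest(config: PipelineConfig):
    if config.mode == "fully_automated":
        query = TargetQuery(config.uniprot_id, config.activity_type)
        payload = fetch_bioactivities(query, config.endpoint)
        return parse_chembl_payload(payload)
    return parse_input(config.input_path, config.input_format)


def _featurize(config: PipelineConfig, dataset) -> FeatureMatrix:
    smiles = [r.smiles for r in dataset.records]
    ids = [r.compound_id for r in dataset.records]
    blocks = []
    desc, rejected = compute_descriptors(smiles, ids)
    blocks.append(desc)
    rejected_ids = {cid for cid, _ in rejected}
    kept_ids = [i for i in ids if i not in rejected_ids]
    kept_smiles = [s for i, s in zip(ids, smiles) if i not in rejected_ids]
    for fp_args in config.fingerprints:
        spec = FingerprintSpec(**fp_args)
        block, _ = compute_fingerprints(kept_smiles, spec, kept_ids)
        blocks.append(block)
    blocks[0] = desc.subset_rows(kept_ids)
    return merge_feature_blocks(blocks)


def run_pipeline(config: PipelineConfig) -> RunArtifacts:
    """Execute the whole workflow and persist per-stage artifacts."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    manifest = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": artifacts,
    }

    def save(name: str, writer) -> Path:
        path = workdir / name
        writer(path)
        artifacts.append(name)
        return path

    def finish(halted_at: str | None = None, **extra) -> RunArtifacts:
        manifest["halted_at"] = halted_at
        (workdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str), encoding="utf-8"
        )
        return RunArtifacts(workdir=workdir, manifest=manifest, halted_at=halted_at, **extra)

    # --- ingest / curate / featurize --------------------------------------
    if config.mode == "customized_features":
        features, raw_y = _read_feature_table(config.input_path)
        if features.shape[0] < 4:
            raise EmptyDatasetError("feature table has fewer than 4 usable rows")
        constant = features.values.columns[
            (features.values.max() == features.values.min()).to_numpy()
        ].tolist()
        if constant:
            features = FeatureMatrix(
                features.values.drop(columns=constant),
                features.column_kind.drop(index=constant),
                {"removed_constant_columns": constant},
            )
    else:
        records = _ingest(config)
        dataset = curate(records, config.activity_type)
        save("curation_log.csv", lambda p: dataset.log_table().to_csv(p, index=False))
        features = _featurize(config, dataset)
        raw_y = pd.Series(
            {r.compound_id: r.activity_value for r in dataset.records}, dtype=float
        ).loc[features.row_ids]
    save("features.csv", features.to_csv)
    save(
        "features_manifest.json",
        lambda p: Path(p).write_text(json.dumps(features.meta, default=str), encoding="utf-8"),
    )

    # --- activities, partition, scaling -----------------------------------
    activities = scale_activities(raw_y, skip=config.activity_prescaled)
    split = partition_data(
        features.row_ids, train_fraction=config.train_fraction, seed=config.seed + SEED_PARTITION
    )
    X_train = features.subset_rows(split.train_ids)
    X_ivs = features.subset_rows(split.ivs_ids)
    # columns constant over the training rows (even if not globally) have
    # no fittable min-max range; drop them from both partitions and log
    tr_vals = X_train.values
    train_constant = tr_vals.columns[(tr_vals.max() == tr_vals.min()).to_numpy()].tolist()
    if train_constant:
        logger.info("dropping %d columns constant on the training partition", len(train_constant))
        keep = [c for c in X_train.column_names if c not in set(train_constant)]
        X_train = X_train.subset_columns(keep)
        X_ivs = X_ivs.subset_columns(keep)
    manifest["train_constant_columns_removed"] = train_constant
    scaler = fit_minmax(X_train)
    X_train_s = apply_minmax(X_train, scaler)
    X_ivs_s = apply_minmax(X_ivs, scaler)
    y_train = activities.values.loc[split.train_ids]
    y_ivs = activities.values.loc[split.ivs_ids]
    save(
        "split.json",
        lambda p: Path(p).write_text(
            json.dumps({"train_ids": split.train_ids, "ivs_ids": split.ivs_ids}),
            encoding="utf-8",
        ),
    )

    # --- modelability gate -------------------------------------------------
    modi_results = [
        modi(X_train_s, y_train.to_numpy(), k=k, gate_threshold=config.modi_threshold)
        for k in (3, 5)
    ]
    save(
        "modi.json",
        lambda p: Path(p).write_text(
            json.dumps([dataclasses.asdict(m) for m in modi_results], indent=1),
            encoding="utf-8",
        ),
    )
    gate_result = next(m for m in modi_results if m.k == config.modi_k)
    try:
        modelability_gate(gate_result, mode=config.modi_mode)
    except ModelabilityGateFailure:
        logger.error("pipeline halted at the modelability gate")
        return finish(halted_at="modelability_gate", modi_results=modi_results)

    # --- ranking, stepwise selection, final models -------------------------
    learner = config.learner_config()
    report = ValidationReport()
    selected: dict = {}
    bundles: dict = {}
    ad_frames = []

    # one internal split shared by every stepwise run and replayed in the
    # final validation so scores are comparable across models
    first_trace = None
    for mi, method in enumerate(config.ranking_methods):
        table = rank_by_forest(
            X_train_s,
            y_train.to_numpy(),
            nfold=config.nfold,
            ntree=config.ntree,
            seed=config.seed + SEED_RANKING,
            method=method,
        )
        save(f"importance_{method}.csv", table.to_csv)
        ranked = rank_features(table)
        trace = stepwise_trace(
            X_train_s,
            y_train.to_numpy(),
            ranked,
            learner=learner,
            step_size=config.step_size,
            seed=config.seed + SEED_STEPWISE,
            ranking_method=method,
        )
        if first_trace is None:
            first_trace = trace
        save(f"stepwise_{method}.csv", trace.to_csv)
        save(f"stepwise_{method}.png", lambda p, tr=trace: plot_trace(tr, p))
        sf = select_features(trace, ranked, tolerance=config.selection_tolerance)
        selected[method] = sf
        _, bundle = fit_and_validate(
            X_train_s,
            y_train.to_numpy(),
            X_ivs_s,
            y_ivs.to_numpy(),
            sf.features,
            learner=learner,
            seed=config.seed + SEED_MODEL,
            internal_split=trace.split,
            model_name=f"sf_{method}",
            report=report,
            bundle_dir=workdir / "bundles" / f"sf_{method}",
            scaler=scaler,
            activity_prescaled=config.activity_prescaled,
            ad_z=config.ad_z,
        )
        bundles[f"sf_{method}"] = bundle
        (workdir / "bundles" / f"sf_{method}" / "featurization.json").write_text(
            json.dumps({"fingerprints": config.fingerprints}), encoding="utf-8"
        )
        ad = applicability_domain(
            X_train_s.subset_columns(sf.features),
            X_ivs_s.subset_columns(sf.features),
            z=config.ad_z,
        )
        frame = ad.table.copy()
        frame.insert(0, "model", f"sf_{method}")
        ad_frames.append((f"sf_{method}", ad, frame))

    _, full_bundle = fit_and_validate(
        X_train_s,
        y_train.to_numpy(),
        X_ivs_s,
        y_ivs.to_numpy(),
        None,
        learner=learner,
        seed=config.seed + SEED_MODEL,
        internal_split=first_trace.split if first_trace else None,
        model_name="full",
        report=report,
        bundle_dir=workdir / "bundles" / "full",
        scaler=scaler,
        activity_prescaled=config.activity_prescaled,
        ad_z=config.ad_z,
    )
    bundles["full"] = full_bundle
    ad_full = applicability_domain(X_train_s, X_ivs_s, z=config.ad_z)
    frame = ad_full.table.copy()
    frame.insert(0, "model", "full")
    ad_frames.append(("full", ad_full, frame))

    save("validation_report.csv", report.to_csv)
    save(
        "ad_report.csv",
        lambda p: pd.concat([f for _, _, f in ad_frames], ignore_index=True).to_csv(p, index=False),
    )
    for name in bundles:
        artifacts.append(f"bundles/{name}")

    ad_reports = {name: ad for name, ad, _ in ad_frames}
    return finish(
        halted_at=None,
        modi_results=modi_results,
        validation=report,
        ad_reports=ad_reports,
        selected=selected,
        bundles=bundles,
    )


def predict_external(bundle_path: str | Path, new_input, input_kind: str = "features"):
    """Predict new compounds from a persisted model bundle.

    ``new_input`` is a feature table (DataFrame or CSV path with a
    compound_id column, ``input_kind="features"``) or a list of SMILES
    (``input_kind="structures"``, featurized with the bundle's stored
    featurization settings).  Predictions carry applicability-domain flags.
    """
    bundle_path = Path(bundle_path)
    bundle = ModelBundle.load(bundle_path)
    if input_kind == "features":
        if isinstance(new_input, (str, Path)):
            df = pd.read_csv(new_input)
            if "compound_id" in df.columns:
                df = df.set_index("compound_id")
        else:
            df = new_input
        return bundle.predict(df)
    if input_kind == "structures":
        feat_file = bundle_path / "featurization.json"
        fp_specs = [{"kind": "morgan"}]
        if feat_file.exists():
            fp_specs = json.loads(feat_file.read_text(encoding="utf-8")).get(
                "fingerprints", fp_specs
            )
        smiles = list(new_input)
        ids = [f"query{i + 1}" for i in range(len(smiles))]
        desc, rejected = compute_descriptors(smiles, ids)
        rejected_ids = {cid for cid, _ in rejected}
        kept = [i for i in ids if i not in rejected_ids]
        kept_smiles = [s for i, s in zip(ids, smiles) if i not in rejected_ids]
        blocks = [desc.subset_rows(kept)]
        for args in fp_specs:
            block, _ = compute_fingerprints(kept_smiles, FingerprintSpec(**args), kept)
            blocks.append(block)
        df = pd.concat([b.values for b in blocks], axis=1)
        return bundle.predict(df)
    raise ConfigurationError("input_kind must be 'features' or 'structures'")
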