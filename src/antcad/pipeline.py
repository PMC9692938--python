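"""End-to-end orchestration: pre-process, extract, select, classify, report.

A :class:`PipelineConfig` bundles the stage configurations under one master
seed.  Stage seeds are derived deterministically from the master seed with
``SeedSequence([master, stage_index])`` (stage indices: split 0,
auto-encoder 1, selection 2, classifier 3), so no stage touches global
randomness and the full run is reproducible from the config alone.

:func:`run_pipeline` executes the chain on an image dataset and persists
every intermediate artifact (feature tables, selection result, metric
report) so downstream stages can be resumed without recomputation.
:func:`compare_selection` reruns the shared classifier on (a) all features,
(b) the selector's subset, and (c) a random subset of equal size over one
shared train/test split — the with/without-selection contrast.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .aco import ACOConfig, random_subset_baseline, run_aco
from .autoencoder import AEConfig, extract_features, save_params, train
from .evaluation import ClassifierSpec, evaluate
from .image_prep import (
    KNOWN_BACKBONE_DIMS,
    ImageRecord,
    PrepConfig,
    TARGET_SHAPES,
    cnn_feature_adapter,
    load_image_dir,
    records_to_table,
    resize_image,
    stratified_split,
    write_split_manifest,
)
from .table import FeatureTable, write_feature_csv

__all__ = ["PipelineConfig", "run_pipeline", "compare_selection", "stage_seed"]

logger = logging.getLogger(__name__)

STAGE_INDEX = {"split": 0, "autoencoder": 1, "selection": 2, "classifier": 3}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    seq = np.random.SeedSequence([master_seed, STAGE_INDEX[stage]])
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything needed to rerun an experiment from scratch.

    ``extractor`` is ``autoencoder``, ``raw_pixels``, or
    ``cnn_adapter:<registered name>``.  ``ae`` holds AEConfig overrides
    (``hidden_dim``, ``epochs``, ...) — the input dimension is inferred from
    the prep target at run time.  Stage seeds inside ``aco``/``classifier``
    are overridden by seeds derived from ``seed``.
    """

    prep: PrepConfig = field(default_factory=PrepConfig)
    extractor: str = "autoencoder"
    ae: dict = field(default_factory=dict)
    aco: ACOConfig = field(default_factory=ACOConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    output_dir: str | None = None
    input_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extractor not in ("autoencoder", "raw_pixels") and not self.extractor.startswith(
            "cnn_adapter:"
        ):
            raise ValueError(f"unknown extractor: {self.extractor!r}")

    def extracted_dim(self) -> int:
        """Feature count the selector will see; resolvable before any work."""
        h, w = TARGET_SHAPES[self.prep.target]
        if self.extractor == "autoencoder":
            return int(self.ae.get("hidden_dim", 256))
        if self.extractor == "raw_pixels":
            channels = 1 if self.prep.target == "ae_gray_64" else 3
            return h * w * channels
        name = self.extractor.split(":", 1)[1]
        if name not in KNOWN_BACKBONE_DIMS:
            raise ValueError(f"unknown backbone {name!r} in extractor")
        return KNOWN_BACKBONE_DIMS[name]

    def validate(self) -> None:
        """Pre-flight checks that need no data loading."""
        self.aco.resolve_subset_size(self.extracted_dim())

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "prep" in payload:
            payload["prep"] = PrepConfig(**payload["prep"])
        if "aco" in payload:
            payload["aco"] = ACOConfig(**payload["aco"])
        if "classifier" in payload:
            payload["classifier"] = ClassifierSpec(**payload["classifier"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def as_dict(self) -> dict:
        return {
            "prep": dict(self.prep.__dict__),
            "extractor": self.extractor,
            "ae": dict(self.ae),
            "aco": self.aco.as_dict(),
            "classifier": self.classifier.describe(),
            "output_dir": self.output_dir,
            "input_dir": self.input_dir,
            "seed": self.seed,
        }


def _derived_seeds(master: int) -> dict[str, int]:
    return {stage: stage_seed(master, stage) for stage in STAGE_INDEX}


def _replace_seed(cfg: ACOConfig, seed: int) -> ACOConfig:
    payload = {k: v for k, v in cfg.__dict__.items()}
    payload["seed"] = seed
    return ACOConfig(**payload)


def _extract_tables(
    config: PipelineConfig,
    train_recs: Sequence[ImageRecord],
    test_recs: Sequence[ImageRecord],
    classes: list[str],
    seeds: dict[str, int],
    artifacts: dict,
    out: Path | None,
) -> tuple[FeatureTable, FeatureTable]:
    if config.extractor.startswith("cnn_adapter:"):
        name = config.extractor.split(":", 1)[1]
        h, w = TARGET_SHAPES[config.prep.target]
        train_rs = [resize_image(r, h, w) for r in train_recs]
        test_rs = [resize_image(r, h, w) for r in test_recs]
        return cnn_feature_adapter(train_rs, name), cnn_feature_adapter(test_rs, name)

    train_px = records_to_table(train_recs, config.prep, classes=classes)
    test_px = records_to_table(test_recs, config.prep, classes=classes)
    if config.extractor == "raw_pixels":
        return train_px, test_px

    ae_cfg = AEConfig(
        input_dim=train_px.n_features,
        hidden_dim=int(config.ae.get("hidden_dim", 256)),
        transfer_encoder=config.ae.get("transfer_encoder", "logistic"),
        transfer_decoder=config.ae.get("transfer_decoder", "logistic"),
        epochs=int(config.ae.get("epochs", 200)),
        learning_rate=float(config.ae.get("learning_rate", 0.1)),
        seed=seeds["autoencoder"],
    )
    params, costs = train(train_px.X, ae_cfg, return_costs=True)
    artifacts["ae_initial_cost"] = costs[0]
    artifacts["ae_final_cost"] = costs[-1]
    if out is not None:
        save_params(params, ae_cfg, out / "autoencoder.json")
    train_feats = extract_features(
        train_px.X, params, ae_cfg, y=train_px.y,
        sample_ids=train_px.sample_ids, class_names=train_px.class_names,
    )
    test_feats = extract_features(
        test_px.X, params, ae_cfg, y=test_px.y,
        sample_ids=test_px.sample_ids, class_names=test_px.class_names,
    )
    return train_feats, test_feats


def _prepare(
    config: PipelineConfig, records: Sequence[ImageRecord] | None
) -> tuple[FeatureTable, FeatureTable, dict[str, int], dict, Path | None]:
    """Shared front half: load, split, extract; returns train/test tables."""
    config.validate()
    if records is None:
        if config.input_dir is None:
            raise ValueError("no records supplied and no input_dir configured")
        records = load_image_dir(config.input_dir)
    seeds = _derived_seeds(config.seed)
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    artifacts: dict = {}
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    prep = PrepConfig(**{**config.prep.__dict__, "seed": seeds["split"]})
    train_recs, test_recs = stratified_split(records, prep)
    classes = sorted({r.label for r in records})
    timings["split"] = time.perf_counter() - t0
    if out is not None:
        write_split_manifest(train_recs, test_recs, out / "split_manifest.txt")

    t0 = time.perf_counter()
    train_feats, test_feats = _extract_tables(
        config, train_recs, test_recs, classes, seeds, artifacts, out
    )
    timings["extract"] = time.perf_counter() - t0
    if out is not None:
        write_feature_csv(train_feats, out / "features_train.csv")
        write_feature_csv(test_feats, out / "features_test.csv")
    artifacts["timings"] = timings
    return train_feats, test_feats, seeds, artifacts, out


def run_pipeline(
    config: PipelineConfig, records: Sequence[ImageRecord] | None = None
) -> dict:
    """Execute the full chain and return (and optionally persist) the report.

    Stages: stratified split -> feature extraction -> ACO selection on the
    training table -> final classifier fit/evaluate on the selected subset.
    The report echoes the config, derived stage seeds and library versions;
    identical master seeds give identical report content (timings aside).
    """
    train_feats, test_feats, seeds, artifacts, out = _prepare(config, records)
    timings = artifacts.pop("timings")

    t0 = time.perf_counter()
    aco_cfg = _replace_seed(config.aco, seeds["selection"])
    selection = run_aco(train_feats, aco_cfg)
    timings["select"] = time.perf_counter() - t0
    if out is not None:
        selection.to_json(out / "selection.json")

    t0 = time.perf_counter()
    clf = ClassifierSpec(
        family=config.classifier.family,
        hyperparameters=dict(config.classifier.hyperparameters),
        seed=seeds["classifier"],
    )
    report = evaluate(
        clf,
        train_feats.select_features(selection.best_subset),
        test_feats.select_features(selection.best_subset),
    )
    timings["classify"] = time.perf_counter() - t0
    if out is not None:
        report.to_json(out / "metrics.json")

    run_report = {
        "config": config.as_dict(),
        "seeds": seeds,
        "versions": {"antcad": _pkg_version, "numpy": np.__version__},
        "selected_features": [int(i) for i in selection.best_subset],
        "selection_score": selection.best_score,
        "metrics": report.as_dict(),
        "artifacts": artifacts,
        "timings": timings,
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(run_report, indent=2))
    return run_report


def _split_table_rows(
    table: FeatureTable, fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified row split of a feature table (nearest-train rounding)."""
    y = table.require_labels()
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in range(y.n_categories):
        members = np.nonzero(y.codes == c)[0]
        order = rng.permutation(members.size)
        n_train = int(np.floor(fraction * members.size + 0.5))
        train_idx.extend(members[order[:n_train]])
        test_idx.extend(members[order[n_train:]])
    return table.take_samples(train_idx), table.take_samples(test_idx)


def compare_selection(
    config: PipelineConfig,
    records: Sequence[ImageRecord] | None = None,
    table: FeatureTable | None = None,
) -> dict:
    """Three-row contrast: all features vs selected subset vs random subset.

    All rows share one train/test split and one classifier family, so the
    only varying factor is which feature columns the classifier sees.  A
    labeled feature table may be passed directly to skip image processing.
    """
    seeds = _derived_seeds(config.seed)
    if table is not None:
        train_feats, test_feats = _split_table_rows(
            table, config.prep.train_fraction, seeds["split"]
        )
        out = Path(config.output_dir) if config.output_dir else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
    else:
        train_feats, test_feats, seeds, _artifacts, out = _prepare(config, records)

    aco_cfg = _replace_seed(config.aco, seeds["selection"])
    k = aco_cfg.resolve_subset_size(train_feats.n_features)
    selection = run_aco(train_feats, aco_cfg)
    random_subset = random_subset_baseline(
        train_feats.n_features, k, np.random.default_rng(seeds["selection"])
    )
    clf = ClassifierSpec(
        family=config.classifier.family,
        hyperparameters=dict(config.classifier.hyperparameters),
        seed=seeds["classifier"],
    )

    rows = {}
    for name, subset in (
        ("all_features", list(range(train_feats.n_features))),
        ("aco_subset", selection.best_subset),
        ("random_subset", random_subset),
    ):
        report = evaluate(
            clf, train_feats.select_features(subset), test_feats.select_features(subset)
        )
        rows[name] = {"n_features": len(subset), **report.as_dict()}

    comparison = {
        "config": config.as_dict(),
        "seeds": seeds,
        "subset_size": k,
        "aco_subset": [int(i) for i in selection.best_subset],
        "random_subset": [int(i) for i in random_subset],
        "rows": rows,
    }
    if out is not None:
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
    return comparison
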