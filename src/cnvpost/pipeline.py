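"""Stage chaining: post-processing, training and filtering as library calls.

Each function here is one pipeline stage with file inputs/outputs; the
command-line layer (:mod:`cnvpost.cli`) is a thin wrapper around them.
Every run can write a machine-readable manifest (tool versions, config
hash, seed, per-stage counts) so that two runs with identical manifests
produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .aux_filters import AuxFilterConfig, depth_filter, gap_filter
from .caller_io import DIALECTS, read_caller_vcf_with_stats, write_bedpe, read_bedpe
from .merge import MergeConfig, merge_calls
from .model import ValidationError
from .reclassify import ClassificationConfig, reclassify
from .rf_filter import (
    LabeledCallSet,
    RFModel,
    default_grid,
    filter_by_score,
    load_model,
    save_model,
    score_calls,
    split_by_chromosome,
    train_rf,
)

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, command: str, config: dict, counts: dict, seed=None):
    manifest = {
        "tool": "cnvpost",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "config_hash": config_hash(config),
        "counts": counts,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest


def run_postprocess(
    vcf_inputs,
    out_bedpe,
    class_cfg: ClassificationConfig = ClassificationConfig(),
    merge_cfg: MergeConfig = MergeConfig(),
    manifest_path=None,
):
    """Read caller VCFs, reclassify per tool, merge across tools, write BEDPE.

    ``vcf_inputs`` is a list of (path, dialect-name-or-CallerDialect).
    Returns the merged call list; an empty input set yields an empty BEDPE
    with a warning, not an error.
    """
    adjacencies = []
    counts = {"inputs": len(list(vcf_inputs)), "read": 0, "unmatched_bnd": 0}
    for path, dialect in vcf_inputs:
        adjs, stats = read_caller_vcf_with_stats(path, dialect)
        adjacencies.extend(adjs)
        counts["read"] += stats.n_adjacencies
        counts["unmatched_bnd"] += stats.n_unmatched_bnd
    result = reclassify(adjacencies, class_cfg)
    counts["classified"] = len(result.calls)
    counts["excluded"] = result.excluded_by_reason()
    merged = merge_calls(result.calls, merge_cfg)
    counts["merged"] = len(merged)
    if not merged:
        logger.warning("no classifiable calls; writing empty BEDPE")
    write_bedpe(merged, out_bedpe)
    logger.info("post-processing counts: %s", counts)
    if manifest_path:
        write_manifest(
            manifest_path, "postprocess",
            {"classification": asdict(class_cfg), "merge": asdict(merge_cfg)},
            counts,
        )
    return merged


def read_labels(path) -> dict[str, int]:
    """Two-column (call name, 0/1 label) tab-separated table."""
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                name, label = line.split()
                labels[name] = int(label)
            except ValueError as exc:
                raise ValidationError(f"{path}: line {lineno}: bad label row") from exc
    return labels


def run_train(
    bedpe_path,
    labels_path,
    holdout,
    model_out,
    report_out=None,
    grid=None,
    folds: int = 10,
    seed: int = 0,
    manifest_path=None,
) -> RFModel:
    """Label merged calls, hold out chromosomes, grid-search-train, persist.

    The CV report (chosen grid point, per-fold accuracies) and a per-type
    held-out precision/recall table are written alongside the model.
    """
    calls = read_bedpe(bedpe_path)
    label_map = read_labels(labels_path)
    missing = [c.name for c in calls if c.name not in label_map]
    if missing:
        raise ValidationError(f"{len(missing)} calls lack labels, e.g. {missing[:3]}")
    labeled = LabeledCallSet(calls, np.array([label_map[c.name] for c in calls]))
    train, test = split_by_chromosome(labeled, holdout)
    model = train_rf(train, grid=grid, folds=folds, seed=seed)
    save_model(model, model_out)
    scored = score_calls(model, test.calls)
    heldout = _heldout_report(scored, test.labels)
    if report_out:
        with open(report_out, "w") as fh:
            json.dump(
                {
                    "chosen_hyperparameters": model.hyperparams,
                    "cv": model.cv_report.to_dict(orient="records"),
                    "holdout_chromosomes": sorted(holdout),
                    "heldout": heldout,
                },
                fh, indent=2, default=str,
            )
            fh.write("\n")
    if manifest_path:
        write_manifest(
            manifest_path, "train",
            {"holdout": sorted(holdout), "folds": folds,
             "grid": grid if grid is not None else default_grid()},
            {"train": len(train), "test": len(test)},
            seed=seed,
        )
    return model


def _heldout_report(scored, labels, cutoff: float = 0.5) -> dict:
    pred = np.array([c.score >= cutoff for c in scored], dtype=int)
    labels = np.asarray(labels)
    report = {"accuracy": float((pred == labels).mean()), "cutoff": cutoff,
              "per_type": {}}
    for cnv_type in sorted({c.cnv_type.value for c in scored}):
        mask = np.array([c.cnv_type.value == cnv_type for c in scored])
        tp = int(((pred == 1) & (labels == 1) & mask).sum())
        fp = int(((pred == 1) & (labels == 0) & mask).sum())
        fn = int(((pred == 0) & (labels == 1) & mask).sum())
        report["per_type"][cnv_type] = {
            "tp": tp, "fp": fp, "fn": fn,
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
        }
    return report


def run_filter(
    bedpe_path,
    model_path,
    out_bedpe,
    cutoff: float = 0.5,
    aux_cfg: AuxFilterConfig = AuxFilterConfig(),
    depth_track=None,
    genome=None,
    manifest_path=None,
):
    """Score a merged BEDPE with a trained model, apply the cutoff and the
    (default-off) auxiliary depth/gap filters, write the final BEDPE."""
    calls = read_bedpe(bedpe_path)
    model = load_model(model_path)
    scored = score_calls(model, calls)
    retained = filter_by_score(scored, cutoff)
    counts = {"input": len(calls), "after_score_cutoff": len(retained)}
    if aux_cfg.enabled:
        retained = depth_filter(retained, depth_track, aux_cfg)
        counts["after_depth_filter"] = len(retained)
        retained = gap_filter(retained, genome, aux_cfg)
        counts["after_gap_filter"] = len(retained)
    write_bedpe(retained, out_bedpe)
    logger.info("filter counts: %s", counts)
    if manifest_path:
        write_manifest(
            manifest_path, "filter",
            {"cutoff": cutoff, "aux": asdict(aux_cfg)}, counts,
        )
    return retained
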