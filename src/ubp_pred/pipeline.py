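"""The end-to-end training workflow: featurize -> select -> tune -> train -> test.

One :class:`RunConfig` drives the whole run.  All randomness flows from a
single root seed, expanded deterministically into per-stage seeds, so a
rerun with the same config reproduces every artifact bit for bit.  Each
stage writes its artifact into the run directory as it completes, and a
provenance manifest (effective config, derived seeds, library versions,
stage outputs) is written at the end; on failure, the stage name is
reported and partial outputs are preserved.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from ubp_pred import __version__
from ubp_pred.classifier import HyperParams, TrainedModel, default_params, train
from ubp_pred.evaluation import MetricSet, independent_test
from ubp_pred.features import FeatureMatrix, build_feature_matrix
from ubp_pred.io_formats import apply_dataset_filters, read_fasta, read_labels, read_pssm
from ubp_pred.selection import (
    IfsTrace,
    drop_zero_importance,
    incremental_feature_selection,
    make_cv_evaluator,
    rank_features,
)
from ubp_pred.tuning import mopso_tune

STAGES = ("featurize", "split", "rank", "ifs", "tune", "train", "test")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the production setup:
    5 folds, swarm 80, 200 iterations, minimum length 50."""

    fasta: str
    pssm_dir: str
    labels: str
    out_dir: str
    seed: int = 0
    min_len: int = 50
    include_pssm: bool = True
    pssm_block: str = "log_odds"
    pssm_normalize: str = "none"
    test_fraction: float = 0.3
    folds: int = 5
    repeats: int = 1
    rf_trees: int = 500
    ifs_max_size: int | None = None
    ifs_step: int = 1
    tune: bool = True
    swarm_size: int = 80
    max_iter: int = 200
    objectives: tuple[str, ...] = ("sen", "spe")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence([self.seed, idx])
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    """Objects and artifact paths produced by one run."""

    config: RunConfig
    matrix: FeatureMatrix
    trace: IfsTrace
    best_features: list[str]
    params: HyperParams
    model: TrainedModel
    test_metrics: MetricSet
    artifacts: dict[str, str] = field(default_factory=dict)


def _log(msg: str) -> None:
    print(f"[ubp-pred] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full workflow and return its result object.

    Stages: featurize the filtered dataset; stratified train/test split;
    random-forest importance ranking with zero-importance features dropped;
    incremental feature selection by cross-validated MCC; optional MOPSO
    hyperparameter tuning on the selected subset; final training; and the
    independent test on the held-out split.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- featurize ----------------------------------------------------------
    stage = "featurize"
    try:
        records = read_fasta(config.fasta)
        kept, rejected = apply_dataset_filters(records, min_len=config.min_len)
        if rejected:
            _log(f"filtered out {len(rejected)} sequences "
                 f"({sorted(set(r for _, r in rejected))})")
        labels = read_labels(config.labels)
        pssms = None
        if config.include_pssm:
            pssms = {
                rec.id: read_pssm(
                    Path(config.pssm_dir) / f"{rec.id}.pssm",
                    protein_id=rec.id,
                    block=config.pssm_block,
                )
                for rec in kept
            }
        matrix = build_feature_matrix(
            kept,
            pssms,
            labels,
            include_pssm=config.include_pssm,
            pssm_normalize=config.pssm_normalize,
        )
        matrix.to_tsv(out / "matrix.tsv")
        artifacts["matrix"] = str(out / "matrix.tsv")
        _log(f"featurized {matrix.n} proteins x {matrix.d} features")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- split --------------------------------------------------------------
    stage = "split"
    try:
        idx = np.arange(matrix.n)
        train_idx, test_idx = train_test_split(
            idx,
            test_size=config.test_fraction,
            stratify=matrix.labels,
            random_state=config.stage_seed(stage),
        )
        train_matrix = matrix.select_rows(np.sort(train_idx))
        test_matrix = matrix.select_rows(np.sort(test_idx))
        (out / "split.json").write_text(
            json.dumps({"train": train_matrix.ids, "test": test_matrix.ids})
        )
        artifacts["split"] = str(out / "split.json")
        _log(f"split {train_matrix.n} train / {test_matrix.n} test")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- rank ---------------------------------------------------------------
    stage = "rank"
    try:
        ranked = rank_features(
            train_matrix, seed=config.stage_seed(stage), n_trees=config.rf_trees
        )
        nonzero = drop_zero_importance(ranked)
        with open(out / "ranking.tsv", "w") as fh:
            fh.write("feature\timportance\n")
            for name, imp in ranked.ranking:
                fh.write(f"{name}\t{imp:.8g}\n")
        artifacts["ranking"] = str(out / "ranking.tsv")
        _log(f"ranked {len(ranked)} features, {nonzero.n_nonzero} with importance > 0")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- ifs ----------------------------------------------------------------
    stage = "ifs"
    try:
        evaluator = make_cv_evaluator(
            params=default_params(),
            k=config.folds,
            repeats=config.repeats,
            seed=config.stage_seed(stage),
        )
        trace = incremental_feature_selection(
            train_matrix,
            nonzero,
            evaluator,
            max_size=config.ifs_max_size,
            step=config.ifs_step,
        )
        with open(out / "ifs_trace.tsv", "w") as fh:
            fh.write("subset_size\tmcc\n")
            for k, mcc in trace.steps:
                fh.write(f"{k}\t{mcc:.6f}\n")
        (out / "best_features.txt").write_text("\n".join(trace.best_subset) + "\n")
        artifacts["ifs_trace"] = str(out / "ifs_trace.tsv")
        artifacts["best_features"] = str(out / "best_features.txt")
        _log(f"IFS chose {trace.best_size} features "
             f"(cv MCC {dict(trace.steps)[trace.best_size]:.3f})")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    train_selected = train_matrix.select_features(trace.best_subset)
    test_selected = test_matrix.select_features(trace.best_subset)

    # -- tune ---------------------------------------------------------------
    stage = "tune"
    try:
        if config.tune:
            tune_seed = config.stage_seed(stage)

            def tune_evaluator(params: HyperParams) -> MetricSet:
                return make_cv_evaluator(
                    params=params, k=config.folds, seed=tune_seed
                )(train_selected)

            best_params, archive, history = mopso_tune(
                tune_evaluator,
                swarm_size=config.swarm_size,
                max_iter=config.max_iter,
                seed=tune_seed,
                objectives=tuple(config.objectives),
            )
            with open(out / "archive.tsv", "w") as fh:
                fh.write("\t".join(config.objectives) + "\tmcc\n")
                for entry in archive.entries:
                    objs = "\t".join(f"{v:.6f}" for v in entry.objectives)
                    fh.write(f"{objs}\t{entry.metrics.mcc:.6f}\n")
            artifacts["archive"] = str(out / "archive.tsv")
            _log(f"MOPSO archive size {len(archive)}; best cv MCC "
                 f"{archive.best_by('mcc').metrics.mcc:.3f}")
        else:
            best_params = default_params()
            _log("tuning disabled; using default hyperparameters")
        (out / "best_params.json").write_text(json.dumps(best_params.as_dict(), indent=2))
        artifacts["best_params"] = str(out / "best_params.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- train --------------------------------------------------------------
    stage = "train"
    try:
        model = train(
            train_selected, params=best_params, seed=config.stage_seed(stage), nthread=1
        )
        model.save(out / "model.json")
        artifacts["model"] = str(out / "model.json")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- test ---------------------------------------------------------------
    stage = "test"
    try:
        metrics = independent_test(model, test_selected, train_ids=set(train_selected.ids))
        with open(out / "metrics.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            for name, value in metrics.as_dict().items():
                fh.write(f"{name}\t{value:.6f}\n")
        artifacts["metrics"] = str(out / "metrics.tsv")
        _log(f"independent test MCC {metrics.mcc:.3f}")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "config": {**asdict(config), "objectives": list(config.objectives)},
        "stage_seeds": {s: RunConfig.stage_seed(config, s) for s in STAGES},
        "artifacts": artifacts,
        "n_train": train_selected.n,
        "n_test": test_selected.n,
        "n_features_selected": len(trace.best_subset),
        "test_metrics": metrics.as_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(out / "manifest.json")

    return PipelineResult(
        config=config,
        matrix=matrix,
        trace=trace,
        best_features=trace.best_subset,
        params=best_params,
        model=model,
        test_metrics=metrics,
        artifacts=artifacts,
    )
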