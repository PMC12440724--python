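"""Strategy-grid orchestration, delta tables and reader comparison.

``run_grid`` evaluates every enumerated (color, ROI shape, fusion, margin)
model on a train/test cohort pair: per strategy it fine-tunes a backbone on
the training crops, extracts first-pooling-layer deep features, runs the
selection chain and records train/test metrics. With the default margin
schedule (2, 4, 6, 8, 10 mm) the result table has 4 intratumoral + 6 x 5
fusion = 34 model rows per cohort.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import BackboneConfig, extract_features_batch, fine_tune_backbone
from .crops import DEFAULT_MARGINS_MM, StrategyConfig, build_crops, enumerate_strategies
from .errors import ParameterError, PerifuseError
from .metrics import compare_auc_paired, evaluate_at_threshold
from .selection import ChainParams, FeatureMatrix, fit_and_evaluate, run_selection_chain
from .synthetic import SyntheticCase

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("auc", "accuracy", "sensitivity", "specificity")


@dataclass
class GridConfig:
    """Everything the grid needs beyond the cohorts and the margins."""

    architecture_id: str = "vgg16-tiny"
    epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 16
    chain: ChainParams = field(default_factory=ChainParams)
    cv_folds: int = 5
    n_boot: int = 200
    share_backbone: bool = False


@dataclass
class GridResult:
    """Result table plus provenance and per-model test scores."""

    table: pd.DataFrame
    provenance: dict
    test_scores: dict[str, np.ndarray]
    test_labels: np.ndarray
    selection_reports: dict[str, object] = field(default_factory=dict)


def _strategy_seed(master_seed: int, name: str) -> int:
    """Stable per-strategy seed, independent of enumeration order."""
    return (master_seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


def _crops_for_cohort(cases: list[SyntheticCase], strategy: StrategyConfig):
    """Crops + per-crop labels + per-case crop index lists, abort on failure."""
    crops, labels, case_slices = [], [], []
    for case in cases:
        try:
            case_crops = build_crops(case, strategy)
        except PerifuseError as exc:
            raise ParameterError(
                f"crop construction failed for case {case.case_id!r} "
                f"under {strategy.name}: {exc}"
            ) from exc
        start = len(crops)
        crops.extend(case_crops)
        labels.extend([case.label] * len(case_crops))
        case_slices.append(list(range(start, start + len(case_crops))))
    return crops, np.asarray(labels), case_slices


def _feature_matrix(feats, crops, cases, case_slices) -> FeatureMatrix:
    """Assemble one row per case; FLF concatenates intra|peri blocks."""
    region_order = list(dict.fromkeys(c.region_tag for c in crops))
    rows, names, tags = [], None, None
    for case, idx in zip(cases, case_slices):
        by_tag = {crops[i].region_tag: feats[i] for i in idx}
        blocks = [by_tag[tag] for tag in region_order]
        rows.append(np.concatenate(blocks))
        if names is None:
            names, tags = [], []
            for tag, block in zip(region_order, blocks):
                names.extend(f"{tag}_feat_{j:06d}" for j in range(len(block)))
                tags.extend([tag] * len(block))
    return FeatureMatrix(
        values=np.vstack(rows),
        case_ids=[c.case_id for c in cases],
        labels=np.array([c.label for c in cases]),
        feature_names=names,
        region_tags=tags,
    )


def run_grid(
    train_cohort: list[SyntheticCase],
    test_cohort: list[SyntheticCase],
    margins_mm=DEFAULT_MARGINS_MM,
    config: GridConfig | None = None,
    master_seed: int = 0,
) -> GridResult:
    """Evaluate the full strategy grid on a train/test cohort pair.

    Per strategy, one backbone is fine-tuned on that strategy's training
    crops (``config.share_backbone`` reuses the first one instead), features
    are extracted for both cohorts in the same forward pass style, and the
    selection chain plus classifier produce train/test metric rows. A case
    whose crops cannot be built aborts the grid with its case id — no silent
    drops. Deterministic given ``master_seed``.
    """
    config = config or GridConfig()
    train_ids = {c.case_id for c in train_cohort}
    overlap = train_ids & {c.case_id for c in test_cohort}
    if overlap:
        raise ParameterError(f"cohorts are not disjoint: {sorted(overlap)[:5]}")

    strategies = enumerate_strategies(margins_mm)
    rows = []
    test_scores: dict[str, np.ndarray] = {}
    reports = {}
    shared_backbone = None
    for strategy in strategies:
        t0 = time.perf_counter()
        seed = _strategy_seed(master_seed, strategy.name)
        backbone_config = BackboneConfig(
            architecture_id=config.architecture_id,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
        )
        tr_crops, tr_labels, tr_slices = _crops_for_cohort(train_cohort, strategy)
        te_crops, _, te_slices = _crops_for_cohort(test_cohort, strategy)

        if config.share_backbone and shared_backbone is not None:
            state = shared_backbone
            tr_feats, _ = extract_features_batch(state, tr_crops)
        else:
            # One forward pass serves both the head's GAP features and the
            # block1 deep features.
            state = fine_tune_backbone(tr_crops, tr_labels, backbone_config, seed)
            tr_feats, _ = extract_features_batch(state, tr_crops)
            if config.share_backbone:
                shared_backbone = state
        te_feats, _ = extract_features_batch(state, te_crops)

        train_fm = _feature_matrix(tr_feats, tr_crops, train_cohort, tr_slices)
        test_fm = _feature_matrix(te_feats, te_crops, test_cohort, te_slices)
        tr_sel, te_sel, report = run_selection_chain(train_fm, test_fm, config.chain, seed)
        train_rep, test_rep, model = fit_and_evaluate(
            tr_sel, te_sel, cv_folds=config.cv_folds, n_boot=config.n_boot, seed=seed
        )
        reports[strategy.name] = report
        test_scores[strategy.name] = model.scores(te_sel)
        for cohort, rep in (("training", train_rep), ("testing", test_rep)):
            row = {"model": strategy.name, "cohort": cohort}
            row.update(rep.as_row())
            row["n_features_selected"] = report.n_after_lasso
            rows.append(row)
        logger.info(
            "%-28s %6.2fs  train AUC %.3f  test AUC %.3f",
            strategy.name, time.perf_counter() - t0, train_rep.auc, test_rep.auc,
        )

    table = pd.DataFrame(rows)
    provenance = {
        "master_seed": master_seed,
        "margins_mm": [float(m) for m in margins_mm],
        "n_train": len(train_cohort),
        "n_test": len(test_cohort),
        "architecture_id": config.architecture_id,
        "epochs": config.epochs,
        "share_backbone": config.share_backbone,
        "n_models": len(strategies),
        "config_hash": zlib.crc32(json.dumps(
            {k: v for k, v in asdict(config).items()}, sort_keys=True, default=str
        ).encode()),
    }
    return GridResult(
        table=table,
        provenance=provenance,
        test_scores=test_scores,
        test_labels=np.array([c.label for c in test_cohort]),
        selection_reports=reports,
    )


def delta_table(results: pd.DataFrame, reference_model_name: str) -> pd.DataFrame:
    """Testing-cohort metric deltas versus a reference model.

    The reference row is all zeros; every other row is metric minus the
    reference metric.
    """
    testing = results[results["cohort"] == "testing"].set_index("model")
    if reference_model_name not in testing.index:
        raise ParameterError(
            f"unknown reference model {reference_model_name!r}; "
            f"available: {list(testing.index)}"
        )
    ref = testing.loc[reference_model_name]
    out = pd.DataFrame(index=testing.index)
    for metric in METRIC_COLUMNS:
        out[f"delta_{metric}"] = testing[metric] - ref[metric]
    return out.reset_index()


def reader_comparison(
    labels,
    model_scores,
    model_name: str,
    readers: dict[str, np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-versus-reader table: AUC with 95% CI plus paired DeLong p.

    Reader scores may be binary calls or ordinal confidence ratings on the
    same test cases as the model scores.
    """
    labels = np.asarray(labels, dtype=int)
    rows = []
    for name, scores in [(model_name, np.asarray(model_scores, float))] + [
        (rname, np.asarray(rs, float)) for rname, rs in readers.items()
    ]:
        thr = 0.5 if set(np.unique(scores)) <= {0.0, 1.0} else float(np.median(scores))
        rep = evaluate_at_threshold(labels, scores, thr, n_boot=n_boot, seed=seed)
        # delta < 0 means this reader underperforms the model
        delta, p = compare_auc_paired(scores, np.asarray(model_scores, float), labels)
        rows.append(
            {
                "reader": name,
                "cohort": "testing",
                "auc_ci": rep.format_auc(),
                "auc": rep.auc,
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "delta_auc_vs_model": delta,
                "delong_p_vs_model": p,
            }
        )
    return pd.DataFrame(rows)


def save_results(result: GridResult, out_dir: str | Path) -> Path:
    """Write results.csv plus a JSON provenance block; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    result.table.to_csv(csv_path, index=False)
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    return csv_path
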