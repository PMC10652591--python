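"""End-to-end orchestration: preprocess -> screen -> integrate -> classify ->
evaluate, with a run manifest and the four ablation run modes.

Modes
-----
``paired``             the full screening chain (z-score, Cox, promoter pairs)
``random_pairs``       randomly drawn unmapped gene/CpG blocks of matched size
``preprocessed_full``  all preprocessed features, no screening
``mono_expression``    expression-only autoencoder input
``mono_methylation``   methylation-only autoencoder input

Feature screening runs on the full cohort (the screening statistics are
unsupervised with respect to subtype prediction on held-out folds);
the autoencoder is trained on the 70% training partition only, and
classifier cross-validation is performed on the training partition's latent
features.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import autoencoder as ae_mod
from . import classify as clf_mod
from . import preprocess as pre_mod
from . import screen as screen_mod
from .io import ClinicalTable, OmicsMatrix, ProbeAnnotation
from .metrics import MetricsSummary, summarize_folds
from .screen import CpgGenePairSet
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

MODES = ("paired", "random_pairs", "preprocessed_full", "mono_expression", "mono_methylation")


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "paired"
    seed: int = 0
    split_fraction: float = 0.7
    low_expr_threshold: float = 0.1
    low_expr_sample_frac: float = 0.9
    z_threshold: float = 1.0
    cox_alpha: float = 0.05
    pre_cox_pairing: bool = False
    bottleneck_dim: int = 64
    ae_hidden_dim: int | None = None
    ae_activation: str = "relu"
    ae_epochs: int = 1500
    ae_batch_size: int = 16
    ae_optimizer: str = "adam"
    ae_learning_rate: float = 1e-3
    # ANN: the relu/adam preset; CNN: the elu preset — with a single filter a
    # relu conv chain loses signal through dead units at this scale
    ann: clf_mod.ANNConfig = field(default_factory=clf_mod.ann_lgg_preset)
    cnn: clf_mod.CNNConfig = field(default_factory=clf_mod.cnn_gbm_preset)
    classifiers: tuple = ("ann", "cnn")
    cv_folds: int = 10
    random_n_genes: int | None = None  # matched to paired counts when None
    random_n_cpgs: int | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown run mode: {self.mode!r}")


def _sha(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def _select_features(config, expr, meth, clinical, annotation):
    """Mode-dependent choice of the two autoencoder feature blocks."""
    mode = config.mode
    if mode == "paired":
        stage = {}
        ztab_e = screen_mod.compute_zscores(expr, clinical.subtype_of)
        _, degs = screen_mod.select_differential(ztab_e, config.z_threshold)
        ztab_m = screen_mod.compute_zscores(meth, clinical.subtype_of)
        _, dmrs = screen_mod.select_differential(ztab_m, config.z_threshold)
        if config.pre_cox_pairing:
            pre_pairs = screen_mod.map_promoter_pairs(degs, dmrs, annotation)
            degs = set(pre_pairs.gene_ids)
            dmrs = set(pre_pairs.cpg_ids)
        surv_genes, cox_genes = screen_mod.screen_survival(
            expr, clinical, degs, alpha=config.cox_alpha
        )
        surv_cpgs, cox_cpgs = screen_mod.screen_survival(
            meth, clinical, dmrs, alpha=config.cox_alpha
        )
        pairs = screen_mod.map_promoter_pairs(surv_genes, surv_cpgs, annotation)
        stage.update(
            z_table_expr=ztab_e, z_table_meth=ztab_m,
            degs=degs, dmrs=dmrs,
            cox_table_expr=cox_genes, cox_table_meth=cox_cpgs,
            surv_genes=surv_genes, surv_cpgs=surv_cpgs, pairs=pairs,
        )
        return pairs.gene_ids, pairs.cpg_ids, stage
    if mode == "random_pairs":
        n_genes = config.random_n_genes or min(60, len(expr.feature_ids))
        n_cpgs = config.random_n_cpgs or min(60, len(meth.feature_ids))
        # derived stream: the draw must not replay another stage's rng
        draw_seed = int(np.random.SeedSequence([config.seed, 815]).generate_state(1)[0] % (2**31))
        pairs = screen_mod.sample_random_pairs(expr, meth, n_genes, n_cpgs, seed=draw_seed)
        return pairs.gene_ids, pairs.cpg_ids, {"pairs": pairs}
    if mode == "preprocessed_full":
        return expr.feature_ids, meth.feature_ids, {}
    if mode == "mono_expression":
        return expr.feature_ids, [], {}
    if mode == "mono_methylation":
        return [], meth.feature_ids, {}
    raise ValueError(config.mode)


def run_pipeline(
    config: PipelineConfig,
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    clinical: ClinicalTable,
    annotation: ProbeAnnotation,
) -> dict:
    """Execute the staged pipeline; returns the run manifest.

    The manifest records per-stage shapes and checksums, the seeds in force,
    and the final cross-validated :class:`MetricsSummary` per classifier
    (under ``"summaries"``).
    """
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": {}}

    # --- preprocess
    expr = pre_mod.filter_low_expressed(
        expr, config.low_expr_threshold, config.low_expr_sample_frac
    )
    expr, meth, clinical = pre_mod.intersect_paired_samples(expr, meth, clinical)
    split = pre_mod.stratified_split(clinical, config.split_fraction, config.seed)
    manifest["stages"]["preprocess"] = {
        "n_genes": expr.shape[0],
        "n_cpgs": meth.shape[0],
        "n_samples": expr.shape[1],
        "n_train": len(split.train_ids),
        "expr_checksum": _sha(expr.values),
        "meth_checksum": _sha(meth.values),
    }
    logger.info("preprocess: %s", manifest["stages"]["preprocess"])

    # --- screen / feature choice
    gene_block, cpg_block, stage = _select_features(config, expr, meth, clinical, annotation)
    manifest["stages"]["screen"] = {
        "n_gene_features": len(gene_block),
        "n_cpg_features": len(cpg_block),
    }
    if "pairs" in stage:
        manifest["stages"]["screen"]["n_pairs"] = len(stage["pairs"])
        manifest["stages"]["screen"]["pair_checksum"] = _sha(stage["pairs"].records)
    logger.info("screen: %s", manifest["stages"]["screen"])

    # --- integrate (autoencoder)
    train_ids = [s for s in expr.sample_ids if s in set(split.train_ids)]
    expr_all = expr.values.loc[gene_block].to_numpy(dtype=float).T if gene_block else np.zeros((expr.shape[1], 0))
    meth_all = meth.values.loc[cpg_block].to_numpy(dtype=float).T if cpg_block else np.zeros((meth.shape[1], 0))
    sample_order = expr.sample_ids
    train_mask = np.array([s in set(split.train_ids) for s in sample_order])
    # clamp the autoencoder widths to the selected feature count so small
    # cohorts (few surviving pairs) still yield a valid compression stack
    concat = len(gene_block) + len(cpg_block)
    hidden = config.ae_hidden_dim if config.ae_hidden_dim is not None else max(
        2, round(0.5 * concat)
    )
    hidden = max(2, min(hidden, concat))
    bottleneck = max(1, min(config.bottleneck_dim, hidden - 1, concat // 2))
    if (bottleneck, hidden) != (config.bottleneck_dim, config.ae_hidden_dim or hidden):
        logger.warning(
            "autoencoder widths clamped to hidden=%d bottleneck=%d (%d inputs)",
            hidden, bottleneck, concat,
        )
    ae_config = ae_mod.AEConfig(
        expr_dim=len(gene_block),
        meth_dim=len(cpg_block),
        bottleneck_dim=bottleneck,
        hidden_dim=hidden,
        activation=config.ae_activation,
        epochs=config.ae_epochs,
        batch_size=config.ae_batch_size,
        optimizer=config.ae_optimizer,
        learning_rate=config.ae_learning_rate,
        seed=config.seed,
    )
    ae = ae_mod.build_cnc_autoencoder(ae_config)
    history = ae_mod.train_autoencoder(
        ae,
        expr_all[train_mask],
        meth_all[train_mask],
        holdout=(expr_all[~train_mask], meth_all[~train_mask]) if (~train_mask).any() else None,
    )
    latent = ae_mod.encode(ae, expr_all, meth_all, sample_ids=sample_order)
    manifest["stages"]["integrate"] = {
        "concat_width": ae.concat_width,
        "bottleneck_dim": ae_config.bottleneck_dim,
        "final_train_mse": history.attrs["final_train_mse"],
        "final_holdout_mse": history.attrs.get("final_holdout_mse"),
        "latent_checksum": hashlib.sha256(latent.values.tobytes()).hexdigest()[:16],
    }
    logger.info("integrate: %s", manifest["stages"]["integrate"])

    # --- classify + evaluate (CV on training partition latents)
    labels_all = clinical.subtype_of.loc[sample_order].to_numpy()
    latent_train = latent.values[train_mask]
    labels_train = labels_all[train_mask]
    summaries: dict[str, MetricsSummary] = {}
    builders = {"ann": (clf_mod.build_ann, config.ann), "cnn": (clf_mod.build_cnn, config.cnn)}
    for name in config.classifiers:
        builder, clf_config = builders[name]
        results = clf_mod.stratified_cv_evaluate(
            builder, clf_config, latent_train, labels_train,
            k=config.cv_folds, seed=config.seed,
        )
        summaries[name] = summarize_folds([r.metrics for r in results])
        manifest["stages"][f"classify_{name}"] = {
            "k": len(results),
            "mean_accuracy": float(summaries[name].mean["accuracy"]),
            "mean_mcc": float(summaries[name].mean["mcc"]),
        }
        logger.info("classify %s: %s", name, manifest["stages"][f"classify_{name}"])

    manifest["summaries"] = summaries
    manifest["latent"] = latent
    manifest["split"] = split
    manifest["history"] = history
    if "pairs" in stage:
        manifest["pairs"] = stage["pairs"]
    manifest["screen_detail"] = {
        k: v for k, v in stage.items() if k not in ("pairs",)
    }
    return manifest


def run_on_simulated(config: PipelineConfig, sim: SimConfig):
    """Convenience wrapper: simulate a cohort, run the pipeline on it.

    Returns ``(manifest, truth)``.
    """
    expr, meth, clinical, annotation, truth = generate_dataset(sim)
    manifest = run_pipeline(config, expr, meth, clinical, annotation)
    return manifest, truth


def compare_modes(manifests_by_mode: dict[str, list[dict]], classifier: str = "cnn"):
    """Per-mode accuracy distributions with pairwise Mann-Whitney tests.

    ``manifests_by_mode`` maps a mode name to the manifests of repeated runs.
    Modes with a single run are described but not tested. Returns
    ``(table, pairwise)`` where pairwise is a DataFrame of two-sided
    Mann-Whitney p-values on the per-run mean accuracies.
    """
    acc: dict[str, list[float]] = {}
    for mode, manifests in manifests_by_mode.items():
        acc[mode] = [
            float(m["summaries"][classifier].mean["accuracy"]) for m in manifests
        ]
    table = pd.DataFrame(
        {
            "mode": list(acc),
            "n_runs": [len(v) for v in acc.values()],
            "mean_accuracy": [float(np.mean(v)) for v in acc.values()],
            "min_accuracy": [float(np.min(v)) for v in acc.values()],
            "max_accuracy": [float(np.max(v)) for v in acc.values()],
        }
    )
    modes = list(acc)
    pairwise = pd.DataFrame(index=modes, columns=modes, dtype=float)
    for i, a in enumerate(modes):
        for b in modes[i + 1:]:
            if len(acc[a]) < 2 or len(acc[b]) < 2:
                continue
            res = stats.mannwhitneyu(acc[a], acc[b], alternative="two-sided")
            pairwise.loc[a, b] = pairwise.loc[b, a] = float(res.pvalue)
    return table, pairwise


def manifest_checksums(manifest: dict) -> dict:
    """The deterministic-stage checksums of a manifest (for rerun equality)."""
    out = {}
    for stage, info in manifest["stages"].items():
        for key, val in info.items():
            if key.endswith("checksum"):
                out[f"{stage}.{key}"] = val
    return out


def manifest_to_json(manifest: dict) -> str:
    """Serializable view of a manifest (summaries flattened to means/CIs)."""
    view = {
        "mode": manifest["mode"],
        "seed": manifest["seed"],
        "stages": manifest["stages"],
        "metrics": {
            name: {
                "mean": s.mean.to_dict(),
                "ci_lo": s.ci_lo.to_dict(),
                "ci_hi": s.ci_hi.to_dict(),
            }
            for name, s in manifest["summaries"].items()
        },
    }
    return json.dumps(view, indent=2, default=float)
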