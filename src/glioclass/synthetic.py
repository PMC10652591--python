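"""Synthetic di-omics datasets with planted subtype and survival structure.

The generator emulates the statistical structure the pipeline is built to
exploit in glioma cohorts:

* a handful of *informative* genes carry subtype-specific mean shifts on the
  log2 expression scale (each informative gene gets a mixed up/down sign
  pattern across subtypes, so every subtype has a distinct signature);
* each informative gene is paired with one promoter CpG whose beta value is
  logit-normal with a logit-mean shift *opposite* in sign to the gene's
  expression shift — promoter hypermethylation suppresses expression;
* survival-linked genes additionally share a per-sample *prognostic program*
  component (a latent co-regulated axis, independent of subtype, also
  reflected with opposite sign in their promoter CpGs), and overall-survival
  times follow an exponential (constant-baseline-hazard Cox) model whose
  linear predictor is a standardized, signature-aligned combination of those
  genes, with independent censoring;
* everything else is uninformative noise, and non-planted CpGs receive
  gene-body / 3'UTR annotation records (plus a configurable fraction of decoy
  promoter records) so the promoter-pairing stage has genuine negatives.

Expression is simulated directly on the log2(RSEM+1) scale (truncated normal
at 0) rather than via counts: the pipeline only ever sees the log scale, and
the direct parameterization gives analytic control over subtype z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    OmicsMatrix,
    ProbeAnnotation,
    PROMOTER_REGIONS,
)

_PROMOTER_CLASSES = ("TSS1500", "TSS200", "FirstExon", "UTR5")
_DECOY_CLASSES = ("Body", "UTR3")


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated cohort.

    Defaults correspond to a desk-scale three-subtype cohort of 150 patients
    with 60 planted promoter pairs, a 2-SD expression effect, a 1.5
    logit-scale methylation effect, and a unit Cox log-hazard coefficient on
    the survival signature — the conditions under which the screening chain
    and the classifiers are exercised throughout the test-suite.
    """

    n_per_subtype: tuple = (50, 50, 50)
    n_genes: int = 500
    n_cpgs: int = 1500
    n_informative_pairs: int = 60
    expr_effect: float = 2.0  # subtype mean shift, in population-SD units
    meth_effect: float = 1.5  # logit-scale shift of planted CpG betas
    cox_coef: float = 1.0  # log-hazard coefficient b on the risk score
    n_survival_features: int | None = None  # None -> all informative genes
    prognostic_latent_sd: float = 1.25  # program loading on expression, SD units
    meth_program_sd: float | None = 1.05  # program loading on CpG logits; None -> same
    censor_rate: float = 0.2
    base_expr_mean: float = 6.0
    base_expr_sd: float = 1.0
    logit_sd: float = 0.8
    baseline_hazard: float = 1.0 / 500.0  # events per day; median OS ~ 1 year
    decoy_promoter_frac: float = 0.3  # non-planted CpGs given decoy promoter records
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_subtype) < 2:
            raise ValueError("need at least two subtypes")
        if any(n <= 0 for n in self.n_per_subtype):
            raise ValueError("all subtype sizes must be positive")
        if min(self.n_genes, self.n_cpgs) < self.n_informative_pairs:
            raise ValueError(
                "n_informative_pairs must not exceed min(n_genes, n_cpgs)"
            )
        if self.n_informative_pairs < 0 or self.n_genes <= 0 or self.n_cpgs <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        n_surv = self.n_survival_features
        if n_surv is not None and not (0 < n_surv <= self.n_informative_pairs):
            raise ValueError(
                "n_survival_features must be in (0, n_informative_pairs]"
            )


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    informative_gene_ids: set
    informative_cpg_ids: set
    survival_feature_ids: set
    pair_table: pd.DataFrame  # cpg_id, gene_id, region
    subtype_of: pd.Series
    n_genes: int
    n_cpgs: int


def _mixed_sign_patterns(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n sign patterns over k subtypes, each containing both +1 and -1."""
    patterns = np.empty((n, k), dtype=int)
    for i in range(n):
        while True:
            p = rng.choice([-1, 1], size=k)
            if p.min() < p.max():
                patterns[i] = p
                break
    return patterns


def generate_dataset(config: SimConfig):
    """Simulate one cohort.

    Returns ``(expression, methylation, clinical, annotation, truth)``;
    deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    k = len(config.n_per_subtype)
    subtype_labels = [f"subtype{i + 1}" for i in range(k)]
    sample_subtypes = np.repeat(subtype_labels, config.n_per_subtype)
    n = len(sample_subtypes)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    cpg_ids = np.array([f"cg{i:08d}" for i in range(config.n_cpgs)])
    subtype_index = np.repeat(np.arange(k), config.n_per_subtype)

    m = config.n_informative_pairs
    info_gene_idx = rng.choice(config.n_genes, size=m, replace=False)
    info_cpg_idx = rng.choice(config.n_cpgs, size=m, replace=False)
    patterns = _mixed_sign_patterns(rng, m, k)  # per informative gene

    n_surv = config.n_survival_features or m
    surv_rows = np.arange(n_surv)  # first n_surv informative pairs
    # latent prognostic program shared by the survival-linked features
    program = rng.normal(0.0, 1.0, size=n)

    # --- expression: base normal truncated at 0, planted subtype shifts;
    # survival-linked genes also load on the prognostic program
    expr = rng.normal(config.base_expr_mean, config.base_expr_sd, size=(config.n_genes, n))
    shift = config.expr_effect * config.base_expr_sd
    for row, gi in enumerate(info_gene_idx):
        expr[gi] += shift * patterns[row][subtype_index]
        if row < n_surv:
            expr[gi] += config.prognostic_latent_sd * config.base_expr_sd * program
    expr = np.clip(expr, 0.0, None)

    # --- methylation: logit-normal betas; planted CpGs shifted opposite in
    # sign to their gene's expression shifts (subtype pattern and program)
    logits = rng.normal(0.0, config.logit_sd, size=(config.n_cpgs, n))
    for row, ci in enumerate(info_cpg_idx):
        logits[ci] += -config.meth_effect * patterns[row][subtype_index]
        if row < n_surv:
            gm = (config.meth_program_sd if config.meth_program_sd is not None
                  else config.prognostic_latent_sd)
            logits[ci] += -gm * program
    meth = 1.0 / (1.0 + np.exp(-logits))

    # --- annotation: planted promoter pairs plus decoy records
    regions = rng.choice(_PROMOTER_CLASSES, size=m)
    records = [
        (cpg_ids[ci], gene_ids[gi], reg)
        for ci, gi, reg in zip(info_cpg_idx, info_gene_idx, regions)
    ]
    non_planted = np.setdiff1d(np.arange(config.n_cpgs), info_cpg_idx)
    body_targets = rng.integers(0, config.n_genes, size=len(non_planted))
    body_regions = rng.choice(_DECOY_CLASSES, size=len(non_planted))
    records += [
        (cpg_ids[ci], gene_ids[gi], reg)
        for ci, gi, reg in zip(non_planted, body_targets, body_regions)
    ]
    n_decoy = int(round(config.decoy_promoter_frac * len(non_planted)))
    if n_decoy:
        decoy_cpgs = rng.choice(non_planted, size=n_decoy, replace=False)
        decoy_genes = rng.integers(0, config.n_genes, size=n_decoy)
        decoy_regions = rng.choice(_PROMOTER_CLASSES, size=n_decoy)
        records += [
            (cpg_ids[ci], gene_ids[gi], reg)
            for ci, gi, reg in zip(decoy_cpgs, decoy_genes, decoy_regions)
        ]
    annotation = ProbeAnnotation(
        records=pd.DataFrame(records, columns=["cpg_id", "gene_id", "region"])
    )

    # --- survival: exponential times under a Cox hazard on the standardized
    # mean of the survival-linked genes' within-subtype-centered values.
    # Subtype centering isolates the shared prognostic-program axis, so every
    # survival feature (gene and paired CpG) keeps a uniform marginal link to
    # the hazard regardless of its subtype signature.
    surv_gene_idx = info_gene_idx[surv_rows]
    z = expr[surv_gene_idx].copy()
    for s in range(k):
        cols = subtype_index == s
        z[:, cols] -= z[:, cols].mean(axis=1, keepdims=True)
    z /= z.std(axis=1, keepdims=True)
    risk = z.mean(axis=0)
    risk = (risk - risk.mean()) / (risk.std() or 1.0)
    lam = config.baseline_hazard * np.exp(config.cox_coef * risk)
    times = rng.exponential(1.0 / lam)
    censored = rng.random(n) < config.censor_rate
    times = np.where(censored, times * rng.random(n), times)
    times = np.maximum(times, 1e-3)
    events = (~censored).astype(int)

    expression = OmicsMatrix(
        layer="expression",
        values=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
    )
    methylation = OmicsMatrix(
        layer="methylation",
        values=pd.DataFrame(meth, index=cpg_ids, columns=sample_ids),
    )
    clinical = ClinicalTable(
        table=pd.DataFrame(
            {
                "subtype": sample_subtypes,
                "os_time": times,
                "os_event": events,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        label_set=tuple(subtype_labels),
    )
    truth = GroundTruth(
        informative_gene_ids=set(gene_ids[info_gene_idx]),
        informative_cpg_ids=set(cpg_ids[info_cpg_idx]),
        survival_feature_ids=set(gene_ids[surv_gene_idx]),
        pair_table=pd.DataFrame(
            {
                "cpg_id": cpg_ids[info_cpg_idx],
                "gene_id": gene_ids[info_gene_idx],
                "region": regions,
            }
        ),
        subtype_of=clinical.subtype_of.copy(),
        n_genes=config.n_genes,
        n_cpgs=config.n_cpgs,
    )
    return expression, methylation, clinical, annotation, truth


def _stage_row(selected: set, truth_set: set, universe: int) -> dict:
    tp = len(selected & truth_set)
    fp = len(selected - truth_set)
    fn = len(truth_set - selected)
    tn = universe - tp - fp - fn
    sens = tp / len(truth_set) if truth_set else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) > 0 else 0.0
    prec = tp / len(selected) if selected else 0.0
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else 0.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": sens,
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "fpr": fpr,
        "precision": prec,
        "f1": f1,
    }


def planted_recovery_report(
    truth: GroundTruth,
    selected_genes: set,
    selected_cpgs: set,
    pairs=None,
) -> pd.DataFrame:
    """Per-stage recovery of the planted structure.

    Rows: gene screen, CpG screen and (when ``pairs`` is given) the promoter
    pair set, each scored against the ground truth with TP/FP/TN/FN counts,
    sensitivity, specificity, FPR, precision and F1.
    """
    rows = {
        "genes": _stage_row(set(selected_genes), truth.informative_gene_ids, truth.n_genes),
        "cpgs": _stage_row(set(selected_cpgs), truth.informative_cpg_ids, truth.n_cpgs),
    }
    if pairs is not None:
        truth_pairs = {
            (c, g) for c, g in zip(truth.pair_table["cpg_id"], truth.pair_table["gene_id"])
        }
        found = {(c, g) for c, g in zip(pairs.records["cpg_id"], pairs.records["gene_id"])}
        rows["pairs"] = _stage_row(found, truth_pairs, truth.n_genes * truth.n_cpgs)
    return pd.DataFrame.from_dict(rows, orient="index")
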