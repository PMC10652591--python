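"""Cohort preprocessing: low-expression filtering, paired-sample
intersection, and the stratified train/validation split."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple
    validation_ids: tuple
    seed: int
    fraction: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation sets overlap")


def filter_low_expressed(
    expr: OmicsMatrix, threshold: float = 0.1, sample_frac: float = 0.9
) -> OmicsMatrix:
    """Drop genes with value < ``threshold`` in at least ``sample_frac`` of
    samples (the low-expression rule on the log2(RSEM+1) scale).

    Idempotent; survivor order preserved. The boundary is inclusive: a gene
    low in exactly 90% of samples is removed.
    """
    if expr.layer != "expression":
        raise ValueError("low-expression filter applies to the expression layer only")
    values = expr.values
    frac_low = (values < threshold).mean(axis=1)
    keep = frac_low < sample_frac
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filtered %d low-expressed genes", n_removed)
    return OmicsMatrix(layer="expression", values=values.loc[keep])


def intersect_paired_samples(
    expr: OmicsMatrix, meth: OmicsMatrix, clinical: ClinicalTable
):
    """Restrict all three inputs to samples profiled on both layers with
    clinical follow-up, in one shared sample order.

    The shared order is the expression matrix's order filtered to the
    intersection; downstream stages pair rows positionally, so the equality of
    orders is part of the contract.
    """
    common = [
        s
        for s in expr.sample_ids
        if s in set(meth.sample_ids) and s in set(clinical.sample_ids)
    ]
    if not common:
        raise ValueError("no samples shared by expression, methylation and clinical data")
    expr_out = OmicsMatrix(layer="expression", values=expr.values[common])
    meth_out = OmicsMatrix(layer="methylation", values=meth.values[common])
    clin_out = ClinicalTable(
        table=clinical.table.loc[common], label_set=clinical.label_set
    )
    return expr_out, meth_out, clin_out


def stratified_split(
    clinical: ClinicalTable, fraction: float = 0.7, seed: int = 0
) -> SplitAssignment:
    """Per-subtype random split into train (``fraction``) and validation."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for label, group in clinical.table.groupby("subtype", sort=True, observed=True):
        ids = list(group.index)
        if len(ids) < 2:
            raise ValueError(f"subtype {label!r} has fewer than 2 samples")
        order = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in order[:n_train])
        val.extend(ids[i] for i in order[n_train:])
    return SplitAssignment(
        train_ids=tuple(sorted(train)),
        validation_ids=tuple(sorted(val)),
        seed=seed,
        fraction=fraction,
    )


def write_split(split: SplitAssignment, path, sep="\t") -> None:
    rows = [(s, "train") for s in split.train_ids] + [
        (s, "validation") for s in split.validation_ids
    ]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(path, sep=sep, index=False)
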