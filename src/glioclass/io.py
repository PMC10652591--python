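"""Tabular I/O and validation into the package's domain types.

Matrices are stored features x samples on disk (the Xena convention: first
column feature ids, header row sample ids). The internal contract is the same
orientation inside :class:`OmicsMatrix`; model-facing code transposes to
samples-major at the model boundary.

The probe-annotation format is a 3-column minimal subset of an Illumina 450K
manifest: ``cpg_id``, ``gene_id``, ``region``. Region spellings are mapped
case-insensitively onto a closed vocabulary through an alias table shipped as
package data (``data/region_aliases.tsv``) so other array dialects can be
added without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, MetricsSummary

logger = logging.getLogger(__name__)

LAYERS = ("expression", "methylation")
REGIONS = ("TSS1500", "TSS200", "FirstExon", "UTR5", "Body", "UTR3", "Other")
#: promoter region classes used for CpG-gene pairing
PROMOTER_REGIONS = frozenset({"TSS1500", "TSS200", "FirstExon", "UTR5"})


def _load_region_aliases() -> dict[str, str]:
    with resources.files("glioclass.data").joinpath("region_aliases.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return dict(zip(table["alias"], table["canonical"]))


_REGION_ALIASES = _load_region_aliases()


def canonical_region(region: str) -> str:
    """Map a manifest region spelling onto the closed vocabulary."""
    key = str(region).strip().lower()
    if key in _REGION_ALIASES:
        return _REGION_ALIASES[key]
    raise ValueError(f"unmappable genomic region string: {region!r}")


@dataclass
class OmicsMatrix:
    """One omics layer: real-valued matrix, features x samples."""

    layer: str
    values: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown omics layer: {self.layer!r}")
        validate_omics_values(self.values, self.layer)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def samples_major(self) -> np.ndarray:
        """Samples x features array for model input."""
        return np.ascontiguousarray(self.values.to_numpy(dtype=float).T)


@dataclass
class ClinicalTable:
    """Per-sample subtype label and overall-survival outcome."""

    table: pd.DataFrame  # index = sample_id; columns subtype, os_time, os_event
    label_set: tuple

    def __post_init__(self):
        t = self.table
        for col in ("subtype", "os_time", "os_event"):
            if col not in t.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in clinical table: {dups}")
        if (t["os_time"] <= 0).any():
            bad = t.index[t["os_time"] <= 0].tolist()
            raise ValueError(f"non-positive survival time for samples: {bad}")
        if not set(t["os_event"].unique()) <= {0, 1}:
            raise ValueError("os_event must be coded 0/1")
        unknown = set(t["subtype"]) - set(self.label_set)
        if unknown:
            raise ValueError(f"subtype labels outside declared set: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def subtype_of(self) -> pd.Series:
        return self.table["subtype"]


@dataclass
class ProbeAnnotation:
    """CpG -> (gene, genomic region) records; one CpG may map to several."""

    records: pd.DataFrame  # columns cpg_id, gene_id, region

    def __post_init__(self):
        r = self.records
        for col in ("cpg_id", "gene_id", "region"):
            if col not in r.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        bad = set(r["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"regions outside closed vocabulary: {sorted(bad)}")


def validate_omics_values(values: pd.DataFrame, layer: str) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dups}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing value in validated matrix at feature {values.index[i]!r}, "
            f"sample {values.columns[j]!r}"
        )
    if layer == "methylation":
        out = (arr < 0) | (arr > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"beta value {arr[i, j]} outside [0, 1] for probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
    elif layer == "expression":
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value {arr[i, j]} for gene "
                f"{values.index[i]!r}, sample {values.columns[j]!r} "
                "(expected log2(RSEM+1) scale)"
            )


def _read_table(path, sep=None) -> pd.DataFrame:
    # delimiter sniffed unless set; gzip handled transparently by pandas
    if sep is None:
        return pd.read_csv(path, sep=None, engine="python", index_col=0)
    return pd.read_csv(path, sep=sep, index_col=0)


def read_omics_matrix(path, layer: str, missing: str = "drop", sep=None) -> OmicsMatrix:
    """Read a features x samples matrix and validate it.

    ``missing`` controls rows with missing values: ``"drop"`` removes the
    feature, ``"impute-median"`` fills with the feature's median across
    samples. Either way the count is logged.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown omics layer: {layer!r}")
    values = _read_table(path, sep=sep).astype(float)
    n_missing_rows = int(values.isna().any(axis=1).sum())
    if n_missing_rows:
        if missing == "drop":
            values = values.dropna(axis=0)
            logger.info("dropped %d features with missing values", n_missing_rows)
        elif missing == "impute-median":
            med = values.median(axis=1)
            values = values.apply(lambda row: row.fillna(med[row.name]), axis=1)
            logger.info("median-imputed %d features with missing values", n_missing_rows)
        else:
            raise ValueError(f"unknown missing-value policy: {missing!r}")
    return OmicsMatrix(layer=layer, values=values)


def read_clinical(path, label_set, sep=None) -> ClinicalTable:
    """Read the clinical table (sample_id, subtype, os_time, os_event).

    Rows whose subtype is outside ``label_set`` are rejected with a logged
    count; os_event is coerced to {0, 1}.
    """
    if sep is None:
        t = pd.read_csv(path, sep=None, engine="python")
    else:
        t = pd.read_csv(path, sep=sep)
    required = {"sample_id", "subtype", "os_time", "os_event"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"clinical table missing required columns: {sorted(missing)}")
    t = t.set_index("sample_id")
    known = t["subtype"].isin(list(label_set))
    n_rejected = int((~known).sum())
    if n_rejected:
        logger.warning(
            "rejected %d clinical rows with subtype outside %s",
            n_rejected,
            sorted(label_set),
        )
        t = t[known]
    t = t.copy()
    t["os_event"] = t["os_event"].astype(float).round().clip(0, 1).astype(int)
    t["os_time"] = t["os_time"].astype(float)
    return ClinicalTable(table=t[["subtype", "os_time", "os_event"]], label_set=tuple(label_set))


def read_probe_annotation(path, sep=None) -> ProbeAnnotation:
    """Read a 3-column CpG annotation table; all regions retained."""
    if sep is None:
        t = pd.read_csv(path, sep=None, engine="python")
    else:
        t = pd.read_csv(path, sep=sep)
    required = {"cpg_id", "gene_id", "region"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"probe annotation missing required columns: {sorted(missing)}")
    t = t.copy()
    t["region"] = [canonical_region(r) for r in t["region"]]
    return ProbeAnnotation(records=t[["cpg_id", "gene_id", "region"]].reset_index(drop=True))


def write_omics_matrix(matrix: OmicsMatrix, path, sep="\t", float_format="%.10g") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="feature_id", float_format=float_format)


def write_clinical(clinical: ClinicalTable, path, sep="\t") -> None:
    clinical.table.to_csv(path, sep=sep, index_label="sample_id")


def write_probe_annotation(annotation: ProbeAnnotation, path, sep="\t") -> None:
    annotation.records.to_csv(path, sep=sep, index=False)


_CELL_FMT = "{mean:.4f} [{lo:.4f}–{hi:.4f}]"


def write_metrics_report(summaries: dict[str, MetricsSummary] | MetricsSummary, path, sep="\t") -> None:
    """Write the cross-validation report: one row per classifier, one column
    per metric, each cell formatted as ``mean [lo-hi]``.

    Confidence intervals for rate metrics are clipped to their valid range
    (noted in the report footer via the mean/CI construction in metrics).
    """
    if isinstance(summaries, MetricsSummary):
        summaries = {"model": summaries}
    if not summaries:
        raise ValueError("no summaries to report")
    for name, s in summaries.items():
        if len(s.folds) == 0:
            raise ValueError(f"summary for {name!r} has no folds")
    rows = {}
    for name, s in summaries.items():
        rows[name] = {
            m: _CELL_FMT.format(mean=s.mean[m], lo=s.ci_lo[m], hi=s.ci_hi[m])
            for m in METRIC_NAMES
        }
    pd.DataFrame.from_dict(rows, orient="index")[METRIC_NAMES].to_csv(
        path, sep=sep, index_label="classifier"
    )


def read_metrics_report(path, sep="\t") -> pd.DataFrame:
    """Parse a metrics report back into numeric (mean, lo, hi) per cell."""
    raw = pd.read_csv(path, sep=sep, index_col=0)
    parsed = {}
    for clf, row in raw.iterrows():
        rec = {}
        for m in METRIC_NAMES:
            cell = row[m]
            mean_part, ci_part = cell.split(" [")
            lo, hi = ci_part.rstrip("]").split("–")
            rec[m] = (float(mean_part), float(lo), float(hi))
        parsed[clf] = rec
    return pd.DataFrame.from_dict(parsed, orient="index")[METRIC_NAMES]
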