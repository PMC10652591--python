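"""Three-stage survival-aware feature screening.

1. **Differential screening** by subtype z-score: for feature *f* and subtype
   *s*, ``z = (x̄_s − μ) / σ`` with x̄_s the subtype mean and (μ, σ) the mean
   and population standard deviation (ddof = 0) over *all* samples of the
   cohort. Features with z > 1 (up / hypermethylated) or z < −1 (down /
   hypomethylated) in any subtype form the DEG/DMR union carried forward.
2. **Survival screening** by univariate Cox proportional hazards: one model
   per feature, h(t) = h0(t)·exp(b·x); features with Wald p < 0.05 are kept.
   Ties are handled with the Efron approximation; the baseline hazard is
   never estimated (irrelevant to screening). No multiplicity correction is
   applied by default, matching common practice for this screening design; an
   FDR option exists.
3. **Promoter pairing**: a (CpG, gene) pair survives when the CpG passed both
   screens, the gene passed both screens, and the annotation places the CpG
   in the gene's promoter (TSS1500, TSS200, first exon or 5'UTR).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, OmicsMatrix, ProbeAnnotation, PROMOTER_REGIONS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# z-score differential screening


def compute_zscores(matrix: OmicsMatrix, subtype_of: pd.Series) -> pd.DataFrame:
    """Subtype z-score table for every (feature, subtype).

    Columns: feature_id, subtype, subtype_mean, pop_mean, pop_sd, z,
    undefined. Rows with zero population SD are flagged undefined (z = NaN)
    and are never selected downstream.
    """
    samples = matrix.sample_ids
    unknown = [s for s in samples if s not in subtype_of.index]
    if unknown:
        raise ValueError(f"samples without subtype label: {unknown[:5]}")
    labels = subtype_of.loc[samples]
    values = matrix.values.to_numpy(dtype=float)
    pop_mean = values.mean(axis=1)
    pop_sd = values.std(axis=1, ddof=0)
    frames = []
    for subtype in sorted(labels.unique()):
        cols = np.asarray(labels == subtype)
        if cols.sum() == 0:
            raise ValueError(f"subtype {subtype!r} has no samples")
        sub_mean = values[:, cols].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (sub_mean - pop_mean) / pop_sd
        undefined = pop_sd == 0
        z = np.where(undefined, np.nan, z)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": matrix.feature_ids,
                    "subtype": subtype,
                    "subtype_mean": sub_mean,
                    "pop_mean": pop_mean,
                    "pop_sd": pop_sd,
                    "z": z,
                    "undefined": undefined,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def select_differential(ztable: pd.DataFrame, threshold: float = 1.0):
    """Per-subtype selected feature sets (|z| strictly above threshold) and
    their union.

    Returns ``(per_subtype, union)`` where per_subtype maps each subtype to a
    dict with ``up`` and ``down`` sets.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    per_subtype: dict = {}
    union: set = set()
    for subtype, group in ztable.groupby("subtype", sort=True, observed=True):
        ok = group[~group["undefined"]]
        up = set(ok.loc[ok["z"] > threshold, "feature_id"])
        down = set(ok.loc[ok["z"] < -threshold, "feature_id"])
        per_subtype[subtype] = {"up": up, "down": down}
        union |= up | down
    return per_subtype, union


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float


def compare_selected_groups(
    matrix: OmicsMatrix, up_set: set, down_set: set
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U on the mean levels of up- vs down-selected
    features (exact enumeration when both groups have n <= 8)."""
    if not up_set or not down_set:
        raise ValueError("both feature sets must be nonempty")
    means = matrix.values.mean(axis=1)
    x = means.loc[sorted(up_set & set(matrix.feature_ids))].to_numpy()
    y = means.loc[sorted(down_set & set(matrix.feature_ids))].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("feature sets do not overlap the matrix")
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# univariate Cox screening


@dataclass(frozen=True)
class CoxResult:
    feature_id: str
    coef: float
    hr: float
    se: float
    p_value: float
    converged: bool
    n_iter: int


def efron_loglik_derivatives(b: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log partial likelihood, score and information at coefficient ``b``
    under the Efron tie approximation (single covariate).

    Inputs need not be sorted. Used both by the Newton solver and, at
    solver-independent points, by tests.
    """
    order = np.argsort(time, kind="stable")
    x = x[order]
    time = time[order]
    event = event[order].astype(bool)
    eta = b * x
    # guard overflow for extreme b during bracketing
    w = np.exp(np.clip(eta, -700, 700))
    wx = w * x
    wxx = w * x * x
    loglik = 0.0
    score = 0.0
    info = 0.0
    n = len(x)
    i = 0
    # cumulative sums over the risk set {j : t_j >= t}, built backwards
    s0_tail = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    s1_tail = np.concatenate([np.cumsum(wx[::-1])[::-1], [0.0]])
    s2_tail = np.concatenate([np.cumsum(wxx[::-1])[::-1], [0.0]])
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.arange(i, j)[event[i:j]]
        d = len(deaths)
        if d:
            s0 = s0_tail[i]
            s1 = s1_tail[i]
            s2 = s2_tail[i]
            s0d = w[deaths].sum()
            s1d = wx[deaths].sum()
            s2d = wxx[deaths].sum()
            xsum = x[deaths].sum()
            loglik += b * xsum
            score += xsum
            for el in range(d):
                a = el / d
                den = s0 - a * s0d
                n1 = s1 - a * s1d
                n2 = s2 - a * s2d
                loglik -= math.log(den)
                score -= n1 / den
                info += n2 / den - (n1 / den) ** 2
        i = j
    return loglik, score, info


def fit_univariate_cox(
    values: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    feature_id: str = "",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxResult:
    """Fit h(t) = h0(t)·exp(b·x) for a single covariate by Newton-Raphson on
    the Efron partial likelihood.

    Convergence is declared when |score| < ``tol``. Monotone likelihoods
    (e.g. perfect separation) are returned flagged (``converged=False``,
    p = NaN) and excluded downstream. The Wald p-value is two-sided on b/se.
    """
    x = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"degenerate covariate{': ' + feature_id if feature_id else ''}")
    if event.sum() == 0:
        raise ValueError("no events: cannot fit a Cox model")
    # fit on the standardized covariate for conditioning and a scale-free
    # divergence criterion; back-transform the coefficient afterwards
    xs = (x - x.mean()) / sd
    b = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, score, info = efron_loglik_derivatives(b, xs, time, event)
        if info <= 0 or not np.isfinite(score):
            break
        step = float(np.clip(score / info, -2.0, 2.0))  # damp early oversized steps
        b += step
        if abs(b) > 10:  # monotone likelihood (e.g. perfect separation):
            break       # |log HR| > 10 per SD is not a finite-data optimum
        if abs(score) < tol:
            converged = True
            break
    if not converged:
        return CoxResult(feature_id, float("nan"), float("nan"), float("nan"), float("nan"), False, it)
    _, _, info = efron_loglik_derivatives(b, xs, time, event)
    if info < 1e-8:  # flat likelihood at the "optimum": treat as divergent
        return CoxResult(feature_id, float("nan"), float("nan"), float("nan"), float("nan"), False, it)
    se_std = 1.0 / math.sqrt(info)
    p = 2.0 * stats.norm.sf(abs(b / se_std))
    coef = b / sd
    return CoxResult(feature_id, coef, math.exp(coef), se_std / sd, float(p), True, it)


def screen_survival(
    matrix: OmicsMatrix,
    clinical: ClinicalTable,
    candidate_set: set,
    alpha: float = 0.05,
    fdr: bool = False,
):
    """Univariate Cox screen over ``candidate_set``.

    Returns ``(selected_set, table)`` where table has one row per candidate
    (feature_id, coef, hr, se, p_value, converged). Per-feature failures
    (constant covariate, non-convergence) are logged and excluded, never
    abort the batch. With ``fdr=True`` the selection uses Benjamini-Hochberg
    adjusted p-values at the same ``alpha``.
    """
    missing = candidate_set - set(matrix.feature_ids)
    if missing:
        raise ValueError(f"candidates not in matrix: {sorted(missing)[:5]}")
    samples = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
    if not samples:
        raise ValueError("no overlap between matrix and clinical samples")
    sub = matrix.values[samples]
    time = clinical.table.loc[samples, "os_time"].to_numpy(dtype=float)
    event = clinical.table.loc[samples, "os_event"].to_numpy(dtype=int)
    rows = []
    for fid in sorted(candidate_set):
        x = sub.loc[fid].to_numpy(dtype=float)
        try:
            res = fit_univariate_cox(x, time, event, feature_id=fid)
        except ValueError as exc:
            logger.info("excluded %s from survival screen: %s", fid, exc)
            continue
        if not res.converged:
            logger.info("excluded %s: Cox fit did not converge (monotone likelihood)", fid)
        rows.append(res)
    table = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "coef": r.coef,
                "hr": r.hr,
                "se": r.se,
                "p_value": r.p_value,
                "converged": r.converged,
            }
            for r in rows
        ]
    )
    if table.empty:
        return set(), table
    ok = table[table["converged"]].copy()
    if fdr and not ok.empty:
        from statsmodels.stats.multitest import multipletests

        ok["p_adj"] = multipletests(ok["p_value"], method="fdr_bh")[1]
        selected = set(ok.loc[ok["p_adj"] < alpha, "feature_id"])
    else:
        selected = set(ok.loc[ok["p_value"] < alpha, "feature_id"])
    return selected, table


# ---------------------------------------------------------------------------
# promoter pairing


@dataclass
class CpgGenePairSet:
    """Survival-linked promoter CpG-gene pairs and the two derived feature
    blocks (deduplicated gene and CpG lists) that feed the autoencoder."""

    records: pd.DataFrame  # cpg_id, gene_id, region

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set(self.records["gene_id"]))

    @property
    def cpg_ids(self) -> list[str]:
        return sorted(set(self.records["cpg_id"]))

    def __len__(self) -> int:
        return len(self.records)


def map_promoter_pairs(
    genes_selected: set, cpgs_selected: set, annotation: ProbeAnnotation
) -> CpgGenePairSet:
    """Retain (CpG, gene) pairs where both members passed the screens and the
    CpG lies in the gene's promoter. Output is deduplicated and sorted, hence
    invariant to input ordering."""
    if not genes_selected or not cpgs_selected:
        raise ValueError("both selected sets must be nonempty")
    rec = annotation.records
    keep = (
        rec["region"].isin(PROMOTER_REGIONS)
        & rec["cpg_id"].isin(cpgs_selected)
        & rec["gene_id"].isin(genes_selected)
    )
    out = (
        rec.loc[keep, ["cpg_id", "gene_id", "region"]]
        .drop_duplicates(subset=["cpg_id", "gene_id"])
        .sort_values(["cpg_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    if out.empty:
        raise ValueError("empty integration set: no promoter pairs survive both screens")
    return CpgGenePairSet(records=out)


def sample_random_pairs(
    expr: OmicsMatrix, meth: OmicsMatrix, n_genes: int, n_cpgs: int, seed: int = 0
) -> CpgGenePairSet:
    """Uniform random, unmapped gene and CpG blocks of the requested sizes —
    the ablation counterpart to :func:`map_promoter_pairs`."""
    if n_genes > len(expr.feature_ids) or n_cpgs > len(meth.feature_ids):
        raise ValueError("requested more features than available")
    rng = np.random.default_rng(seed)
    genes = rng.choice(expr.feature_ids, size=n_genes, replace=False)
    cpgs = rng.choice(meth.feature_ids, size=n_cpgs, replace=False)
    n = max(n_genes, n_cpgs)
    records = pd.DataFrame(
        {
            "cpg_id": np.resize(np.sort(cpgs), n),
            "gene_id": np.resize(np.sort(genes), n),
            "region": "Other",
        }
    )
    return CpgGenePairSet(records=records)
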