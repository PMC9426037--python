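"""Targeted gene-expression analysis: normalization, covariate-adjusted
differential expression, pathway / cell-type scores, and gene-set
similarity (GSS / dGSS).

The expression container is a thin wrapper over a genes x samples
DataFrame tracking whether values are raw nonnegative counts or
log2-normalized. Normalization follows the housekeeping-gene scheme used
with nCounter-style panels: each sample is rescaled by the geometric mean
of its housekeeping counts relative to the cohort average, then
log2(x + 1) transformed. Values are therefore defined up to a single
cohort-level constant.

Gene-set similarity scores summarize a differential-expression result at
the gene-set level: the global significance score (GSS) of a set S is the
root-mean-square of its member t-statistics,

    GSS(S) = sqrt( mean_{g in S} t_g^2 )

and the directed variant preserves the dominant sign of regulation,

    dGSS(S) = sign(sum_g sign(t_g) t_g^2) * sqrt(| mean_g sign(t_g) t_g^2 |)

so |dGSS| <= GSS always, with equality exactly when every member
t-statistic shares one sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a normalization state."""

    values: pd.DataFrame                 # genes in rows, samples in columns
    state: str = "raw"                   # {"raw", "normalized"}

    def __post_init__(self) -> None:
        if self.state not in {"raw", "normalized"}:
            raise ValueError(f"unknown state: {self.state!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing entries")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dupes)[:5]}")
        if self.state == "raw" and (self.values.values < 0).any():
            raise ValueError("raw expression values must be nonnegative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def normalize(raw: ExpressionMatrix, housekeeping: list[str]) -> ExpressionMatrix:
    """Housekeeping-gene normalization followed by log2(x + 1).

    Per-sample scale factor = geometric mean of the sample's housekeeping
    counts divided by the cohort-wide mean of those geometric means; counts
    are divided by the factor before the log transform.
    """
    if raw.state != "raw":
        raise ValueError("normalize expects a raw expression matrix")
    missing = [g for g in housekeeping if g not in raw.genes]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    hk = raw.values.loc[housekeeping]
    zero_samples = hk.columns[(hk <= 0).any(axis=0)].tolist()
    if zero_samples:
        raise ValueError(
            f"housekeeping gene with zero count in samples: {zero_samples}"
        )
    geo = np.exp(np.log(hk).mean(axis=0))           # per-sample geometric mean
    factors = geo / geo.mean()
    scaled = raw.values.div(factors, axis=1)
    return ExpressionMatrix(values=np.log2(scaled + 1.0), state="normalized")


@dataclass
class DGEResult:
    """Per-gene linear-model contrast between two groups, covariate-adjusted."""

    table: pd.DataFrame        # index gene; log2_fc, t, p, p_adj
    target: str
    reference: str
    covariates: list[str] = field(default_factory=list)

    @property
    def t_statistics(self) -> pd.Series:
        return self.table["t"]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]


def _design_matrix(group: pd.Series, target: str, reference: str,
                   covariates: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(group))}
    cols["group"] = (group == target).astype(float).values
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name]
            if col.dtype.kind in "biufc":
                cols[name] = col.astype(float).values
            else:
                levels = sorted(col.astype(str).unique())
                for lev in levels[1:]:          # first level absorbed by intercept
                    cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float).values
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names


def dge(expr: ExpressionMatrix, group: pd.Series, target: str, reference: str,
        covariates: pd.DataFrame | None = None) -> DGEResult:
    """Per-gene OLS of log2 expression on a group indicator plus covariates.

    The reported log2 fold change is the group coefficient (target minus
    reference on the log2 scale) and its plain, unmoderated t-statistic;
    p-values are BH-adjusted across genes.
    """
    if expr.state != "normalized":
        raise ValueError("dge expects normalized (log2) expression")
    group = group.reindex(expr.samples)
    if group.isna().any():
        raise ValueError("group labels missing for some samples")
    keep = group.isin([target, reference])
    if keep.sum() < 3:
        raise ValueError("need at least 3 samples across the two groups")
    y = expr.values.loc[:, keep.values].values.T          # samples x genes
    cov = covariates.reindex(group.index)[keep.values] if covariates is not None else None
    x, names = _design_matrix(group[keep], target, reference, cov)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify aliased columns by pivoted QR-style scan
        aliased = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    n, p = x.shape
    if n <= p:
        raise ValueError("fewer samples than design columns")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y                              # p x genes
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    j = names.index("group")
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[j] / se, 0.0)
    from scipy import stats
    p_raw = 2.0 * stats.t.sf(np.abs(t), dof)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2_fc": beta[j], "t": t, "p": p_raw, "p_adj": p_adj},
        index=expr.genes,
    )
    covs = list(covariates.columns) if covariates is not None else []
    return DGEResult(table=table, target=target, reference=reference, covariates=covs)


def pathway_score(expr: ExpressionMatrix, gene_set: list[str]) -> pd.Series:
    """Per-sample pathway score: PC1 of the set's gene-centered submatrix.

    The sign of PC1 is ambiguous; the score is oriented so it correlates
    nonnegatively with the per-sample mean expression of the set, with a
    deterministic fallback (first loading nonnegative) when that
    correlation is exactly zero.
    """
    if expr.state != "normalized":
        raise ValueError("pathway_score expects normalized expression")
    present = [g for g in gene_set if g in expr.genes]
    if not present:
        raise ValueError("gene set has empty intersection with the matrix")
    sub = expr.values.loc[present]
    centered = sub.sub(sub.mean(axis=1), axis=0).values   # genes x samples
    # PC1 over samples: left singular structure of centered.T
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    score = u[:, 0] * s[0]
    mean_expr = sub.mean(axis=0).values
    r = np.dot(score - score.mean(), mean_expr - mean_expr.mean())
    if r < 0:
        score = -score
    elif r == 0:
        loading = vt[0]
        nz = np.nonzero(loading)[0]
        if nz.size and loading[nz[0]] < 0:
            score = -score
    return pd.Series(score, index=expr.samples, name="pathway_score")


def cell_type_score(expr: ExpressionMatrix,
                    marker_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean log2-normalized expression of each marker set, per sample."""
    if expr.state != "normalized":
        raise ValueError("cell_type_score expects normalized expression")
    scores = {}
    for cell_type, markers in marker_sets.items():
        if not markers:
            raise ValueError(f"empty marker set for {cell_type!r}")
        missing = [m for m in markers if m not in expr.genes]
        if missing:
            raise ValueError(f"markers absent for {cell_type!r}: {missing}")
        scores[cell_type] = expr.values.loc[markers].mean(axis=0)
    return pd.DataFrame(scores)


def gss_scores(t_stats: pd.Series, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """GSS and dGSS for each gene set, from gene-level t-statistics."""
    rows = {}
    for name, members in gene_sets.items():
        present = [g for g in members if g in t_stats.index]
        if not present:
            raise ValueError(f"gene set {name!r} has empty intersection")
        t = t_stats.loc[present].values.astype(float)
        gss = float(np.sqrt(np.mean(t ** 2)))
        signed = np.sign(t) * t ** 2
        total = signed.sum()
        dgss = float(np.sign(total) * np.sqrt(abs(signed.mean())))
        rows[name] = {"n_genes": len(present), "gss": gss, "dgss": dgss}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_set"
    return out


def gss(dge_result: DGEResult, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Gene-set similarity table for a differential-expression contrast."""
    return gss_scores(dge_result.t_statistics, gene_sets)
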