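"""Normalization, QC, variable-gene selection and per-cell expression metrics.

Two normalization paths mirror the two library chemistries:

* full-length libraries are normalized to RPKM (reads per kilobase of
  union-exon model per million mapped reads);
* 3'-counting libraries are library-size normalized: counts divided by the
  cell's total and multiplied by a common target (the mean library size of
  all processed cells by default).

In both, values below 1 are considered non-detected and set to zero, and
the matrix is then log2-transformed (zeros stay zero; no pseudocount —
the detection floor already guarantees log2 values >= 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .panel import ConfigurationError

__all__ = [
    "ExpressionMatrix",
    "rpkm_normalize",
    "normalize_3p",
    "detection_threshold",
    "qc_filter",
    "QC_DEFAULTS",
    "dropout_frequency",
    "library_bias",
    "highly_variable_genes",
    "ado_from_het_sites",
    "cell_cycle_scores",
    "regress_out",
    "group_correlations",
    "ks_compare",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells log2 expression with its normalization tag.

    ``excluded_cells`` lists cells dropped during normalization (zero
    totals); ``meta`` is optional per-cell metadata (genotype labels,
    batch, QC metrics).
    """

    values: pd.DataFrame
    normalization: Literal["RPKM", "norm3p", "log2"]
    meta: pd.DataFrame | None = None
    excluded_cells: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def linear(self) -> pd.DataFrame:
        """Back-transform to the linear scale (0 stays 0)."""
        v = self.values
        return pd.DataFrame(
            np.where(v.to_numpy() > 0, 2.0 ** v.to_numpy(), 0.0),
            index=v.index,
            columns=v.columns,
        )


def detection_threshold(values: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Zero out sub-threshold values (idempotent), then leave them linear."""
    arr = values.to_numpy(dtype=float).copy()
    arr[arr < floor] = 0.0
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def _log2_detected(values: pd.DataFrame) -> pd.DataFrame:
    arr = detection_threshold(values).to_numpy()
    out = np.zeros_like(arr)
    np.log2(arr, out=out, where=arr > 0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def rpkm_normalize(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    mapped_totals: pd.Series | None = None,
) -> ExpressionMatrix:
    """RPKM-normalize a genes x cells count matrix and log2-transform.

    ``gene_lengths`` are union-exon lengths in bp; ``mapped_totals``
    default to the per-cell column sums.  Cells with a zero total are
    flagged and excluded.  RPKM < 1 is treated as non-detected.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = list(lengths.index[lengths.isna() | (lengths <= 0)][:5])
        raise ConfigurationError(f"missing/non-positive gene lengths, e.g. {bad}")
    totals = mapped_totals.reindex(counts.columns) if mapped_totals is not None else counts.sum(axis=0)
    excluded = list(totals.index[totals <= 0])
    keep = [c for c in counts.columns if c not in excluded]
    sub = counts[keep]
    rpkm = sub.div(lengths / 1_000.0, axis=0).div(totals[keep] / 1e6, axis=1)
    return ExpressionMatrix(_log2_detected(rpkm), "RPKM", excluded_cells=excluded)


def normalize_3p(counts: pd.DataFrame, target: float | None = None) -> ExpressionMatrix:
    """Library-size normalize 3'-counting data and log2-transform.

    Each cell's counts are divided by its library size and multiplied by
    ``target`` (default: the mean library size of the processed cells), so
    pre-threshold per-cell sums equal the target exactly.  Values < 1 are
    non-detected.
    """
    totals = counts.sum(axis=0)
    excluded = list(totals.index[totals <= 0])
    keep = [c for c in counts.columns if c not in excluded]
    sub = counts[keep]
    if target is None:
        target = float(totals[keep].mean())
    norm = sub.div(totals[keep], axis=1) * target
    em = ExpressionMatrix(_log2_detected(norm), "norm3p", excluded_cells=excluded)
    em.meta = pd.DataFrame({"library_size": totals[keep], "target": target})
    return em


#: Printed QC thresholds per dataset mode.  Full-length gene floors differ
#: by cell type; ``min_genes`` here is the primary-HSPC value and is
#: overridable per call.
QC_DEFAULTS: dict[str, dict[str, float]] = {
    "full_length": {"pct_exonic": 50.0, "pct_mapped": 50.0, "min_genes": 1500},
    "three_prime": {
        "min_libsize": 2000,
        "max_pct_mito": 10.0,
        "max_pct_ercc": 50.0,
        "min_genes": 500,
    },
}


def qc_filter(
    metrics: pd.DataFrame,
    mode: Literal["full_length", "three_prime"],
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Apply the per-cell QC filters with strict inequalities as printed.

    Full-length: exonic% > 50, mapped% > 50, detected genes > ``min_genes``
    (6000 JURKAT/SET2, 5000 K562, 1500 primary HSPCs — pass the
    appropriate value).  3'-counting: library size > 2000 reads,
    mitochondrial% < 10, ERCC% < 50, detected genes > 500.  Missing
    metrics fail the cell with reason ``metric_missing:<name>``.

    Returns a DataFrame indexed by cell with ``pass`` and ``reasons``.
    """
    if mode not in QC_DEFAULTS:
        raise ConfigurationError(f"unknown QC mode {mode!r}")
    th = dict(QC_DEFAULTS[mode])
    if thresholds:
        th.update(thresholds)

    if mode == "full_length":
        checks = [
            ("pct_exonic", "gt", th["pct_exonic"]),
            ("pct_mapped", "gt", th["pct_mapped"]),
            ("n_genes_detected", "gt", th["min_genes"]),
        ]
    else:
        checks = [
            ("total_reads", "gt", th["min_libsize"]),
            ("pct_mito", "lt", th["max_pct_mito"]),
            ("pct_ercc", "lt", th["max_pct_ercc"]),
            ("n_genes_detected", "gt", th["min_genes"]),
        ]

    rows = []
    for cell, row in metrics.iterrows():
        reasons = []
        for name, op, cut in checks:
            if name not in row.index or pd.isna(row[name]):
                reasons.append(f"metric_missing:{name}")
                continue
            v = float(row[name])
            ok = v > cut if op == "gt" else v < cut
            if not ok:
                reasons.append(f"{name}:{v:g}_vs_{cut:g}")
        rows.append((cell, not reasons, ";".join(reasons)))
    return pd.DataFrame(rows, columns=["cell_id", "pass", "reasons"]).set_index("cell_id")


def dropout_frequency(
    em: ExpressionMatrix, bulk_expressed: Sequence[str]
) -> pd.Series:
    """Fraction of cells in which each bulk-expressed gene is not detected."""
    genes = [g for g in bulk_expressed if g in em.values.index]
    if not genes:
        raise ConfigurationError("no bulk_expressed genes present in the matrix")
    sub = em.values.loc[genes]
    return (sub == 0).mean(axis=1).rename("dropout_frequency")


def library_bias(
    em: ExpressionMatrix | pd.DataFrame, top_frac: float = 0.10
) -> pd.Series:
    """Per-cell ratio of the top-decile mean to the all-gene mean.

    Computed on the linear scale: mean expression of the top
    ``ceil(top_frac * n_detected)`` detected genes over the mean of all
    genes; ties broken by descending value then input order.  High values
    mean a few genes dominate the library.  Pass a plain DataFrame of
    linear RPKM values to avoid the log2 back-transform (which cannot
    distinguish RPKM = 1 from non-detected).
    """
    linear = em.linear() if isinstance(em, ExpressionMatrix) else em
    out = {}
    for cell in linear.columns:
        v = linear[cell]
        detected = v[v > 0]
        if len(detected) < 10:
            out[cell] = np.nan
            continue
        k = int(np.ceil(top_frac * len(detected)))
        top = detected.sort_values(ascending=False, kind="stable").iloc[:k]
        out[cell] = float(top.mean() / v.mean())
    return pd.Series(out, name="library_bias")


def highly_variable_genes(
    em: ExpressionMatrix,
    span: float = 0.3,
    iterations: int = 3,
    cv_scale: Literal["linear", "log2"] = "linear",
) -> pd.DataFrame:
    """Select genes whose coefficient of variation exceeds the mean trend.

    A lowess curve of CV against log2(mean expression) captures the
    technical mean-variance relationship; genes above the curve with
    log2(mean) >= 0 are flagged.  CV is computed on linear-scale values by
    default (configurable).  Returns a per-gene table with ``mean, cv,
    log2_mean, fitted_cv, selected``.
    """
    vals = em.linear() if cv_scale == "linear" else em.values
    mean = vals.mean(axis=1)
    expressed = mean > 0
    if expressed.sum() < 50:
        raise ConfigurationError("need >= 50 genes with positive mean")
    sd = vals.std(axis=1, ddof=1)
    cv = pd.Series(np.where(expressed, sd / mean.where(expressed), np.nan), index=vals.index)
    log2_mean = pd.Series(
        np.where(expressed, np.log2(mean.where(expressed)), np.nan), index=vals.index
    )
    sub = cv[expressed]
    if sub.nunique() <= 1:
        fitted = pd.Series(sub.iloc[0] if len(sub) else np.nan, index=sub.index)
    else:
        fitted_vals = lowess(
            sub.to_numpy(),
            log2_mean[expressed].to_numpy(),
            frac=span,
            it=iterations,
            return_sorted=False,
        )
        fitted = pd.Series(fitted_vals, index=sub.index)
    fit = pd.DataFrame(
        {
            "mean": mean,
            "cv": cv,
            "log2_mean": log2_mean,
            "fitted_cv": fitted.reindex(vals.index),
        }
    )
    fit["selected"] = (
        expressed & (fit["log2_mean"] >= 0) & (fit["cv"] > fit["fitted_cv"])
    ).fillna(False)
    return fit


def ado_from_het_sites(
    counts: pd.DataFrame,
    min_coverage: int = 10,
    af_window: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Allelic-dropout rate per heterozygous site from per-cell allele counts.

    ``counts`` has one row per (cell, site) with ``n_ref``/``n_alt`` (and
    optionally ``coverage``; defaults to ref+alt+other).  Cell-sites with
    coverage >= ``min_coverage`` are biallelic when the alt fraction lies
    strictly inside ``af_window`` and monoallelic otherwise; the ADO rate
    is the monoallelic fraction among informative cells.
    """
    df = counts.copy()
    if "coverage" not in df.columns:
        df["coverage"] = df["n_ref"] + df["n_alt"] + df.get("n_other", 0)
    df = df[df["coverage"] >= min_coverage]
    denom = (df["n_ref"] + df["n_alt"]).to_numpy(dtype=float)
    af = np.where(denom > 0, df["n_alt"].to_numpy(dtype=float) / np.where(denom > 0, denom, 1), 0.0)
    lo, hi = af_window
    mono = ~((af > lo) & (af < hi))
    df = df.assign(_mono=mono)
    key = "variant" if "variant" in df.columns else "site"
    g = df.groupby(key)["_mono"].agg(["count", "sum"])
    out = pd.DataFrame(
        {
            "n_informative_cells": g["count"].astype(int),
            "n_monoallelic": g["sum"].astype(int),
        }
    )
    out["ado_rate"] = out["n_monoallelic"] / out["n_informative_cells"]
    return out


def cell_cycle_scores(
    em: ExpressionMatrix, s_genes: Sequence[str], g2m_genes: Sequence[str]
) -> pd.DataFrame:
    """Per-cell S-phase and G2M-phase scores: mean log2 expression of each set."""
    scores = {}
    for name, genes in (("s_score", s_genes), ("g2m_score", g2m_genes)):
        present = [g for g in genes if g in em.values.index]
        absent = set(genes) - set(present)
        if absent:
            warnings.warn(
                f"{name}: {len(absent)} gene-set members absent from matrix",
                stacklevel=2,
            )
        if not present:
            raise ConfigurationError(f"no {name} gene-set members present in matrix")
        scores[name] = em.values.loc[present].mean(axis=0)
    return pd.DataFrame(scores)


def regress_out(em: ExpressionMatrix, covariates: pd.DataFrame) -> ExpressionMatrix:
    """Residualize per-gene expression on per-cell covariates (OLS).

    Fits ``expression ~ intercept + covariates`` gene by gene and returns
    residuals with the gene mean added back, removing e.g. cell-cycle
    scores or batch indicators while preserving average expression.
    Rank-deficient covariate matrices raise an error naming the collinear
    columns.
    """
    cov = covariates.reindex(em.cells)
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = [
            c
            for i, c in enumerate(cov.columns)
            if np.linalg.matrix_rank(np.delete(X, i + 1, axis=1)) == rank
        ]
        raise ConfigurationError(f"collinear covariate columns: {collinear}")
    Y = em.values.to_numpy(dtype=float).T  # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T + em.values.to_numpy().mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(out, index=em.genes, columns=em.cells), "log2", meta=em.meta
    )


def group_correlations(
    em: ExpressionMatrix,
    groups: pd.Series,
    min_cells_expr: int = 5,
) -> dict[str, np.ndarray]:
    """Within-group pairwise Pearson correlations between single cells.

    Genes expressed in fewer than ``min_cells_expr`` cells (globally) are
    dropped first; each group of >= 2 cells yields the flattened
    upper-triangle of its cell-cell correlation matrix of log2 values.
    """
    expressed = (em.values > 0).sum(axis=1) >= min_cells_expr
    vals = em.values[expressed]
    out: dict[str, np.ndarray] = {}
    for grp, cells in groups.groupby(groups).groups.items():
        cells = [c for c in cells if c in vals.columns]
        if len(cells) < 2:
            raise ConfigurationError(f"group {grp!r} has fewer than 2 cells")
        corr = np.corrcoef(vals[cells].to_numpy(), rowvar=False)
        iu = np.triu_indices(len(cells), k=1)
        out[str(grp)] = corr[iu]
    return out


def ks_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov comparison of two correlation distributions."""
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
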