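"""Combined differential-expression test and the multi-subclone ANOVA screen.

The combined test compares two genotype groups per gene on two axes:

* a two-sided Wilcoxon rank-sum test on the log2 expression values
  (exact for small groups, normal approximation with tie and continuity
  corrections otherwise), and
* Fisher's exact test on the 2x2 table of expressing vs non-expressing
  cells per group ("expressed" = value > 0 after the detection floor).

The two p values are combined with Fisher's method (chi-square with 2k
degrees of freedom on -2*sum(log p)); when one component is degenerate —
every cell expressing in both groups, or constant values — the other
passes through with k = 1.  Benjamini-Hochberg adjustment runs over the
genes tested in the comparison, and a gene is significant at adjusted
p < 0.1 with |log2 fold change| > 0.5.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .panel import ConfigurationError

__all__ = [
    "gene_inclusion_filter",
    "fishers_method",
    "bh_adjust",
    "combined_de_test",
    "anova_subclones",
]

P_FLOOR = 1e-300

SIG_P_ADJ = 0.1
SIG_LOG2FC = 0.5


def gene_inclusion_filter(
    em: ExpressionMatrix | pd.DataFrame, min_cells: int | None = None
) -> list[str]:
    """Genes expressed in enough cells to be tested.

    ``min_cells`` defaults to 2 when the matrix has fewer than 200 cells
    and 5 otherwise; a gene is kept iff its value is > 0 in at least
    ``min_cells`` cells.
    """
    vals = em.values if isinstance(em, ExpressionMatrix) else em
    if vals.empty:
        raise ConfigurationError("empty expression matrix")
    if min_cells is None:
        min_cells = 2 if vals.shape[1] < 200 else 5
    n_expr = (vals > 0).sum(axis=1)
    return list(vals.index[n_expr >= min_cells])


def fishers_method(pvals: Sequence[float]) -> float:
    """Combine independent p values: -2*sum(ln p) ~ chi-square(2k)."""
    p = np.clip(np.asarray(pvals, dtype=float), P_FLOOR, 1.0)
    if p.size == 0:
        return 1.0
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p; exact for small groups, NaN if degenerate."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return np.nan
    small = min(a.size, b.size) < 8
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (small and not ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def _fisher_p(expr_a: int, n_a: int, expr_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p on the expression-frequency table.

    NaN when the table is degenerate (all or none expressing in both
    groups), in which case the frequency axis carries no information.
    """
    if expr_a + expr_b == 0 or (n_a - expr_a) + (n_b - expr_b) == 0:
        return np.nan
    table = [[expr_a, n_a - expr_a], [expr_b, n_b - expr_b]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def combined_de_test(
    em: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    genes: Sequence[str] | None = None,
    min_cells: int | None = None,
) -> pd.DataFrame:
    """Per-gene combined Wilcoxon + Fisher's-exact differential expression.

    ``group_a``/``group_b`` are cell-id lists; ``genes`` defaults to
    :func:`gene_inclusion_filter` computed on the tested cells.  The
    returned table has one row per tested gene with ``p_wilcoxon,
    p_fisher, p_combined, p_adj, log2fc, freq_a, freq_b, significant``;
    log2fc is mean(A) - mean(B) on the log2 matrix (zeros included) and
    significance requires adjusted p < 0.1 and |log2fc| > 0.5.
    """
    vals = em.values if isinstance(em, ExpressionMatrix) else em
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise ConfigurationError("both groups need >= 3 cells")
    missing = (set(group_a) | set(group_b)) - set(vals.columns)
    if missing:
        raise ConfigurationError(f"cells absent from matrix: {sorted(missing)[:5]}")
    tested = vals[group_a + group_b]
    if genes is None:
        genes = gene_inclusion_filter(tested, min_cells)
    if not genes:
        raise ConfigurationError("no genes pass the inclusion filter")

    A = tested.loc[genes, group_a].to_numpy(dtype=float)
    B = tested.loc[genes, group_b].to_numpy(dtype=float)
    n_a, n_b = A.shape[1], B.shape[1]

    # vectorized asymptotic rank-sum for the bulk; exact/degenerate per gene
    with np.errstate(invalid="ignore"):
        pw = stats.mannwhitneyu(
            A, B, alternative="two-sided", method="asymptotic", axis=1
        ).pvalue
    small = min(n_a, n_b) < 8
    for i in range(len(genes)):
        if np.ptp(np.concatenate([A[i], B[i]])) == 0:
            pw[i] = np.nan
        elif small:
            pw[i] = _wilcoxon_p(A[i], B[i])

    expr_a = (A > 0).sum(axis=1)
    expr_b = (B > 0).sum(axis=1)
    pf = np.array(
        [_fisher_p(int(ea), n_a, int(eb), n_b) for ea, eb in zip(expr_a, expr_b)]
    )

    p_comb = np.array(
        [
            fishers_method([p for p in (w, f) if not np.isnan(p)])
            for w, f in zip(pw, pf)
        ]
    )
    p_adj = bh_adjust(p_comb)
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    out = pd.DataFrame(
        {
            "p_wilcoxon": pw,
            "p_fisher": pf,
            "p_combined": p_comb,
            "p_adj": p_adj,
            "log2fc": log2fc,
            "freq_a": expr_a / n_a,
            "freq_b": expr_b / n_b,
        },
        index=pd.Index(genes, name="gene"),
    )
    out["significant"] = (out["p_adj"] < SIG_P_ADJ) & (out["log2fc"].abs() > SIG_LOG2FC)
    return out


def anova_subclones(
    em: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per gene across genetic subclones.

    ``labels`` maps cell id to subclone; genes with an undefined F
    statistic (constant values) get p = 1 by convention.  ``selected``
    flags p < ``alpha``.
    """
    vals = em.values if isinstance(em, ExpressionMatrix) else em
    groups = [list(idx) for _, idx in labels.groupby(labels).groups.items()]
    if len(groups) < 2 or sum(len(g) >= 2 for g in groups) < 2:
        raise ConfigurationError("need >= 2 subclones with >= 2 cells each")
    arrays = [vals[g].to_numpy(dtype=float) for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(*arrays, axis=1)
    F = np.nan_to_num(res.statistic, nan=0.0)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    out = pd.DataFrame(
        {"F": F, "p": p, "selected": p < alpha}, index=vals.index.rename("gene")
    )
    return out
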