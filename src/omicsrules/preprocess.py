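"""Matching, normalization and two-omics differential gene selection.

Genes kept for mining must be (a) differentially expressed, (b)
differentially methylated (both at BH-adjusted p below ``alpha``) and
(c) present in the protein--protein interaction universe. The
differential test is a two-group moderated t-statistic with empirical
Bayes variance shrinkage; its hyperparameters are fitted by method of
moments on the log sample variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


class PreprocessError(ValueError):
    """Raised when matching or testing preconditions are violated."""


@dataclass
class PairedOmics:
    """Matched expression/methylation matrices with shared indices.

    Both matrices are genes x samples with identical row and column
    orderings; ``labels`` is a 0/1 group indicator per sample.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    expression: np.ndarray
    methylation: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.methylation = np.asarray(self.methylation, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, m = len(self.gene_ids), len(self.sample_ids)
        if self.expression.shape != (n, m) or self.methylation.shape != (n, m):
            raise PreprocessError(
                f"matrix shapes {self.expression.shape}/{self.methylation.shape} "
                f"do not match {n} genes x {m} samples"
            )
        if self.labels.shape != (m,):
            raise PreprocessError("labels length does not match sample count")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise PreprocessError("labels must be binary (0/1)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "PairedOmics":
        """Restrict to ``genes`` (kept in the given order)."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise PreprocessError(f"genes absent from data: {missing}")
        rows = [idx[g] for g in genes]
        return PairedOmics(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            expression=self.expression[rows],
            methylation=self.methylation[rows],
            labels=self.labels.copy(),
        )


@dataclass
class DiffTestResult:
    """Per-probe moderated-t results plus the probe -> gene map."""

    probe_ids: list[str]
    gene_map: dict[str, str]
    effect: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    df_prior: float = np.nan
    s2_prior: float = np.nan

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe": self.probe_ids,
                "gene": [self.gene_map[p] for p in self.probe_ids],
                "effect": self.effect,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_adj": self.p_adj,
            }
        )


def match_omics(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    labels: pd.Series,
) -> PairedOmics:
    """Restrict both omics to their shared genes and samples.

    Rows (genes) and columns (samples) absent from either input are
    dropped; the surviving identifiers are sorted lexicographically so
    the result is order-independent.
    """
    genes = sorted(set(expression.index) & set(methylation.index))
    samples = sorted(
        set(expression.columns) & set(methylation.columns) & set(labels.index)
    )
    if not genes or not samples:
        raise PreprocessError("no matched genes/samples between the two omics")
    return PairedOmics(
        gene_ids=list(genes),
        sample_ids=list(samples),
        expression=expression.loc[genes, samples].to_numpy(dtype=float),
        methylation=methylation.loc[genes, samples].to_numpy(dtype=float),
        labels=labels.loc[samples].to_numpy(dtype=int),
    )


def zero_mean_normalize(matrix: np.ndarray) -> np.ndarray:
    """Center every row at mean zero; row variance is unchanged."""
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise PreprocessError("matrix contains non-finite values")
    return matrix - matrix.mean(axis=1, keepdims=True)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped to [0, 1])."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance
    prior (d0, s0^2) from log sample variances.

    Matches the classic moderated-t hyperparameter fit: with z = log s^2,
    E z = log s0^2 + psi(df/2) - log(df/2) - [psi(d0/2) - log(d0/2)] and
    Var z = psi'(df/2) + psi'(d0/2); d0 is recovered by inverting the
    trigamma function with Newton iterations.
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if z.size > 1 else 0.0
    excess = e_var - special.polygamma(1, df / 2.0)
    if excess <= 0:
        # No between-probe variance heterogeneity: infinite prior df.
        return np.inf, float(np.exp(e_mean))
    # Solve trigamma(d0/2) = excess for d0/2 by Newton on y = d0/2.
    y = 0.5 + 1.0 / excess  # good starting point for trigamma inverse
    for _ in range(50):
        tri = special.polygamma(1, y)
        delta = tri * (1.0 - tri / excess) / special.polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = float(np.exp(e_mean + special.digamma(y) - np.log(y)))
    return float(d0), s0_sq


def moderated_t_test(
    matrix: np.ndarray,
    labels: np.ndarray,
    probe_ids: list[str] | None = None,
    gene_map: dict[str, str] | None = None,
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> DiffTestResult:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Per row the pooled variance s^2 is shrunk towards the moments-fitted
    prior: s~^2 = (d0 s0^2 + d s^2) / (d0 + d); the moderated t uses
    s~ and is referred to a t distribution with d + d0 degrees of
    freedom. BH adjustment is applied across all rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g1 = matrix[:, labels == 1]
    g0 = matrix[:, labels == 0]
    n1, n0 = g1.shape[1], g0.shape[1]
    if n1 < 2 or n0 < 2:
        raise PreprocessError("each group needs at least 2 samples")
    df = n1 + n0 - 2
    effect = g1.mean(axis=1) - g0.mean(axis=1)
    ss = g1.var(axis=1, ddof=1) * (n1 - 1) + g0.var(axis=1, ddof=1) * (n0 - 1)
    s2 = ss / df
    if prior_df is not None:
        d0 = float(prior_df)
        s0_sq = float(prior_s2) if prior_s2 is not None else float(np.median(s2))
    else:
        d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df_total)
    p_raw = np.where(se > 0, p_raw, 1.0)
    if probe_ids is None:
        probe_ids = [f"row{i}" for i in range(matrix.shape[0])]
    if gene_map is None:
        gene_map = {p: p for p in probe_ids}
    return DiffTestResult(
        probe_ids=list(probe_ids),
        gene_map=dict(gene_map),
        effect=effect,
        t=t,
        p_raw=p_raw,
        p_adj=benjamini_hochberg(p_raw),
        df_prior=float(d0),
        s2_prior=s0_sq,
    )


def collapse_probes(result: DiffTestResult) -> pd.DataFrame:
    """Keep one probe per gene: minimum adjusted p, ties by probe ID.

    Returns a frame indexed by gene with the retained probe's statistics.
    """
    frame = result.as_frame()
    frame = frame.sort_values(["gene", "p_adj", "probe"], kind="stable")
    kept = frame.groupby("gene", sort=True).head(1).set_index("gene")
    return kept


def select_significant_intersection(
    expr_result: DiffTestResult,
    meth_result: DiffTestResult,
    ppi_genes: set[str],
    alpha: float = 0.05,
) -> list[str]:
    """Genes with adjusted p < alpha in BOTH omics and present in the PPI
    universe, sorted lexicographically."""
    if not 0.0 < alpha < 1.0:
        raise PreprocessError(f"alpha must be in (0, 1), got {alpha}")
    expr_genes = _significant_genes(expr_result, alpha)
    meth_genes = _significant_genes(meth_result, alpha)
    selected = sorted(expr_genes & meth_genes & set(ppi_genes))
    if not selected:
        warnings.warn("no genes pass the two-omics significance filter", stacklevel=2)
    return selected


def _significant_genes(result: DiffTestResult, alpha: float) -> set[str]:
    collapsed = collapse_probes(result)
    return set(collapsed.index[collapsed["p_adj"] < alpha])
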