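"""Combined co-expression/co-methylation network and dynamic thresholds.

The pairwise similarity is the product of the expression correlation, a
functional-similarity weight and the methylation correlation, min-max
normalized over all off-diagonal pairs into [0, 1]. Its complement,
masked by the PPI adjacency, weights a gene graph whose all-pairs
shortest distances drive per-gene-pair threshold modifiers: pairs closer
than the median distance get a threshold above the user minimum, distant
pairs a lower one. Per-gene-set thresholds average the pairwise values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from omicsrules.discretize import item_gene

#: Gaussian consistency factor for the median absolute deviation.
MAD_SCALE = 1.4826
#: Default damping factor on the distance deviation term.
DEFAULT_C1 = 0.10


class NetdistError(ValueError):
    pass


@dataclass
class PairMatrix:
    """Symmetric gene x gene matrix with an explicit gene ordering."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise NetdistError(f"expected {n}x{n} matrix, got {self.values.shape}")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-12,
        ) and np.array_equal(finite, finite.T)
        if not sym_ok:
            raise NetdistError("matrix is not symmetric")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def loc(self, p: str, q: str) -> float:
        return float(self.values[self._index[p], self._index[q]])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (unordered-pair) values, finite or not."""
        iu = np.triu_indices(len(self.gene_ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)


@dataclass
class ThresholdParams:
    """User minimum thresholds and the deviation-scaling constants."""

    uv_min_s: float = 0.1
    uv_min_c: float = 0.1
    ud_min_l: float = 1.0
    c1: float = DEFAULT_C1
    c2: float = MAD_SCALE

    def __post_init__(self) -> None:
        if not 0.0 < self.uv_min_s <= 1.0:
            raise NetdistError(f"uv_min_s must be in (0, 1], got {self.uv_min_s}")
        if not 0.0 < self.uv_min_c <= 1.0:
            raise NetdistError(f"uv_min_c must be in (0, 1], got {self.uv_min_c}")
        if self.ud_min_l <= 0:
            raise NetdistError(f"ud_min_l must be > 0, got {self.ud_min_l}")
        if self.c1 <= 0 or self.c2 <= 0:
            raise NetdistError("c1 and c2 must be positive")


def _safe_corr(rows: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows correlate as 0."""
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance rows: correlations set to 0",
            stacklevel=3,
        )
    centered = rows - rows.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * rows.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = centered @ centered.T / denom
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, np.where(degenerate, 0.0, 1.0))
    return np.clip(corr, -1.0, 1.0)


def cecm(
    expression: np.ndarray,
    methylation: np.ndarray,
    gene_ids: list[str],
    biosim: PairMatrix | None = None,
) -> PairMatrix:
    """Normalized combined co-expression/co-methylation similarity.

    Raw value per pair = corr(expr_p, expr_q) * biosim(p, q) *
    corr(meth_p, meth_q); the raw off-diagonal values are min-max
    normalized into [0, 1] (diagonal included in the mapping but pinned
    to the image of its raw value).
    """
    if expression.shape[1] < 3:
        raise NetdistError("need at least 3 samples for correlations")
    r_ex = _safe_corr(expression)
    r_m = _safe_corr(methylation)
    if biosim is None:
        sim = np.ones_like(r_ex)
    else:
        if list(biosim.gene_ids) != list(gene_ids):
            sim = biosim.to_frame().loc[gene_ids, gene_ids].to_numpy()
        else:
            sim = biosim.values
        if np.nanmin(sim) < 0 or np.nanmax(sim) > 1:
            raise NetdistError("functional-similarity values must lie in [0, 1]")
    raw = r_ex * sim * r_m
    iu = np.triu_indices(len(gene_ids), k=1)
    off = raw[iu]
    lo, hi = off.min(), off.max()
    if hi > lo:
        scaled = (raw - lo) / (hi - lo)
    else:
        warnings.warn("degenerate similarity spread; all pairs set to 1", stacklevel=2)
        scaled = np.ones_like(raw)
    return PairMatrix(list(gene_ids), np.clip(scaled, 0.0, 1.0))


def dissimilarity(cecm_matrix: PairMatrix) -> PairMatrix:
    """Elementwise complement 1 - CECM."""
    return PairMatrix(list(cecm_matrix.gene_ids), 1.0 - cecm_matrix.values)


def ppi_adjacency(edges: list[tuple[str, str]] | list[tuple[str, str, float]],
                  gene_ids: list[str]) -> PairMatrix:
    """Symmetric adjacency over ``gene_ids`` from an edge list.

    Unweighted edges get weight 1; self-loops are dropped; edges touching
    genes outside ``gene_ids`` are ignored.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    h = np.zeros((len(gene_ids), len(gene_ids)))
    for edge in edges:
        u, v = edge[0], edge[1]
        w = float(edge[2]) if len(edge) > 2 else 1.0
        if u == v or u not in index or v not in index:
            continue
        h[index[u], index[v]] = w
        h[index[v], index[u]] = w
    return PairMatrix(list(gene_ids), h)


def mask_with_ppi(dissim: PairMatrix, adjacency: PairMatrix) -> nx.Graph:
    """Weighted graph with an edge iff the PPI adjacency is non-zero;
    weight = adjacency * dissimilarity. Every gene is a node, so genes
    without interactions become isolated nodes."""
    if list(dissim.gene_ids) != list(adjacency.gene_ids):
        adjacency = PairMatrix(
            list(dissim.gene_ids),
            adjacency.to_frame()
            .reindex(index=dissim.gene_ids, columns=dissim.gene_ids, fill_value=0.0)
            .to_numpy(),
        )
    graph = nx.Graph()
    graph.add_nodes_from(dissim.gene_ids)
    n = len(dissim.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            h = adjacency.values[i, j]
            if h != 0:
                graph.add_edge(
                    dissim.gene_ids[i],
                    dissim.gene_ids[j],
                    weight=h * dissim.values[i, j],
                )
    return graph


def all_pairs_wesd(graph: nx.Graph) -> PairMatrix:
    """All-pairs weighted shortest distances (Dijkstra).

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    for _, _, w in graph.edges.data("weight"):
        if w < 0:
            raise NetdistError("negative edge weight")
    genes = list(graph.nodes)
    index = {g: i for i, g in enumerate(genes)}
    values = np.full((len(genes), len(genes)), np.inf)
    np.fill_diagonal(values, 0.0)
    for source, dists in nx.all_pairs_dijkstra_path_length(graph, weight="weight"):
        i = index[source]
        for target, d in dists.items():
            values[i, index[target]] = d
    return PairMatrix(genes, values)


def wesd_stats(wesd: PairMatrix) -> dict[str, float]:
    """Max/min/avg/median/MAD of the finite off-diagonal distances."""
    off = wesd.offdiag()
    finite = off[np.isfinite(off)]
    if finite.size == 0:
        return {"max": np.nan, "min": np.nan, "avg": np.nan, "med": np.nan, "mad": np.nan}
    med = float(np.median(finite))
    return {
        "max": float(finite.max()),
        "min": float(finite.min()),
        "avg": float(finite.mean()),
        "med": med,
        "mad": float(np.median(np.abs(finite - med))),
    }


def wv_threshold_matrix(
    wesd: PairMatrix,
    uv_min: float,
    c1: float = DEFAULT_C1,
    c2: float = MAD_SCALE,
) -> PairMatrix:
    """Per-pair dynamic threshold derived from the distance matrix.

    Off-diagonal: uv_min * (1 - c1 * (d - med) / (c2 * MAD)), clamped at
    0 from below; diagonal and unreachable pairs fall back to uv_min.
    With MAD = 0 (degenerate spread) every pair gets uv_min.
    """
    stats_ = wesd_stats(wesd)
    med, mad = stats_["med"], stats_["mad"]
    n = len(wesd.gene_ids)
    if not np.isfinite(med) or mad == 0 or not np.isfinite(mad):
        if mad == 0:
            warnings.warn(
                "degenerate distance spread (MAD = 0); thresholds fall back to the "
                "user minimum",
                stacklevel=2,
            )
        return PairMatrix(list(wesd.gene_ids), np.full((n, n), uv_min))
    with np.errstate(invalid="ignore"):
        values = uv_min * (1.0 - c1 * (wesd.values - med) / (c2 * mad))
    values = np.where(np.isfinite(wesd.values), values, uv_min)
    np.fill_diagonal(values, uv_min)
    return PairMatrix(list(wesd.gene_ids), np.maximum(values, 0.0))


def wv_threshold(
    p: str,
    q: str,
    wesd: PairMatrix,
    uv_min: float,
    c1: float = DEFAULT_C1,
    c2: float = MAD_SCALE,
) -> float:
    """Single-pair form of :func:`wv_threshold_matrix`."""
    if p == q:
        return uv_min
    return wv_threshold_matrix(wesd, uv_min, c1, c2).loc(p, q)


def _gene_pairs(items: set[str] | frozenset[str]) -> tuple[list[str], list[tuple[str, str]]]:
    genes = sorted({item_gene(it) for it in items})
    return genes, list(itertools.combinations(genes, 2))


def dbv_threshold(items: set[str] | frozenset[str], wv: PairMatrix, uv_min: float) -> float:
    """Per-gene-set dynamic threshold: mean of the pairwise threshold
    values over all unordered gene pairs of the set (directional items
    are collapsed to their genes); singletons fall back to uv_min."""
    _, pairs = _gene_pairs(items)
    if not pairs:
        return uv_min
    return float(np.mean([wv.loc(p, q) for p, q in pairs]))


def avg_wesd(items: set[str] | frozenset[str], wesd: PairMatrix) -> float:
    """Mean shortest distance over the unordered gene pairs of a rule's
    full gene set; unreachable pairs contribute the maximum finite
    distance; sets collapsing to a single gene give 0."""
    genes, pairs = _gene_pairs(items)
    if not pairs:
        if len(items) > 1:
            warnings.warn(
                f"items {sorted(items)} collapse to the single gene {genes[0]}",
                stacklevel=2,
            )
        return 0.0
    finite_max = wesd_stats(wesd)["max"]
    dists = []
    for p, q in pairs:
        d = wesd.loc(p, q)
        if not math.isfinite(d):
            d = finite_max if math.isfinite(finite_max) else 0.0
        dists.append(d)
    return float(np.mean(dists))
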