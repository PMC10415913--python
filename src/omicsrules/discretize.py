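"""Discretization of normalized paired omics into directional items.

A gene becomes the item ``GENE+`` in a sample when it is up-regulated
(expression > 0 after row centering) AND hypo-methylated (methylation
< 0), and ``GENE-`` when down-regulated AND hyper-methylated. Discordant
expression/methylation states produce no item. Exactly-zero values map
to 0 in both binary matrices, so constant rows never create items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from omicsrules.preprocess import PairedOmics

UP_SUFFIX = "+"
DOWN_SUFFIX = "-"


@dataclass
class DiscretizedPair:
    """Binary genes x samples matrices for expression and methylation."""

    gene_ids: list[str]
    sample_ids: list[str]
    ddie: np.ndarray  # 1 = up-regulated
    ddim: np.ndarray  # 1 = hypo-methylated

    def __post_init__(self) -> None:
        if self.ddie.shape != self.ddim.shape:
            raise ValueError("expression/methylation shapes differ")
        if self.ddie.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match identifiers")


@dataclass
class PostDiscretized:
    """Samples x 2n binary matrix; column i is GENE_i+ and column i+n is
    GENE_i-. A gene is never '+' and '-' in the same sample."""

    sample_ids: list[str]
    item_ids: list[str]
    pdid: np.ndarray

    def __post_init__(self) -> None:
        if self.pdid.shape != (len(self.sample_ids), len(self.item_ids)):
            raise ValueError("matrix shape does not match identifiers")
        n = len(self.item_ids) // 2
        if np.any(self.pdid[:, :n] + self.pdid[:, n:] > 1):
            raise ValueError("a gene is simultaneously '+' and '-'")


@dataclass
class TransactionDB:
    """One item set per sample; empty transactions are retained."""

    sample_ids: list[str]
    transactions: list[frozenset[str]]
    item_ids: list[str]

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)


def item_name(gene: str, up: bool) -> str:
    return gene + (UP_SUFFIX if up else DOWN_SUFFIX)


def item_gene(item: str) -> str:
    """Strip the directional suffix from an item ID."""
    if item.endswith((UP_SUFFIX, DOWN_SUFFIX)):
        return item[:-1]
    return item


def discretize_expression(die_norm: np.ndarray) -> np.ndarray:
    """1 where value > 0 (up-regulated), else 0."""
    return (np.asarray(die_norm, dtype=float) > 0).astype(np.int8)


def discretize_methylation(dim_norm: np.ndarray) -> np.ndarray:
    """1 where value < 0 (hypo-methylated), else 0."""
    return (np.asarray(dim_norm, dtype=float) < 0).astype(np.int8)


def discretize_pair(omics: PairedOmics) -> DiscretizedPair:
    return DiscretizedPair(
        gene_ids=list(omics.gene_ids),
        sample_ids=list(omics.sample_ids),
        ddie=discretize_expression(omics.expression),
        ddim=discretize_methylation(omics.methylation),
    )


def post_discretize(pair: DiscretizedPair) -> PostDiscretized:
    """Merge the transposed binary matrices into one samples x 2n matrix.

    (E=1, M=1) sets the first-half column, (E=0, M=0) the second-half
    column; discordant combinations set neither.
    """
    e_t = pair.ddie.T  # samples x genes
    m_t = pair.ddim.T
    up = ((e_t == 1) & (m_t == 1)).astype(np.int8)
    down = ((e_t == 0) & (m_t == 0)).astype(np.int8)
    items = [item_name(g, up=True) for g in pair.gene_ids] + [
        item_name(g, up=False) for g in pair.gene_ids
    ]
    return PostDiscretized(
        sample_ids=list(pair.sample_ids),
        item_ids=items,
        pdid=np.hstack([up, down]),
    )


def to_transactions(post: PostDiscretized) -> TransactionDB:
    """One transaction per sample holding the item IDs set to 1."""
    item_arr = np.asarray(post.item_ids, dtype=object)
    transactions = [
        frozenset(item_arr[row.astype(bool)]) for row in post.pdid
    ]
    return TransactionDB(
        sample_ids=list(post.sample_ids),
        transactions=transactions,
        item_ids=list(post.item_ids),
    )
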