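"""TOPSIS multi-criteria ranking of mined rules.

Criteria are support, confidence and lift (benefit — higher is better)
and the rule's average network distance (cost — lower is better). Each
rule's city-block distances to the per-criterion best (PIS) and worst
(NIS) vectors give a relative closeness score in (0, 1); rules are
ranked by descending closeness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from omicsrules.mining import Rule

CRITERIA = ("support", "confidence", "lift", "avg_wesd")
#: benefit criteria are maximized, cost criteria minimized
ORIENTATION = {"support": "benefit", "confidence": "benefit", "lift": "benefit",
               "avg_wesd": "cost"}


class RankingError(ValueError):
    pass


@dataclass
class DecisionMatrix:
    """Rules x criteria value matrix with per-criterion orientation."""

    labels: list[str]
    criteria: list[str]
    values: np.ndarray
    benefit: np.ndarray  # bool per criterion
    weights: np.ndarray
    rules: list[Rule] | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] == 0:
            raise RankingError("decision matrix needs at least one rule")
        if self.values.shape != (len(self.labels), len(self.criteria)):
            raise RankingError("matrix shape does not match labels/criteria")
        if not np.all(np.isfinite(self.values)):
            raise RankingError("decision matrix contains non-finite values")


@dataclass
class RankedRuleTable:
    """Per-rule TOPSIS outcome, ordered as the input rules."""

    labels: list[str]
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray
    is_final: np.ndarray
    rules: list[Rule] | None = None
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "rule": self.labels,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "relative_score": self.closeness,
                "rank": self.rank,
                "final": self.is_final,
            }
        )
        if self.rules is not None:
            frame.insert(1, "confidence", [r.confidence for r in self.rules])
            frame.insert(2, "support", [r.support for r in self.rules])
            frame.insert(3, "lift", [r.lift for r in self.rules])
            frame.insert(4, "avg_wesd", [r.avg_wesd for r in self.rules])
        return frame.sort_values("rank").reset_index(drop=True)


def build_decision_matrix(
    rules: list[Rule],
    normalization: str = "none",
    weights: np.ndarray | None = None,
) -> DecisionMatrix:
    """Populate the rules x 4 criteria matrix, optionally normalized.

    ``normalization``: "none" (raw metric values), "minmax" (each column
    rescaled to [0, 1]) or "vector" (each column divided by its
    Euclidean norm). Weights default to equal.
    """
    if not rules:
        raise RankingError("no rules to rank")
    values = np.array(
        [[r.support, r.confidence, r.lift, r.avg_wesd] for r in rules], dtype=float
    )
    if normalization == "minmax":
        lo, hi = values.min(axis=0), values.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        values = (values - lo) / span
    elif normalization == "vector":
        norm = np.linalg.norm(values, axis=0)
        values = values / np.where(norm > 0, norm, 1.0)
    elif normalization != "none":
        raise RankingError(f"unknown normalization {normalization!r}")
    if weights is None:
        weights = np.ones(len(CRITERIA))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(CRITERIA),) or np.any(weights < 0) or weights.sum() == 0:
        raise RankingError("weights must be 4 non-negative values, not all zero")
    return DecisionMatrix(
        labels=[r.label() for r in rules],
        criteria=list(CRITERIA),
        values=values * weights,
        benefit=np.array([ORIENTATION[c] == "benefit" for c in CRITERIA]),
        weights=weights,
        rules=list(rules),
        normalization=normalization,
    )


def pis_nis(matrix: DecisionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative ideal vectors: column max (benefit) or min
    (cost) for PIS, and the reverse for NIS."""
    col_max = matrix.values.max(axis=0)
    col_min = matrix.values.min(axis=0)
    pis = np.where(matrix.benefit, col_max, col_min)
    nis = np.where(matrix.benefit, col_min, col_max)
    return pis, nis


def topsis_distances(
    matrix: DecisionMatrix,
    pis: np.ndarray,
    nis: np.ndarray,
    metric: str = "cityblock",
) -> tuple[np.ndarray, np.ndarray]:
    """Distances of every rule to PIS and NIS.

    City-block (sum of absolute differences) by default; "euclidean"
    selects the root-sum-square form.
    """
    diff_plus = np.abs(pis - matrix.values)
    diff_minus = np.abs(matrix.values - nis)
    if metric == "cityblock":
        return diff_plus.sum(axis=1), diff_minus.sum(axis=1)
    if metric == "euclidean":
        return (
            np.sqrt((diff_plus**2).sum(axis=1)),
            np.sqrt((diff_minus**2).sum(axis=1)),
        )
    raise RankingError(f"unknown distance metric {metric!r}")


def relative_closeness(
    d_plus: np.ndarray,
    d_minus: np.ndarray,
    orientation: str = "classical",
) -> np.ndarray:
    """Relative closeness per rule.

    "classical": S = d- / (d+ + d-), so S -> 1 means closest to the
    ideal. "literal" flips the numerator to d+. Rules with d+ = d- = 0
    (PIS == NIS on every criterion) score 0.5.
    """
    if orientation not in ("classical", "literal"):
        raise RankingError(f"unknown orientation {orientation!r}")
    total = d_plus + d_minus
    degenerate = total == 0
    if degenerate.all():
        import warnings

        warnings.warn("all rules are equidistant from PIS and NIS", stacklevel=2)
    numerator = d_plus if orientation == "literal" else d_minus
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(degenerate, 0.5, numerator / np.where(degenerate, 1.0, total))
    return s


def rank_scores(
    scores: np.ndarray,
    labels: list[str] | None = None,
    rules: list[Rule] | None = None,
) -> np.ndarray:
    """Descending-order ranks (1 = largest score).

    Ties are broken by higher support, then higher confidence, then the
    lexicographically smallest rule label; without rule metadata the
    label alone breaks ties, and without labels the input order does.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if labels is None:
        labels = [""] * n
    if rules is not None:
        key = [
            (-scores[i], -rules[i].support, -rules[i].confidence, labels[i], i)
            for i in range(n)
        ]
    else:
        key = [(-scores[i], 0.0, 0.0, labels[i], i) for i in range(n)]
    order = sorted(range(n), key=lambda i: key[i])
    rank = np.empty(n, dtype=int)
    for position, i in enumerate(order, start=1):
        rank[i] = position
    return rank


def rank_rules(
    matrix: DecisionMatrix,
    closeness_threshold: float | None = None,
    distance: str = "cityblock",
    orientation: str = "classical",
) -> RankedRuleTable:
    """Full TOPSIS pass: ideal vectors, distances, closeness, ranks.

    Rules scoring below ``closeness_threshold`` are flagged not-final
    but still reported.
    """
    pis, nis = pis_nis(matrix)
    d_plus, d_minus = topsis_distances(matrix, pis, nis, metric=distance)
    closeness = relative_closeness(d_plus, d_minus, orientation=orientation)
    rank = rank_scores(closeness, labels=matrix.labels, rules=matrix.rules)
    if closeness_threshold is None:
        is_final = np.ones(len(closeness), dtype=bool)
    else:
        is_final = closeness >= closeness_threshold
    return RankedRuleTable(
        labels=list(matrix.labels),
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=closeness,
        rank=rank,
        is_final=is_final,
        rules=matrix.rules,
        config={
            "normalization": matrix.normalization,
            "distance": distance,
            "orientation": orientation,
            "closeness_threshold": closeness_threshold,
        },
    )
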