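"""File formats and pipeline configuration.

All inputs and outputs are plain text: matrices as TSV/CSV with a gene
identifier column and sample-ID header, labels as a two-column TSV, PPI
interactions as an edge list, transactions in basket format, rules as
TSV or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from omicsrules.discretize import TransactionDB
from omicsrules.mining import GeneSetRecord, Rule
from omicsrules.netdist import PairMatrix


class FormatError(ValueError):
    pass


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Numeric matrix with gene/probe IDs in the first column and sample
    IDs in the header.

    Duplicate gene IDs are allowed (multiple probes per gene); duplicate
    sample IDs are rejected. Non-numeric cells and ragged rows raise a
    :class:`FormatError` with coordinates.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        n_cols = len(header)
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise FormatError(f"duplicate sample IDs in {path}: {dupes}")
        gene_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                    ) from None
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return pd.DataFrame(np.asarray(rows), index=gene_ids, columns=sample_ids)


def write_matrix(frame: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    frame.to_csv(path, sep=_sep_for(path), index_label=index_label)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column sample/label file -> 0/1 Series indexed by sample."""
    frame = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample, label)")
    series = pd.Series(
        frame.iloc[:, 1].astype(int).to_numpy(), index=frame.iloc[:, 0]
    )
    if series.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs")
    return series


def read_edge_list(path: str | Path) -> list[tuple[str, str] | tuple[str, str, float]]:
    """PPI edges: two gene IDs per line, optional third weight column."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least two columns")
            if len(parts) >= 3:
                edges.append((parts[0], parts[1], float(parts[2])))
            else:
                edges.append((parts[0], parts[1]))
    return edges


def read_square_matrix(path: str | Path) -> PairMatrix:
    frame = read_matrix(path)
    if list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: row and column identifiers differ")
    return PairMatrix(list(frame.index), frame.to_numpy())


def write_square_matrix(matrix: PairMatrix, path: str | Path) -> None:
    write_matrix(matrix.to_frame(), path)


def write_transactions(db: TransactionDB, path: str | Path) -> None:
    """Basket format: sample ID, tab, comma-separated sorted item IDs."""
    with open(path, "w") as fh:
        for sample, tx in zip(db.sample_ids, db.transactions):
            fh.write(f"{sample}\t{','.join(sorted(tx))}\n")


def read_transactions(path: str | Path) -> TransactionDB:
    sample_ids, transactions = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample, _, items = line.partition("\t")
            sample_ids.append(sample)
            transactions.append(
                frozenset(it for it in items.split(",") if it)
            )
    item_ids = sorted({it for tx in transactions for it in tx})
    return TransactionDB(sample_ids=sample_ids, transactions=transactions,
                         item_ids=item_ids)


RULE_COLUMNS = [
    "antecedent", "consequent", "support", "confidence", "lift",
    "avg_wesd", "dbvc", "dbvl",
]


def rules_to_frame(rules: list[Rule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "antecedent": ",".join(sorted(r.antecedent)),
                "consequent": ",".join(sorted(r.consequent)),
                "support": r.support,
                "confidence": r.confidence,
                "lift": r.lift,
                "avg_wesd": r.avg_wesd,
                "dbvc": r.dbvc,
                "dbvl": r.dbvl,
            }
            for r in rules
        ],
        columns=RULE_COLUMNS,
    )


def write_rules(rules: list[Rule], path: str | Path) -> None:
    path = Path(path)
    frame = rules_to_frame(rules)
    if path.suffix == ".json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        frame.to_csv(path, sep="\t", index=False)


def read_rules(path: str | Path) -> list[Rule]:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, sep="\t").to_dict(orient="records")
    return [
        Rule(
            antecedent=frozenset(str(rec["antecedent"]).split(",")),
            consequent=frozenset(str(rec["consequent"]).split(",")),
            support=float(rec["support"]),
            confidence=float(rec["confidence"]),
            lift=float(rec["lift"]),
            avg_wesd=float(rec.get("avg_wesd", np.nan)),
            dbvc=float(rec.get("dbvc", np.nan)),
            dbvl=float(rec.get("dbvl", np.nan)),
        )
        for rec in records
    ]


def write_gene_sets(records: list[GeneSetRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "items": ",".join(sorted(r.items)),
                "support": r.support,
                "count": r.count,
                "dbvs": r.dbvs if r.dbvs is not None else np.nan,
            }
            for r in records
        ],
        columns=["items", "support", "count", "dbvs"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    expression: str = ""
    methylation: str = ""
    labels: str = ""
    ppi: str = ""
    similarity: str | None = None
    output_dir: str = "results"
    uv_min_s: float = 0.1
    uv_min_c: float = 0.1
    ud_min_l: float = 1.0
    c1: float = 0.10
    c2: float = 1.4826
    alpha: float = 0.05
    max_itemset_size: int = 4
    support_is_absolute: bool = False
    topsis_normalization: str = "none"
    topsis_distance: str = "cityblock"
    topsis_orientation: str = "classical"
    topsis_weights: list[float] | None = None
    closeness_threshold: float | None = None
    evaluate_top_k: int = 0
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise FormatError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_itemset_size < 1:
            raise FormatError("max_itemset_size must be >= 1")
        if self.topsis_normalization not in ("none", "minmax", "vector"):
            raise FormatError(f"unknown normalization {self.topsis_normalization!r}")
        if self.topsis_distance not in ("cityblock", "euclidean"):
            raise FormatError(f"unknown distance {self.topsis_distance!r}")
        if self.topsis_orientation not in ("classical", "literal"):
            raise FormatError(f"unknown orientation {self.topsis_orientation!r}")
        if self.cv_folds < 2:
            raise FormatError("cv_folds must be >= 2")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load YAML or JSON config; unknown keys are rejected; keyword
    overrides win over file values."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise FormatError(f"{path}: unknown config keys {unknown}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
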