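"""Synthetic paired expression/methylation datasets with planted modules.

Each planted module is a small set of genes that is (a) differentially
expressed AND differentially methylated between the two sample groups,
with expression and methylation shifted in opposite directions
(methylation suppresses expression), and (b) fully connected in the
emitted PPI edge list. Background genes carry i.i.d. Gaussian noise and
sparse random edges. The generator is fully deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from omicsrules.preprocess import PairedOmics

#: planted per-gene direction: expression up + methylation down in cases
UP_HYPO = "up-hypo"
#: expression down + methylation up in cases
DOWN_HYPER = "down-hyper"


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    n_genes: int = 30
    n_samples_case: int = 13
    n_samples_control: int = 13
    n_modules: int = 2
    module_size: int = 3
    effect_size: float = 4.0
    noise_sd: float = 1.0
    ppi_background_density: float = 0.05
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples_case", "n_samples_control", "probes_per_gene"):
            if getattr(self, name) < 1:
                raise SynthConfigError(f"{name} must be a positive integer")
        if self.n_modules < 0:
            raise SynthConfigError("n_modules must be non-negative")
        if self.n_modules > 0 and self.module_size < 2:
            raise SynthConfigError("module_size must be at least 2")
        if self.n_modules * self.module_size > self.n_genes:
            raise SynthConfigError(
                "module_size * n_modules exceeds n_genes "
                f"({self.module_size} * {self.n_modules} > {self.n_genes})"
            )
        if self.effect_size <= 0:
            raise SynthConfigError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise SynthConfigError("noise_sd must be > 0")
        if not 0.0 <= self.ppi_background_density <= 1.0:
            raise SynthConfigError("ppi_background_density must be in [0, 1]")


@dataclass
class SynthTruth:
    planted_modules: list[list[str]]
    planted_directions: dict[str, str]
    expected_top_rules: list[list[str]]

    def planted_genes(self) -> set[str]:
        return {g for module in self.planted_modules for g in module}


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1)) if n > 1 else 1
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_paired_omics(
    config: SynthConfig,
) -> tuple[PairedOmics, list[tuple[str, str]], pd.DataFrame, SynthTruth]:
    """Generate a paired dataset, PPI edge list, similarity matrix and
    the planted ground truth.

    Case samples carry a +effect_size*noise_sd expression shift and a
    -effect_size*noise_sd methylation shift for up-hypo genes (signs
    flipped for down-hyper genes); the anti-correlation between a
    planted gene's expression and methylation arises from these opposed
    group shifts. The similarity matrix is all ones.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    n_case, n_ctrl = config.n_samples_case, config.n_samples_control
    samples = [f"case{i}" for i in range(n_case)] + [f"ctrl{i}" for i in range(n_ctrl)]
    labels = np.array([1] * n_case + [0] * n_ctrl)

    expr = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    meth = rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))

    modules: list[list[str]] = []
    directions: dict[str, str] = {}
    shift = config.effect_size * config.noise_sd
    case_cols = labels == 1
    for mod in range(config.n_modules):
        start = mod * config.module_size
        members = genes[start : start + config.module_size]
        modules.append(members)
        for g in members:
            row = genes.index(g)
            direction = UP_HYPO if rng.random() < 0.5 else DOWN_HYPER
            directions[g] = direction
            sign = 1.0 if direction == UP_HYPO else -1.0
            expr[row, case_cols] += sign * shift
            meth[row, case_cols] -= sign * shift

    edges: set[tuple[str, str]] = set()
    for members in modules:
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                edges.add((u, v))
    for i in range(config.n_genes):
        for j in range(i + 1, config.n_genes):
            pair = (genes[i], genes[j])
            if pair in edges:
                continue
            if rng.random() < config.ppi_background_density:
                edges.add(pair)
    edge_list = sorted(edges)

    similarity = pd.DataFrame(
        np.ones((config.n_genes, config.n_genes)), index=genes, columns=genes
    )

    expected_rules = [
        [g + ("+" if directions[g] == UP_HYPO else "-") for g in members]
        for members in modules
    ]
    truth = SynthTruth(
        planted_modules=modules,
        planted_directions=directions,
        expected_top_rules=expected_rules,
    )
    omics = PairedOmics(
        gene_ids=genes,
        sample_ids=samples,
        expression=expr,
        methylation=meth,
        labels=labels,
    )
    return omics, edge_list, similarity, truth


def expand_probes(omics: PairedOmics, probes_per_gene: int, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Duplicate each gene into k jittered probe rows (expression and
    methylation frames indexed by probe) plus the probe -> gene map."""
    rng = np.random.default_rng(seed)
    probe_ids, gene_map, expr_rows, meth_rows = [], {}, [], []
    for i, gene in enumerate(omics.gene_ids):
        for k in range(probes_per_gene):
            probe = f"{gene}_p{k}"
            probe_ids.append(probe)
            gene_map[probe] = gene
            jitter_e = rng.normal(0, 0.1, omics.n_samples) if k else 0.0
            jitter_m = rng.normal(0, 0.1, omics.n_samples) if k else 0.0
            expr_rows.append(omics.expression[i] + jitter_e)
            meth_rows.append(omics.methylation[i] + jitter_m)
    expr = pd.DataFrame(expr_rows, index=probe_ids, columns=omics.sample_ids)
    meth = pd.DataFrame(meth_rows, index=probe_ids, columns=omics.sample_ids)
    return expr, meth, gene_map


def write_dataset(
    directory: str | Path,
    omics: PairedOmics,
    edges: list[tuple[str, str]],
    similarity: pd.DataFrame,
    truth: SynthTruth,
) -> dict[str, Path]:
    """Write the generated dataset as plain TSV/JSON files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "methylation": directory / "methylation.tsv",
        "labels": directory / "labels.tsv",
        "ppi": directory / "ppi_edges.tsv",
        "similarity": directory / "similarity.tsv",
        "truth": directory / "truth.json",
    }
    expr = pd.DataFrame(omics.expression, index=omics.gene_ids, columns=omics.sample_ids)
    meth = pd.DataFrame(omics.methylation, index=omics.gene_ids, columns=omics.sample_ids)
    expr.to_csv(paths["expression"], sep="\t", index_label="gene")
    meth.to_csv(paths["methylation"], sep="\t", index_label="gene")
    pd.DataFrame({"sample": omics.sample_ids, "label": omics.labels}).to_csv(
        paths["labels"], sep="\t", index=False
    )
    with open(paths["ppi"], "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")
    similarity.to_csv(paths["similarity"], sep="\t", index_label="gene")
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=2)
    return paths
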