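"""End-to-end pipeline driver.

Stages: match/normalize -> two-omics differential selection ->
discretization -> network distances and dynamic thresholds -> FP-growth
mining with dynamic filters -> TOPSIS ranking (-> optional per-rule
classification). Every intermediate artifact is written as plain text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from omicsrules import io as oio
from omicsrules.discretize import discretize_pair, post_discretize, to_transactions
from omicsrules.evaluate import evaluate_rule
from omicsrules.mining import mine_rules
from omicsrules.netdist import (
    PairMatrix,
    ThresholdParams,
    all_pairs_wesd,
    cecm,
    dissimilarity,
    mask_with_ppi,
    ppi_adjacency,
    wv_threshold_matrix,
)
from omicsrules.preprocess import (
    PairedOmics,
    match_omics,
    moderated_t_test,
    select_significant_intersection,
    zero_mean_normalize,
)
from omicsrules.ranking import RankedRuleTable, build_decision_matrix, rank_rules

log = logging.getLogger("omicsrules")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    ranked: RankedRuleTable | None
    counts: dict[str, int] = field(default_factory=dict)
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: oio.PipelineConfig) -> PipelineResult:
    """Execute the full pipeline per the loaded configuration.

    Returns a ranked rule table (None when no genes/rules survive) plus
    per-stage counts and the written artifact paths.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    def _stage(name: str):
        log.info("stage: %s", name)
        return name

    stage = _stage("read")
    try:
        expr = oio.read_matrix(config.expression)
        meth = oio.read_matrix(config.methylation)
        labels = oio.read_labels(config.labels)
        edges = oio.read_edge_list(config.ppi)
        biosim_frame = (
            oio.read_matrix(config.similarity) if config.similarity else None
        )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("preprocess")
    try:
        # Matching operates on probe-level rows; duplicate-probe rows of
        # the same gene are distinguished positionally via unique probe
        # IDs assigned by the reader contract (index may repeat).
        probe_expr = expr[~expr.isna().any(axis=1)]
        probe_meth = meth[~meth.isna().any(axis=1)]
        shared_samples = sorted(
            set(probe_expr.columns) & set(probe_meth.columns) & set(labels.index)
        )
        if not shared_samples:
            raise PipelineError(stage, "no matched samples")
        label_vec = labels.loc[shared_samples].to_numpy(dtype=int)

        expr_norm = zero_mean_normalize(probe_expr[shared_samples].to_numpy())
        meth_norm = zero_mean_normalize(probe_meth[shared_samples].to_numpy())
        expr_res = moderated_t_test(
            expr_norm, label_vec,
            probe_ids=[f"e{i}" for i in range(len(probe_expr))],
            gene_map={f"e{i}": g for i, g in enumerate(probe_expr.index)},
        )
        meth_res = moderated_t_test(
            meth_norm, label_vec,
            probe_ids=[f"m{i}" for i in range(len(probe_meth))],
            gene_map={f"m{i}": g for i, g in enumerate(probe_meth.index)},
        )
        ppi_genes = {g for e in edges for g in e[:2]}
        selected = select_significant_intersection(
            expr_res, meth_res, ppi_genes, alpha=config.alpha
        )
        counts["genes_matched"] = len(set(probe_expr.index) & set(probe_meth.index))
        counts["genes_significant"] = len(selected)
        stats = pd.concat(
            [expr_res.as_frame().assign(omics="expression"),
             meth_res.as_frame().assign(omics="methylation")]
        )
        artifacts["probe_stats"] = out / "probe_stats.tsv"
        stats.to_csv(artifacts["probe_stats"], sep="\t", index=False)
        artifacts["selected_genes"] = out / "selected_genes.txt"
        artifacts["selected_genes"].write_text("\n".join(selected) + "\n")
        if not selected:
            log.warning("no significant genes; stopping gracefully")
            return PipelineResult(ranked=None, counts=counts, artifacts=artifacts)

        # collapse probes: per gene keep the min-adjusted-p probe row
        from omicsrules.preprocess import collapse_probes

        expr_keep = collapse_probes(expr_res)
        meth_keep = collapse_probes(meth_res)
        probe_pos_e = {p: i for i, p in enumerate(expr_res.probe_ids)}
        probe_pos_m = {p: i for i, p in enumerate(meth_res.probe_ids)}
        rows_e = [probe_pos_e[expr_keep.loc[g, "probe"]] for g in selected]
        rows_m = [probe_pos_m[meth_keep.loc[g, "probe"]] for g in selected]
        omics = PairedOmics(
            gene_ids=list(selected),
            sample_ids=list(shared_samples),
            expression=expr_norm[rows_e],
            methylation=meth_norm[rows_m],
            labels=label_vec,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("discretize")
    try:
        post = post_discretize(discretize_pair(omics))
        db = to_transactions(post)
        artifacts["transactions"] = out / "transactions.tsv"
        oio.write_transactions(db, artifacts["transactions"])
        counts["transactions"] = db.n_transactions
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("network")
    try:
        biosim = None
        if biosim_frame is not None:
            sub = biosim_frame.loc[omics.gene_ids, omics.gene_ids]
            biosim = PairMatrix(list(omics.gene_ids), sub.to_numpy())
        cecm_m = cecm(omics.expression, omics.methylation, omics.gene_ids, biosim)
        dissim = dissimilarity(cecm_m)
        adjacency = ppi_adjacency(edges, omics.gene_ids)
        graph = mask_with_ppi(dissim, adjacency)
        wesd = all_pairs_wesd(graph)
        params = ThresholdParams(
            uv_min_s=config.uv_min_s, uv_min_c=config.uv_min_c,
            ud_min_l=config.ud_min_l, c1=config.c1, c2=config.c2,
        )
        wv_msc = wv_threshold_matrix(wesd, params.uv_min_s, params.c1, params.c2)
        wv_mcc = wv_threshold_matrix(wesd, params.uv_min_c, params.c1, params.c2)
        wv_mlc = wv_threshold_matrix(wesd, params.ud_min_l, params.c1, params.c2)
        artifacts["wesd"] = out / "wesd.tsv"
        oio.write_square_matrix(wesd, artifacts["wesd"])
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("mine")
    try:
        kept_sets, rules = mine_rules(
            db, wv_msc, wv_mcc, wv_mlc, wesd, params,
            max_size=config.max_itemset_size,
        )
        counts["frequent_sets"] = len(kept_sets)
        counts["rules"] = len(rules)
        artifacts["gene_sets"] = out / "gene_sets.tsv"
        oio.write_gene_sets(kept_sets, artifacts["gene_sets"])
        artifacts["rules"] = out / "rules.tsv"
        oio.write_rules(rules, artifacts["rules"])
        if not rules:
            log.warning("no rules pass the dynamic thresholds")
            return PipelineResult(ranked=None, counts=counts, artifacts=artifacts)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = _stage("rank")
    try:
        weights = (
            np.asarray(config.topsis_weights, dtype=float)
            if config.topsis_weights is not None
            else None
        )
        matrix = build_decision_matrix(
            rules, normalization=config.topsis_normalization, weights=weights
        )
        ranked = rank_rules(
            matrix,
            closeness_threshold=config.closeness_threshold,
            distance=config.topsis_distance,
            orientation=config.topsis_orientation,
        )
        counts["rules_ranked"] = len(ranked.labels)
        artifacts["ranked_rules"] = out / "ranked_rules.tsv"
        ranked.to_frame().to_csv(artifacts["ranked_rules"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    if config.evaluate_top_k > 0:
        stage = _stage("evaluate")
        try:
            frame = ranked.to_frame().head(config.evaluate_top_k)
            evaluations = []
            by_label = {r.label(): r for r in rules}
            for i, label in enumerate(frame["rule"]):
                ev = evaluate_rule(
                    omics, by_label[label],
                    folds=config.cv_folds, repeats=config.cv_repeats,
                    seed=config.seed + i,
                )
                evaluations.append(ev.__dict__)
            artifacts["evaluations"] = out / "rule_evaluations.tsv"
            pd.DataFrame(evaluations).to_csv(
                artifacts["evaluations"], sep="\t", index=False
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    for name, value in counts.items():
        log.info("count %s = %d", name, value)
    return PipelineResult(ranked=ranked, counts=counts, artifacts=artifacts)
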