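"""End-to-end pipeline: normalization -> differential filtering -> ratio
biomarker discovery -> two-threshold combined rule -> Bayesian network ->
metastasis/survival subgroup analysis.

Discovery (candidate filtering, ratio search, cutoff choice) uses training
specimens only; the frozen rule is then evaluated on the held-out test
specimens.  A ``split`` column in the metadata (train/test) controls the
partition; without one, every specimen is treated as training and the
evaluation is resubstitution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import bayesnet, biomarker, diffexpr, io, normalize, survival
from .biomarker import CombinedRule, RatioMarker
from .diffexpr import FilterThresholds

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    metadata_path: str | None = None
    output_dir: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    combined_rule: CombinedRule = field(default_factory=CombinedRule)
    ratio_cutoff: float = 0.06
    ratio_cutoff_strategy: str = "fixed"      # or "youden"
    ratio_pool_mode: str = "differential"     # or "abundance"
    met_cutoff: float = 0.15
    de_method: str = "welch_log"
    percentile_method: str = "linear"
    bn_top_k: int = 27
    bn_max_iter: int = 10_000
    bn_tabu_len: int = 10
    bn_patience: int = 10
    bn_score: str = "bic"
    evaluation_marker: RatioMarker | None = None  # skip discovery when given
    seed: int = 0


@dataclass
class PipelineReport:
    de_table: pd.DataFrame
    candidates: list[str]
    single_ranking: pd.DataFrame
    ratio_table: pd.DataFrame
    marker: RatioMarker | None
    confusion: dict
    bn_dag: bayesnet.Dag | None
    cancer_neighborhood: tuple | None
    met_ranked: pd.DataFrame | None
    met_ratios: pd.DataFrame | None
    km_fits: dict
    logrank: survival.LogrankResult | None
    summary: str


def _split(samples: pd.DataFrame) -> tuple[pd.Index, pd.Index]:
    if samples["split"].notna().any():
        train = samples.index[samples["split"] == "train"]
        test = samples.index[samples["split"] == "test"]
    else:
        log.info("no split column: all specimens are training (resubstitution)")
        train, test = samples.index, pd.Index([])
    return train, test


def _evaluate_rules(norm_vals: pd.DataFrame, samples: pd.DataFrame,
                    marker: RatioMarker, rule: CombinedRule) -> dict:
    """Ratio-rule and combined-rule confusion tables on the PDAC/CP specimens
    of one cohort."""
    keep = samples["diagnosis"].isin(["PDAC", "CP"])
    sub = samples.loc[keep]
    ratios = biomarker.ratio_values(norm_vals, marker.numerator_id, marker.denominator_id)
    ratios = ratios.reindex(sub.index).dropna()
    sub = sub.loc[ratios.index]
    ratio_pred = [biomarker.classify_ratio(x, marker.cutoff) for x in ratios]
    combined_pred = [
        biomarker.classify_combined(x, y if pd.notna(y) else None, rule)
        for x, y in zip(ratios, sub["ca199_u_ml"])
    ]
    truth = sub["diagnosis"].to_numpy()
    return {
        "ratio": biomarker.confusion_metrics(ratio_pred, truth),
        "combined": biomarker.confusion_metrics(combined_pred, truth),
        "decisions": pd.DataFrame({
            "x": ratios, "y": sub["ca199_u_ml"],
            "ratio_call": ratio_pred, "combined_call": combined_pred,
            "diagnosis": truth,
        }),
    }


def _format_confusion(name: str, c) -> str:
    return (f"{name}: TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp} "
            f"sensitivity={c.sensitivity}% specificity={c.specificity}%")


def run_pipeline(config: PipelineConfig,
                 counts: pd.DataFrame | None = None,
                 samples: pd.DataFrame | None = None) -> PipelineReport:
    """Run every stage and return the collected results.

    ``counts``/``samples`` may be passed directly (e.g. from the simulator);
    otherwise they are read from the configured paths.
    """
    stage = "input"
    try:
        if counts is None:
            counts = io.read_counts(config.counts_path)
        if samples is None:
            samples = io.read_metadata(config.metadata_path, counts)
        if "split" not in samples.columns:
            samples = samples.copy()
            samples["split"] = pd.NA
        if samples.empty:
            raise ValueError("empty metadata")
        train_ids, test_ids = _split(samples)
        if len(train_ids) == 0:
            raise ValueError("no training specimens")

        stage = "normalize"
        norm = {}
        for name, ids in (("train", train_ids), ("test", test_ids)):
            if len(ids) >= 2:
                norm[name] = normalize.normalize_counts(
                    counts[ids], config.percentile_method)
                log.info("stage normalize[%s]: %d miRNAs x %d specimens, "
                         "%d housekeeping", name, *norm[name].values.shape,
                         len(norm[name].housekeeping_ids))

        tr = norm["train"]
        tr_samples = samples.loc[train_ids]
        tr_labels = tr_samples["diagnosis"]

        stage = "diffexpr"
        de = diffexpr.differential_expression(
            tr.values, tr_labels, "PDAC", "CP",
            method=config.de_method, raw_counts=counts[train_ids])
        candidates = diffexpr.candidate_filter(de, config.thresholds, mode="diagnostic")
        log.info("stage diffexpr: %d/%d candidates pass the diagnostic filter",
                 len(candidates), len(de))

        stage = "biomarker"
        marker = config.evaluation_marker
        single_ranking = pd.DataFrame(columns=["mirna_id", "auc"])
        ratio_table = pd.DataFrame(columns=["numerator", "denominator", "auc", "n_evaluated"])
        pdac_cp = tr_labels.isin(["PDAC", "CP"])
        dx_cols = tr.values.columns[pdac_cp.reindex(tr.values.columns).fillna(False)]
        dx_vals = tr.values[dx_cols]
        dx_labels = tr_labels.loc[dx_cols]
        if marker is None:
            if not candidates:
                log.warning("no diagnostic candidates; skipping ratio discovery")
            else:
                single_ranking = biomarker.rank_single_markers(
                    dx_vals, dx_labels, "PDAC", candidates)
                numerator = single_ranking.iloc[0]["mirna_id"]
                if config.ratio_pool_mode == "differential":
                    pool = diffexpr.candidate_filter(de, config.thresholds, mode="metastatic")
                else:
                    pool = list(de.index[de["expressed_in_all"]
                                         & (de[[c for c in de.columns
                                                if c.startswith("mean_")]].max(axis=1)
                                            >= config.thresholds.min_mean_norm)])
                pool = [m for m in pool if m != numerator]
                if pool:
                    ratio_table = biomarker.ratio_search(
                        dx_vals, dx_labels, "PDAC", numerator, pool)
                    denominator = ratio_table.iloc[0]["denominator"]
                    rvals = biomarker.ratio_values(dx_vals, numerator, denominator)
                    rl = dx_labels.loc[rvals.index]
                    cutoff = biomarker.choose_cutoff(
                        rvals, rl, "PDAC", strategy=config.ratio_cutoff_strategy,
                        fixed=config.ratio_cutoff)
                    marker = RatioMarker(
                        numerator_id=numerator, denominator_id=denominator,
                        cutoff=cutoff,
                        auc=float(ratio_table.iloc[0]["auc"]),
                        roc_points=biomarker.roc_curve(rvals, rl, "PDAC"))
        else:
            log.info("evaluation-only mode: using supplied marker %s/%s",
                     marker.numerator_id, marker.denominator_id)

        confusion: dict = {}
        if marker is not None:
            for name in norm:
                confusion[name] = _evaluate_rules(
                    norm[name].values, samples.loc[norm[name].values.columns],
                    marker, config.combined_rule)

        stage = "bayesnet"
        bn_dag = None
        cancer_nb = None
        if len(train_ids) >= 4:
            abundant = de.index[de["expressed_in_all"]]
            order = de.loc[abundant, [c for c in de.columns if c.startswith("mean_")]]
            top = order.max(axis=1).sort_values(ascending=False).index[: config.bn_top_k]
            keep = list(dict.fromkeys(
                ([marker.numerator_id, marker.denominator_id] if marker else []) + list(top)
            ))[: config.bn_top_k]
            disc = bayesnet.discretize_by_median(tr.values.loc[keep])
            disc = bayesnet.add_pathology_nodes(disc, tr_samples)
            bn_dag = bayesnet.tabu_search(
                disc, max_iter=config.bn_max_iter, tabu_len=config.bn_tabu_len,
                patience=config.bn_patience, seed=config.seed, score=config.bn_score)
            cancer_nb = bayesnet.neighborhood(bn_dag, "cancer")
            log.info("stage bayesnet: %d nodes, %d edges, score %.2f",
                     len(bn_dag.nodes), len(bn_dag.edges), bn_dag.score)

        stage = "survival"
        met_ranked = met_ratios = None
        km_fits: dict = {}
        lr = None
        pdac_all = samples.index[(samples["diagnosis"] == "PDAC")
                                 & samples["os_days"].notna()]
        tr_pdac = [s for s in train_ids if samples.loc[s, "diagnosis"] == "PDAC"]
        met_labels = samples.loc[tr_pdac, "metastasis"]
        if (len(pdac_all) >= 4 and met_labels.notna().all()
                and set(met_labels.unique()) == {"M0", "M1"}
                and bool(samples.loc[pdac_all, "os_event"].fillna(False).sum())):
            norm_pdac = tr.values[tr_pdac]
            de_met = diffexpr.differential_expression(
                norm_pdac, met_labels, "M1", "M0",
                method=config.de_method, raw_counts=counts[tr_pdac])
            surv_train = samples.loc[[s for s in tr_pdac if s in pdac_all],
                                     ["os_days", "os_event"]].astype(
                                         {"os_days": float, "os_event": bool})
            if len(surv_train) >= 4 and surv_train["os_event"].sum() > 0:
                met_ranked, met_ratios = biomarker.metastasis_candidates(
                    norm_pdac, met_labels, surv_train, de_met, config.thresholds)
            if met_ratios is not None and not met_ratios.empty:
                num, den = met_ratios.iloc[0][["numerator", "denominator"]]
                # pooled-cohort survival stratification by the frozen cutoff
                parts = [biomarker.ratio_values(norm[n].values, num, den) for n in norm]
                ratio_all = pd.concat(parts).reindex(pdac_all).dropna()
                groups = survival.stratify_by_ratio(ratio_all, config.met_cutoff)
                surv_all = samples.loc[ratio_all.index, ["os_days", "os_event"]].astype(
                    {"os_days": float, "os_event": bool})
                for gname in ("above", "below"):
                    m = groups == gname
                    if m.any():
                        km_fits[gname] = survival.km_estimate(
                            surv_all.loc[m.to_numpy(), "os_days"],
                            surv_all.loc[m.to_numpy(), "os_event"])
                if groups.nunique() == 2 and surv_all["os_event"].sum() > 0:
                    lr = survival.logrank_test(
                        surv_all["os_days"], surv_all["os_event"], groups)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    lines = ["# Pipeline summary", ""]
    if marker is not None:
        lines.append(f"Ratio marker: {marker.numerator_id}/{marker.denominator_id} "
                     f"cutoff {marker.cutoff:g} (training AUC {marker.auc:.3f})")
        for name in confusion:
            lines.append(f"[{name}] " + _format_confusion("ratio rule", confusion[name]["ratio"]))
            lines.append(f"[{name}] " + _format_confusion("combined rule (with CA19-9)",
                                                          confusion[name]["combined"]))
    if bn_dag is not None:
        causes, consequences, _ = cancer_nb
        lines.append(f"Bayesian network: {len(bn_dag.nodes)} nodes, "
                     f"{len(bn_dag.edges)} edges, BIC {bn_dag.score:.1f}")
        lines.append(f"cancer causes: {sorted(causes)}; consequences: {sorted(consequences)}")
    if lr is not None:
        meds = {g: km_fits[g].median_os for g in km_fits}
        lines.append(f"Survival: median OS above/below cutoff = "
                     f"{meds.get('above', float('nan')):.0f}/"
                     f"{meds.get('below', float('nan')):.0f} days, "
                     f"log-rank p = {lr.p_value:.3f}")
    summary = "\n".join(lines)

    report = PipelineReport(
        de_table=de, candidates=candidates, single_ranking=single_ranking,
        ratio_table=ratio_table, marker=marker, confusion=confusion,
        bn_dag=bn_dag, cancer_neighborhood=cancer_nb,
        met_ranked=met_ranked, met_ratios=met_ratios,
        km_fits=km_fits, logrank=lr, summary=summary,
    )
    if config.output_dir:
        _write_outputs(report, Path(config.output_dir))
    return report


def _write_outputs(report: PipelineReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.de_table.to_csv(out / "de_results.tsv", sep="\t", index_label="mirna_id")
    report.single_ranking.to_csv(out / "single_marker_auc.tsv", sep="\t", index=False)
    report.ratio_table.to_csv(out / "ratio_search.tsv", sep="\t", index=False)
    for name, res in report.confusion.items():
        res["decisions"].to_csv(out / f"decisions_{name}.csv", index_label="specimen_id")
    if report.marker is not None and report.marker.roc_points is not None:
        pd.DataFrame(report.marker.roc_points,
                     columns=["fpr", "tpr"]).to_csv(out / "roc_train.tsv",
                                                    sep="\t", index=False)
    if report.bn_dag is not None:
        edges = pd.DataFrame(report.bn_dag.edges, columns=["from", "to"])
        edges.to_csv(out / "bn_edges.tsv", sep="\t", index=False)
        _write_dot(report.bn_dag.graph, out / "bn.dot")
        _, _, sub = report.cancer_neighborhood
        _write_dot(sub, out / "bn_cancer_neighborhood.dot")
    for g, fit in report.km_fits.items():
        pd.DataFrame({"time": fit.times, "survival": fit.survival,
                      "n_at_risk": fit.n_at_risk}).assign(group=g).to_csv(
            out / f"km_{g}.tsv", sep="\t", index=False)
    (out / "summary.txt").write_text(report.summary + "\n")


def _write_dot(g: nx.DiGraph, path: Path) -> None:
    lines = ["digraph bn {"]
    for n in sorted(g.nodes):
        lines.append(f'  "{n}";')
    for u, v in sorted(g.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
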