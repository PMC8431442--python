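"""ROC/AUC machinery, ratio-biomarker search and the diagnostic decision rules.

The core diagnostic construct is the quotient (ratio) biomarker: the
normalized expression of a target miRNA divided by that of a reference
miRNA, scored with the Mann-Whitney AUC and turned into a decision rule by
a fixed cutoff.  The combined rule adds a second threshold on serum CA19-9:
a specimen is called Benign only when the ratio and CA19-9 both fall below
their thresholds, and Tumor otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .survival import logrank_test, stratify_by_median

log = logging.getLogger(__name__)

__all__ = [
    "RatioMarker",
    "CombinedRule",
    "ConfusionResult",
    "auc",
    "roc_curve",
    "rank_single_markers",
    "ratio_search",
    "ratio_values",
    "choose_cutoff",
    "classify_ratio",
    "classify_combined",
    "confusion_metrics",
    "metastasis_candidates",
]


def auc(values, labels, case_label) -> float:
    """Mann-Whitney AUC: the fraction of (case, control) pairs where the case
    scores higher, ties counted 1/2.

    Orientation is fixed by ``case_label``; a marker running the "wrong way"
    yields AUC < 0.5 and is reported as-is (no flipping).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if not np.isfinite(v).all():
        raise ValueError("marker values must be finite")
    case = y == case_label
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(v)  # average ranks give the 1/2-tie convention
    u = ranks[case].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve(values, labels, case_label) -> np.ndarray:
    """(1-specificity, sensitivity) points swept over all distinct thresholds.

    Points run from (0,0) to (1,1); their trapezoidal area equals the
    Mann-Whitney AUC.
    """
    v = np.asarray(values, dtype=float)
    y = (np.asarray(labels) == case_label).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(y, v, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    return pts


@dataclass
class RatioMarker:
    """A quotient biomarker numerator/denominator with its decision cutoff."""

    numerator_id: str
    denominator_id: str
    cutoff: float
    auc: float = float("nan")
    roc_points: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class CombinedRule:
    """Two-threshold rule: Benign iff ratio < x0 and CA19-9 < y0."""

    x0: float = 0.06
    y0: float = 300.0

    def __post_init__(self) -> None:
        if self.x0 <= 0 or self.y0 <= 0:
            raise ValueError("thresholds must be positive")


def rank_single_markers(norm_values: pd.DataFrame, labels, case_label,
                        candidates: list[str]) -> pd.DataFrame:
    """One row per candidate miRNA with its AUC, sorted by descending AUC
    (ties broken by miRNA id)."""
    if not candidates:
        raise ValueError("empty candidate list")
    rows = [(m, auc(norm_values.loc[m], labels, case_label)) for m in candidates]
    table = pd.DataFrame(rows, columns=["mirna_id", "auc"])
    return (table.sort_values(["auc", "mirna_id"], ascending=[False, True],
                              kind="stable").reset_index(drop=True))


def ratio_values(norm_values: pd.DataFrame, numerator_id: str,
                 denominator_id: str) -> pd.Series:
    """Per-specimen numerator/denominator quotient.

    Specimens where the denominator is 0 are excluded (logged), not imputed.
    """
    num = norm_values.loc[numerator_id]
    den = norm_values.loc[denominator_id]
    ok = den > 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("ratio %s/%s: excluded %d specimens with zero denominator",
                    numerator_id, denominator_id, n_dropped)
    return num[ok] / den[ok]


def ratio_search(norm_values: pd.DataFrame, labels, case_label,
                 numerator_id: str, candidates: list[str]) -> pd.DataFrame:
    """Exhaustive denominator search: AUC of numerator/denominator for every
    candidate denominator, sorted by descending AUC (ties by denominator id).

    Denominators with a zero normalized value in any specimen are skipped.
    """
    if numerator_id not in norm_values.index:
        raise KeyError(f"numerator {numerator_id!r} not in matrix")
    pool = [c for c in candidates if c != numerator_id]
    if not pool:
        raise ValueError("empty candidate set")
    labels = pd.Series(np.asarray(labels), index=norm_values.columns)
    rows = []
    for d in pool:
        den = norm_values.loc[d]
        if (den <= 0).any():
            log.warning("ratio_search: skipping denominator %s (zero normalized value)", d)
            continue
        r = norm_values.loc[numerator_id] / den
        rows.append((numerator_id, d, auc(r, labels, case_label), len(r)))
    table = pd.DataFrame(rows, columns=["numerator", "denominator", "auc", "n_evaluated"])
    return (table.sort_values(["auc", "denominator"], ascending=[False, True],
                              kind="stable").reset_index(drop=True))


def choose_cutoff(values, labels, case_label, strategy: str = "youden",
                  fixed: float | None = None) -> float:
    """Decision cutoff for a marker.

    ``fixed`` returns the supplied constant; ``youden`` maximizes
    sensitivity + specificity - 1 over midpoints of consecutive distinct
    values (ties resolved toward the smaller cutoff), calling Tumor at
    value >= cutoff.
    """
    if strategy == "fixed":
        if fixed is None:
            raise ValueError("fixed strategy requires a cutoff value")
        return float(fixed)
    if strategy != "youden":
        raise ValueError(f"unknown strategy {strategy!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels) == case_label
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(v)
    # candidate thresholds: below the minimum, between values, above the max
    mids = np.concatenate([[distinct[0] - 1.0],
                           (distinct[:-1] + distinct[1:]) / 2.0,
                           [distinct[-1] + 1.0]])
    best_j, best_c = -np.inf, mids[0]
    n1, n0 = y.sum(), (~y).sum()
    for c in mids:
        call = v >= c
        sens = (call & y).sum() / n1
        spec = (~call & ~y).sum() / n0
        j = sens + spec - 1.0
        if j > best_j:  # strict: first (smallest) cutoff wins ties
            best_j, best_c = j, c
    return float(best_c)


def classify_ratio(x: float, cutoff: float) -> str:
    """Benign when the ratio is strictly below the cutoff, Tumor otherwise."""
    if x < 0:
        raise ValueError("ratio must be non-negative")
    return "Benign" if x < cutoff else "Tumor"


def classify_combined(x: float, y: float | None, rule: CombinedRule) -> str:
    """Benign iff ratio < x0 AND CA19-9 < y0; Tumor otherwise.

    A missing CA19-9 degrades to the ratio-only rule with a logged warning.
    """
    if y is None or (isinstance(y, float) and np.isnan(y)):
        log.warning("missing CA19-9; falling back to ratio-only rule")
        return classify_ratio(x, rule.x0)
    if y < 0:
        raise ValueError("CA19-9 must be non-negative")
    return "Benign" if (x < rule.x0 and y < rule.y0) else "Tumor"


def _round_half_up(value: float, decimals: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1.{'0' * decimals}"),
                                               rounding=ROUND_HALF_UP))


@dataclass
class ConfusionResult:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        """100 * TP / (TP + FN), half-up rounded to 1 decimal."""
        return _round_half_up(100.0 * self.tp / (self.tp + self.fn))

    @property
    def specificity(self) -> float:
        """100 * TN / (TN + FP), half-up rounded to 1 decimal."""
        return _round_half_up(100.0 * self.tn / (self.tn + self.fp))

    @property
    def sensitivity_exact(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_exact(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def confusion_metrics(predicted, truth, positive_pred: str = "Tumor",
                      positive_truth: str = "PDAC") -> ConfusionResult:
    """Confusion counts and sensitivity/specificity percentages.

    Pathology is the gold standard: sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), as percentages rounded half-up to 1 decimal.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if len(pred) != len(true):
        raise ValueError("prediction/truth length mismatch")
    known_pred = {positive_pred, "Benign", "Tumor"}
    if not set(pred) <= known_pred:
        raise ValueError(f"unknown predicted labels: {set(pred) - known_pred}")
    allowed_truth = {positive_truth, "CP", "PDAC", "M0", "M1"}
    if not set(true) <= allowed_truth:
        raise ValueError(f"unknown truth labels: {set(true) - allowed_truth}")
    pos_p = pred == positive_pred
    pos_t = true == positive_truth
    return ConfusionResult(
        tp=int((pos_p & pos_t).sum()),
        fn=int((~pos_p & pos_t).sum()),
        tn=int((~pos_p & ~pos_t).sum()),
        fp=int((pos_p & ~pos_t).sum()),
    )


def metastasis_candidates(
    norm_pdac: pd.DataFrame,
    metastasis_labels,
    survival_table: pd.DataFrame,
    de_table: pd.DataFrame,
    thresholds=None,
    logrank_alpha: float = 0.05,
    top_k: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metastasis-marker discovery inside the PDAC subgroup.

    Applies the metastatic candidate filter (no fold-change clause), ranks
    the survivors by M1-vs-M0 AUC, keeps those whose median split shows
    log-rank p < ``logrank_alpha`` on the supplied survival table (an
    internal stand-in for the external-cohort survival check), then searches
    ratio partners for the top-ranked marker.  Returns (ranked single
    markers, ratio table for the best marker).
    """
    from .diffexpr import candidate_filter

    met = pd.Series(np.asarray(metastasis_labels), index=norm_pdac.columns)
    if set(met.unique()) != {"M0", "M1"}:
        raise ValueError("need both M0 and M1 specimens")
    if survival_table["os_event"].sum() == 0:
        raise ValueError("survival table has no events")
    cands = candidate_filter(de_table, thresholds, mode="metastatic")
    if not cands:
        return (pd.DataFrame(columns=["mirna_id", "auc", "logrank_p"]),
                pd.DataFrame(columns=["numerator", "denominator", "auc", "n_evaluated"]))
    ranked = rank_single_markers(norm_pdac, met, "M1", cands)
    keep_rows = []
    for _, row in ranked.iterrows():
        m = row["mirna_id"]
        vals = norm_pdac.loc[m, survival_table.index]
        groups = stratify_by_median(vals)
        if groups.nunique() < 2:
            continue
        res = logrank_test(survival_table["os_days"], survival_table["os_event"], groups)
        if res.p_value < logrank_alpha:
            keep_rows.append({"mirna_id": m, "auc": row["auc"], "logrank_p": res.p_value})
    surv_ranked = pd.DataFrame(keep_rows, columns=["mirna_id", "auc", "logrank_p"])
    if surv_ranked.empty:
        return surv_ranked, pd.DataFrame(columns=["numerator", "denominator", "auc", "n_evaluated"])
    numerator = surv_ranked.iloc[0]["mirna_id"]
    pool = [m for m in cands if m != numerator]
    ratios = ratio_search(norm_pdac, met, "M1", numerator, pool) if pool else pd.DataFrame(
        columns=["numerator", "denominator", "auc", "n_evaluated"])
    return surv_ranked, ratios.head(top_k)
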