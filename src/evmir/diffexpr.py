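"""Differential expression and candidate filtering for normalized miRNA matrices.

Two-group tests are run on log2(normalized + 1): either a plain Welch t-test
or a moderated t-test with empirical-Bayes variance shrinkage (scaled
inverse-chi-square prior fitted by method of moments across miRNAs, in the
style of limma).  Candidates are then filtered on expression-in-all-specimens,
mean normalized abundance, fold change and significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FilterThresholds",
    "log2_fold_change",
    "de_test",
    "bh_fdr",
    "differential_expression",
    "candidate_filter",
]


@dataclass
class FilterThresholds:
    """Candidate-filter cutoffs.

    min_mean_norm: mean normalized expression required (inclusive, >= 50 by
    default); min_abs_log2fc: absolute log2 fold change required (strict, > 1
    by default; diagnostic mode only); alpha: significance level on the
    p-value, or on the BH q-value when use_fdr is set.
    """

    min_mean_norm: float = 50.0
    min_abs_log2fc: float = 1.0
    alpha: float = 0.05
    use_fdr: bool = False

    def __post_init__(self) -> None:
        if self.min_mean_norm < 0 or self.min_abs_log2fc < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


def log2_fold_change(mean_a: float, mean_b: float, pseudocount: float = 0.5) -> float:
    """log2((mean_a + eps) / (mean_b + eps)); the pseudocount keeps it finite."""
    if mean_a < 0 or mean_b < 0:
        raise ValueError("group means must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((mean_a + pseudocount) / (mean_b + pseudocount)))


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of log s^2 across miRNAs against the
    theoretical digamma/trigamma moments; returns (prior_df, prior_s2).
    A prior_df of inf means the observed variances are less dispersed than
    sampling alone predicts (complete shrinkage to the common value).
    """
    s2 = s2[s2 > 0]
    z = np.log(s2)
    e_z = float(np.mean(z))
    v_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    excess = v_z - special.polygamma(1, df / 2.0)
    if excess <= 1e-8:
        # observed spread of log-variances is explained by sampling alone:
        # point-mass prior (complete shrinkage), bias-corrected for chi-square
        s0_2 = float(np.exp(e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)))
        return np.inf, s0_2
    # invert trigamma(d0/2) = excess by bisection on log-scale
    lo, hi = 1e-6, 1e8
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > excess:
            lo = mid
        else:
            hi = mid
    d0 = 2.0 * np.sqrt(lo * hi)
    s0_2 = float(np.exp(
        e_z - special.polygamma(0, df / 2.0) + np.log(df / 2.0)
        + special.polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)
    ))
    return float(d0), s0_2


def de_test(
    norm_values: pd.DataFrame,
    labels: pd.Series,
    group_a: str,
    group_b: str,
    method: str = "welch_log",
    log_pseudocount: float = 1.0,
) -> pd.Series:
    """Two-sided per-miRNA p-values for group_a vs group_b.

    ``welch_log``: unequal-variance t-test on log2(normalized + pseudocount).
    ``moderated``: pooled-variance t statistic with the per-miRNA variance
    shrunk toward a common prior (method-of-moments empirical Bayes), tested
    on the augmented degrees of freedom.
    """
    labels = labels.reindex(norm_values.columns)
    a = norm_values.loc[:, (labels == group_a).to_numpy()].to_numpy(dtype=float)
    b = norm_values.loc[:, (labels == group_b).to_numpy()].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 specimens")
    la = np.log2(a + log_pseudocount)
    lb = np.log2(b + log_pseudocount)
    if method == "welch_log":
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance rows with equal means: statistic 0/0 -> define p = 1
        p = np.where(np.isnan(p), 1.0, p)
    elif method == "moderated":
        n1, n2 = la.shape[1], lb.shape[1]
        df = n1 + n2 - 2
        diff = la.mean(axis=1) - lb.mean(axis=1)
        ss = la.var(axis=1, ddof=1) * (n1 - 1) + lb.var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / df
        d0, s0_2 = _fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0_2)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
            df_total = d0 + df
        se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = diff / se
        t = np.where(np.isnan(t), 0.0, t)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.Series(p, index=norm_values.index, name="p_value")


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="fdr")
    return q


def differential_expression(
    norm,
    labels: pd.Series,
    group_a: str = "PDAC",
    group_b: str = "CP",
    method: str = "welch_log",
    fc_pseudocount: float = 0.5,
    log_pseudocount: float = 1.0,
    log_ratio_fc: bool = False,
    raw_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-miRNA differential table: group means, log2FC, p, BH-FDR,
    and the expressed-in-all-specimens flag (on raw counts when supplied,
    otherwise on normalized values).

    ``log_ratio_fc`` switches the fold change to the difference of group mean
    log2 expressions instead of the log2 ratio of group means.
    """
    values = norm.values if hasattr(norm, "values") and not isinstance(norm, pd.DataFrame) else norm
    labels = labels.reindex(values.columns)
    a_mask = (labels == group_a).to_numpy()
    b_mask = (labels == group_b).to_numpy()
    sub = values.loc[:, a_mask | b_mask]
    mean_a = values.loc[:, a_mask].mean(axis=1)
    mean_b = values.loc[:, b_mask].mean(axis=1)
    if log_ratio_fc:
        fc = (np.log2(values.loc[:, a_mask] + fc_pseudocount).mean(axis=1)
              - np.log2(values.loc[:, b_mask] + fc_pseudocount).mean(axis=1))
    else:
        fc = pd.Series(
            [log2_fold_change(x, y, fc_pseudocount) for x, y in zip(mean_a, mean_b)],
            index=values.index,
        )
    p = de_test(sub, labels[a_mask | b_mask], group_a, group_b,
                method=method, log_pseudocount=log_pseudocount)
    expr_source = raw_counts if raw_counts is not None else values
    expressed = (expr_source.loc[values.index, sub.columns].to_numpy() >= 1).all(axis=1)
    return pd.DataFrame({
        f"mean_{group_a.lower()}": mean_a,
        f"mean_{group_b.lower()}": mean_b,
        "log2fc": fc,
        "p_value": p,
        "fdr": bh_fdr(p),
        "expressed_in_all": expressed,
    })


def candidate_filter(
    de: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    mode: str = "diagnostic",
    mean_rule: str = "max",
) -> list[str]:
    """miRNAs passing every configured clause.

    Clauses: expressed in all specimens (raw count >= 1 everywhere); mean
    normalized expression >= min_mean_norm, applied to the larger of the two
    group means (``mean_rule="max"``) or to the pooled mean
    (``mean_rule="pooled"``); p (or BH q when use_fdr) < alpha; and, in
    diagnostic mode only, |log2FC| > min_abs_log2fc.  Metastatic mode drops
    the fold-change clause.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    mean_cols = [c for c in de.columns if c.startswith("mean_")]
    if mean_rule == "max":
        mean_stat = de[mean_cols].max(axis=1)
    elif mean_rule == "pooled":
        mean_stat = de[mean_cols].mean(axis=1)
    else:
        raise ValueError(f"unknown mean_rule {mean_rule!r}")
    sig = de["fdr"] if thresholds.use_fdr else de["p_value"]
    keep = (
        de["expressed_in_all"]
        & (mean_stat >= thresholds.min_mean_norm)
        & (sig < thresholds.alpha)
    )
    if mode == "diagnostic":
        keep &= de["log2fc"].abs() > thresholds.min_abs_log2fc
    elif mode != "metastatic":
        raise ValueError(f"unknown mode {mode!r}")
    return list(de.index[keep])
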