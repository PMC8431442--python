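"""Housekeeping-based normalization of small-RNA-seq count matrices.

The normalization scheme used throughout the pipeline: every miRNA with at
least one read in every specimen forms the housekeeping set; the per-specimen
size factor is the 75th percentile of the housekeeping counts in that
specimen; normalized expression is the raw read count divided by the size
factor.  Also provides the per-miRNA max-scaling used before PCA and the
2^-ddCt relative-quantification utility for qRT-PCR data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "PcaResult",
    "select_housekeeping",
    "size_factors",
    "normalize_counts",
    "max_scale",
    "pca",
    "ddct",
]


class NormalizationError(ValueError):
    """Raised when the housekeeping rule cannot produce valid size factors."""


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the count-matrix contract: unique ids, >= 2 specimens, integer
    non-negative entries (rows are miRNAs, columns are specimens)."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate miRNA id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate specimen id: {dup!r}")
    if counts.shape[1] < 2:
        raise ValueError("count matrix needs at least 2 specimens")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix must be numeric")
    if (values < 0).any():
        raise ValueError("count matrix has negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count matrix has non-integer entries")


def select_housekeeping(counts: pd.DataFrame) -> pd.Index:
    """Return the miRNAs with >= 1 read in every specimen, in input order.

    Raises :class:`NormalizationError` when no miRNA qualifies, since the
    size factor is then undefined.
    """
    mask = (counts.to_numpy() >= 1).all(axis=1)
    ids = counts.index[mask]
    if len(ids) == 0:
        raise NormalizationError("no housekeeping miRNA: no miRNA has >=1 read in all specimens")
    return ids


def size_factors(
    counts: pd.DataFrame,
    housekeeping_ids: pd.Index | list[str],
    percentile_method: str = "linear",
) -> pd.Series:
    """75th percentile of housekeeping counts per specimen.

    ``percentile_method`` is "linear" (Hyndman-Fan type 7, the default of
    ``quantile`` in R and numpy) or "nearest" (nearest-rank alternative).
    """
    if len(housekeeping_ids) == 0:
        raise NormalizationError("empty housekeeping set")
    if percentile_method not in ("linear", "nearest"):
        raise ValueError(f"unknown percentile method {percentile_method!r}")
    hk = counts.loc[list(housekeeping_ids)].to_numpy(dtype=float)
    factors = np.percentile(hk, 75, axis=0, method=percentile_method)
    sf = pd.Series(factors, index=counts.columns, name="size_factor")
    if (sf <= 0).any():
        bad = sf.index[sf <= 0][0]
        raise NormalizationError(f"size factor is 0 for specimen {bad!r}")
    return sf


@dataclass
class NormalizedMatrix:
    """Normalized expression (reads / size factor) with its provenance."""

    values: pd.DataFrame
    housekeeping_ids: pd.Index
    size_factors: pd.Series
    percentile_method: str = "linear"

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.index

    @property
    def specimen_ids(self) -> pd.Index:
        return self.values.columns


def normalize_counts(counts: pd.DataFrame, percentile_method: str = "linear") -> NormalizedMatrix:
    """Divide each specimen's counts by its housekeeping 75th-percentile size factor."""
    validate_counts(counts)
    hk = select_housekeeping(counts)
    sf = size_factors(counts, hk, percentile_method)
    norm = counts.astype(float).div(sf, axis=1)
    log.info(
        "normalized %d miRNAs x %d specimens (housekeeping set: %d miRNAs)",
        counts.shape[0], counts.shape[1], len(hk),
    )
    return NormalizedMatrix(values=norm, housekeeping_ids=hk, size_factors=sf,
                            percentile_method=percentile_method)


def max_scale(norm: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Divide each miRNA row by its maximum so every retained row peaks at 1.

    All-zero rows have no defined scale and are dropped; returns the scaled
    matrix and the number of dropped rows.
    """
    row_max = norm.max(axis=1)
    keep = row_max > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("max_scale: dropped %d all-zero miRNA rows", n_dropped)
    scaled = norm.loc[keep].div(row_max[keep], axis=0)
    return scaled, n_dropped


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # specimens x PCs
    variance_fractions: np.ndarray = field(repr=False)


def pca(scaled: pd.DataFrame, n_components: int | None = None, center: bool = True) -> PcaResult:
    """PCA with specimens as observations and miRNAs as variables.

    Variables are centered (configurable) but not re-scaled beyond the
    max-scaling already applied.  Coordinates are the centered data projected
    on the right singular vectors; variance fractions are non-increasing.
    """
    x = scaled.to_numpy(dtype=float).T  # observations x variables
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 specimens and >= 2 miRNAs")
    if not center:
        x = x.copy()
        # sklearn always centers; emulate "no centering" by adding back the mean
        # after projecting raw data on the SVD of the uncentered matrix.
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        coords = x @ vt.T
        var = s**2 / np.sum(s**2)
    else:
        k = min(x.shape) if n_components is None else min(n_components, min(x.shape))
        model = _SkPCA(n_components=k, svd_solver="full")
        coords = model.fit_transform(x)
        var = model.explained_variance_ratio_
        if np.allclose(model.explained_variance_, 0):
            raise ValueError("rank-0 input: all specimens identical")
    if n_components is not None:
        coords = coords[:, :n_components]
        var = var[:n_components]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=scaled.columns, columns=cols),
        variance_fractions=np.asarray(var),
    )


def ddct(ct_target_case: float, ct_ref_case: float,
         ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target,case - Ct_ref,case) - (Ct_target,ctrl - Ct_ref,ctrl).
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_value = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_value))
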