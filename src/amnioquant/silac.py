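"""Protein-level SILAC H/L ratio quantification and outlier significance.

Peptide evidence is aggregated per protein group into a heavy/light ratio
(median of razor-peptide log2 ratios, exponentiated), ratios are normalized
so the median log ratio over quantified proteins is zero, and each protein
receives outlier p-values against the asymmetric percentile spread of the
ratio distribution: Significance A on the pooled distribution, and
Significance B computed within consecutive bins of protein intensity so
that the intensity dependence of ratio variance is respected.

The percentile construction: with distribution percentiles ``p15.87``,
``p50`` and ``p84.13`` of the log ratios, a protein at log ratio ``r``
gets the one-sided z-score

    z = (r - p50) / (p84.13 - p50)      if r >= p50
    z = (p50 - r) / (p50 - p15.87)      otherwise

and p-value ``erfc(z / sqrt(2)) / 2``, i.e. the upper-tail Gaussian
probability on the side where the protein lies.  On a Gaussian null the
two half-widths estimate sigma, so the score is a calibrated outlier
probability while tolerating asymmetric real ratio distributions.

Ratios are reported on the natural H/L scale; internal statistics are on
the log2 scale throughout.  Unquantified proteins carry NaN, never 0 or 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import erfc
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, InputError

__all__ = [
    "RatioNormalizer",
    "aggregate_protein_ratio",
    "aggregate_evidence",
    "normalize_ratios",
    "ratio_outlier_pvalues",
    "significance_a",
    "significance_b",
    "PROTEIN_COLUMNS",
]

#: canonical internal column names for protein-group tables
PROTEIN_COLUMNS = [
    "protein_group_id",
    "gene_name",
    "protein_name",
    "ratio_hl_raw",
    "ratio_hl_normalized",
    "ratio_count",
    "intensity_total",
    "significance_a",
    "significance_b",
    "is_reverse",
    "is_contaminant",
    "annotation_status",
]

_MIN_SIGNIFICANCE_RECORDS = 20


def _annotation_status(protein_name: str) -> str:
    name = (protein_name or "").lower()
    if "uncharacterized" in name or "unknown" in name:
        return "unknown"
    if name.startswith("predicted") or "putative" in name:
        return "predicted"
    return "known"


def aggregate_protein_ratio(evidences: pd.DataFrame, min_ratio_count: int = 3) -> dict:
    """Aggregate peptide evidence of a single protein group into one record.

    The raw H/L ratio is the median of the razor-peptide log2 ratios,
    exponentiated (a geometric-median-type combiner, resistant to single
    corrupted peptides).  A protein with fewer than ``min_ratio_count``
    finite razor ratios is returned unquantified (``ratio_hl_raw`` NaN).

    Raises
    ------
    InputError
        If the evidence table is empty or mixes protein group ids.
    """
    if min_ratio_count < 1:
        raise InputError(f"min_ratio_count must be >= 1, got {min_ratio_count}")
    if len(evidences) == 0:
        raise InputError("empty evidence list")
    ids = evidences["protein_group_id"].unique()
    if len(ids) != 1:
        raise InputError(f"evidence mixes protein group ids: {sorted(map(str, ids))}")
    pid = str(ids[0])

    ratios = pd.to_numeric(evidences["ratio_hl"], errors="coerce").to_numpy(float)
    razor = evidences["is_razor"].astype(bool).to_numpy()
    usable = razor & np.isfinite(ratios) & (ratios > 0)
    ratio_count = int(usable.sum())

    if ratio_count >= min_ratio_count:
        ratio_raw = float(2.0 ** np.median(np.log2(ratios[usable])))
    else:
        ratio_raw = float("nan")

    intensity = (
        pd.to_numeric(evidences["intensity_h"], errors="coerce").fillna(0.0)
        + pd.to_numeric(evidences["intensity_l"], errors="coerce").fillna(0.0)
    ).sum()

    gene = str(evidences["gene_name"].iloc[0]) if "gene_name" in evidences else ""
    name = str(evidences["protein_name"].iloc[0]) if "protein_name" in evidences else ""
    return {
        "protein_group_id": pid,
        "gene_name": gene,
        "protein_name": name,
        "ratio_hl_raw": ratio_raw,
        "ratio_hl_normalized": float("nan"),
        "ratio_count": ratio_count,
        "intensity_total": float(intensity),
        "significance_a": float("nan"),
        "significance_b": float("nan"),
        "is_reverse": pid.startswith("REV__"),
        "is_contaminant": pid.startswith("CON__"),
        "annotation_status": _annotation_status(name),
    }


def aggregate_evidence(evidence: pd.DataFrame, min_ratio_count: int = 3) -> pd.DataFrame:
    """Aggregate a full evidence table into a protein-group table.

    Vectorized equivalent of calling :func:`aggregate_protein_ratio` per
    protein group; row order follows first appearance in the evidence.
    """
    if len(evidence) == 0:
        raise InputError("empty evidence table")
    records = [
        aggregate_protein_ratio(group, min_ratio_count=min_ratio_count)
        for _, group in evidence.groupby("protein_group_id", sort=False)
    ]
    return pd.DataFrame(records, columns=PROTEIN_COLUMNS)


class RatioNormalizer(BaseEstimator, TransformerMixin):
    """Rescale H/L ratios so the median log ratio of quantified proteins is 0.

    A single multiplicative constant (the exponentiated median log ratio of
    the fitting set) is divided out; rank order and relative spacing of the
    ratios are untouched.  Fitting on the same ratios that are transformed
    makes the operation idempotent.

    Attributes
    ----------
    median_log2_ : float
        Median log2 ratio of the finite, positive fitting ratios.
    n_quantified_ : int
        Number of ratios that contributed to the median.
    """

    def fit(self, X, y=None):
        ratios = np.asarray(X, dtype=float).ravel()
        finite = np.isfinite(ratios) & (ratios > 0)
        if not finite.any():
            raise InputError("no quantified ratios to normalize")
        self.median_log2_ = float(np.median(np.log2(ratios[finite])))
        self.n_quantified_ = int(finite.sum())
        return self

    def transform(self, X):
        if not hasattr(self, "median_log2_"):
            raise InputError("RatioNormalizer is not fitted")
        ratios = np.asarray(X, dtype=float)
        return ratios / 2.0**self.median_log2_


def normalize_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``ratio_hl_normalized`` via median-log normalization.

    Returns a copy; unquantified proteins stay NaN.  The fitted shift is
    stored in ``df.attrs['normalization_log2_shift']``.
    """
    normalizer = RatioNormalizer().fit(records["ratio_hl_raw"])
    out = records.copy()
    out["ratio_hl_normalized"] = normalizer.transform(records["ratio_hl_raw"].to_numpy(float))
    out.attrs["normalization_log2_shift"] = normalizer.median_log2_
    return out


def ratio_outlier_pvalues(log_ratios: np.ndarray) -> np.ndarray:
    """Percentile-z outlier p-values of log ratios against their own spread.

    NaN inputs yield NaN outputs; at least 20 finite values are required
    for the percentile estimates to be meaningful.
    """
    x = np.asarray(log_ratios, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < _MIN_SIGNIFICANCE_RECORDS:
        raise InputError(
            f"need >= {_MIN_SIGNIFICANCE_RECORDS} quantified records for "
            f"significance scores, got {int(finite.sum())}"
        )
    p_low, p_med, p_high = np.percentile(x[finite], [15.87, 50.0, 84.13])
    right = p_high - p_med
    left = p_med - p_low
    if right <= 0 or left <= 0:
        side = "upper (p84.13 - p50)" if right <= 0 else "lower (p50 - p15.87)"
        raise DegenerateInputError(
            f"degenerate ratio distribution: {side} percentile scale is zero"
        )
    out = np.full(x.shape, np.nan)
    upper = finite & (x >= p_med)
    lower = finite & (x < p_med)
    z = np.empty(x.shape)
    z[upper] = (x[upper] - p_med) / right
    z[lower] = (p_med - x[lower]) / left
    out[finite] = 0.5 * erfc(z[finite] / np.sqrt(2.0))
    return out


def significance_a(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``significance_a`` from the pooled normalized-ratio distribution."""
    out = records.copy()
    log_ratios = np.log2(out["ratio_hl_normalized"].to_numpy(float))
    out["significance_a"] = ratio_outlier_pvalues(log_ratios)
    return out


def significance_b(records: pd.DataFrame, bin_size: int = 300) -> pd.DataFrame:
    """Fill ``significance_b``: Significance A within protein-intensity bins.

    Quantified records are sorted by ``intensity_total`` (descending) and
    partitioned into consecutive bins of ``bin_size``; the final partial
    bin is absorbed into the last full bin so every bin has at least
    ``bin_size`` members.  The percentile-z score is computed independently
    per bin, letting high- and low-intensity regimes carry their own ratio
    variance.
    """
    if bin_size < _MIN_SIGNIFICANCE_RECORDS:
        raise InputError(f"bin_size must be >= {_MIN_SIGNIFICANCE_RECORDS}, got {bin_size}")
    if records["intensity_total"].isna().any():
        raise InputError("missing intensity_total values; cannot bin for significance B")
    out = records.copy()
    out["significance_b"] = np.nan

    quantified = out.index[
        np.isfinite(out["ratio_hl_normalized"].to_numpy(float))
        & (out["ratio_hl_normalized"].to_numpy(float) > 0)
    ]
    if len(quantified) < _MIN_SIGNIFICANCE_RECORDS:
        raise InputError(
            f"need >= {_MIN_SIGNIFICANCE_RECORDS} quantified records, got {len(quantified)}"
        )
    order = out.loc[quantified, "intensity_total"].sort_values(ascending=False).index
    n = len(order)
    n_bins = max(1, n // bin_size)
    for b in range(n_bins):
        start = b * bin_size
        stop = (b + 1) * bin_size if b < n_bins - 1 else n
        idx = order[start:stop]
        log_ratios = np.log2(out.loc[idx, "ratio_hl_normalized"].to_numpy(float))
        out.loc[idx, "significance_b"] = ratio_outlier_pvalues(log_ratios)
    return out
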