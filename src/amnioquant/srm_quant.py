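"""SRM peak-area normalization and protein quantification.

Each sample is injected several times (replicate preparations x repeat
injections); the first replicate's first injection serves as the
reference.  Every other (replicate, injection) is aligned to the
reference by a single additive constant on the log2 scale, estimated by
robust regression (intercept-only linear model under a Huber M-estimator,
tuning constant 1.345 for 95% Gaussian efficiency) over the transitions
shared with the reference, so occasional gross peak-integration failures
cannot drag the constant.

Between samples, a panel of housekeeping control peptides absorbs loading
and instrument-response differences: per sample, the median control-peptide
log2 area is subtracted from every measurement.

Protein T21/CN ratios are then means of per-peptide log2 area differences
(equivalently geometric means on the natural scale), with per-peptide
coefficients of variation (CV, percent of the mean on the natural area
scale) as assay-precision metrics, and a Welch two-sample t-test on
transition-centered log2 areas as the differential-expression test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InputError

__all__ = [
    "SRMNormalizationModel",
    "SRMProteinResult",
    "ReplicateNormalizer",
    "HousekeepingNormalizer",
    "fit_replicate_normalization",
    "normalize_replicates",
    "normalize_housekeeping",
    "protein_ratio",
    "compute_cv",
    "test_differential",
]

logger = logging.getLogger(__name__)

REFERENCE = (1, 1)  # (replicate_index, injection_index)

_TRANSITION_KEY = ["protein_id", "peptide", "transition"]


def _ensure_log2(measurements: pd.DataFrame) -> pd.DataFrame:
    out = measurements.copy()
    if "log2_area" not in out.columns:
        area = out["area"].to_numpy(float)
        if np.any(~(area > 0)):
            raise InputError("areas must be strictly positive")
        out["log2_area"] = np.log2(area)
    return out


@dataclass
class SRMNormalizationModel:
    """Per-(replicate, injection) log2 alignment constants for one sample.

    ``offsets[(rep, inj)]`` is the constant c such that adding c to that
    injection's log2 areas aligns it with the reference injection
    (replicate 1, injection 1), whose constant is 0 by construction.
    """

    sample_id: str
    offsets: dict[tuple[int, int], float]
    loss: str = "huber"
    tuning_constant: float = 1.345

    def apply(self, measurements: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with aligned ``log2_area`` (and ``area``)."""
        out = _ensure_log2(measurements)
        mask = out["sample_id"] == self.sample_id
        keys = list(
            zip(out.loc[mask, "replicate_index"], out.loc[mask, "injection_index"])
        )
        shift = np.array([self.offsets.get((int(r), int(i)), 0.0) for r, i in keys])
        out.loc[mask, "log2_area"] = out.loc[mask, "log2_area"].to_numpy(float) + shift
        out.loc[mask, "area"] = 2.0 ** out.loc[mask, "log2_area"].to_numpy(float)
        return out


def _robust_location(values: np.ndarray, tuning_constant: float) -> float:
    """Huber M-estimate of location (intercept-only robust linear model)."""
    exog = np.ones((len(values), 1))
    model = sm.RLM(values, exog, M=sm.robust.norms.HuberT(t=tuning_constant))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(model.fit().params[0])


def fit_replicate_normalization(
    measurements: pd.DataFrame,
    tuning_constant: float = 1.345,
    min_shared: int = 5,
) -> SRMNormalizationModel:
    """Fit alignment constants for the injections of a single sample.

    For each non-reference (replicate, injection), the constant is the
    Huber M-estimate of ``log2_area_ref - log2_area_rep`` over shared
    transitions.

    Raises
    ------
    InputError
        If the table mixes samples, the reference injection is missing, or
        fewer than ``min_shared`` transitions are shared with the reference.
    """
    samples = measurements["sample_id"].unique()
    if len(samples) != 1:
        raise InputError(f"expected one sample, got {sorted(map(str, samples))}")
    sample_id = str(samples[0])

    df = _ensure_log2(measurements)
    groups = df.groupby(["replicate_index", "injection_index"])
    keys = {(int(r), int(i)) for r, i in groups.groups}
    if REFERENCE not in keys:
        raise InputError(
            f"reference injection (replicate 1, injection 1) missing for {sample_id}"
        )
    ref = (
        groups.get_group(REFERENCE)
        .groupby(_TRANSITION_KEY)["log2_area"]
        .mean()
    )

    offsets: dict[tuple[int, int], float] = {REFERENCE: 0.0}
    for key in sorted(keys - {REFERENCE}):
        rep = groups.get_group(key).groupby(_TRANSITION_KEY)["log2_area"].mean()
        shared = ref.index.intersection(rep.index)
        if len(shared) < min_shared:
            raise InputError(
                f"replicate {key} of {sample_id} shares only {len(shared)} transitions "
                f"with the reference (need >= {min_shared})"
            )
        diffs = (ref.loc[shared] - rep.loc[shared]).to_numpy(float)
        offsets[key] = _robust_location(diffs, tuning_constant)
    return SRMNormalizationModel(
        sample_id=sample_id, offsets=offsets, tuning_constant=tuning_constant
    )


def normalize_replicates(
    measurements: pd.DataFrame,
    tuning_constant: float = 1.345,
    min_shared: int = 5,
) -> tuple[pd.DataFrame, list[SRMNormalizationModel]]:
    """Fit and apply replicate alignment for every sample in the table."""
    out = _ensure_log2(measurements)
    models = []
    for sample_id in out["sample_id"].unique():
        model = fit_replicate_normalization(
            out[out["sample_id"] == sample_id],
            tuning_constant=tuning_constant,
            min_shared=min_shared,
        )
        out = model.apply(out)
        models.append(model)
    return out, models


class ReplicateNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around per-sample replicate alignment.

    Attributes
    ----------
    models_ : list of SRMNormalizationModel
        One fitted alignment model per sample seen during :meth:`fit`.
    """

    def __init__(self, tuning_constant: float = 1.345, min_shared: int = 5):
        self.tuning_constant = tuning_constant
        self.min_shared = min_shared

    def fit(self, X: pd.DataFrame, y=None):
        df = _ensure_log2(X)
        self.models_ = [
            fit_replicate_normalization(
                df[df["sample_id"] == sid],
                tuning_constant=self.tuning_constant,
                min_shared=self.min_shared,
            )
            for sid in df["sample_id"].unique()
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise InputError("ReplicateNormalizer is not fitted")
        out = _ensure_log2(X)
        for model in self.models_:
            out = model.apply(out)
        return out


def normalize_housekeeping(
    measurements: pd.DataFrame, control_peptides: Iterable[str]
) -> pd.DataFrame:
    """Subtract each sample's median control-peptide log2 area.

    After adjustment the median control-peptide log2 area is 0 in every
    sample, removing sample-loading and common-mode instrument effects.
    """
    control = set(map(str, control_peptides))
    if not control:
        raise InputError("empty control-peptide set")
    out = _ensure_log2(measurements)
    for sample_id, group in out.groupby("sample_id"):
        mask = group["peptide"].astype(str).isin(control)
        if not mask.any():
            raise InputError(f"no control peptides observed in sample {sample_id}")
        median = float(group.loc[mask, "log2_area"].median())
        idx = group.index
        out.loc[idx, "log2_area"] = out.loc[idx, "log2_area"] - median
    out["area"] = 2.0 ** out["log2_area"].to_numpy(float)
    return out


class HousekeepingNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around housekeeping-panel normalization.

    Attributes
    ----------
    medians_ : dict
        Per-sample median control-peptide log2 area estimated during fit.
    """

    def __init__(self, control_peptides: Sequence[str] = ()):
        self.control_peptides = control_peptides

    def fit(self, X: pd.DataFrame, y=None):
        control = set(map(str, self.control_peptides))
        if not control:
            raise InputError("empty control-peptide set")
        df = _ensure_log2(X)
        self.medians_ = {}
        for sample_id, group in df.groupby("sample_id"):
            mask = group["peptide"].astype(str).isin(control)
            if not mask.any():
                raise InputError(f"no control peptides observed in sample {sample_id}")
            self.medians_[sample_id] = float(group.loc[mask, "log2_area"].median())
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "medians_"):
            raise InputError("HousekeepingNormalizer is not fitted")
        out = _ensure_log2(X)
        shift = out["sample_id"].map(self.medians_).fillna(0.0).to_numpy(float)
        out["log2_area"] = out["log2_area"].to_numpy(float) - shift
        out["area"] = 2.0 ** out["log2_area"].to_numpy(float)
        return out


def compute_cv(areas: np.ndarray) -> float:
    """Coefficient of variation (percent) of natural-scale areas.

    Returns NaN with a warning for fewer than two measurements.
    """
    values = np.asarray(areas, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        logger.warning("CV undefined for %d measurement(s)", len(values))
        return float("nan")
    return float(100.0 * np.std(values, ddof=1) / np.mean(values))


def test_differential(
    t21_log2_areas: np.ndarray, cn_log2_areas: np.ndarray
) -> float:
    """Welch two-sample t-test on normalized log2 areas; p in (0, 1].

    Returns NaN with a warning when either group has fewer than three
    measurements or both groups are constant (degenerate variance).  The
    choice of Welch's unequal-variance test is an assumption of this
    implementation.
    """
    x = np.asarray(t21_log2_areas, dtype=float)
    y = np.asarray(cn_log2_areas, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        logger.warning(
            "differential test needs >= 3 measurements per group (got %d, %d)",
            len(x), len(y),
        )
        return float("nan")
    if np.var(x) == 0 and np.var(y) == 0:
        logger.warning("degenerate variance in both groups; p-value undefined")
        return float("nan")
    p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return max(p, np.finfo(float).tiny)


@dataclass
class SRMProteinResult:
    """Quantification of one protein in one T21 vs CN sample comparison."""

    protein_id: str
    t21_sample: str
    cn_sample: str
    ratio_t21_cn: float
    cv_percent: dict[str, float] = field(default_factory=dict)
    mean_cv_percent: float = float("nan")
    p_value: float = float("nan")
    peptide_log2_ratios: dict[str, float] = field(default_factory=dict)


def protein_ratio(
    t21_measurements: pd.DataFrame,
    cn_measurements: pd.DataFrame,
    protein_id: str,
) -> SRMProteinResult:
    """T21/CN abundance ratio of one protein between two normalized samples.

    Per shared peptide, the log2 ratio is mean(T21 log2 areas) -
    mean(CN log2 areas); the protein log2 ratio is the unweighted mean over
    peptides (a geometric mean on the natural scale).  Per-peptide CVs are
    averaged between the two samples; the p-value compares
    transition-centered log2 areas between groups with Welch's test.
    """
    t21 = _ensure_log2(t21_measurements)
    cn = _ensure_log2(cn_measurements)
    t21 = t21[t21["protein_id"].astype(str) == str(protein_id)]
    cn = cn[cn["protein_id"].astype(str) == str(protein_id)]
    t21_samples = t21["sample_id"].unique()
    cn_samples = cn["sample_id"].unique()
    if len(t21_samples) != 1 or len(cn_samples) != 1:
        raise InputError("protein_ratio expects exactly one sample per group")

    shared = sorted(set(t21["peptide"]) & set(cn["peptide"]))
    if not shared:
        raise InputError(f"no shared peptides for protein {protein_id}")

    peptide_ratios: dict[str, float] = {}
    cvs: dict[str, float] = {}
    for pep in shared:
        a = t21.loc[t21["peptide"] == pep, "log2_area"].to_numpy(float)
        b = cn.loc[cn["peptide"] == pep, "log2_area"].to_numpy(float)
        peptide_ratios[pep] = float(np.mean(a) - np.mean(b))
        cv_parts = [
            compute_cv(2.0**a),
            compute_cv(2.0**b),
        ]
        cvs[pep] = float(np.nanmean(cv_parts)) if np.isfinite(cv_parts).any() else float("nan")

    protein_log2 = float(np.mean(list(peptide_ratios.values())))

    # center each transition by its grand mean so only the group difference
    # and technical noise enter the test
    both = pd.concat([t21.assign(_grp="T21"), cn.assign(_grp="CN")])
    both["_centered"] = both["log2_area"] - both.groupby(_TRANSITION_KEY)[
        "log2_area"
    ].transform("mean")
    p = test_differential(
        both.loc[both["_grp"] == "T21", "_centered"].to_numpy(float),
        both.loc[both["_grp"] == "CN", "_centered"].to_numpy(float),
    )

    return SRMProteinResult(
        protein_id=str(protein_id),
        t21_sample=str(t21_samples[0]),
        cn_sample=str(cn_samples[0]),
        ratio_t21_cn=float(2.0**protein_log2),
        cv_percent=cvs,
        mean_cv_percent=float(np.nanmean(list(cvs.values()))),
        p_value=p,
        peptide_log2_ratios=peptide_ratios,
    )
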