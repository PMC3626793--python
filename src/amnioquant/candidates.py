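"""Control-pair-calibrated candidate selection cascade.

The euploid:euploid control pair measures how far an H/L log ratio can
stray from zero through biological and analytical variability alone.  A
Gaussian summary (mu, sigma) of the control-pair log2 normalized ratios
defines two intervals: mu +/- 2*sigma (covering 95.45% of a Gaussian null,
so ~4.55% of null proteins land outside) separates "significantly
different" from background, and mu +/- 0.5*sigma marks "no clear
differential expression".

The cascade then proceeds:

1. Flag proteins strictly outside mu +/- 2*sigma in each experimental
   pair; the union is the raw candidate pool.  Control-pair outliers are
   "variable proteins" and are excluded wherever they reappear.
2. Drop reverse (decoy) hits, known contaminants, proteins never reaching
   an outlier significance score (A or B) <= alpha in a pair where they
   were flagged, and proteins whose annotation is unknown/predicted.
3. Drop proteins with opposite-sign fold changes between experimental
   pairs that rest on few razor peptides (max per-pair ratio count below
   ``razor_min``).
4. Keep "high probability" proteins: >= 2 consistent razor peptides in
   every quantifying pair, differential expression in the same direction
   in >= 2 experimental pairs, and any further pair either agreeing in
   direction or sitting strictly inside mu +/- 0.5*sigma.

Every exclusion is recorded per protein, making the cascade auditable and
exactly reproducible — deliberately replacing the manual consistency
curation such lists traditionally receive with deterministic rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, DesignError, InputError

__all__ = [
    "PairDesign",
    "ControlVariabilityModel",
    "fit_control_variability",
    "flag_outliers",
    "build_initial_candidates",
    "filter_consistent",
    "select_high_probability",
    "classify_direction",
    "stage_counts",
    "STAGES",
]

logger = logging.getLogger(__name__)

STAGES = ("excluded", "initial", "consistency_filtered", "high_probability")

EXCLUSION_REASONS = (
    "variable_protein",
    "reverse",
    "contaminant",
    "not_significant",
    "unknown_or_predicted",
    "inconsistent_razor",
    "inconsistent_pairs",
    "insufficient_peptides",
)


@dataclass(frozen=True)
class PairDesign:
    """Design of one SILAC mixing pair."""

    pair_id: str
    pair_type: str  # "control" | "experimental"
    heavy_karyotype: str  # "CN" | "T21"
    gestational_age_weeks: float = 16.0

    def __post_init__(self) -> None:
        if self.pair_type not in ("control", "experimental"):
            raise DesignError(f"unknown pair_type {self.pair_type!r}")
        if self.heavy_karyotype not in ("CN", "T21"):
            raise DesignError(f"unknown heavy_karyotype {self.heavy_karyotype!r}")
        if self.pair_type == "control" and self.heavy_karyotype != "CN":
            raise DesignError("control pairs must have heavy_karyotype CN")
        if self.pair_type == "experimental" and self.heavy_karyotype != "T21":
            raise DesignError("experimental pairs must have heavy_karyotype T21")
        if self.gestational_age_weeks <= 0:
            raise DesignError("gestational_age_weeks must be positive")


class ControlVariabilityModel(BaseEstimator):
    """Gaussian variability model of control-pair log2 normalized ratios.

    Parameters
    ----------
    sigma_mult : float, default 2.0
        Half-width multiplier of the outlier interval (mu +/- 2*sigma
        covers 95.45% of a Gaussian).
    half_sigma_mult : float, default 0.5
        Half-width multiplier of the "no clear differential expression"
        interval.
    min_records : int, default 30
        Minimum number of finite log ratios required to fit.

    Attributes
    ----------
    mu_ : float
        Mean of the fitted log2 normalized ratios.
    sigma_ : float
        Standard deviation (ddof=1) of the same.
    interval_outlier_ : tuple of float
        (mu - sigma_mult*sigma, mu + sigma_mult*sigma).
    interval_indifferent_ : tuple of float
        (mu - half_sigma_mult*sigma, mu + half_sigma_mult*sigma).
    n_ : int
        Number of ratios used in the fit.
    """

    def __init__(self, sigma_mult: float = 2.0, half_sigma_mult: float = 0.5,
                 min_records: int = 30):
        self.sigma_mult = sigma_mult
        self.half_sigma_mult = half_sigma_mult
        self.min_records = min_records

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if len(x) < self.min_records:
            raise InputError(
                f"need >= {self.min_records} quantified control-pair records, got {len(x)}"
            )
        self.mu_ = float(np.mean(x))
        self.sigma_ = float(np.std(x, ddof=1))
        if self.sigma_ == 0.0:
            raise DegenerateInputError(
                "control-pair log ratios have zero spread; variability model is degenerate"
            )
        self.n_ = len(x)
        self.interval_outlier_ = (
            self.mu_ - self.sigma_mult * self.sigma_,
            self.mu_ + self.sigma_mult * self.sigma_,
        )
        self.interval_indifferent_ = (
            self.mu_ - self.half_sigma_mult * self.sigma_,
            self.mu_ + self.half_sigma_mult * self.sigma_,
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "mu_"):
            raise InputError("ControlVariabilityModel is not fitted")

    def is_outlier(self, log2_ratios) -> np.ndarray:
        """True where a log2 ratio lies strictly outside mu +/- 2*sigma."""
        self._check_fitted()
        x = np.asarray(log2_ratios, dtype=float)
        lo, hi = self.interval_outlier_
        return np.where(np.isfinite(x), (x < lo) | (x > hi), False)

    def is_indifferent(self, log2_ratios) -> np.ndarray:
        """True where a log2 ratio lies strictly inside mu +/- 0.5*sigma."""
        self._check_fitted()
        x = np.asarray(log2_ratios, dtype=float)
        lo, hi = self.interval_indifferent_
        return np.where(np.isfinite(x), (x > lo) & (x < hi), False)

    def predict(self, X) -> np.ndarray:
        """sklearn outlier convention: -1 for outliers, 1 for inliers."""
        return np.where(self.is_outlier(X), -1, 1)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "mu": self.mu_,
            "sigma": self.sigma_,
            "n": self.n_,
            "sigma_mult": self.sigma_mult,
            "half_sigma_mult": self.half_sigma_mult,
            "interval_outlier": list(self.interval_outlier_),
            "interval_indifferent": list(self.interval_indifferent_),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ControlVariabilityModel":
        model = cls(
            sigma_mult=float(payload["sigma_mult"]),
            half_sigma_mult=float(payload["half_sigma_mult"]),
        )
        model.mu_ = float(payload["mu"])
        model.sigma_ = float(payload["sigma"])
        model.n_ = int(payload["n"])
        model.interval_outlier_ = (
            model.mu_ - model.sigma_mult * model.sigma_,
            model.mu_ + model.sigma_mult * model.sigma_,
        )
        model.interval_indifferent_ = (
            model.mu_ - model.half_sigma_mult * model.sigma_,
            model.mu_ + model.half_sigma_mult * model.sigma_,
        )
        return model


def _log2_normalized(records: pd.DataFrame) -> np.ndarray:
    ratios = records["ratio_hl_normalized"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(np.isfinite(ratios) & (ratios > 0), np.log2(ratios), np.nan)


def fit_control_variability(
    control_records: pd.DataFrame,
    sigma_mult: float = 2.0,
    half_sigma_mult: float = 0.5,
    min_records: int = 30,
) -> ControlVariabilityModel:
    """Fit the empirical-null variability model on control-pair records."""
    model = ControlVariabilityModel(
        sigma_mult=sigma_mult, half_sigma_mult=half_sigma_mult, min_records=min_records
    )
    return model.fit(_log2_normalized(control_records))


def flag_outliers(records: pd.DataFrame, model: ControlVariabilityModel) -> set[str]:
    """Protein ids whose log2 normalized ratio lies strictly outside mu +/- 2*sigma."""
    log_ratios = _log2_normalized(records)
    median = float(np.nanmedian(log_ratios)) if np.isfinite(log_ratios).any() else 0.0
    if abs(median) > 0.01:
        logger.warning(
            "flag_outliers: input looks unnormalized (median log2 ratio %.3f != 0)", median
        )
    flagged = model.is_outlier(log_ratios)
    return set(records.loc[flagged, "protein_group_id"].astype(str))


def _experimental_ids(designs: Sequence[PairDesign]) -> tuple[str, list[str]]:
    controls = [d.pair_id for d in designs if d.pair_type == "control"]
    experimentals = [d.pair_id for d in designs if d.pair_type == "experimental"]
    if len(controls) != 1:
        raise DesignError(f"exactly one control pair required, got {len(controls)}")
    if not experimentals:
        raise DesignError("at least one experimental pair required")
    return controls[0], experimentals


def build_initial_candidates(
    pair_tables: Mapping[str, pd.DataFrame],
    designs: Sequence[PairDesign],
    model: ControlVariabilityModel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Collate per-pair outlier lists and apply the exclusion filters.

    The candidate pool is the union of the experimental pairs' outlier
    sets.  Each pooled protein is then annotated with exclusion reasons:
    ``variable_protein`` (also an outlier in the control pair), ``reverse``,
    ``contaminant``, ``not_significant`` (no pair in which the protein was
    flagged gives significance A or B <= alpha), and
    ``unknown_or_predicted``.  Proteins with no reason reach stage
    ``initial``; the rest are ``excluded`` with their reasons on record.

    Returns one row per pooled protein with per-pair ratios, ratio counts,
    outlier flags, ``exclusion_reasons`` (``;``-joined, sorted) and
    ``stage``.
    """
    control_id, experimental_ids = _experimental_ids(designs)
    for pid in [control_id, *experimental_ids]:
        if pid not in pair_tables:
            raise DesignError(f"pair {pid!r} missing from pair_tables")

    variable = flag_outliers(pair_tables[control_id], model)
    outliers = {pid: flag_outliers(pair_tables[pid], model) for pid in experimental_ids}
    pool = sorted(set().union(*outliers.values()))

    indexed = {
        pid: table.drop_duplicates("protein_group_id").set_index(
            table.drop_duplicates("protein_group_id")["protein_group_id"].astype(str)
        )
        for pid, table in pair_tables.items()
    }

    rows = []
    for protein in pool:
        reasons: set[str] = set()
        gene = ""
        is_reverse = is_contaminant = False
        annotation = "known"
        significant_somewhere = False
        row: dict = {"protein_group_id": protein}
        for pid in [control_id, *experimental_ids]:
            table = indexed[pid]
            if protein in table.index:
                rec = table.loc[protein]
                row[f"ratio_{pid}"] = float(rec["ratio_hl_normalized"])
                row[f"ratio_count_{pid}"] = int(rec["ratio_count"])
                gene = gene or str(rec.get("gene_name", ""))
                is_reverse = is_reverse or bool(rec.get("is_reverse", False))
                is_contaminant = is_contaminant or bool(rec.get("is_contaminant", False))
                status = str(rec.get("annotation_status", "known"))
                if status in ("unknown", "predicted"):
                    annotation = status
                flagged = pid != control_id and protein in outliers[pid]
                row[f"outlier_{pid}"] = bool(
                    protein in variable if pid == control_id else flagged
                )
                if flagged:
                    sig_a = float(rec.get("significance_a", np.nan))
                    sig_b = float(rec.get("significance_b", np.nan))
                    if (np.isfinite(sig_a) and sig_a <= alpha) or (
                        np.isfinite(sig_b) and sig_b <= alpha
                    ):
                        significant_somewhere = True
            else:
                row[f"ratio_{pid}"] = np.nan
                row[f"ratio_count_{pid}"] = 0
                row[f"outlier_{pid}"] = False

        if protein in variable:
            reasons.add("variable_protein")
        if is_reverse:
            reasons.add("reverse")
        if is_contaminant:
            reasons.add("contaminant")
        if not significant_somewhere:
            reasons.add("not_significant")
        if annotation in ("unknown", "predicted"):
            reasons.add("unknown_or_predicted")

        for reason in sorted(reasons):
            logger.debug("exclude %s (%s): %s", protein, gene, reason)
        row["gene_name"] = gene
        row["exclusion_reasons"] = ";".join(sorted(reasons))
        row["stage"] = "initial" if not reasons else "excluded"
        row["direction"] = "undetermined"
        rows.append(row)

    if rows:
        out = pd.DataFrame(rows)
    else:
        columns = ["protein_group_id"]
        for pid in [control_id, *experimental_ids]:
            columns += [f"ratio_{pid}", f"ratio_count_{pid}", f"outlier_{pid}"]
        columns += ["gene_name", "exclusion_reasons", "stage", "direction"]
        out = pd.DataFrame(columns=columns)
    out.attrs["control_pair"] = control_id
    out.attrs["experimental_pairs"] = list(experimental_ids)
    out.attrs["alpha"] = alpha
    out.attrs["notes"] = (
        "significance thresholds applied per pair; control-pair 2-sigma interval "
        "applied verbatim to experimental pairs"
    )
    return out


def _add_reason(df: pd.DataFrame, idx, reason: str) -> None:
    # records the exclusion; `stage` keeps the furthest stage the protein reached
    current = df.at[idx, "exclusion_reasons"]
    parts = set(current.split(";")) - {""} | {reason}
    df.at[idx, "exclusion_reasons"] = ";".join(sorted(parts))


def filter_consistent(candidates: pd.DataFrame, razor_min: int = 3) -> pd.DataFrame:
    """Remove sign-conflicting candidates supported by few razor peptides.

    A protein is removed (reason ``inconsistent_razor``) iff two
    experimental pairs show strictly opposite-sign log2 normalized ratios
    AND its maximum per-pair ratio count is below ``razor_min``.  Surviving
    ``initial`` candidates advance to stage ``consistency_filtered``;
    removed ones keep stage ``initial`` (the furthest stage reached) with
    the reason on record.
    """
    out = candidates.copy()
    experimental = out.attrs.get("experimental_pairs")
    if experimental is None:
        raise InputError("candidates table lacks experimental-pair metadata")
    for idx in out.index[out["stage"] == "initial"]:
        signs = []
        counts = []
        for pid in experimental:
            ratio = out.at[idx, f"ratio_{pid}"]
            if np.isfinite(ratio) and ratio > 0:
                signs.append(np.sign(np.log2(ratio)))
                counts.append(int(out.at[idx, f"ratio_count_{pid}"]))
        conflicting = any(s > 0 for s in signs) and any(s < 0 for s in signs)
        if conflicting and (max(counts) if counts else 0) < razor_min:
            _add_reason(out, idx, "inconsistent_razor")
            logger.debug(
                "exclude %s: inconsistent_razor (signs %s, counts %s)",
                out.at[idx, "protein_group_id"], signs, counts,
            )
        else:
            out.at[idx, "stage"] = "consistency_filtered"
    return out


def stage_counts(candidates: pd.DataFrame) -> dict[str, int]:
    """Cumulative counts of proteins that reached each cascade stage."""
    if len(candidates) == 0:
        return {"pooled": 0, "initial": 0, "consistency_filtered": 0, "high_probability": 0}
    rank = {stage: i for i, stage in enumerate(STAGES)}
    reached = candidates["stage"].map(rank)
    return {
        "pooled": int(len(candidates)),
        "initial": int((reached >= rank["initial"]).sum()),
        "consistency_filtered": int((reached >= rank["consistency_filtered"]).sum()),
        "high_probability": int((reached >= rank["high_probability"]).sum()),
    }


def classify_direction(ratio_hl_normalized: float) -> str:
    """Classify a normalized H/L ratio as decreased, increased or undetermined."""
    ratio = float(ratio_hl_normalized)
    if not np.isfinite(ratio) or ratio <= 0:
        raise InputError(f"ratio must be positive and finite, got {ratio_hl_normalized!r}")
    if ratio < 1.0:
        return "decreased"
    if ratio > 1.0:
        return "increased"
    return "undetermined"


def select_high_probability(
    candidates: pd.DataFrame,
    model: ControlVariabilityModel,
    pair_evidence: Mapping[str, pd.DataFrame],
    min_razor_peptides: int = 2,
) -> pd.DataFrame:
    """Apply the final consistency rules and assign directions.

    A ``consistency_filtered`` candidate is retained iff

    (a) in every experimental pair where it is quantified, it has at least
        ``min_razor_peptides`` razor peptides whose normalized log2 ratios
        all share the sign of the protein's normalized log2 ratio
        (``insufficient_peptides`` / ``inconsistent_razor`` otherwise);
    (b) at least two experimental pairs show differential expression
        (outside the 2-sigma interval) in the same direction
        (``inconsistent_pairs`` otherwise);
    (c) every other quantifying pair either agrees in direction or lies
        strictly inside mu +/- 0.5*sigma, i.e. shows no clear differential
        expression (``inconsistent_pairs`` otherwise).

    ``pair_evidence`` maps experimental pair id to an evidence table
    carrying ``log2_ratio_normalized`` per peptide row (as produced by the
    pipeline's quantification step).  Survivors reach stage
    ``high_probability`` with ``direction`` set from the consensus sign and
    ``ratio_hl`` set to the geometric mean of their per-pair normalized
    ratios.
    """
    out = candidates.copy()
    experimental = out.attrs.get("experimental_pairs")
    if experimental is None:
        raise InputError("candidates table lacks experimental-pair metadata")
    if "ratio_hl" not in out.columns:
        out["ratio_hl"] = np.nan

    evidence_by_protein: dict[str, dict[str, pd.DataFrame]] = {}
    for pid in experimental:
        ev = pair_evidence.get(pid)
        if ev is None:
            continue
        for protein, group in ev.groupby("protein_group_id", sort=False):
            evidence_by_protein.setdefault(str(protein), {})[pid] = group

    for idx in out.index[out["stage"] == "consistency_filtered"]:
        protein = str(out.at[idx, "protein_group_id"])
        quantifying = []
        for pid in experimental:
            ratio = out.at[idx, f"ratio_{pid}"]
            if np.isfinite(ratio) and ratio > 0:
                quantifying.append((pid, float(np.log2(ratio))))

        failed = None
        # rule (a): peptide support and within-pair peptide consistency
        for pid, log_ratio in quantifying:
            group = evidence_by_protein.get(protein, {}).get(pid)
            if group is None:
                failed = "insufficient_peptides"
                break
            razor = group[group["is_razor"].astype(bool)]
            pep_log = razor["log2_ratio_normalized"].to_numpy(float)
            pep_log = pep_log[np.isfinite(pep_log)]
            if len(pep_log) < min_razor_peptides:
                failed = "insufficient_peptides"
                break
            prot_sign = np.sign(log_ratio)
            if np.any(np.sign(pep_log) * prot_sign < 0):
                failed = "inconsistent_razor"
                break

        consensus = 0.0
        if failed is None:
            # rule (b): differential expression (2-sigma outlier) in the
            # same direction across >= 2 experimental pairs
            n_up = sum(
                1
                for pid, lr in quantifying
                if lr > 0 and bool(out.at[idx, f"outlier_{pid}"])
            )
            n_down = sum(
                1
                for pid, lr in quantifying
                if lr < 0 and bool(out.at[idx, f"outlier_{pid}"])
            )
            if max(n_up, n_down) < 2:
                failed = "inconsistent_pairs"
            else:
                consensus = 1.0 if n_up >= n_down else -1.0
                # rule (c): remaining pairs agree or show no clear change
                for pid, log_ratio in quantifying:
                    if np.sign(log_ratio) == consensus:
                        continue
                    if not model.is_indifferent([log_ratio])[0]:
                        failed = "inconsistent_pairs"
                        break

        if failed is not None:
            _add_reason(out, idx, failed)
            logger.debug("exclude %s: %s", protein, failed)
            continue

        out.at[idx, "stage"] = "high_probability"
        mean_log = float(np.mean([lr for _, lr in quantifying]))
        out.at[idx, "ratio_hl"] = 2.0**mean_log
        out.at[idx, "direction"] = "increased" if consensus > 0 else "decreased"
    return out
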