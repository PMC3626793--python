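"""Synthetic SILAC evidence and SRM peak-area generators.

The generators emulate the statistical structure of a paired SILAC
amniocyte comparison — one euploid:euploid "control" pair whose H/L
log-ratio spread defines the empirical null, plus several euploid:trisomy
"experimental" pairs in which a stated fraction of proteins carries a
consistent ~2-fold dysregulation — and of a targeted SRM verification
experiment in which each sample is measured over replicate injections
that differ by multiplicative offsets and occasionally contain gross
outlier areas.  Every simulated quantity is recorded in a ground-truth
table so each downstream stage can be tested without external data.

All randomness flows from a single integer seed.  Each pair (and the
protein-level design) gets its own ``numpy`` Generator derived from the
master seed by a fixed offset, so adding pairs never perturbs the data
of earlier pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SilacSimConfig",
    "SrmSimConfig",
    "SrmTruth",
    "simulate_silac_experiment",
    "simulate_srm_experiment",
    "CONTROL_PAIR_ID",
    "experimental_pair_id",
]

#: canonical internal column names for evidence tables
EVIDENCE_COLUMNS = [
    "protein_group_id",
    "gene_name",
    "protein_name",
    "sequence",
    "is_razor",
    "intensity_h",
    "intensity_l",
    "ratio_hl",
]

CONTROL_PAIR_ID = "control"

#: SILAC H/L ratios of the nine SRM verification candidates, used as the
#: default ground truth for the SRM simulator.
DEFAULT_SRM_TRUE_RATIOS: dict[str, float] = {
    "AKAP12": 0.41,
    "IGF2R": 0.65,
    "LCRMP": 4.38,
    "MCAM": 0.45,
    "NES": 0.18,
    "PLOD2": 7.77,
    "PYGL": 1.81,
    "SOD1": 1.91,
    "TPM2": 2.70,
}

_AMINO_ACIDS = np.array(list("ACDEFGHILNPQSTVWY"))  # sequence filler (no K/R/M/G start bias)


def experimental_pair_id(index: int) -> str:
    """Pair id of the ``index``-th experimental (euploid:trisomy) pair (1-based)."""
    return f"exp{index}"


@dataclass(frozen=True)
class SilacSimConfig:
    """Parameters of a simulated SILAC amniocyte experiment.

    Parameters
    ----------
    n_proteins:
        Total number of protein groups, including contaminant and reverse
        entries.
    frac_dysregulated:
        Fraction of *normal* proteins given a true differential effect in
        every experimental pair.
    effect_log2:
        Mean absolute log2 effect size of dysregulated proteins (1.0 = 2-fold).
        The sign is drawn symmetrically per protein and is shared across pairs.
    bio_sigma:
        Standard deviation of the protein-level null log2 H/L ratios
        (biological plus analytical pair-to-pair variability).
    peptide_count_mean:
        Mean of the zero-truncated Poisson law for razor-peptide counts.
    peptide_sigma:
        Standard deviation of peptide-level log2 ratio noise around the
        protein's pair-level ratio.
    frac_contaminant, frac_reverse:
        Fractions of protein groups emitted as known contaminants ("CON__")
        and reversed decoy hits ("REV__").
    frac_unannotated:
        Fraction of normal proteins whose name marks them as
        uncharacterized/predicted rather than a known protein.
    n_experimental_pairs:
        Number of euploid:trisomy pairs simulated alongside the single
        euploid:euploid control pair.
    global_bias_log2:
        Constant log2 offset added to every ratio (mixing or labelling bias);
        exercises the median normalization.
    dropout_rate:
        Probability that a peptide observation is missing completely at
        random in a given pair.
    frac_nonrazor:
        Fraction of peptides flagged non-razor (excluded from quantification).
    seed:
        Master seed for all random streams.
    """

    n_proteins: int = 2000
    frac_dysregulated: float = 0.10
    effect_log2: float = 1.0
    bio_sigma: float = 0.35
    peptide_count_mean: float = 6.0
    peptide_sigma: float = 0.20
    frac_contaminant: float = 0.01
    frac_reverse: float = 0.01
    frac_unannotated: float = 0.02
    n_experimental_pairs: int = 3
    global_bias_log2: float = 0.0
    dropout_rate: float = 0.0
    frac_nonrazor: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        for name in (
            "frac_dysregulated",
            "frac_contaminant",
            "frac_reverse",
            "frac_unannotated",
            "dropout_rate",
            "frac_nonrazor",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.frac_contaminant + self.frac_reverse > 1.0:
            raise ConfigurationError("frac_contaminant + frac_reverse must be <= 1")
        if self.bio_sigma <= 0:
            raise ConfigurationError(f"bio_sigma must be positive, got {self.bio_sigma}")
        if self.peptide_sigma < 0:
            raise ConfigurationError("peptide_sigma must be non-negative")
        if self.peptide_count_mean <= 0:
            raise ConfigurationError("peptide_count_mean must be positive")
        if self.effect_log2 < 0:
            raise ConfigurationError("effect_log2 must be non-negative")
        if self.n_experimental_pairs < 1:
            raise ConfigurationError("n_experimental_pairs must be >= 1")


def _design_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, 0])


def _pair_rng(seed: int, pair_index: int) -> np.random.Generator:
    # pair_index 0 = control pair, 1.. = experimental pairs
    return np.random.default_rng([seed, 1 + pair_index])


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Draw zero-truncated Poisson counts by rejection (vectorized redraw)."""
    counts = rng.poisson(mean, size)
    while True:
        zeros = counts == 0
        if not zeros.any():
            return counts
        counts[zeros] = rng.poisson(mean, int(zeros.sum()))


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 17))
    body = "".join(rng.choice(_AMINO_ACIDS, length - 1))
    terminal = "K" if rng.random() < 0.5 else "R"
    return body + terminal


def simulate_silac_experiment(
    config: SilacSimConfig,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate evidence tables for one control pair and N experimental pairs.

    Returns
    -------
    evidence:
        Mapping pair id -> evidence table (one row per peptide observation,
        columns :data:`EVIDENCE_COLUMNS`).
    truth:
        One row per protein group: ``protein_group_id``, ``gene_name``,
        ``category`` (normal | contaminant | reverse), ``is_dysregulated``,
        ``annotation_status`` and one ``true_log2_ratio_<pair>`` column per
        pair (the generating effect, before biological noise and bias).
    """
    config.validate()
    rng = _design_rng(config.seed)
    n = config.n_proteins

    n_con = int(round(config.frac_contaminant * n))
    n_rev = int(round(config.frac_reverse * n))
    category = np.array(["normal"] * n, dtype=object)
    # deterministic placement at the tail keeps ids stable as n grows
    if n_rev:
        category[n - n_rev :] = "reverse"
    if n_con:
        category[n - n_rev - n_con : n - n_rev] = "contaminant"

    base_ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    prefix = np.where(
        category == "contaminant", "CON__", np.where(category == "reverse", "REV__", "")
    )
    protein_ids = np.char.add(prefix.astype(str), base_ids.astype(str)).astype(object)
    gene_names = np.array([f"GENE{i:04d}" for i in range(n)], dtype=object)

    is_normal = category == "normal"
    annotation = np.array(["known"] * n, dtype=object)
    unannotated = is_normal & (rng.random(n) < config.frac_unannotated)
    kinds = rng.random(n) < 0.5
    annotation[unannotated & kinds] = "unknown"
    annotation[unannotated & ~kinds] = "predicted"

    protein_names = np.empty(n, dtype=object)
    for i in range(n):
        if annotation[i] == "unknown":
            protein_names[i] = f"Uncharacterized protein {base_ids[i]}"
        elif annotation[i] == "predicted":
            protein_names[i] = f"Predicted protein {base_ids[i]}"
        else:
            protein_names[i] = f"Protein {gene_names[i]}"

    is_dys = is_normal & (rng.random(n) < config.frac_dysregulated)
    signs = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    effects = np.where(is_dys, signs * config.effect_log2, 0.0)

    peptide_counts = _zero_truncated_poisson(rng, config.peptide_count_mean, n)
    base_abundance = 10.0 ** rng.normal(6.0, 0.8, n)

    peptides: list[list[str]] = []
    razor_flags: list[np.ndarray] = []
    pep_shares: list[np.ndarray] = []
    for i in range(n):
        k = int(peptide_counts[i])
        peptides.append([_random_peptide(rng) for _ in range(k)])
        flags = rng.random(k) >= config.frac_nonrazor
        if not flags.any():  # keep at least one razor peptide per protein
            flags[0] = True
        razor_flags.append(flags)
        pep_shares.append(2.0 ** rng.normal(0.0, 0.5, k))

    pair_ids = [CONTROL_PAIR_ID] + [
        experimental_pair_id(j + 1) for j in range(config.n_experimental_pairs)
    ]

    truth = pd.DataFrame(
        {
            "protein_group_id": protein_ids,
            "gene_name": gene_names,
            "category": category,
            "annotation_status": annotation,
            "is_dysregulated": is_dys,
        }
    )
    for pair in pair_ids:
        truth[f"true_log2_ratio_{pair}"] = 0.0 if pair == CONTROL_PAIR_ID else effects

    evidence: dict[str, pd.DataFrame] = {}
    for pair_index, pair in enumerate(pair_ids):
        prng = _pair_rng(config.seed, pair_index)
        true_pair = np.zeros(n) if pair == CONTROL_PAIR_ID else effects
        protein_log2 = (
            true_pair + prng.normal(0.0, config.bio_sigma, n) + config.global_bias_log2
        )
        rows: dict[str, list] = {c: [] for c in EVIDENCE_COLUMNS}
        for i in range(n):
            k = int(peptide_counts[i])
            pep_log2 = protein_log2[i] + prng.normal(0.0, config.peptide_sigma, k)
            intensity_l = base_abundance[i] * pep_shares[i]
            intensity_h = intensity_l * 2.0**pep_log2
            keep = (
                prng.random(k) >= config.dropout_rate
                if config.dropout_rate > 0
                else np.ones(k, dtype=bool)
            )
            for j in range(k):
                if not keep[j]:
                    continue
                rows["protein_group_id"].append(protein_ids[i])
                rows["gene_name"].append(gene_names[i])
                rows["protein_name"].append(protein_names[i])
                rows["sequence"].append(peptides[i][j])
                rows["is_razor"].append(bool(razor_flags[i][j]))
                rows["intensity_h"].append(intensity_h[j])
                rows["intensity_l"].append(intensity_l[j])
                rows["ratio_hl"].append(intensity_h[j] / intensity_l[j])
        evidence[pair] = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)

    return evidence, truth


# ---------------------------------------------------------------------------
# SRM peak-area simulation
# ---------------------------------------------------------------------------

#: canonical internal column names for SRM area tables
SRM_COLUMNS = [
    "sample_id",
    "group",
    "gestational_age_weeks",
    "replicate_index",
    "injection_index",
    "protein_id",
    "peptide",
    "transition",
    "area",
]


@dataclass(frozen=True)
class SrmSimConfig:
    """Parameters of a simulated SRM verification experiment.

    Each sample is injected ``n_injections`` times from each of
    ``n_replicates`` replicate preparations; non-reference replicates carry
    a multiplicative (log2-additive) offset of spread
    ``replicate_offset_sigma``, on top of within-replicate technical noise
    ``tech_sigma`` and per-sample loading offsets ``sample_loading_sigma``.
    ``outlier_frac`` of all areas are inflated by ``outlier_shift_log2``
    (>= 4) log2 units to emulate gross integration failures.
    """

    n_samples_per_group: int = 5
    n_replicates: int = 3
    n_injections: int = 2
    replicate_offset_sigma: float = 0.3
    tech_sigma: float = 0.1
    sample_loading_sigma: float = 0.3
    outlier_frac: float = 0.0
    outlier_shift_log2: float = 5.0
    true_ratios: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SRM_TRUE_RATIOS)
    )
    n_peptides_per_protein: int = 2
    n_transitions_per_peptide: int = 3
    housekeeping_peptides: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 1:
            raise ConfigurationError("n_samples_per_group must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_injections < 1:
            raise ConfigurationError("n_injections must be >= 1")
        if self.n_replicates * self.n_injections < 2:
            raise ConfigurationError("need at least 2 measurements per sample")
        for name in ("replicate_offset_sigma", "tech_sigma", "sample_loading_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.outlier_frac < 1.0:
            raise ConfigurationError("outlier_frac must lie in [0, 1)")
        if self.outlier_shift_log2 < 4.0:
            raise ConfigurationError("outlier_shift_log2 must be >= 4 log2 units")
        if not self.true_ratios:
            raise ConfigurationError("true_ratios must name at least one protein")
        for protein, ratio in self.true_ratios.items():
            if ratio <= 0:
                raise ConfigurationError(f"true ratio for {protein} must be positive")


@dataclass
class SrmTruth:
    """Ground truth of one SRM simulation."""

    true_ratios: dict[str, float]
    #: per (sample_id, replicate_index, injection_index) log2 offset
    replicate_offsets: pd.DataFrame
    #: positional indices (into the area table) of injected gross outliers
    outlier_rows: np.ndarray
    #: per-sample log2 loading offsets
    sample_loading: pd.DataFrame


def simulate_srm_experiment(config: SrmSimConfig) -> tuple[pd.DataFrame, SrmTruth]:
    """Simulate an SRM peak-area table plus its ground truth.

    log2(area) = peptide base level + group effect (T21 samples only)
    + per-sample loading + per-(replicate, injection) offset
    + per-transition response + technical noise; a fixed count
    ``round(outlier_frac * n_rows)`` of rows is additionally inflated by
    ``outlier_shift_log2``.  The reference injection (replicate 1,
    injection 1) of every sample has offset 0 by construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 100])

    proteins = list(config.true_ratios)
    peptide_names: dict[str, list[str]] = {}
    for prot in proteins:
        peptide_names[prot] = [
            f"{prot}.pep{j + 1}" for j in range(config.n_peptides_per_protein)
        ]
    housekeeping = list(config.housekeeping_peptides)

    # fixed per-peptide base abundance and per-transition response
    base_level: dict[str, float] = {}
    transition_effect: dict[tuple[str, int], float] = {}
    all_peptides: list[tuple[str, str]] = []  # (protein, peptide)
    for prot in proteins:
        for pep in peptide_names[prot]:
            all_peptides.append((prot, pep))
    for pep in housekeeping:
        all_peptides.append(("HOUSEKEEPING", pep))
    for prot, pep in all_peptides:
        base_level[pep] = float(rng.normal(20.0, 1.5))
        for t in range(config.n_transitions_per_peptide):
            transition_effect[(pep, t + 1)] = float(rng.normal(0.0, 1.0))

    groups = ["CN", "T21"]
    samples = []
    ages = np.linspace(15.0, 18.0, config.n_samples_per_group)
    for group in groups:
        for s in range(config.n_samples_per_group):
            samples.append((f"{group}-{s + 1:02d}", group, float(ages[s])))

    loading = {sid: float(rng.normal(0.0, config.sample_loading_sigma)) for sid, _, _ in samples}

    offsets_rows = []
    offsets: dict[tuple[str, int, int], float] = {}
    for sid, _, _ in samples:
        for rep in range(1, config.n_replicates + 1):
            for inj in range(1, config.n_injections + 1):
                off = (
                    0.0
                    if (rep == 1 and inj == 1)
                    else float(rng.normal(0.0, config.replicate_offset_sigma))
                )
                offsets[(sid, rep, inj)] = off
                offsets_rows.append(
                    {
                        "sample_id": sid,
                        "replicate_index": rep,
                        "injection_index": inj,
                        "offset_log2": off,
                    }
                )

    rows: dict[str, list] = {c: [] for c in SRM_COLUMNS}
    for sid, group, age in samples:
        for prot, pep in all_peptides:
            if prot == "HOUSEKEEPING":
                group_effect = 0.0
            else:
                group_effect = (
                    float(np.log2(config.true_ratios[prot])) if group == "T21" else 0.0
                )
            for rep in range(1, config.n_replicates + 1):
                for inj in range(1, config.n_injections + 1):
                    for t in range(1, config.n_transitions_per_peptide + 1):
                        log2_area = (
                            base_level[pep]
                            + group_effect
                            + loading[sid]
                            + offsets[(sid, rep, inj)]
                            + transition_effect[(pep, t)]
                            + float(rng.normal(0.0, config.tech_sigma))
                        )
                        rows["sample_id"].append(sid)
                        rows["group"].append(group)
                        rows["gestational_age_weeks"].append(age)
                        rows["replicate_index"].append(rep)
                        rows["injection_index"].append(inj)
                        rows["protein_id"].append(prot)
                        rows["peptide"].append(pep)
                        rows["transition"].append(f"{pep}.y{t}")
                        rows["area"].append(2.0**log2_area)

    areas = pd.DataFrame(rows, columns=SRM_COLUMNS)
    n_outliers = int(round(config.outlier_frac * len(areas)))
    outlier_rows = (
        rng.choice(len(areas), size=n_outliers, replace=False)
        if n_outliers
        else np.array([], dtype=int)
    )
    if n_outliers:
        areas.loc[outlier_rows, "area"] *= 2.0**config.outlier_shift_log2
    areas["is_outlier"] = False
    if n_outliers:
        areas.loc[outlier_rows, "is_outlier"] = True

    truth = SrmTruth(
        true_ratios=dict(config.true_ratios),
        replicate_offsets=pd.DataFrame(offsets_rows),
        outlier_rows=np.sort(outlier_rows),
        sample_loading=pd.DataFrame(
            {"sample_id": list(loading), "loading_log2": list(loading.values())}
        ),
    )
    return areas, truth
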