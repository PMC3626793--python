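"""Rule-based SRM assay design.

Selects proteotypic peptides for targeted triple-quadrupole assays and
builds Q1/Q3 transition lists.  The peptide filter cascade, applied per
protein in this order:

1. rank the catalog by +2 precursor survey intensity and keep the top 5;
2. eliminate peptides shorter than 7 or longer than 20 residues;
3. eliminate peptides whose +3 charge state carries a significant share
   of the signal (default: +3 / (+2 + +3) >= 0.3, i.e. the doubly charged
   precursor signal is materially split);
4. avoid peptides starting with cysteine or methionine (unstable N-termini:
   Cys side-chain chemistry, Met oxidation);
5. require uniqueness (the verdict — e.g. from a BLAST search — is an
   input flag, not computed here);
6. keep the two surviving peptides with the highest +2 intensity.

Transitions: from a survey of y-ion intensities (the paper-standard 8-ion
survey), the most intense ``n_final`` (default 3) singly charged y-ions
are retained; ties prefer the longer fragment (higher specificity).  Q1 is
the doubly protonated precursor m/z, Q3 the singly protonated y-fragment
m/z, both monoisotopic (computed with pyteomics).  Heavy SILAC labels
shift every labelled residue: Lys8 (13C6,15N2) +8.0142 Da, Arg6 (13C6)
+6.0201 Da.  Collision energy follows the common charge-2 linear rule
CE = 0.034 * Q1 + 3.314 V.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import logging
import re

import numpy as np
import pandas as pd
from pyteomics import mass as _mass

from .errors import InputError

__all__ = [
    "SRMTransition",
    "rank_and_filter_peptides",
    "choose_transitions",
    "compute_transition_mz",
    "collision_energy",
    "tryptic_peptides",
    "PEPTIDE_RULES",
    "HEAVY_SHIFTS",
]

logger = logging.getLogger(__name__)

PEPTIDE_RULES = (
    "top5_rank",
    "length_7_20",
    "no_plus3_dominance",
    "no_nterm_cys_met",
    "unique",
    "top2_final",
)

#: heavy-label mass shifts in Da per labelled residue
HEAVY_SHIFTS = {"K": 8.0142, "R": 6.0201}

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: trypsin: cleave C-terminal to K/R except before proline
_TRYPSIN_RULE = re.compile(r"[KR](?!P)")


@dataclass(frozen=True)
class SRMTransition:
    """One precursor -> y-fragment transition of the final assay."""

    sequence: str
    precursor_charge: int
    y_ion_index: int
    q1_mz: float
    q3_mz: float
    collision_energy: float
    heavy_label: str | None = None


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise InputError("empty peptide sequence")
    unknown = set(sequence) - _STANDARD_RESIDUES
    if unknown:
        raise InputError(
            f"unknown residue {sorted(unknown)[0]!r} in peptide {sequence!r}"
        )


def compute_transition_mz(
    sequence: str,
    y_ion_index: int,
    precursor_charge: int = 2,
    heavy_label: str | None = None,
) -> tuple[float, float]:
    """Monoisotopic (Q1, Q3) m/z for one peptide transition.

    Q1 is the precursor at ``precursor_charge``; Q3 the singly charged
    y-ion of length ``y_ion_index``.  ``heavy_label`` of ``"K"`` or ``"R"``
    adds the SILAC shift for every occurrence of that residue in the
    precursor and (for Q3) in the fragment.
    """
    _validate_sequence(sequence)
    if not 1 <= y_ion_index < len(sequence):
        raise InputError(
            f"y_ion_index must lie in [1, {len(sequence) - 1}] for {sequence!r}, "
            f"got {y_ion_index}"
        )
    if precursor_charge < 1:
        raise InputError("precursor_charge must be >= 1")
    if heavy_label not in (None, "K", "R"):
        raise InputError(f"heavy_label must be None, 'K' or 'R', got {heavy_label!r}")

    q1 = _mass.fast_mass(sequence, ion_type="M", charge=precursor_charge)
    fragment = sequence[-y_ion_index:]
    q3 = _mass.fast_mass(fragment, ion_type="y", charge=1)
    if heavy_label is not None:
        shift = HEAVY_SHIFTS[heavy_label]
        q1 += sequence.count(heavy_label) * shift / precursor_charge
        q3 += fragment.count(heavy_label) * shift
    return q1, q3


def collision_energy(q1_mz: float, slope: float = 0.034, intercept: float = 3.314) -> float:
    """Linear charge-2 collision-energy prediction, in volts."""
    return slope * q1_mz + intercept


def rank_and_filter_peptides(
    catalog: pd.DataFrame,
    top_n_initial: int = 5,
    top_n_final: int = 2,
    min_length: int = 7,
    max_length: int = 20,
    plus3_frac: float = 0.3,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the proteotypic-peptide filter cascade per protein.

    ``catalog`` columns: ``protein_id``, ``sequence``, ``intensity_plus2``,
    ``intensity_plus3``, ``is_unique``.  Returns a copy with one boolean
    column per rule in :data:`PEPTIDE_RULES` plus ``selected`` (all rules
    passed), and the list of proteins left with no selectable peptide (a
    design gap, reported rather than fatal).

    The four predicate rules (length, +3 dominance, N-terminal residue,
    uniqueness) are evaluated for every peptide; the two rank rules
    (top-5 initial, top-2 final) depend on the stated order.
    """
    if len(catalog) == 0:
        raise InputError("empty peptide catalog")
    required = {"protein_id", "sequence", "intensity_plus2", "intensity_plus3", "is_unique"}
    missing = required - set(catalog.columns)
    if missing:
        raise InputError(f"catalog missing columns: {sorted(missing)}")
    for seq in catalog["sequence"]:
        _validate_sequence(str(seq))

    out = catalog.copy().reset_index(drop=True)
    i2 = out["intensity_plus2"].to_numpy(float)
    i3 = out["intensity_plus3"].to_numpy(float)
    lengths = out["sequence"].str.len().to_numpy()
    with np.errstate(invalid="ignore"):
        frac3 = np.where(i2 + i3 > 0, i3 / (i2 + i3), 0.0)

    out["length_7_20"] = (lengths >= min_length) & (lengths <= max_length)
    out["no_plus3_dominance"] = frac3 < plus3_frac
    out["no_nterm_cys_met"] = ~out["sequence"].str[0].isin(["C", "M"])
    out["unique"] = out["is_unique"].astype(bool)
    out["top5_rank"] = False
    out["top2_final"] = False

    design_gaps: list[str] = []
    for protein, group in out.groupby("protein_id", sort=False):
        ranked = group.sort_values(
            ["intensity_plus2", "sequence"], ascending=[False, True]
        )
        top5 = ranked.index[:top_n_initial]
        out.loc[top5, "top5_rank"] = True
        survivors = out.loc[top5]
        survivors = survivors[
            survivors["length_7_20"]
            & survivors["no_plus3_dominance"]
            & survivors["no_nterm_cys_met"]
            & survivors["unique"]
        ]
        final = survivors.sort_values(
            ["intensity_plus2", "sequence"], ascending=[False, True]
        ).index[:top_n_final]
        out.loc[final, "top2_final"] = True
        if len(final) == 0:
            design_gaps.append(str(protein))
            logger.warning("no selectable SRM peptide for protein %s", protein)

    out["selected"] = out[list(PEPTIDE_RULES)].all(axis=1)
    return out, design_gaps


def choose_transitions(
    sequence: str,
    survey: Mapping[int, float],
    n_final: int = 3,
    precursor_charge: int = 2,
    heavy_label: str | None = None,
    ce_slope: float = 0.034,
    ce_intercept: float = 3.314,
) -> list[SRMTransition]:
    """Keep the ``n_final`` most intense surveyed y-ion transitions.

    ``survey`` maps y-ion index to measured survey intensity.  Ties are
    broken toward the larger y-ion index (the longer fragment is more
    specific).  If fewer than ``n_final`` ions were surveyed, all are
    retained and a warning is logged.
    """
    if not survey:
        raise InputError("empty y-ion survey")
    if len(survey) < n_final:
        logger.warning(
            "only %d surveyed y-ions for %s (requested %d); keeping all",
            len(survey), sequence, n_final,
        )
    ranked = sorted(survey.items(), key=lambda item: (-item[1], -item[0]))
    chosen = sorted(idx for idx, _ in ranked[:n_final])
    transitions = []
    for y_index in chosen:
        q1, q3 = compute_transition_mz(
            sequence, y_index, precursor_charge=precursor_charge, heavy_label=heavy_label
        )
        transitions.append(
            SRMTransition(
                sequence=sequence,
                precursor_charge=precursor_charge,
                y_ion_index=y_index,
                q1_mz=q1,
                q3_mz=q3,
                collision_energy=collision_energy(q1, ce_slope, ce_intercept),
                heavy_label=heavy_label,
            )
        )
    return transitions


def tryptic_peptides(protein_sequence: str, min_length: int = 1) -> list[str]:
    """Fully tryptic peptides (cleave after K/R, not before P, 0 missed cleavages).

    Returns peptides in N-to-C order, keeping duplicates out but
    preserving first occurrence.
    """
    _validate_sequence(protein_sequence)
    pieces = []
    start = 0
    for match in _TRYPSIN_RULE.finditer(protein_sequence):
        end = match.end()
        pieces.append(protein_sequence[start:end])
        start = end
    if start < len(protein_sequence):
        pieces.append(protein_sequence[start:])
    seen = set()
    out = []
    for pep in pieces:
        if len(pep) >= min_length and pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out
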