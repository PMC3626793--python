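"""Table readers and writers for the pipeline's file formats.

Proteomics tables (evidence, protein groups, candidate reports) are
tab-delimited with a header, using MaxQuant-era column names by default;
SRM area and transition tables are CSV in the dialect common SRM software
imports.  All files are UTF-8 with "." as the decimal point.  Column-name
maps are configurable so tables from other processing tools can be read
without rewriting headers; unknown columns are preserved untouched.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .candidates import PairDesign
from .errors import InputError
from .srm_design import SRMTransition

__all__ = [
    "MAXQUANT_PROTEIN_COLUMNS",
    "MAXQUANT_EVIDENCE_COLUMNS",
    "read_protein_groups",
    "write_protein_groups",
    "read_evidence",
    "write_evidence",
    "read_srm_areas",
    "write_srm_areas",
    "write_transition_list",
    "read_transition_list",
    "read_pair_designs",
    "load_high_probability_table",
    "load_housekeeping_peptides",
]

logger = logging.getLogger(__name__)

#: default file-header -> internal-name map for protein-group tables
MAXQUANT_PROTEIN_COLUMNS: dict[str, str] = {
    "Protein IDs": "protein_group_id",
    "Gene Names": "gene_name",
    "Protein Names": "protein_name",
    "Ratio H/L": "ratio_hl_raw",
    "Ratio H/L Normalized": "ratio_hl_normalized",
    "Ratio H/L Count": "ratio_count",
    "Intensity": "intensity_total",
    "Significance A": "significance_a",
    "Significance B": "significance_b",
    "Reverse": "is_reverse",
    "Contaminant": "is_contaminant",
    "Annotation status": "annotation_status",
}

#: default file-header -> internal-name map for evidence tables
MAXQUANT_EVIDENCE_COLUMNS: dict[str, str] = {
    "Protein IDs": "protein_group_id",
    "Gene Names": "gene_name",
    "Protein Names": "protein_name",
    "Sequence": "sequence",
    "Razor": "is_razor",
    "Intensity H": "intensity_h",
    "Intensity L": "intensity_l",
    "Ratio H/L": "ratio_hl",
}

_FLAG_COLUMNS = {"is_reverse", "is_contaminant", "is_razor"}
_MANDATORY_PROTEIN = ("protein_group_id", "ratio_hl_raw")
_MANDATORY_EVIDENCE = ("protein_group_id", "sequence", "ratio_hl")

SRM_AREA_COLUMNS: dict[str, str] = {
    "sample": "sample_id",
    "group": "group",
    "gestational_age_weeks": "gestational_age_weeks",
    "replicate": "replicate_index",
    "injection": "injection_index",
    "protein": "protein_id",
    "peptide": "peptide",
    "transition": "transition",
    "area": "area",
}


def _decode_flag(values: pd.Series) -> pd.Series:
    if values.dtype == bool:
        return values
    text = values.astype(str).str.strip().str.lower()
    return text.isin(["+", "true", "1", "yes"])


def _read_table(
    path: str | Path,
    column_map: Mapping[str, str],
    mandatory: Sequence[str],
    sep: str,
) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    rename = {file_col: name for file_col, name in column_map.items() if file_col in df}
    # accept tables already using internal names
    for name in column_map.values():
        if name in df.columns:
            rename[name] = name
    df = df.rename(columns=rename)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing mandatory column(s) {missing}")
    return df


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    for col in columns:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_protein_groups(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a protein-groups table; rows with unparsable ratios are skipped.

    The number of skipped rows is reported in ``df.attrs['n_skipped']``
    and logged.
    """
    df = _read_table(path, column_map or MAXQUANT_PROTEIN_COLUMNS, _MANDATORY_PROTEIN, "\t")
    n_rows = len(df)
    raw = pd.to_numeric(df["ratio_hl_raw"], errors="coerce")
    original = df["ratio_hl_raw"].astype(str).str.strip()
    # NaN-coded entries ("", "NaN") are legitimately unquantified; anything
    # else unparsable is a corrupt row and is dropped with a warning
    unquantified = original.isin(["", "nan", "NaN", "NA"])
    bad = raw.isna() & ~unquantified
    if bad.any():
        for idx in df.index[bad][:10]:
            logger.warning("%s: skipping row %d, unparsable ratio %r",
                           path, idx, df.at[idx, "ratio_hl_raw"])
        df = df[~bad]
    df = df.copy()
    df = _coerce_numeric(
        df,
        [
            "ratio_hl_raw",
            "ratio_hl_normalized",
            "ratio_count",
            "intensity_total",
            "significance_a",
            "significance_b",
        ],
    )
    if "ratio_count" in df.columns:
        df["ratio_count"] = df["ratio_count"].fillna(0).astype(int)
    for col in ("is_reverse", "is_contaminant"):
        if col in df.columns:
            df[col] = _decode_flag(df[col])
        else:
            df[col] = False
    if "annotation_status" not in df.columns:
        df["annotation_status"] = "known"
    df = df.reset_index(drop=True)
    df.attrs["n_skipped"] = int(bad.sum())
    df.attrs["n_rows"] = len(df)
    logger.info("%s: read %d protein groups (%d skipped)", path, len(df), int(bad.sum()))
    return df


def write_protein_groups(
    df: pd.DataFrame, path: str | Path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write a protein-groups table with file-format column names."""
    column_map = column_map or MAXQUANT_PROTEIN_COLUMNS
    inverse = {name: file_col for file_col, name in column_map.items()}
    out = df.copy()
    for col in _FLAG_COLUMNS & set(out.columns):
        out[col] = np.where(out[col].astype(bool), "+", "")
    out = out.rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


def read_evidence(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a peptide evidence table."""
    df = _read_table(path, column_map or MAXQUANT_EVIDENCE_COLUMNS, _MANDATORY_EVIDENCE, "\t")
    df = df.copy()
    df = _coerce_numeric(df, ["intensity_h", "intensity_l", "ratio_hl", "log2_ratio_normalized"])
    if "is_razor" in df.columns:
        df["is_razor"] = _decode_flag(df["is_razor"])
    else:
        df["is_razor"] = True
    return df.reset_index(drop=True)


def write_evidence(
    df: pd.DataFrame, path: str | Path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write a peptide evidence table with file-format column names."""
    column_map = column_map or MAXQUANT_EVIDENCE_COLUMNS
    inverse = {name: file_col for file_col, name in column_map.items()}
    out = df.copy()
    if "is_razor" in out.columns:
        out["is_razor"] = np.where(out["is_razor"].astype(bool), "+", "")
    out = out.rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


def read_srm_areas(path: str | Path) -> pd.DataFrame:
    """Read an SRM peak-area CSV table."""
    df = pd.read_csv(path, comment="#")
    rename = {c: SRM_AREA_COLUMNS[c] for c in df.columns if c in SRM_AREA_COLUMNS}
    df = df.rename(columns=rename)
    missing = [c for c in ("sample_id", "replicate_index", "injection_index",
                           "protein_id", "peptide", "transition", "area")
               if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing mandatory column(s) {missing}")
    df = _coerce_numeric(df, ["gestational_age_weeks", "area"])
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["injection_index"] = df["injection_index"].astype(int)
    if (df["area"] <= 0).any() or df["area"].isna().any():
        raise InputError(f"{path}: areas must be strictly positive")
    return df


def write_srm_areas(df: pd.DataFrame, path: str | Path) -> None:
    """Write an SRM peak-area CSV table."""
    inverse = {name: file_col for file_col, name in SRM_AREA_COLUMNS.items()}
    df.rename(columns=inverse).to_csv(path, index=False)


def write_transition_list(
    transitions: Iterable[SRMTransition],
    path: str | Path,
    protein_ids: Mapping[str, str] | None = None,
    instrument_settings: Mapping[str, str] | None = None,
) -> None:
    """Write a vendor-neutral transition-list CSV.

    ``protein_ids`` optionally maps peptide sequence to protein id.
    ``instrument_settings`` are recorded as ``#``-prefixed header comments
    (they carry no computational content).
    """
    rows = []
    for t in transitions:
        rows.append(
            {
                "protein": (protein_ids or {}).get(t.sequence, ""),
                "peptide": t.sequence,
                "precursor_charge": t.precursor_charge,
                "q1_mz": round(t.q1_mz, 4),
                "q3_mz": round(t.q3_mz, 4),
                "y_ion_index": t.y_ion_index,
                "collision_energy": round(t.collision_energy, 2),
                "label": t.heavy_label or "light",
            }
        )
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        for key, value in (instrument_settings or {}).items():
            handle.write(f"# {key}: {value}\n")
        pd.DataFrame(rows).to_csv(handle, index=False)


def read_transition_list(path: str | Path) -> pd.DataFrame:
    """Read a transition-list CSV (header comments ignored)."""
    return pd.read_csv(path, comment="#")


def read_pair_designs(path: str | Path) -> list[PairDesign]:
    """Read pair designs from a YAML or JSON file.

    Expected structure: a list of mappings with keys ``pair_id``,
    ``pair_type``, ``heavy_karyotype`` and optional
    ``gestational_age_weeks``.
    """
    with open(path, "r", encoding="utf-8") as handle:
        payload = yaml.safe_load(handle)
    if not isinstance(payload, list):
        raise InputError(f"{path}: expected a list of pair designs")
    designs = []
    for entry in payload:
        designs.append(
            PairDesign(
                pair_id=str(entry["pair_id"]),
                pair_type=str(entry["pair_type"]),
                heavy_karyotype=str(entry["heavy_karyotype"]),
                gestational_age_weeks=float(entry.get("gestational_age_weeks", 16.0)),
            )
        )
    return designs


def _data_path(name: str):
    return importlib.resources.files("amnioquant.data").joinpath(name)


def load_high_probability_table() -> pd.DataFrame:
    """Packaged transcription of the published high-probability protein list.

    Columns: ``gene_name``, ``protein_name``, ``ratio_hl`` (normalized H/L)
    and the published ``direction`` label.
    """
    with importlib.resources.as_file(_data_path("high_probability_proteins.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["ratio_hl"] = df["ratio_hl"].astype(float)
    return df


def load_housekeeping_peptides() -> pd.DataFrame:
    """Packaged synthetic stand-in list of housekeeping control peptides.

    Ten tryptic peptides of seven high-abundance housekeeping proteins;
    the sequences are synthetic stand-ins for the published control-peptide
    panel (see the file header).  Columns: ``gene_name``, ``sequence``.
    """
    with importlib.resources.as_file(
        _data_path("housekeeping_peptides_synthetic.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")
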