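import numpy as np
import pandas as pd
import pytest

import amnioquant as aq


@pytest.fixture(scope="session")
def small_silac():
    """A small simulated SILAC experiment shared across read-only tests."""
    config = aq.SilacSimConfig(n_proteins=400, seed=7)
    evidence, truth = aq.simulate_silac_experiment(config)
    return config, evidence, truth


@pytest.fixture(scope="session")
def quantified_pairs(small_silac):
    """Protein tables + augmented evidence for every pair of `small_silac`."""
    _config, evidence, _truth = small_silac
    tables, augmented = {}, {}
    for pair_id, ev in evidence.items():
        tables[pair_id], augmented[pair_id] = aq.quantify_pair(ev)
    return tables, augmented


def make_protein_table(log2_ratios, prefix="P", intensity=None, ratio_count=5):
    """Build a minimal normalized protein-group table from log2 ratios."""
    log2_ratios = np.asarray(log2_ratios, dtype=float)
    n = len(log2_ratios)
    intensity = np.full(n, 1e6) if intensity is None else np.asarray(intensity, float)
    return pd.DataFrame(
        {
            "protein_group_id": [f"{prefix}{i:04d}" for i in range(n)],
            "gene_name": [f"G{i:04d}" for i in range(n)],
            "protein_name": [f"Protein G{i:04d}" for i in range(n)],
            "ratio_hl_raw": 2.0**log2_ratios,
            "ratio_hl_normalized": 2.0**log2_ratios,
            "ratio_count": ratio_count,
            "intensity_total": intensity,
            "significance_a": 0.01,
            "significance_b": 0.01,
            "is_reverse": False,
            "is_contaminant": False,
            "annotation_status": "known",
        }
    )
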