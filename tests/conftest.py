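"""Shared fixtures: tiny on-disk tables and simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from permdiff.io import ChannelInfo, PeptideQuantTable


@pytest.fixture()
def channel_map():
    return {
        "young_1": ChannelInfo("young", 1),
        "young_2": ChannelInfo("young", 2),
        "young_3": ChannelInfo("young", 3),
        "sen_1": ChannelInfo("senescent", 1),
        "sen_2": ChannelInfo("senescent", 2),
        "sen_3": ChannelInfo("senescent", 3),
    }


@pytest.fixture()
def peptide_tsv(tmp_path, channel_map):
    """3-peptide fixture TSV with 6 channels."""
    rows = [
        ["pep1", "PROT1", True, 0.95, 100.0, 110.0, 90.0, 200.0, 210.0, 190.0],
        ["pep2", "PROT1", True, 0.80, 50.0, 55.0, 45.0, 52.0, 48.0, 51.0],
        ["pep3", "PROT2;PROT3", False, 0.99, 10.0, 12.0, 11.0, 9.0, 10.0, 11.0],
    ]
    df = pd.DataFrame(rows, columns=["peptide_id", "protein_group",
                                     "is_unique", "isolation_purity",
                                     *channel_map])
    path = tmp_path / "peptides.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture()
def peptide_table(peptide_tsv, channel_map):
    from permdiff.io import read_peptide_table
    return read_peptide_table(peptide_tsv, channel_map)


@pytest.fixture()
def expression_tsv(tmp_path):
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(10)]
    samples = [f"s{i}" for i in range(6)]
    df = pd.DataFrame(rng.normal(8, 1, size=(10, 6)), index=genes,
                      columns=samples)
    path = tmp_path / "expr.tsv"
    df.to_csv(path, sep="\t", index_label="gene_id")
    groups = {f"s{i}": ("a" if i < 3 else "b") for i in range(6)}
    return path, groups


def make_peptide_table(intensities: np.ndarray, channel_map,
                       protein_groups=None, purity=0.95, unique=True):
    """Helper: wrap a peptides x 6 intensity array into a table."""
    n = intensities.shape[0]
    if protein_groups is None:
        protein_groups = [f"P{i // 2}" for i in range(n)]
    df = pd.DataFrame({
        "peptide_id": [f"pep{i}" for i in range(n)],
        "protein_group": protein_groups,
        "is_unique": [unique] * n if isinstance(unique, bool) else unique,
        "isolation_purity": [purity] * n if np.isscalar(purity) else purity,
    })
    for j, ch in enumerate(channel_map):
        df[ch] = intensities[:, j]
    return PeptideQuantTable(data=df, channels=dict(channel_map))
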