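import numpy as np
import pandas as pd
import pytest

from tpp2d import QuantTable, SimConfig, simulate_dataset


def make_long_df(rows):
    """rows: (protein, peptide, ligand, conc, temp, rep, intensity) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "peptide", "ligand", "concentration_nM",
            "temperature_C", "replicate", "intensity",
        ],
    )


@pytest.fixture
def toy_peptides() -> QuantTable:
    """One run of PROT1 with four peptides and PROT2 with one peptide."""
    rows = [
        ("PROT1", "AAAK", "ACTH", 500.0, 37.0, 1, 100.0),
        ("PROT1", "CCCK", "ACTH", 500.0, 37.0, 1, 80.0),
        ("PROT1", "DDDK", "ACTH", 500.0, 37.0, 1, 60.0),
        ("PROT1", "EEEK", "ACTH", 500.0, 37.0, 1, 10.0),
        ("PROT2", "FFFK", "ACTH", 500.0, 37.0, 1, 50.0),
    ]
    return QuantTable(make_long_df(rows), level="peptide")


@pytest.fixture
def one_protein_two_conc() -> QuantTable:
    """PROT1 at one temperature: vehicle [8,8,8], 500 nM [16,16,16]."""
    rows = []
    for r, v in enumerate([8.0, 8.0, 8.0], start=1):
        rows.append(("PROT1", "", "vehicle", 0.0, 52.0, r, v))
    for r, v in enumerate([16.0, 16.0, 16.0], start=1):
        rows.append(("PROT1", "", "ACTH", 500.0, 52.0, r, v))
    return QuantTable(make_long_df(rows), level="protein")


@pytest.fixture(scope="session")
def small_affected_sim():
    """Small mixed-direction simulation with low noise, reused across tests."""
    cfg = SimConfig(
        n_proteins=40, fraction_affected=0.25, noise_cv=0.05,
        destabilized_fraction=0.5, seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_sim():
    cfg = SimConfig(n_proteins=80, fraction_affected=0.0, noise_cv=0.1, seed=5)
    return simulate_dataset(cfg)
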