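"""Experimental design description for a 2D thermal proteome profiling run.

A 2D-TPP experiment crosses a temperature gradient with a ligand
concentration series (including a vehicle control at concentration 0),
measured in replicate. The defaults below describe the canonical design
this package targets: 7 temperatures from 37 to 67 °C in 5 °C steps,
concentrations {0, 20, 100, 500} nM, and 3 replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

#: Canonical long-format column names, in output order.
COLUMNS = [
    "protein_id",
    "peptide",
    "ligand",
    "concentration_nM",
    "temperature_C",
    "replicate",
    "intensity",
]

#: Key columns that must be unique per row in a quantitative table.
KEY_COLUMNS = [
    "protein_id",
    "peptide",
    "ligand",
    "concentration_nM",
    "temperature_C",
    "replicate",
]

DEFAULT_TEMPERATURES = (37.0, 42.0, 47.0, 52.0, 57.0, 62.0, 67.0)
DEFAULT_CONCENTRATIONS = (0.0, 20.0, 100.0, 500.0)
DEFAULT_REPLICATES = 3

#: Default label for vehicle (solvent-only) rows; vehicle is always c = 0.
VEHICLE_LABEL = "vehicle"


@dataclass(frozen=True)
class DesignSummary:
    """Expected measurement grid: temperatures × concentrations × replicates.

    Parameters
    ----------
    temperatures
        Strictly increasing list of incubation temperatures in °C.
    concentrations
        Strictly increasing list of ligand concentrations in nM; the first
        element must be 0 (the vehicle control).
    replicates
        Number of biological replicates per condition.
    ligands
        Treatment labels, excluding the vehicle label.
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    replicates: int = DEFAULT_REPLICATES
    ligands: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        concs = tuple(float(c) for c in self.concentrations)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "concentrations", concs)
        object.__setattr__(self, "ligands", tuple(self.ligands))
        if len(temps) < 1 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        if len(concs) < 1 or any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        if concs[0] != 0.0:
            raise ValueError("first concentration must be 0 (vehicle)")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")

    @property
    def treatment_concentrations(self) -> tuple[float, ...]:
        return self.concentrations[1:]

    @classmethod
    def from_table(cls, data: pd.DataFrame) -> "DesignSummary":
        """Infer the design realized in a long-format table."""
        temps = tuple(sorted(data["temperature_C"].unique()))
        concs = tuple(sorted(data["concentration_nM"].unique()))
        reps = int(data["replicate"].max())
        ligands = tuple(
            sorted(
                data.loc[data["concentration_nM"] > 0, "ligand"]
                .astype(str)
                .unique()
            )
        )
        return cls(temps, concs, reps, ligands)

    def n_cells_per_protein(self) -> int:
        """Expected number of (ligand, temperature, concentration, replicate)
        cells per protein: each ligand gets the non-zero concentration series,
        and the vehicle series at c = 0 is shared."""
        n_lig = max(len(self.ligands), 1)
        n_treat = len(self.treatment_concentrations)
        return len(self.temperatures) * self.replicates * (n_lig * n_treat + 1)


def sample_id(row: pd.Series | dict) -> str:
    """Stable sample identifier ``ligand_<c>nM_<T>C_r<rep>`` for matrix columns."""
    c = row["concentration_nM"]
    t = row["temperature_C"]
    return (
        f"{row['ligand']}_{c:g}nM_{t:g}C_r{int(row['replicate'])}"
    )
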