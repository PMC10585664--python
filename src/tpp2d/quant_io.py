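"""Reading, validation and TOP3 protein quantitation of label-free tables.

Input tables are long-format TSV/CSV exports of a label-free (DIA)
quantitation run: one row per observed intensity, keyed by
(protein, peptide, ligand, concentration, temperature, replicate).
Wide-format exports (one intensity column per LC-MS run) are supported
through a run-annotation sidecar mapping each run column to its condition.

Protein-level quantities are derived from peptide intensities with the TOP3
rule: the arithmetic mean of the three most intense peptides of a protein
within a run. Zero intensities are treated as *missing* (not detected), never
as an abundance of zero, and are dropped on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import COLUMNS, KEY_COLUMNS, DesignSummary

logger = logging.getLogger(__name__)

_REQUIRED = ["protein_id", "ligand", "concentration_nM", "temperature_C", "replicate", "intensity"]


class QuantTableError(ValueError):
    """Raised for malformed quantitative tables (duplicate keys, bad values)."""


class ConfigError(ValueError):
    """Raised for invalid column mappings or run configuration."""


@dataclass
class QuantTable:
    """A validated long-format intensity table.

    Attributes
    ----------
    data
        DataFrame with the canonical columns (see :data:`tpp2d.design.COLUMNS`).
    level
        ``"peptide"`` or ``"protein"``.
    n_dropped
        Rows removed on construction (non-numeric, negative, or zero
        intensity — zero means "not detected" in label-free LC-MS).
    """

    data: pd.DataFrame
    level: str = "protein"
    n_dropped: int = 0
    extra_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.level not in ("peptide", "protein"):
            raise ConfigError(f"level must be 'peptide' or 'protein', got {self.level!r}")
        df = self.data.copy()
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ConfigError(f"missing required column(s): {', '.join(missing)}")
        if "peptide" not in df.columns:
            df["peptide"] = ""
        df["peptide"] = df["peptide"].fillna("").astype(str)
        if self.level == "protein" and (df["peptide"] != "").any():
            raise QuantTableError("protein-level table must have an empty peptide field")

        n0 = len(df)
        df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
        df = df[df["intensity"].notna() & (df["intensity"] > 0)]
        dropped = n0 - len(df)
        if dropped:
            logger.info("dropped %d row(s) with missing/zero/negative intensity", dropped)

        for col in ("concentration_nM", "temperature_C"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
        if (df["replicate"] < 1).any():
            raise QuantTableError("replicate indices must be positive integers")
        if (df["concentration_nM"] < 0).any():
            raise QuantTableError("concentrations must be non-negative")

        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            first = df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise QuantTableError(f"duplicate observation key: {first}")

        extra = [c for c in df.columns if c not in COLUMNS]
        df = df[COLUMNS + extra].reset_index(drop=True)
        self.data = df
        self.n_dropped = self.n_dropped + dropped
        self.extra_columns = tuple(extra)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def design(self) -> DesignSummary:
        return DesignSummary.from_table(self.data)

    @property
    def ligands(self) -> tuple[str, ...]:
        return self.design.ligands


def _apply_mapping(df: pd.DataFrame, columns: dict | None) -> pd.DataFrame:
    if not columns:
        return df
    rename = {}
    for canonical, actual in columns.items():
        if actual not in df.columns:
            raise ConfigError(f"mapped column {actual!r} (for {canonical!r}) not in file")
        rename[actual] = canonical
    return df.rename(columns=rename)


def read_quant_table(
    path: str | Path,
    format_spec: dict | None = None,
    level: str = "protein",
) -> QuantTable:
    """Read a TSV/CSV intensity table into a validated :class:`QuantTable`.

    Parameters
    ----------
    path
        Input file. Lines starting with ``#`` are treated as metadata and
        skipped.
    format_spec
        Optional dict with keys:

        ``delimiter``
            Field separator (default tab).
        ``columns``
            Mapping of canonical name -> column name in the file.
        ``format``
            ``"long"`` (default) or ``"wide"``. Wide format has one intensity
            column per run and requires ``run_annotation``.
        ``run_annotation``
            For wide format: path to (or DataFrame of) a sidecar table with a
            ``run`` column naming each intensity column plus the canonical
            condition columns (ligand, concentration_nM, temperature_C,
            replicate).
    level
        ``"peptide"`` or ``"protein"``.
    """
    spec = dict(format_spec or {})
    sep = spec.get("delimiter", "\t")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    df = _apply_mapping(df, spec.get("columns"))

    if spec.get("format", "long") == "wide":
        ann = spec.get("run_annotation")
        if ann is None:
            raise ConfigError("wide format requires a 'run_annotation' sidecar")
        if not isinstance(ann, pd.DataFrame):
            ann = pd.read_csv(ann, sep=sep, comment="#")
        if "run" not in ann.columns:
            raise ConfigError("run annotation must contain a 'run' column")
        runs = ann["run"].astype(str).tolist()
        missing_runs = [r for r in runs if r not in df.columns]
        if missing_runs:
            raise ConfigError(f"run column(s) absent from table: {missing_runs[:3]}")
        id_cols = [c for c in df.columns if c not in runs]
        long = df.melt(id_vars=id_cols, value_vars=runs, var_name="run", value_name="intensity")
        long = long.merge(ann, on="run", how="left").drop(columns=["run"])
        long = long[long["intensity"].notna()]
        df = long

    return QuantTable(df, level=level)


def write_quant_table(
    table: QuantTable, path: str | Path, metadata: dict | None = None
) -> None:
    """Write the canonical long-format TSV, with ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        # %.17g guarantees write->read round-trips to full float64 precision
        table.data.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def top3_quantify(peptides: QuantTable) -> QuantTable:
    """TOP3 protein quantitation from a peptide-level table.

    For each (protein, ligand, concentration, temperature, replicate) run,
    the protein intensity is the arithmetic mean of the three largest peptide
    intensities. Proteins observed with only 1-2 peptides in a run are
    quantified from those and flagged ``low_evidence``; modified and
    unmodified forms of a sequence count as distinct peptides.
    """
    if peptides.level != "peptide":
        raise ConfigError("top3_quantify requires a peptide-level table")
    if len(peptides) == 0:
        raise QuantTableError("empty peptide table")

    run_keys = ["protein_id", "ligand", "concentration_nM", "temperature_C", "replicate"]
    df = peptides.data
    # nlargest per group: sort desc and take head(3) — permutation-invariant
    # because values, not row order, decide rank.
    s = df.sort_values("intensity", ascending=False, kind="mergesort")
    top = s.groupby(run_keys, sort=False).head(3)
    agg = top.groupby(run_keys, sort=True)["intensity"].agg(["mean", "size"]).reset_index()
    agg = agg.rename(columns={"mean": "intensity", "size": "n_peptides"})
    agg["low_evidence"] = agg["n_peptides"] < 3
    agg["peptide"] = ""
    return QuantTable(agg, level="protein")


def validate_design(
    table: QuantTable, expected: DesignSummary | None = None
) -> pd.DataFrame:
    """Report missing (ligand, temperature, concentration, replicate) cells.

    Every protein is checked against the full expected grid: for each
    treatment ligand the non-zero concentration series, plus the shared
    vehicle series at c = 0. Returns one row per protein with the missing-cell
    count; the missing cells themselves are attached as ``report.attrs["missing"]``.
    The table is not modified.
    """
    design = expected or table.design
    cells = []
    for t in design.temperatures:
        for r in range(1, design.replicates + 1):
            cells.append(("__vehicle__", 0.0, t, r))
            for lig in design.ligands:
                for c in design.treatment_concentrations:
                    cells.append((lig, c, t, r))
    grid = pd.DataFrame(cells, columns=["ligand", "concentration_nM", "temperature_C", "replicate"])

    obs = table.data[["protein_id", "ligand", "concentration_nM", "temperature_C", "replicate"]].copy()
    obs.loc[obs["concentration_nM"] == 0, "ligand"] = "__vehicle__"
    obs = obs.drop_duplicates()

    proteins = table.data["protein_id"].unique()
    full = grid.assign(key=1).merge(pd.DataFrame({"protein_id": proteins, "key": 1}), on="key").drop(columns="key")
    merged = full.merge(obs, how="left", indicator=True,
                        on=["protein_id", "ligand", "concentration_nM", "temperature_C", "replicate"])
    missing = merged[merged["_merge"] == "left_only"].drop(columns="_merge")
    missing.loc[missing["ligand"] == "__vehicle__", "ligand"] = "vehicle"

    counts = (
        missing.groupby("protein_id").size().reindex(proteins, fill_value=0).rename("n_missing").reset_index()
    )
    counts.attrs["missing"] = missing.reset_index(drop=True)
    return counts


class Top3Aggregator(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`top3_quantify`.

    Stateless; ``fit`` only validates input so the class composes with
    sklearn pipelines operating on long-format DataFrames.
    """

    def fit(self, X: QuantTable | pd.DataFrame, y=None) -> "Top3Aggregator":
        X = self._as_table(X)
        self.n_peptide_rows_in_ = len(X)
        return self

    def transform(self, X: QuantTable | pd.DataFrame) -> QuantTable:
        return top3_quantify(self._as_table(X))

    @staticmethod
    def _as_table(X) -> QuantTable:
        if isinstance(X, QuantTable):
            return X
        return QuantTable(X, level="peptide")
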