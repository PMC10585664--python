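"""Downstream summaries: differential expression at the reference
temperature, phosphopeptide presence accounting, multi-ligand hit
intersections, and matrix export for external pathway / transcription-factor
tools.

Differential expression uses the lowest (non-denaturing) temperature as an
expression proxy: at 37 °C essentially all protein is soluble, so
treated-vs-vehicle intensity ratios reflect abundance change rather than
thermal stability. The comparison is a Welch t-test on log2 intensities with
Benjamini-Hochberg adjustment across proteins.

Phosphopeptides follow the asterisk site convention (``S*``, ``T*``, ``Y*``;
ambiguous sites parenthesized). A phosphopeptide is *induced* when it is
detected in at least one treated condition and in no vehicle replicate,
*constitutive* when detected in both, and *vehicle_only* otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from itertools import combinations
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import sample_id
from .quant_io import QuantTable

logger = logging.getLogger(__name__)


def _as_frame(table: QuantTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, QuantTable) else table


def differential_expression(
    table: QuantTable | pd.DataFrame,
    ligand: str,
    concentration: float,
    reference_temperature: float = 37.0,
    lfc_threshold: float = 0.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein treated-vs-vehicle comparison at the reference temperature.

    Returns one row per protein with ``log2_fold_change``, Welch ``p_value``,
    BH-``adjusted_p``, a ``call`` in {up, down, unchanged} and a
    ``degenerate`` flag for zero-variance groups (where the t-test is
    undefined and the call falls back to the fold-change sign).
    """
    df = _as_frame(table)
    at_ref = df[df["temperature_C"] == reference_temperature]
    veh = at_ref[at_ref["concentration_nM"] == 0]
    trt = at_ref[(at_ref["ligand"] == ligand) & (at_ref["concentration_nM"] == concentration)]
    if veh.empty:
        raise ValueError("no vehicle observations at the reference temperature")
    if trt.empty:
        raise ValueError(f"no observations for {ligand} at {concentration} nM")

    rows = []
    veh_g = veh.groupby("protein_id")["intensity"]
    trt_g = trt.groupby("protein_id")["intensity"]
    for pid in sorted(set(veh_g.groups) & set(trt_g.groups)):
        a = np.log2(trt_g.get_group(pid).to_numpy())
        b = np.log2(veh_g.get_group(pid).to_numpy())
        if len(a) < 2 or len(b) < 2:
            continue
        lfc = float(a.mean() - b.mean())
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate:
            p = 0.0 if lfc != 0 else 1.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "protein_id": pid,
                "ligand": ligand,
                "concentration_nM": concentration,
                "log2_fold_change": lfc,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no proteins with >= 2 replicates in both groups")
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    sig = (out["adjusted_p"] < alpha) & (out["log2_fold_change"].abs() > lfc_threshold)
    out["call"] = np.where(
        sig & (out["log2_fold_change"] > 0),
        "up",
        np.where(sig & (out["log2_fold_change"] < 0), "down", "unchanged"),
    )
    return out


def is_phosphopeptide(peptide: str) -> bool:
    """Asterisk convention: any ``*`` marks a phosphosite (``(...)`` = ambiguous)."""
    return "*" in peptide


def phospho_accounting(
    table: QuantTable | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify phosphopeptide presence and quantify abundance vs vehicle.

    Returns ``(records, protein_flags)``: per
    (protein, peptide, ligand, concentration) records with the
    ``relative_abundance`` vs the pooled vehicle mean (NaN where the peptide
    is absent from vehicle), plus the per-peptide ``presence`` class; and a
    per-protein table flagging any observed phosphopeptide.
    """
    df = _as_frame(table)
    phos = df[df["peptide"].map(is_phosphopeptide)]
    pep_keys = ["protein_id", "peptide"]

    veh = phos[phos["concentration_nM"] == 0]
    trt = phos[phos["concentration_nM"] > 0]
    veh_mean = veh.groupby(pep_keys)["intensity"].mean().rename("vehicle_intensity")
    in_veh = set(map(tuple, veh[pep_keys].drop_duplicates().itertuples(index=False)))
    in_trt = set(map(tuple, trt[pep_keys].drop_duplicates().itertuples(index=False)))

    def presence(key: tuple) -> str:
        if key in in_trt and key not in in_veh:
            return "induced"
        if key in in_trt:
            return "constitutive"
        return "vehicle_only"

    rec = (
        trt.groupby(pep_keys + ["ligand", "concentration_nM"])["intensity"]
        .mean()
        .reset_index()
        .merge(veh_mean, on=pep_keys, how="left")
    )
    rec["relative_abundance"] = rec["intensity"] / rec["vehicle_intensity"]
    rec["presence"] = [presence((p, s)) for p, s in zip(rec["protein_id"], rec["peptide"])]

    veh_only = sorted(in_veh - in_trt)
    if veh_only:
        rec = pd.concat(
            [
                rec,
                pd.DataFrame(
                    [
                        {
                            "protein_id": p,
                            "peptide": s,
                            "ligand": "vehicle",
                            "concentration_nM": 0.0,
                            "intensity": np.nan,
                            "vehicle_intensity": veh_mean.get((p, s), np.nan),
                            "relative_abundance": np.nan,
                            "presence": "vehicle_only",
                        }
                        for p, s in veh_only
                    ]
                ),
            ],
            ignore_index=True,
        )

    flags = (
        phos.groupby("protein_id")
        .size()
        .rename("n_phosphopeptide_obs")
        .reset_index()
        .assign(phosphorylated=True)
    )
    return rec, flags


def intersect_hits(hit_lists: dict[str, set | list]) -> pd.DataFrame:
    """Exclusive (upset-style) intersection counts over per-ligand hit sets.

    One row per non-empty ligand combination, with the count of proteins
    belonging to exactly that combination; counts sum to the union size.
    """
    if len(hit_lists) < 2:
        raise ValueError("need at least two hit lists to intersect")
    sets = {k: set(v) for k, v in hit_lists.items()}
    names = sorted(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            count = len(inside - outside)
            if count:
                rows.append(
                    {"combination": "&".join(combo), "degree": r, "count": count}
                )
    return pd.DataFrame(rows, columns=["combination", "degree", "count"])


def export_expression_matrix(
    table: QuantTable | pd.DataFrame,
    path=None,
    mapping: pd.DataFrame | None = None,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Gene-by-sample log-intensity matrix for external GSA / TF-activity tools.

    Rows are gene symbols (mapped from accessions via ``mapping`` with columns
    ``protein_id`` and ``gene_symbol``; unmapped accessions are kept under
    their accession with a warning). Columns are sample identifiers
    ``ligand_<c>nM_<T>C_r<rep>``. Written as plain TSV when ``path`` is given.
    """
    df = _as_frame(table).copy()
    df["sample"] = [sample_id(row) for _, row in df.iterrows()]
    mat = df.pivot_table(
        index="protein_id", columns="sample", values="intensity", aggfunc="mean"
    )
    mat = np.log(mat) / np.log(log_base)

    if mapping is not None and len(mapping):
        m = mapping.set_index("protein_id")["gene_symbol"]
        unmapped = [p for p in mat.index if p not in m.index]
        if unmapped:
            logger.warning("%d accession(s) without gene symbol kept as-is", len(unmapped))
        mat.index = [m.get(p, p) for p in mat.index]
    else:
        logger.warning("no accession-to-gene mapping supplied; matrix keyed by accession")
    mat.index.name = "gene"

    if path is not None:
        mat.to_csv(path, sep="\t")
    return mat
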