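"""2D-TPP hit calling: vehicle normalization, fold-change filtering,
nested dose-response tests, permutation FDR, and direction calls.

Pipeline (per ligand, sharing the vehicle control):

1. **Normalize.** Protein abundances are log2-transformed and, per
   (protein, temperature), the mean log2 abundance over the vehicle
   (c = 0) replicates is subtracted; antilogging yields relative soluble
   abundances centered *around* unity at c = 0 (not fixed to it — vehicle
   replicates keep their scatter and contribute residual degrees of
   freedom downstream).
2. **Filter.** A temperature qualifies for a protein when the replicate-mean
   relative abundance at some non-zero concentration reaches the fold-change
   threshold h (>= h, or <= 1/h for destabilization); default h = 1.5.
3. **Test.** At each qualifying temperature, a constant (H0) and a
   4-parameter log-logistic dose response (H1) are fitted to the individual
   replicate points (vehicle included) and compared with a nested-model
   F-statistic; per-temperature F values are combined per protein (sum by
   default) into F_comb.
4. **FDR.** Concentration labels are shuffled within each
   (protein, temperature) cell (vehicle fixed), the full filter+fit pipeline
   is re-run B times, and the FDR at real rank r is the average number of
   permuted F_comb values at or above the rank-r score, divided by r,
   monotonized by a suffix minimum. Default B = 100.
5. **Call.** Proteins at FDR <= threshold (default 0.1) become hits;
   direction is stabilized/destabilized according to the mean relative
   abundance at the highest concentration over qualifying temperatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .fitting import F_CAP, fit_cell, fit_h0, fit_h1, f_statistic
from .quant_io import QuantTable

logger = logging.getLogger(__name__)

CELL_KEYS = ["protein_id", "ligand", "temperature_C"]

REDUCTIONS: dict[str, Callable[[np.ndarray], float]] = {
    "sum": np.sum,
    "mean": np.mean,
    "max": np.max,
}


@dataclass
class RelativeAbundanceTensor:
    """Vehicle-centered relative soluble abundances in long format.

    ``data`` carries the observation key columns plus ``log2_centered`` and
    ``relative_abundance``; ``dropped`` records (protein, temperature) cells
    excluded for lack of any vehicle observation.
    """

    data: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def for_ligand(self, ligand: str) -> pd.DataFrame:
        """Rows for one treatment ligand plus the shared vehicle rows."""
        d = self.data
        return d[(d["concentration_nM"] == 0) | (d["ligand"] == ligand)]

    @property
    def ligands(self) -> tuple[str, ...]:
        d = self.data
        return tuple(sorted(d.loc[d["concentration_nM"] > 0, "ligand"].unique()))


def _as_frame(table: QuantTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, QuantTable) else table


def normalize_to_vehicle(table: QuantTable | pd.DataFrame) -> RelativeAbundanceTensor:
    """Center protein abundances on the vehicle geometric mean (log2 scale).

    For each observation, ``log2_centered = log2(A) - mean_{c=0}(log2 A)``
    within the same (protein, temperature); ``relative_abundance`` is its
    antilog. Cells without any vehicle observation are dropped and recorded.
    """
    df = _as_frame(table).copy()
    if (df["intensity"] <= 0).any():
        raise ValueError("intensities must be strictly positive for normalization")
    df["log2_intensity"] = np.log2(df["intensity"].to_numpy())

    keys = ["protein_id", "temperature_C"]
    veh = df[df["concentration_nM"] == 0]
    ref = veh.groupby(keys)["log2_intensity"].mean().rename("vehicle_log2_mean")
    df = df.merge(ref, on=keys, how="left")

    missing = df["vehicle_log2_mean"].isna()
    dropped = (
        df.loc[missing, keys].drop_duplicates().assign(reason="no vehicle observation")
        .reset_index(drop=True)
    )
    if len(dropped):
        logger.warning(
            "dropped %d (protein, temperature) cell(s) without vehicle data", len(dropped)
        )
    df = df[~missing].copy()

    df["log2_centered"] = df["log2_intensity"] - df["vehicle_log2_mean"]
    df["relative_abundance"] = np.exp2(df["log2_centered"])
    df = df.drop(columns=["log2_intensity", "vehicle_log2_mean"])
    return RelativeAbundanceTensor(df.reset_index(drop=True), dropped)


def fold_change_filter(tensor: RelativeAbundanceTensor, h: float = 1.5) -> pd.DataFrame:
    """Per (protein, ligand, temperature): does the concentration series reach
    the fold-change threshold?

    A temperature qualifies when the replicate-mean relative abundance at some
    c > 0 is >= h or <= 1/h. ``phi_max`` reports the fold change furthest from
    unity on the log scale (signed as the actual ratio).
    """
    if h <= 1:
        raise ValueError(f"fold-change threshold h must exceed 1, got {h}")
    d = tensor.data
    treated = d[d["concentration_nM"] > 0]
    means = (
        treated.groupby(CELL_KEYS + ["concentration_nM"])["relative_abundance"]
        .mean()
        .reset_index()
    )
    if means.empty:
        return pd.DataFrame(columns=CELL_KEYS + ["phi_max", "qualifies"])

    agg = (
        means.groupby(CELL_KEYS)["relative_abundance"].agg(hi="max", lo="min").reset_index()
    )
    hi, lo = agg["hi"].to_numpy(), agg["lo"].to_numpy()
    agg["phi_max"] = np.where(np.abs(np.log2(hi)) >= np.abs(np.log2(lo)), hi, lo)
    agg["qualifies"] = (hi >= h) | (lo <= 1.0 / h)
    return agg.drop(columns=["hi", "lo"])


def permute_dataset(
    tensor: RelativeAbundanceTensor, rng: np.random.Generator | int
) -> RelativeAbundanceTensor:
    """Shuffle concentration labels within each (protein, ligand, temperature).

    Vehicle (c = 0) observations are left untouched, so the centering
    convention is preserved and per-cell value multisets are conserved.
    Deterministic given the generator state / seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    df = tensor.data.copy()
    conc = df["concentration_nM"].to_numpy().copy()
    idx = np.flatnonzero(conc > 0)
    if idx.size == 0:
        return RelativeAbundanceTensor(df, tensor.dropped)
    codes = pd.MultiIndex.from_frame(df.iloc[idx][CELL_KEYS]).codes
    group = np.ravel_multi_index(codes, [c.max() + 1 for c in map(np.asarray, codes)])
    orig_order = np.argsort(group, kind="stable")
    rand_order = np.lexsort((rng.random(idx.size), group))
    conc[idx[orig_order]] = conc[idx[rand_order]]
    df["concentration_nM"] = conc
    return RelativeAbundanceTensor(df, tensor.dropped)


def combine_f(f_values: Sequence[float], reduction: str = "sum") -> float:
    """Combine per-temperature F-statistics into one protein-level score."""
    f = np.asarray(list(f_values), dtype=float)
    if f.size == 0:
        raise ValueError("no per-temperature F-statistics to combine")
    try:
        return float(REDUCTIONS[reduction](f))
    except KeyError:
        raise ValueError(f"unknown reduction {reduction!r}") from None


def _fit_qualifying_cells(
    ligand_df: pd.DataFrame,
    qualifying: pd.DataFrame,
    *,
    min_points: int = 6,
    min_concentrations: int = 3,
    collect_fits: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fit H0/H1 and compute F for every qualifying (protein, temperature).

    ``ligand_df`` must already be restricted to one treatment ligand plus the
    shared vehicle rows. Returns (per-cell F table, fit records).
    """
    qual = qualifying[qualifying["qualifies"]]
    if qual.empty:
        return pd.DataFrame(columns=["protein_id", "temperature_C", "f"]), []

    wanted = set(zip(qual["protein_id"], qual["temperature_C"]))
    groups = ligand_df.groupby(["protein_id", "temperature_C"], sort=True)
    rows, fits = [], []
    for (pid, temp), g in groups:
        if (pid, temp) not in wanted:
            continue
        conc = g["concentration_nM"].to_numpy()
        y = g["relative_abundance"].to_numpy()
        if len(y) < max(min_points, 5) or np.unique(conc).size < min_concentrations:
            continue
        fit = fit_cell(pid, temp, conc, y)
        f = fit.f_stat
        rows.append({"protein_id": pid, "temperature_C": temp, "f": f})
        if collect_fits:
            a, d, ec50, s = fit.h1_params
            fits.append(
                {
                    "protein_id": pid,
                    "temperature_C": temp,
                    "h0_level": fit.h0_level,
                    "h0_rss": fit.h0_rss,
                    "a": a,
                    "d": d,
                    "ec50_nM": ec50,
                    "slope": s,
                    "h1_rss": fit.h1_rss,
                    "n_points": fit.n_points,
                    "converged": fit.converged,
                    "f": f,
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "temperature_C", "f"]), fits


def _combined_scores(
    cell_f: pd.DataFrame, reduction: str
) -> pd.Series:
    if cell_f.empty:
        return pd.Series(dtype=float, name="f_combined")
    return (
        cell_f.groupby("protein_id")["f"]
        .agg(lambda v: combine_f(v.to_numpy(), reduction))
        .rename("f_combined")
    )


def permutation_fdr(
    real_scores: np.ndarray, permuted_runs: Sequence[np.ndarray]
) -> np.ndarray:
    """Rank-based permutation FDR, aligned with ``real_scores`` order.

    Real scores are ranked descending; at rank r (score threshold F_r),
    v_b = #{permuted scores in run b >= F_r} and FDR(r) = mean_b(v_b) / r,
    clipped to [0, 1] and monotonized with a suffix minimum so FDR is
    non-decreasing in rank.
    """
    real = np.asarray(real_scores, dtype=float)
    if real.size == 0:
        return real.copy()
    B = len(permuted_runs)
    if B < 1:
        raise ValueError("need at least one permutation run")
    order = np.argsort(-real, kind="stable")
    thresholds = real[order]
    pooled = np.sort(np.concatenate([np.asarray(p, dtype=float) for p in permuted_runs]))
    ranks = np.arange(1, real.size + 1, dtype=float)
    v_total = pooled.size - np.searchsorted(pooled, thresholds, side="left")
    fdr = np.minimum(v_total / (B * ranks), 1.0)
    fdr = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty_like(fdr)
    out[order] = fdr
    return out


def bootstrap_fdr(
    real_f_combined: pd.Series,
    tensor: RelativeAbundanceTensor,
    ligand: str,
    *,
    B: int = 100,
    rng: np.random.Generator | int | None = None,
    h: float = 1.5,
    reduction: str = "sum",
    min_points: int = 6,
    min_concentrations: int = 3,
) -> pd.Series:
    """Estimate per-protein FDR for one ligand by re-running the pipeline on
    B concentration-shuffled copies of the tensor."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    runs: list[np.ndarray] = []
    for _ in range(B):
        shuffled = permute_dataset(tensor, rng)
        lig_df = shuffled.for_ligand(ligand)
        qual = fold_change_filter(
            RelativeAbundanceTensor(lig_df, shuffled.dropped), h=h
        )
        cell_f, _ = _fit_qualifying_cells(
            lig_df,
            qual,
            min_points=min_points,
            min_concentrations=min_concentrations,
            collect_fits=False,
        )
        runs.append(_combined_scores(cell_f, reduction).to_numpy())
    fdr = permutation_fdr(real_f_combined.to_numpy(), runs)
    return pd.Series(fdr, index=real_f_combined.index, name="fdr")


def call_hits(
    results: pd.DataFrame,
    tensor: RelativeAbundanceTensor,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Annotate results with hit status and direction.

    Direction for a hit is read from the replicate-mean relative abundance at
    the highest concentration, averaged over its qualifying temperatures:
    above 1 -> stabilized, below 1 -> destabilized. Exact ties go to
    stabilized and are logged. Non-hits get direction ``none``.
    """
    out = results.copy()
    out["is_hit"] = out["fdr"] <= fdr_threshold
    d = tensor.data
    cmax = d.loc[d["concentration_nM"] > 0, "concentration_nM"].max()
    top = d[d["concentration_nM"] == cmax]
    top_means = (
        top.groupby(CELL_KEYS)["relative_abundance"].mean().rename("top_mean").reset_index()
    )

    directions = []
    for _, row in out.iterrows():
        if not row["is_hit"]:
            directions.append("none")
            continue
        sel = top_means[
            (top_means["protein_id"] == row["protein_id"])
            & (top_means["ligand"] == row["ligand"])
            & (top_means["temperature_C"].isin(row["qualifying_temperatures"]))
        ]
        m = float(sel["top_mean"].mean()) if len(sel) else np.nan
        if np.isnan(m) or m == 1.0:
            logger.info("direction tie for %s/%s; calling stabilized", row["protein_id"], row["ligand"])
            directions.append("stabilized")
        else:
            directions.append("stabilized" if m > 1.0 else "destabilized")
    out["direction"] = directions
    return out


class VehicleNormalizer(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`normalize_to_vehicle`."""

    def fit(self, X: QuantTable | pd.DataFrame, y=None) -> "VehicleNormalizer":
        self.n_observations_in_ = len(_as_frame(X))
        return self

    def transform(self, X: QuantTable | pd.DataFrame) -> RelativeAbundanceTensor:
        return normalize_to_vehicle(X)


class ThermalShiftCaller(BaseEstimator):
    """Full 2D-TPP hit caller with sklearn estimator semantics.

    Parameters
    ----------
    h : float, default 1.5
        Fold-change threshold for a temperature to qualify.
    fdr_threshold : float, default 0.1
        Permutation-FDR cutoff for calling a hit.
    n_permutations : int, default 100
        Number of bootstrap shuffles B for the FDR estimate.
    reduction : {"sum", "mean", "max"}, default "sum"
        How per-temperature F-statistics combine into F_comb.
    min_points, min_concentrations
        Minimum evidence for a (protein, temperature) fit: at least 6 points
        spanning at least 3 distinct concentrations (vehicle included).
    random_state : int or numpy Generator, optional
        Seed for the permutation shuffles.

    Attributes (after ``fit``)
    --------------------------
    tensor_ : RelativeAbundanceTensor
        Vehicle-centered relative abundances.
    filter_ : DataFrame
        Per (protein, ligand, temperature) fold-change summary.
    fits_ : DataFrame
        H0/H1 parameters, RSS and F per fitted cell.
    results_ : DataFrame
        Per (protein, ligand): qualifying temperatures, F_comb, rank, FDR,
        hit status, direction.
    hits_ : DataFrame
        The FDR-passing subset of ``results_``.
    """

    def __init__(
        self,
        h: float = 1.5,
        fdr_threshold: float = 0.1,
        n_permutations: int = 100,
        reduction: str = "sum",
        min_points: int = 6,
        min_concentrations: int = 3,
        random_state: int | np.random.Generator | None = None,
    ):
        self.h = h
        self.fdr_threshold = fdr_threshold
        self.n_permutations = n_permutations
        self.reduction = reduction
        self.min_points = min_points
        self.min_concentrations = min_concentrations
        self.random_state = random_state

    def fit(self, X: QuantTable | pd.DataFrame, y=None) -> "ThermalShiftCaller":
        if self.h <= 1:
            raise ValueError("h must exceed 1")
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"unknown reduction {self.reduction!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        df = _as_frame(X)
        tensor = normalize_to_vehicle(df)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )

        filters, all_fits, all_results = [], [], []
        for ligand in tensor.ligands:
            lig_df = tensor.for_ligand(ligand)
            lig_tensor = RelativeAbundanceTensor(lig_df, tensor.dropped)
            qual = fold_change_filter(lig_tensor, h=self.h)
            filters.append(qual)
            cell_f, fit_rows = _fit_qualifying_cells(
                lig_df,
                qual,
                min_points=self.min_points,
                min_concentrations=self.min_concentrations,
            )
            for r in fit_rows:
                r["ligand"] = ligand
            all_fits.extend(fit_rows)
            scores = _combined_scores(cell_f, self.reduction)
            if scores.empty:
                continue
            fdr = bootstrap_fdr(
                scores,
                lig_tensor,
                ligand,
                B=self.n_permutations,
                rng=rng,
                h=self.h,
                reduction=self.reduction,
                min_points=self.min_points,
                min_concentrations=self.min_concentrations,
            )
            qt = (
                cell_f.groupby("protein_id")["temperature_C"]
                .agg(lambda v: tuple(sorted(v)))
                .rename("qualifying_temperatures")
            )
            res = pd.concat([scores, qt, fdr], axis=1).reset_index()
            res["ligand"] = ligand
            res = res.sort_values(
                ["f_combined", "protein_id"], ascending=[False, True], kind="mergesort"
            ).reset_index(drop=True)
            res["rank"] = np.arange(1, len(res) + 1)
            all_results.append(res)

        self.tensor_ = tensor
        self.filter_ = (
            pd.concat(filters, ignore_index=True)
            if filters
            else pd.DataFrame(columns=CELL_KEYS + ["phi_max", "qualifies"])
        )
        fit_cols = [
            "protein_id", "ligand", "temperature_C", "h0_level", "h0_rss",
            "a", "d", "ec50_nM", "slope", "h1_rss", "n_points", "converged", "f",
        ]
        self.fits_ = pd.DataFrame(all_fits, columns=fit_cols)
        res_cols = [
            "protein_id", "ligand", "qualifying_temperatures",
            "f_combined", "rank", "fdr", "is_hit", "direction",
        ]
        if all_results:
            results = pd.concat(all_results, ignore_index=True)
            results = call_hits(results, tensor, fdr_threshold=self.fdr_threshold)
            self.results_ = results[res_cols]
        else:
            self.results_ = pd.DataFrame(columns=res_cols)
        self.hits_ = self.results_[
            self.results_["is_hit"].astype(bool)
        ].reset_index(drop=True)
        self.ligands_ = tensor.ligands
        self.n_proteins_ = df["protein_id"].nunique()
        return self

    def predict(self, X=None) -> pd.DataFrame:
        """Return the hit table from the fitted run (X is ignored)."""
        if not hasattr(self, "hits_"):
            raise RuntimeError("call fit first")
        return self.hits_
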