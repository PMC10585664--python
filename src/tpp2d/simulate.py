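"""Synthetic label-free 2D-TPP datasets with known ground truth.

The generator emulates a dose-resolved thermal stability experiment on
cultured cells: each protein melts sigmoidally in temperature, and ligand
binding shifts the apparent melting midpoint in proportion to receptor/target
occupancy. The soluble fraction of protein p at temperature T and ligand
concentration c is

    s(T, c) = plateau + (1 - plateau) / (1 + exp((T - Tm_eff(c)) / w))
    Tm_eff(c) = Tm + dTm * c / (c + Kd)

where Tm is the vehicle melting midpoint (°C), w the melting-transition
width (°C), plateau the non-denaturing background fraction, dTm the
full-occupancy melting-point shift (positive = stabilized, negative =
destabilized), and Kd the binding constant (nM) so that occupancy at c = Kd
is exactly 1/2. Observed intensities are base_abundance * s(T, c) times
multiplicative lognormal noise with a configurable coefficient of variation,
drawn independently per replicate. Unaffected proteins have dTm = 0.

Peptide-level output distributes each protein intensity over peptides with
per-peptide ionization efficiencies that are fixed across runs, so the TOP3
summary is proportional to the protein signal.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_CONCENTRATIONS,
    DEFAULT_REPLICATES,
    DEFAULT_TEMPERATURES,
    DesignSummary,
)
from .quant_io import QuantTable


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the canonical study design."""

    n_proteins: int = 200
    fraction_affected: float = 0.1
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    replicates: int = DEFAULT_REPLICATES
    ligand: str = "ligand"
    tm_mean: float = 50.0          # °C, proteome melting-midpoint mean
    tm_sd: float = 4.0             # °C
    slope_mean: float = 2.5        # °C, melting transition width w
    slope_sd: float = 0.4
    plateau: float = 0.05          # non-denaturing background fraction
    delta_tm_effect: float = 4.0   # °C shift at full occupancy; sign = direction
    destabilized_fraction: float = 0.0  # share of affected proteins with the opposite sign
    kd_log10_mean: float = 2.0     # nM, log10 of the binding-constant median
    kd_log10_sd: float = 0.0
    noise_cv: float = 0.1          # multiplicative lognormal CV
    base_abundance_log10_mean: float = 5.0
    base_abundance_log10_sd: float = 0.5
    peptides_per_protein_mean: float = 6.0  # Poisson mean (min 1)
    dropout: bool = False          # intensity-dependent missingness
    dropout_midpoint_log10: float = 2.5  # log10 intensity with 50% detection
    dropout_width_log10: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_affected <= 1.0:
            raise ValueError("fraction_affected must lie in [0, 1]")
        if not 0.0 <= self.destabilized_fraction <= 1.0:
            raise ValueError("destabilized_fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 <= self.plateau < 1.0:
            raise ValueError("plateau must lie in [0, 1)")
        if self.slope_mean <= 0:
            raise ValueError("melting slope must be positive")
        # validates ordering / vehicle-first invariants
        self.design()

    def design(self) -> DesignSummary:
        return DesignSummary(
            self.temperatures, self.concentrations, self.replicates, (self.ligand,)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["temperatures"] = list(self.temperatures)
        d["concentrations"] = list(self.concentrations)
        return d


def soluble_fraction(
    T: np.ndarray, c: np.ndarray, tm: float, w: float, plateau: float,
    delta_tm: float, kd: float,
) -> np.ndarray:
    """Dose-shifted melting curve s(T, c); vectorized over broadcastable T, c."""
    T = np.asarray(T, dtype=float)
    c = np.asarray(c, dtype=float)
    occupancy = np.where(c > 0, c / (c + kd), 0.0)
    tm_eff = tm + delta_tm * occupancy
    return plateau + (1.0 - plateau) / (1.0 + np.exp((T - tm_eff) / w))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_dataset(
    config: SimConfig, level: str = "protein"
) -> tuple[QuantTable, pd.DataFrame]:
    """Generate a synthetic 2D-TPP dataset and its ground truth.

    Returns ``(table, truth)`` where ``table`` is a protein- or
    peptide-level :class:`QuantTable` (vehicle rows labeled ``vehicle`` at
    c = 0) and ``truth`` has one row per protein: the affected flag, melting
    parameters, Kd, full-occupancy dTm, the per-concentration effective shift
    ``delta_tm_<c>nM``, and the true direction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(n)])

    n_affected = int(round(cfg.fraction_affected * n))
    affected = np.zeros(n, dtype=bool)
    affected[rng.choice(n, size=n_affected, replace=False)] = True

    tm = rng.normal(cfg.tm_mean, cfg.tm_sd, size=n)
    w = np.clip(rng.normal(cfg.slope_mean, cfg.slope_sd, size=n), 0.5, None)
    kd = 10.0 ** rng.normal(cfg.kd_log10_mean, cfg.kd_log10_sd, size=n)
    base = 10.0 ** rng.normal(
        cfg.base_abundance_log10_mean, cfg.base_abundance_log10_sd, size=n
    )
    sign = np.ones(n)
    flip = rng.random(n) < cfg.destabilized_fraction
    sign[flip] = -1.0
    delta = np.where(affected, cfg.delta_tm_effect * sign, 0.0)

    temps = np.asarray(cfg.temperatures)
    concs = np.asarray(cfg.concentrations)
    reps = np.arange(1, cfg.replicates + 1)
    Tg, Cg, Rg = np.meshgrid(temps, concs, reps, indexing="ij")
    Tf, Cf, Rf = Tg.ravel(), Cg.ravel(), Rg.ravel()
    n_cells = Tf.size

    frames = []
    for i in range(n):
        s = soluble_fraction(Tf, Cf, tm[i], w[i], cfg.plateau, delta[i], kd[i])
        noise = _lognormal_noise(rng, cfg.noise_cv, n_cells)
        intensity = base[i] * s * noise
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": ids[i],
                    "peptide": "",
                    "ligand": np.where(Cf == 0, "vehicle", cfg.ligand),
                    "concentration_nM": Cf,
                    "temperature_C": Tf,
                    "replicate": Rf.astype(int),
                    "intensity": intensity,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    level_out = "protein"
    if level == "peptide":
        df = _to_peptide_level(df, ids, rng, cfg)
        level_out = "peptide"

    if cfg.dropout:
        logi = np.log10(np.maximum(df["intensity"].to_numpy(), 1e-12))
        p_detect = 1.0 / (
            1.0 + np.exp(-(logi - cfg.dropout_midpoint_log10) / cfg.dropout_width_log10)
        )
        df = df[rng.random(len(df)) < p_detect]

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "affected": affected,
            "tm_C": tm,
            "slope_C": w,
            "plateau": cfg.plateau,
            "base_abundance": base,
            "kd_nM": kd,
            "delta_tm_C": delta,
            "direction": np.where(
                ~affected, "none", np.where(delta > 0, "stabilized", "destabilized")
            ),
        }
    )
    for c in concs[concs > 0]:
        truth[f"delta_tm_{c:g}nM"] = delta * c / (c + kd)

    return QuantTable(df.reset_index(drop=True), level=level_out), truth


def _to_peptide_level(
    protein_df: pd.DataFrame, ids: np.ndarray, rng: np.random.Generator, cfg: SimConfig
) -> pd.DataFrame:
    """Split protein intensities into peptides with run-invariant shares."""
    frames = []
    for pid in ids:
        sub = protein_df[protein_df["protein_id"] == pid]
        n_pep = max(1, int(rng.poisson(cfg.peptides_per_protein_mean)))
        shares = rng.dirichlet(np.full(n_pep, 1.5))
        for j, share in enumerate(shares):
            pep = sub.copy()
            pep["peptide"] = f"{pid}_pep{j:02d}"
            pep["intensity"] = sub["intensity"] * share
            frames.append(pep)
    return pd.concat(frames, ignore_index=True)


def truth_vs_calls(truth: pd.DataFrame, hits: pd.DataFrame) -> dict:
    """Confusion summary of called hits against simulator ground truth.

    ``hits`` needs ``protein_id`` and (optionally) ``direction`` columns.
    Realized FDR is FP / max(TP + FP, 1); direction accuracy is computed over
    true-positive calls carrying a direction.
    """
    affected = set(truth.loc[truth["affected"], "protein_id"])
    called = set(hits["protein_id"]) if len(hits) else set()
    tp = len(called & affected)
    fp = len(called - affected)
    fn = len(affected - called)
    n_correct_dir = 0
    n_dir = 0
    if len(hits) and "direction" in hits.columns:
        truth_dir = truth.set_index("protein_id")["direction"]
        for _, row in hits.iterrows():
            pid = row["protein_id"]
            if pid in affected:
                n_dir += 1
                if row["direction"] == truth_dir[pid]:
                    n_correct_dir += 1
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_affected": len(affected),
        "n_called": len(called),
        "sensitivity": tp / len(affected) if affected else float("nan"),
        "realized_fdr": fp / max(tp + fp, 1),
        "direction_accuracy": n_correct_dir / n_dir if n_dir else float("nan"),
    }
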