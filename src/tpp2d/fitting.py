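"""Nested dose-response models for one protein at one temperature.

The null model H0 says the relative soluble abundance is independent of
ligand concentration: a single constant, fitted in closed form as the mean.
The alternative H1 is a 4-parameter log-logistic (Hill) dose-response

    f(c) = a + (d - a) * c^s / (c^s + EC50^s),     s > 0

with baseline a = f(0) (vehicle level, ~1 after normalization), plateau
d = f(inf), midpoint EC50 (nM) and Hill slope s. The direction of the
thermal shift is carried by the sign of (d - a): d > a means the soluble
fraction rises with concentration (stabilization at that temperature).

H1 nests H0 (a = d), so the standard nested-model F-statistic

    F = ((RSS0 - RSS1) / (p1 - p0)) / (RSS1 / (n - p1)),  p0 = 1, p1 = 4

measures the improvement of the dose-response over the constant. Replicates
enter as individual points, including the vehicle replicates at c = 0
(centered around unity, not fixed to it), which adds residual degrees of
freedom.

Fitting is multi-start nonlinear least squares: EC50 is optimized on a log
scale over [1, 1e4] nM from deterministic initializations (each observed
non-zero concentration and the geometric mid-range), a and d start from the
low/high-concentration means, s from 1. If the best H1 fit is worse than H0
(optimizer failure), the parameters collapse to the constant and RSS1 := RSS0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

#: Cap applied to F when RSS1 underflows to zero, keeping rankings finite.
F_CAP = 1e6

EC50_BOUNDS = (1.0, 1e4)
SLOPE_BOUNDS = (0.05, 10.0)

P0 = 1  # parameters of H0 (constant)
P1 = 4  # parameters of H1 (4PL)


@dataclass
class DoseResponseFit:
    """Fitted H0/H1 pair for one protein x temperature cell."""

    protein_id: str
    temperature: float
    h0_level: float
    h0_rss: float
    h1_params: tuple[float, float, float, float]  # (a, d, ec50, s)
    h1_rss: float
    n_points: int
    converged: bool

    @property
    def f_stat(self) -> float:
        return f_statistic(self.h0_rss, self.h1_rss, self.n_points)


def four_pl(c: np.ndarray, a: float, d: float, ec50: float, s: float) -> np.ndarray:
    """4PL log-logistic with f(0) = a, f(inf) = d, for s > 0.

    Evaluated as a + (d - a) / (1 + (EC50 / c)^s), with c = 0 mapping
    exactly to a.
    """
    c = np.asarray(c, dtype=float)
    out = np.full(c.shape, float(a))
    pos = c > 0
    occ = 1.0 / (1.0 + (ec50 / c[pos]) ** s)
    out[pos] = a + (d - a) * occ
    return out


def fit_h0(y: np.ndarray) -> tuple[float, float]:
    """Closed-form constant fit: (mean, residual sum of squares)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("H0 fit needs at least 2 points")
    level = float(np.mean(y))
    rss = float(np.sum((y - level) ** 2))
    return level, rss


def _profile_scan(
    conc: np.ndarray, y: np.ndarray, n_ec50: int = 25, n_slope: int = 13
) -> np.ndarray:
    """Coarse deterministic scan over (log10 ec50, s) with the linear
    subproblem in (a, d) solved exactly; returns the best start vector."""
    log_e = np.linspace(*np.log10(EC50_BOUNDS), n_ec50)
    s = np.exp(np.linspace(np.log(SLOPE_BOUNDS[0]), np.log(SLOPE_BOUNDS[1]), n_slope))
    E, S = np.meshgrid(log_e, s, indexing="ij")
    pos = conc > 0
    logc = np.where(pos, np.log10(np.where(pos, conc, 1.0)), 0.0)
    occ = np.where(
        pos[None, None, :],
        1.0 / (1.0 + 10.0 ** (S[..., None] * (E[..., None] - logc[None, None, :]))),
        0.0,
    )
    u = 1.0 - occ
    uu, vv, uv = (u * u).sum(-1), (occ * occ).sum(-1), (u * occ).sum(-1)
    uy, vy = (u * y).sum(-1), (occ * y).sum(-1)
    det = uu * vv - uv * uv
    ok = np.abs(det) > 1e-12
    det_safe = np.where(ok, det, 1.0)
    a = np.where(ok, (uy * vv - vy * uv) / det_safe, y.mean())
    d = np.where(ok, (vy * uu - uy * uv) / det_safe, y.mean())
    rss = ((a[..., None] * u + d[..., None] * occ - y) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return np.array([a[i, j], d[i, j], E[i, j], S[i, j]])


def _starts(conc: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start initializations in (a, d, log10 ec50, s)."""
    pos = np.unique(conc[conc > 0])
    cmin, cmax = pos.min(), pos.max()
    lo = float(np.mean(y[conc == conc.min()]))
    hi = float(np.mean(y[conc == cmax]))
    ec50s = list(pos) + [float(np.sqrt(cmin * cmax))]
    lo_b, hi_b = np.log10(EC50_BOUNDS)
    starts = [_profile_scan(conc, y)]
    for e in ec50s:
        le = float(np.clip(np.log10(e), lo_b, hi_b))
        starts.append(np.array([lo, hi, le, 1.0]))
    return starts


def fit_h1(
    conc: np.ndarray, y: np.ndarray
) -> tuple[tuple[float, float, float, float], float, bool]:
    """Multi-start least-squares fit of the 4PL model.

    Returns ``((a, d, ec50, s), rss, converged)``. Requires >= 6 points over
    >= 3 distinct concentrations (counting c = 0). Falls back to the constant
    fit (``converged=False``) if no start beats H0.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(y, dtype=float)
    if conc.size != y.size:
        raise ValueError("conc and y must have the same length")
    if conc.size < 6:
        raise ValueError("H1 fit needs at least 6 points")
    if np.unique(conc).size < 3:
        raise ValueError("H1 fit needs at least 3 distinct concentrations")

    h0_level, h0_rss = fit_h0(y)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, d, log_e, s = theta
        return four_pl(conc, a, d, 10.0**log_e, s) - y

    lo_b, hi_b = np.log10(EC50_BOUNDS)
    y_lo = min(y.min() / 2, 1e-6)
    y_hi = max(y.max() * 2, 1.0)
    bounds = (
        np.array([y_lo, y_lo, lo_b, SLOPE_BOUNDS[0]]),
        np.array([y_hi, y_hi, hi_b, SLOPE_BOUNDS[1]]),
    )

    best_rss = np.inf
    best = None
    for x0 in _starts(conc, y):
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(residuals, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        rss = float(2 * sol.cost)
        if rss < best_rss:
            best_rss = rss
            best = sol.x
        if best_rss <= 1e-14 * max(1.0, float(np.sum(y**2))):
            break

    if best is None or best_rss > h0_rss:
        # H1 nests H0; a worse RSS can only be an optimizer failure.
        pos = conc[conc > 0]
        ec50 = float(np.sqrt(pos.min() * pos.max())) if pos.size else 1.0
        return (h0_level, h0_level, ec50, 1.0), h0_rss, False

    a, d, log_e, s = best
    return (float(a), float(d), float(10.0**log_e), float(s)), best_rss, True


def f_statistic(
    h0_rss: float, h1_rss: float, n_points: int, p0: int = P0, p1: int = P1, cap: float = F_CAP
) -> float:
    """Nested-model F comparing the constant H0 to the 4PL H1.

    Non-negative by construction; capped at ``cap`` when the H1 residual sum
    of squares underflows to zero. Undefined (raises) for n_points <= p1.
    """
    if n_points <= p1:
        raise ValueError(f"F undefined for n_points={n_points} <= {p1}")
    num = max(h0_rss - h1_rss, 0.0)
    if num == 0.0:
        return 0.0
    if h1_rss <= 0.0:
        return cap
    f = (num / (p1 - p0)) / (h1_rss / (n_points - p1))
    return float(min(f, cap))


def fit_cell(
    protein_id: str, temperature: float, conc: np.ndarray, y: np.ndarray
) -> DoseResponseFit:
    """Fit both models for one (protein, temperature) cell."""
    level, rss0 = fit_h0(y)
    params, rss1, conv = fit_h1(conc, y)
    return DoseResponseFit(
        protein_id=protein_id,
        temperature=float(temperature),
        h0_level=level,
        h0_rss=rss0,
        h1_params=params,
        h1_rss=rss1,
        n_points=int(len(y)),
        converged=conv,
    )
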