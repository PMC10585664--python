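# Methods

## Model and procedure

`tpp2d` tests, per protein and ligand, whether the soluble fraction after
heating depends on ligand concentration. The statistical unit is the
(protein, temperature) cell: a dose-response curve over the concentration
series, observed in replicate, including the vehicle replicates at c = 0.

**Normalization.** Abundances are log2-transformed and centered per
(protein, temperature) on the mean log2 vehicle abundance; the antilog is
the relative soluble abundance. Centering on the *mean of logs* makes the
vehicle geometric mean exactly 1 while leaving vehicle replicate scatter in
the data — the vehicle level is estimated, not fixed, which is what lets the
constant model H0 have a free level and keeps residual degrees of freedom
honest. Cells with no vehicle observation cannot be centered and are dropped
with a logged record. The operation is idempotent and invariant to
per-protein rescaling of raw intensities.

**Fold-change filter.** Only temperatures where the replicate-mean relative
abundance at some non-zero concentration reaches h = 1.5 (or 1/h for
decreases) are tested. This mirrors the practice of restricting model
comparison to temperatures with a visible effect; it also bounds compute,
since dose-response fits happen only in qualifying cells. The filter is
re-applied inside every permutation so real and permuted scores face the
same selection.

**Models.** H0: constant, fitted in closed form (mean; RSS0). H1: the
4-parameter log-logistic written in Hill form,
f(c) = a + (d − a)·c^s/(c^s + EC50^s), so that f(0) = a exactly, f(∞) = d,
s > 0, and stabilization vs destabilization is the sign of d − a. EC50 is
optimized as log10 EC50 over [1, 10^4] nM (the measured series spans
20-500 nM; the bounds allow midpoints modestly outside it), s over
[0.05, 10], and the asymptotes over [min(y_min/2, 10^-6), max(2·y_max, 1)] —
that box is part of the model definition and the brute-force oracle in the
tests searches the same box. A cell is fitted only with ≥ 6 points spanning
≥ 3 distinct concentrations.

**Optimization.** Multi-start bounded least squares (scipy `least_squares`,
trust-region reflective): deterministic starts with EC50 at each observed
non-zero concentration and the geometric mid-range (a, d from the low-/
high-concentration means, s = 1), plus one start from a coarse 25×13
profile scan over (log EC50, s) in which the linear subproblem in (a, d) is
solved exactly. Because H1 nests H0, a best H1 RSS above RSS0 can only be an
optimizer failure; in that case the fit collapses to the constant
(converged = false, RSS1 := RSS0), which enforces RSS1 ≤ RSS0 globally.

**Statistic.** F_T = ((RSS0 − RSS1)/(p1 − p0)) / (RSS1/(n − p1)) with
p0 = 1, p1 = 4. If RSS1 underflows to zero, F is capped at 10^6 to keep the
ranking finite. Per protein, F_comb is the sum of F_T over qualifying
temperatures; sum rewards effects visible at several temperatures, and the
reduction is pluggable (sum | mean | max) because reasonable variants exist.

**Permutation FDR.** Within each (protein, ligand, temperature) cell the
concentration labels of the treated observations are randomly permuted;
vehicle rows stay at c = 0, so centering and per-cell value multisets are
preserved and the null retains the real replicate noise structure. The whole
filter-fit-combine pipeline is re-run on each of B = 100 shuffles. Real
proteins are ranked by F_comb descending; at rank r the estimate is
FDR(r) = (1/B) Σ_b v_b(r)/r with v_b(r) the count of permuted scores in run
b at or above the rank-r real score, clipped to [0, 1] and monotonized by a
suffix minimum (cumulative minimum from the bottom rank upward) so reported
FDR is non-decreasing in rank. Hits are proteins with FDR ≤ 0.1.

**Direction.** A hit is stabilized if the replicate-mean relative abundance
at the highest concentration, averaged over its qualifying temperatures,
exceeds 1, destabilized if below; exact ties go to stabilized and are
logged. This operationalization is a package policy: any monotone summary of
the high-concentration response would serve.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `h` | 1.5 | fold-change (dimensionless) a temperature must reach to be tested |
| `fdr_threshold` | 0.1 | permutation-FDR cutoff for calling hits |
| `n_permutations` (B) | 100 | shuffles behind the FDR estimate |
| `reduction` | sum | per-temperature F aggregation |
| EC50 bounds | [1, 10^4] nM | log-scale search range for the midpoint |
| slope bounds | [0.05, 10] | Hill-slope search range |
| `min_points` / `min_concentrations` | 6 / 3 | evidence required to fit a cell |
| F cap | 10^6 | finite stand-in when RSS1 = 0 |

Defaults are the method's canonical operating point (h = 1.5, FDR 0.1,
B = 100, temperatures 37-67 °C in 5 °C steps, concentrations
{0, 20, 100, 500} nM, 3 replicates).

## Synthetic data

The simulator generates the full design with a mechanistic
shift-through-occupancy model: each protein melts as
s(T, c) = plateau + (1 − plateau)/(1 + exp((T − Tm_eff(c))/w)) with
Tm_eff(c) = Tm + ΔTm·c/(c + Kd), so the melting-point shift scales with
fractional occupancy (exactly ΔTm/2 at c = Kd). Observed intensity is
base_abundance · s(T, c) times lognormal multiplicative noise with mean 1
and configurable CV, matching the error structure of label-free LC-MS.
Defaults: Tm ~ N(50, 4) °C (a typical proteome melting range against the
37-67 °C gradient), transition width w ~ N(2.5, 0.4) °C, plateau 0.05,
ΔTm = 4 °C at full occupancy, Kd = 100 nM (log10 mean 2, sd 0), noise CV
0.1, base abundance lognormal with log10 mean 5 ± 0.5. `destabilized_fraction`
flips the shift sign for a share of affected proteins so one dataset can
exercise both directions. Peptide-level output splits each protein signal
over Dirichlet-distributed, run-invariant peptide efficiencies, so TOP3
recovers a signal proportional to the protein's. Optional
intensity-dependent dropout (logistic in log10 intensity, off by default)
emulates DIA missingness.

What the simulator does **not** emulate: identification errors and protein
inference ambiguity, run-to-run retention/mobility drift, shared peptides,
interference/ratio compression, batch effects, co-eluting isoforms, and
correlated (non-lognormal) noise. Passing tests therefore demonstrate that
the statistics behave as designed under the stated generative model — not
that real acquisitions meet those assumptions.

## Numerical choices and degenerate inputs

- Zero intensities are treated as "not detected" and dropped on read;
  label-free zero is censoring, not abundance zero.
- TOP3 with 1-2 peptides averages what is observed and flags the protein
  `low_evidence` instead of dropping it; modified and unmodified forms of a
  sequence rank as distinct peptides.
- Table write/read round-trips at full float64 precision (`%.17g` on write,
  `float_precision="round_trip"` on read).
- Constant data yield RSS0 = RSS1 = 0 and F = 0 (not the cap).
- Proteins with no qualifying, fittable temperature are untested: no F, no
  FDR, direction `none`.
- FDR ties in F_comb rank deterministically (stable sort, protein id as
  tiebreak); all shuffles flow from one seeded generator, so runs are
  byte-reproducible given (input, config, seed).

## Problem sizes in the validation suite

The test suite and acceptance script size their simulations to exercise the
method honestly at desk scale: null calibration uses 200 proteins × 10 seeds
with B = 20; the power/recovery run uses 150 proteins (10% affected,
ΔTm = 4 °C, Kd = 100 nM, CV 5%, half destabilized) with the default B = 100;
the optimizer-vs-oracle comparison uses 20 random 12-point instances against
a two-stage dense grid that solves the asymptote subproblem exactly. These
sizes give stable pass/fail behavior while keeping a full run in minutes on
one CPU.

## Known limitations

- The per-temperature F-statistics of one protein are treated as independent
  when summed; temperatures share the same vehicle centering, so F_comb is a
  ranking score, not a calibrated F random variable — calibration comes from
  the permutation FDR, which applies the identical reduction to shuffled
  data.
- The permutation scheme conditions on the observed per-cell value multisets;
  effects that alter replicate variance without shifting means are not part
  of the null it tests.
- Direction is read from the top concentration only; non-monotone responses
  (e.g., bell-shaped) can be direction-ambiguous even when confidently
  detected.
- No melting-temperature (Tm) estimation is attempted; the analysis is
  dose-response per temperature by design, and the simulator's Tm ground
  truth is used only to label affected proteins.
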