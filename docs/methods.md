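# Methods

This note documents the models implemented in `fluxmu`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Natural isotope interference correction

The measured ion of a derivatized metabolite is modelled as the backbone
isotopologue vector convolved with the natural-abundance envelope of the
derivatization atoms. Only ¹³C, ²⁹Si and ³⁰Si are modelled; heavy isotopes
of H, N and O are excluded because their natural abundances (0.0115% D,
0.364% ¹⁵N, 0.205% ¹⁸O) contribute negligibly to the envelope of these
ions. Abundances are expressed normalized to the light isotope (ratios
`a = ³⁰Si/²⁸Si`, `b = ²⁹Si/²⁸Si`, `c = ¹³C/¹²C`), with defaults derived
from the IUPAC representative isotopic compositions:
`a = 0.03353 ± 0.000055`, `b = 0.05080 ± 0.00004`, `c = 0.01082 ± 0.0004`
(standard uncertainties, treated as normal).

The envelope coefficients are the exact integer combinatorics of placing
heavy isotopes on `n_Si` silicon and `n_C` carbon atoms: the multiplier of
`a^p b^q c^r` is `multinomial(n_Si; p, q) · binomial(n_C, r)`, at mass
shift `2p + q + r`. Expression generation is symbolic-first (terms are kept
as exact monomials, canonically ordered by shift and degree, and can be
rendered via sympy); numeric evaluation happens per abundance draw.

Two correction modes exist deliberately:

- **clamped** (default): ascending cascade, negative intermediate results
  set to zero (`F_k = 0`) and the clamped value fed into higher rows. This
  matches the solution process of dedicated correction software and is what
  the uncertainty budget propagates.
- **unclamped**: the signed solution of the lower-triangular linear system
  `M x = A`. This is the mathematically exact inverse of the convolution
  and serves as the oracle in tests; diagnostic use only.

The monoisotopic area `A₀` is never modified (nothing lighter can shift
into it) and is always retained in the IF denominator.

Assumption inherited from the measurement method: the time-of-flight
resolution separates no ¹³C-vs-²⁹Si mass defect, so both occupy the same
+1 shift class and ³⁰Si the +2 class.

### Derivative compositions

The bundled composition table covers the eight measured sugar phosphates
(ethoxime + TMS derivatization, [M − CH₃]⁺ ion). The Rl5P entry
(5 TMS + 1 EtOx → 16 extra C, 5 Si) is the documented reference; the other
seven follow from standard structures (carbonyl → ethoxime, each free OH
including both phosphate OH → TMS, one methyl lost in the measured ion) and
are a reconstruction: G6P/F6P 19 C / 6 Si, GAP/DHAP 10 C / 3 Si,
E4P 13 C / 4 Si, R5P 16 C / 5 Si, S7P 22 C / 7 Si. Users with different
derivatization chemistry supply their own YAML.

## Measurement uncertainty model

Intermediate areas follow `A_n = A_n,raw · f_int · f_n,ion` with

| component | distribution | scale | rationale |
|---|---|---|---|
| `A_n,raw` | Poisson(mean = raw counts) | `sqrt(counts)` | ion counting |
| `f_int` | symmetric triangular, mode 1 | `sqrt(0.02² − 1/A_raw)` | 2.0% empirical integration repeatability, deflated by the Poisson part it already contains |
| `f_n,ion` | normal, mean 1 | regression slope | SD of replicate areas grows linearly with area |
| `a, b, c` | normal | see above | abundance uncertainty |

Choices that the tabulated description leaves open, fixed here:

- The triangular half-width is `SD · sqrt(6)` so the distribution's SD
  equals the stated standard uncertainty.
- `f_int` models *one* integration event per peak group: a single standard
  deviate per metabolite per iteration, scaled by each isotopologue's own
  effective SD (perfect correlation across the group). A per-peak
  independent mode is switchable (`shared_integration=False`).
- `f_n,ion` is independent per isotopologue (the `n` subscript).
- Abundance draws are shared across metabolites within an iteration —
  natural abundances are physical constants, not per-peak noise.
- Raw areas are used as Poisson means without rounding.
- The ionization slope is an ordinary least-squares fit through the origin
  of replicate SD against mean area; its numeric value is data-dependent
  (the synthetic generator uses 0.01 as a realistic default).

## Monte Carlo budget

Default 100,000 iterations (reducible; the summary means/SDs converge as
1/√n). Each iteration draws all components, applies the intermediate-area
model, evaluates the shift coefficients at the drawn abundances, runs the
clamped cascade and normalizes. Outputs per IF: mean, SD, relative combined
uncertainty (SD/|mean|, %; reported absent when the mean is 0), and the
2.5–97.5 percentile interval (clamped distributions are skewed, so
percentiles accompany the moment summaries).

Variance contributions are normalized squared Spearman rank correlations
between component draws and each output — the tornado-style decomposition
of spreadsheet risk add-ins. It is exact for monotone near-additive
relations and robust to the clamping nonlinearity, but it is a ranking
heuristic, not a Sobol decomposition; shares are normalized to 100% and
interactions are folded proportionally into the main effects.

## Flux network and labeling simulation

The bundled model is a reconstruction of the upper glycolysis / PPP
branch-point network: GLCupt (basis, fixed to 1), HEX, PGI*, PFK, FBA*,
TPI*, GAPDH (PG3 sink; lower glycolysis removed), G6PDH (CO₂ from C1),
RPE*, RPI*, TKT1*, TKT2*, TALA* (asterisks: reversible; full carbon maps in
`data/network_glycolysis_ppp.csv`). Free parameters after stoichiometric
null-space analysis: the G6PDH net flux (the glycolysis/PPP split) and the
eight exchange fluxes. Scaling all fluxes leaves labeling unchanged, so
fixing uptake to 1 loses no generality.

Labeling is simulated with the EMU decomposition: only the EMUs backward-
reachable from the measured full-backbone fragments are generated, ordered
by size, and solved as small dense LU systems (the largest system here is a
handful of EMUs; no sparse machinery is warranted). Reversible reactions
use the net/exchange parameterization `v_fwd = exch + max(net, 0)`,
`v_rev = exch + max(−net, 0)`. The tracer is modelled as per-atom ¹³C
enrichment probabilities (default 100% pure [1,6-¹³C₂]glucose; purity is a
parameter), so backbone natural abundance is *not* added by the simulator —
measured data are assumed interference-corrected before fitting.

Degenerate inputs: pools whose EMU balance receives no labeling input
(zero throughput, e.g. an idle PPP branch asked to label Rl5P) raise a
singularity error naming the pool; branches carrying exactly zero flux are
pruned instead of solved, so an idle PPP does not poison targets that do
not need it.

### Structural identifiability note

The aldolase exchange (FBA) recombines DHAP and GAP into FBP and splits it
back; because the split returns exactly the marginals that entered, the
FBA exchange has no effect on any measured metabolite-level MID and is
structurally unidentifiable here. Zero-noise fits recover every net flux
and every other exchange; analyses that need a regular Fisher information
(contribution matrix, calibration studies) pin FBA via `fixed_exchanges`.
The CLI skips the contribution matrix with a warning when the information
matrix is singular.

## Flux fitting and statistics

- **Objective**: variance-weighted SSR over included measurements;
  bounded `scipy.optimize.least_squares` (trust-region reflective) with
  multistart (default 20 restarts, seeded). Exchange fluxes are optimized
  on the bounded transform `u ∈ [0, 0.99] → exch = u/(1−u)` for
  conditioning.
- **Degrees of freedom**: included IFs minus one closure constraint per
  metabolite (each normalized fraction vector loses one degree) minus the
  number of fitted parameters. With all 47 entries of the eight pools and
  9 parameters this gives dof = 30 (31 with FBA pinned). For saturated toy
  problems (dof ≤ 0) the χ² verdict is reported as undefined rather than
  raised.
- **Calibration**: the diagonal-weight χ² test on closure-constrained
  fractions is the field convention but only approximate — renormalization
  makes the true error covariance singular and non-diagonal. On correctly
  specified synthetic data the empirical mean SSR is ≈ 1.5 above dof and
  the 95% test rejects ≈ 7% instead of 5%; the calibration test allows the
  3σ binomial band around 5%.
- **Confidence intervals**: 2.5/97.5 percentiles of refits on measurements
  corrupted with independent normal noise on the fraction scale (default
  10,000 samples; no renormalization of the corrupted values, switchable).
  Refits start from the point estimate; non-convergent replicates are
  counted and surfaced (warning above 20%). Percentile-of-refit CIs are
  known to be somewhat optimistic; profile likelihood is out of scope.
- **Contribution matrix**: with `J` the weighted Jacobian at the optimum,
  `C = (JᵀJ)⁻¹` and gain `K = CJᵀ`; measurement `m` contributes
  `K²[j,m]/C[j,j]` of parameter `j`'s variance. Columns sum to 100%
  exactly; a singular `JᵀJ` raises an error reporting the null direction.
- **Scenarios** (applied in order): abundance mask (default threshold 2%),
  global SD inflation (default ×3, a biological-variance proxy), per-entry
  overrides that keep critical analytes at analytical precision.

## Synthetic data

The generator runs the pipeline forwards: flux model → backbone IFs →
envelope convolution (truncated to the measured M+0..M+n window, as in the
instrument) → scaling to a per-metabolite total ion count → the
measurement noise model. Ground truth (fluxes, backbone IFs, noise-free
areas) is emitted alongside for recovery tests.

Default study conditions: PPP split 0.25 of uptake with moderate exchange
fluxes (a glucose-grown yeast regime), 10⁶ summed ion counts per
metabolite, 2.0% integration SD, 1% ionization SD, three biological
replicates, [1,6-¹³C₂]glucose at 100% purity. Canned scenarios: the
reference labeled experiment, an unlabeled standard (isolates the
envelope), and a low-count case (2×10³ ions) that reliably triggers
clamping. Between-replicate biological variability is a lognormal
multiplier on the true IFs (renormalized), applied before measurement
noise.

Measurement sets for fitting draw `IF + N(0, σ)` with
`σ = max(0.02·IF, 0.002)` and renormalize each metabolite's vector to 1 —
measured fractions are normalized quantities, and this is what the closure
convention in the dof bookkeeping assumes. (CI corruption, by contrast,
deliberately does not renormalize by default.)

What the generator does *not* emulate: chromatographic peak shapes and
integration-window errors (only their net factor), detector dead time,
drift, derivatization-yield kinetics, tracer impurity patterns beyond a
single purity parameter, compartmentation, and any systematic bias —
passing tests therefore demonstrate correct propagation and inference
under the stated error model, not accuracy against biased real-world data.

## Problem sizes used in the test suite

Routine tests use 2,000–40,000 MC iterations (the full default is 100,000);
the χ² calibration uses 200 replicate fits; CI-scaling checks use 150
resamples per scenario; the isotopomer oracle comparison uses 3 random flux
vectors on the full network. These sizes keep the suite at a few minutes
while leaving Monte Carlo error well below the tested tolerances.

## Known limitations

- Correction assumes unit ionization efficiency across isotopologues of a
  derivative and no tracer impurity correction.
- The network is a reduced branch-point model: no lower glycolysis, no
  CO₂ refixation, no compartmentation, no isotopically nonstationary
  dynamics; absolute fluxes require an external uptake measurement.
- The contribution analysis is local (linearized at the optimum) and the
  Spearman budget shares are a heuristic decomposition.
- dof bookkeeping treats included IFs as independent up to the closure
  constraint; correlations introduced by the correction cascade itself are
  not propagated into the fit weights.
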