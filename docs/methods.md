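# Methods

## The interacting-sites rate law

The core model treats the hexamer as three independent dimers of
catalytically coupled sites. A site whose dimer partner is free works with
apparent constants (Km1, Vmax1); once the partner is occupied, the
constants become Km2 = a·Km1 and Vmax2 = b·Vmax1. The initial velocity as
a function of variable-substrate concentration c0 is a degree-2/2 rational
function (two algebraically equivalent printed forms, `eq1` in
(Km1, Vmax1, a, b) and `eq2` in (Km1, Km2, Vmax1, Vmax2)) with

* v0(0) = 0 exactly,
* initial slope 2·Vmax1/Km1,
* plateau 2·Vmax2 as c0 → ∞,
* exact reduction to Michaelis–Menten with Vmax = 2·Vmax1 when a = b = 1.

Monotonicity of v0(c0) is *not* asserted as an invariant: a 2/2 rational
function admits non-monotone corners (strong b < 1 with moderate a), and
the model layer does not forbid them. Units are fixed throughout:
concentrations in mM, velocities in U mg⁻¹ (µmol min⁻¹ mg⁻¹); conversion
from raw spectrophotometric slopes is a separate helper
(`absorbance_slope_to_rate`, Beer–Lambert with signed Δε and cuvette path).

The canonical parameterization is (Km1, Vmax1, a, b); (Km2, Vmax2) are
derived views. The cooperativity readout is a (and b): a > 1 means the
second site binds substrate more weakly — negative cooperativity.

A reporting subtlety: at saturation the rate law reaches 2·Vmax2, yet
activities of such enzymes are often quoted as Vmax2 itself. The package
never silently chooses — `saturating_velocity()` always returns 2·b·Vmax1
and `params.Vmax2` is always available raw.

## Weighted fitting

Estimation is weighted least squares with weights 1/SD², SD being the
standard deviation of the replicate-averaged rate; this matters because
wide log-spaced concentration grids (emulating 1 → 0.1 cm cuvettes) make
the error strongly heteroscedastic, and the model-selection outcome is
known to depend on weighting. Policies: `sd` (default; refuses zero or
missing SDs rather than imputing), `uniform`, and `relative`
(w = 1/(cv·v0)², default cv = 0.05) for data without replicate SDs.

The optimizer works in log-parameter space (positivity for free), with a
trust-region least-squares local solver, ftol 10⁻¹⁰ relative on the SSR,
and an iteration cap of 500·(p+1) function evaluations; capped starts are
marked non-converged but their SSR still competes. Multi-start search:
20 log-Latin-hypercube starts over ±3 decades around data-implied scales
(geometric-mean concentration for Km, max velocity for Vmax, 1 for a and
b), plus a deterministic data-scale start, plus — for the interacting-sites
model — the MM-embedded start (a = b = 1, Km1 = Km_MM, Vmax1 = Vmax_MM/2).
The embedded start makes wssr(IS) ≤ wssr(MM) structural, which the F-test
requires. Ties between starts (Δwssr < 10⁻⁸·wssr) resolve to the
lowest-index start for reproducibility. Fitting in natural parameter space
(`transform="natural"`) is available and agrees with log-space on
well-conditioned data.

Standard errors are the usual asymptotic ones: cov = s²·(JᵀWJ)⁻¹ with
s² = wssr/dof and J the central-difference Jacobian at the optimum. A
near-singular information matrix (smallest eigenvalue ≤ 10⁻¹⁴ of the
largest) yields NaN standard errors rather than an exception — with
strongly cooperative truths the (a, b) directions are genuinely sloppy and
their errors can legitimately approach the estimate itself.

Fits consume replicate-averaged rates with SDs. Raw replicates can be
passed as repeated rows (ties in c0 are allowed), which is also how the
"duplicated data shrink errors by √2" scaling is exercised.

## Model selection

Extra-sum-of-squares F-test between the nested 2- and 4-parameter fits:
F = ((wssr_MM − wssr_IS)/2)/(wssr_IS/(n − 4)) against F(2, n−4), richer
model selected iff p < α (default 0.05). A boundary tie p = α keeps the
simpler model; a negative numerator (possible only up to solver tolerance)
clamps F to 0 with a warning. The decision is invariant to rescaling all
SDs by a common factor. Published F values for the original mutant
datasets cannot be recomputed here because the underlying raw rates were
never deposited; the test's operating characteristics are instead verified
on simulated data (type-I error within [3.5%, 6.5%] at α = 0.05 over 2000
null datasets; power ≥ 0.9 at a = 100, 3% CV, n = 16).

## Synthetic data

The generators define the study conditions used in all stochastic tests:

* **Velocity datasets** — Gaussian replicate noise with per-replicate
  SD = σ_abs + cv·v_true (modes `absolute`/`relative`/`mixed`); defaults
  cv = 0.05 and n_rep = 3, matching "measured several times" triplicate
  practice and ~5% assay error. Stored SD is that of the average rate
  (sample SD/√n_rep). Negative draws are kept: they are measurement noise.
  Grids are log-uniform from 0.1·Km1 to max(10·Km2, 100·Km1) with 16
  points by default. Gaussian (not lognormal) noise was chosen because
  replicate spreads of absorbance-slope assays are symmetric in practice.
* **HDX uptake** — uptake(t) = Σⱼ(1 − exp(−kⱼt)) over exchangeable amides
  plus iid Gaussian replicate noise; default timepoints 10 s, 1 min,
  20 min, 1 h, 4 h. The 0.158 Da replicate SD used in the threshold
  experiments is the value whose triplicate 98% confidence interval is
  ±0.30 Da, the standard global-threshold scale for such data.
* **Titrations** — a thermodynamic stand-in (the structural series itself
  carries no binding model): dimers with binding polynomial
  P = 1 + 2K1c + coupling·K1²c², free ligand solved from conservation by
  bisection on [0, total] to 10⁻¹²·total. coupling < 1 reproduces the
  part-of-the-sites signature (suppressed doubly-bound dimers).

Everything is bit-reproducible from explicit seeds. What passing these
tests does **not** show: real assays have outliers, drift and correlated
replicate errors; real HDX has back-exchange (deliberately not corrected
here) and peptide-dependent noise; the titration model is not the
crystallographic occupancy-refinement process.

## HDX differential analysis

Per-timepoint Δuptake between two states is significant when
|Δ| > z₍₁₊c₎/₂ · pooled_SD · √(2/n_rep) (c = 0.98). The normal quantile is
the default because the threshold pools replicate SDs across many
peptides/timepoints globally; a per-peptide Student-t variant
(df = n_rep − 1) is available. A peptide is "changed" if *any* timepoint is
significant — fast-exchanging regions show effects only at the shortest
time, and averaging over times would erase them. Deltas are antisymmetric
under state exchange by construction; no back-exchange correction is
applied anywhere.

## Occupancy filling order

Site classes are a pure function of (own, partner) conformation within the
dimer map. Hexagonal half-hexamers are symmetry-expanded (primed chains)
before analysis so both space groups share one data model. "no FA" cells
are stored as absent, not 0.0, to distinguish unmodelled from weakly
occupied; class means count absent as 0. A class is "filled" at the
smallest molar ratio where its mean occupancy reaches the threshold,
default 0.4 — an editorial choice equal to the smallest refined occupancy
reported in the packaged series; it is configurable, and the wild-type vs
double-mutant order reversal is insensitive to it across [0.35, 0.55].

## Problem sizes and numerical choices

Monte-Carlo sizes are chosen for desk-scale reproducibility: 100 datasets
for parameter recovery, 2000/500 for type-I/power, 10⁴ peptide pairs for
the HDX null rate. Ensemble drivers use a reduced 6-start interacting-sites
search (embedded-MM start plus 5 Latin-hypercube starts) — on these
well-scaled simulated datasets the embedded start alone almost always finds
the optimum, and the reduction leaves the operating characteristics
unchanged while keeping ensembles fast. Single-dataset fits use the full
21-start search.

## Known limitations

* No global-optimality guarantee; strongly cooperative nucleoside-variable
  regimes genuinely exhibit several near-degenerate minima, which is why
  the multi-start trace is part of every result object.
* Standard errors are asymptotic fitting errors only — no
  profile-likelihood or bootstrap intervals.
* Only two site classes of kinetic behaviour are modelled; data hinting at
  more complicated schemes will still be forced into the 4-parameter law.
* The significance threshold treats replicate noise as exchangeable across
  peptides; peptide-specific variance is only partly accommodated by the
  t-quantile option.
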