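# allokin

Tools for analysing cooperative kinetics and ligand binding in hexameric
purine nucleoside phosphorylase (PNP) and enzymes like it: weighted
nonlinear fitting of the two-site **interacting-sites** rate law against the
Michaelis–Menten null model, extra-sum-of-squares F-test model selection,
differential HDX-MS uptake significance analysis, and the site-occupancy
"filling order" analysis of co-crystallisation series.

## The science

Hexameric PNP is a trimer of dimers whose paired active sites interconvert
between open and closed conformations and influence each other. Initial
velocities of such an enzyme do not follow the Michaelis–Menten law; they
follow a two-site rate law in which occupying one site of a dimer rescales
its neighbour's constants:

    v0(c0) = (2·Vmax1·c0/Km1 + 2·b·Vmax1·c0²/(a·Km1²))
             / (1 + 2·c0/Km1 + c0²/(a·Km1²))

with `Km2 = a·Km1`, `Vmax2 = b·Vmax1`, and plateau `2·Vmax2` at saturating
substrate. `a > 1` (with `b ≈ 1`) is the signature of **negative
cooperativity**; `a = b = 1` collapses the law onto Michaelis–Menten with
`Vmax = 2·Vmax1`. Points are weighted `1/SD²` of the replicate-averaged
rate, and the 4-parameter law is preferred over the 2-parameter one only if
an F(2, n−4) test rejects at the 95% confidence level.

Around this core the package provides:

* **HDX-MS differential uptake** — per-timepoint uptake differences between
  liganded states, significant when exceeding
  `z₉₉ · pooled_SD · √(2/n_rep)` (≈ ±0.3 Da at 98% confidence for
  triplicates with ~0.16 Da replicate SD).
* **Occupancy filling order** — classifies hexamer active sites as closed,
  open-in-closed-open-dimer or open-in-open-open-dimer and reports the
  molar ratio at which each class first reaches a refined ligand occupancy
  threshold, using the packaged wild-type and Asp204Ala/Arg217Ala
  double-mutant co-crystallisation series.
* **Synthetic data** — reproducible generators for heteroscedastic
  replicate velocity datasets, replicate exchange-uptake curves, and
  cooperative two-site titrations, so every stage is testable without any
  external data.

## Worked example

```python
import allokin as ak

truth = ak.ISParams(Km1=0.015, Vmax1=10.8, a=4.0/0.015, b=8.2/10.8)
grid = ak.make_concentration_grid(truth.Km1, truth.Km2, 16)
ds = ak.simulate_velocity_dataset(
    "IS", truth, grid, ak.NoiseSpec(mode="relative", cv=0.05, n_rep=3, seed=1)
)

from allokin.selection import fit_and_select
res_mm, res_is, comp = fit_and_select(ds, weighting="sd", seed=0)
print(res_is.summary())
print(comp.summary())
```

prints

```
Interacting-sites weighted least-squares fit
==========================================================
n points:   16    dof:   12    weighting: sd
wssr: 28.0328    starts: 21 (21 converged, best #0)
----------------------------------------------------------
   param       estimate      std.err
     Km1      0.0143262    0.0003106
   Vmax1        10.6472       0.1141
       a        228.758        67.43
       b       0.751701      0.01769
----------------------------------------------------------
derived: Km2 = 3.277 mM, Vmax2 = 8.004 U/mg, 2*Vmax2 = 16.01 U/mg
F(2, 12) = 218.6, p = 3.639e-10 (alpha = 0.05) -> interacting-sites
```

The fit recovers the strongly negatively-cooperative truth (Km2/Km1 ≈ 230
with its characteristically large uncertainty, Vmax2 ≈ 8.2 U mg⁻¹), and the
F-test decisively rejects the Michaelis–Menten description of the same
data. The same workflow is available from the shell:

```bash
allokin simulate velocity --seed 1 -o demo.csv
allokin select demo.csv -o report.json
allokin occupancy-order --enzyme-form DM
```

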