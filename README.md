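# rhizostoich

Rhizosphere effects, ecoenzymatic stoichiometry vector analysis and root
N:P nutrient-limitation classification for factorial forest-soil
experiments.

## The problem

In N-addition experiments across forest stand ages, each plot yields
paired rhizospheric and non-rhizospheric (bulk) soil, rhizosphere
extracellular enzyme activities (BG, NAG, LAP, ACP), and fine-root
chemistry (TC, TN, TP).  Two questions recur: *how strongly do roots
condition their surrounding soil*, and *which nutrient limits the roots
and the rhizosphere microbes?*  This package implements the full
analysis chain for such designs — for soil ecologists who want the
stoichiometric indices, the limitation calls and the factorial
statistics in one tested, scriptable pipeline.

## The core quantities

For each plot, with C_R and C_N the rhizospheric and bulk concentration
of a soil variable:

    RE = (C_R − C_N) / C_N × 100                       rhizosphere effect, %

With B = ln BG, N = ln(NAG+LAP), P = ln ACP (activities in
nmol g⁻¹ h⁻¹, each > 1):

    N:P_SEE        = N / P                              enzymatic N:P acquisition
    vector length  = √[(B/P)² + (B/N)²]                 microbial C limitation
    vector angle   = atan(P/N) · 180/π                  > 45° P-, < 45° N-limited
    microbial N limitation = atan(N/P) · 180/π          = 90° − vector angle

For fine roots (TN, TP in mg g⁻¹):

    N:P_CON          = TN / TP
    root vector angle = atan(TP/TN) · 180/π             > 4.09° N-, < 3.58° P-limited

The root thresholds sit on the classical N:P = 14 and 16 reference
lines (atan(1/14) = 4.09°, atan(1/16) = 3.58°).  Group contrasts use
two-way ANOVA (age × N level) with LSD letters, Pearson correlation
matrices, polynomial trend fits, and standardized major axis (SMA)
regression of the ln-activity stoichiometry.

A synthetic-data module generates balanced 3-age × 5-N × 3-block
datasets with known ground truth (configurable REs, trends, lognormal
noise, root TN–TP copula), so every stage is testable and parameter
recovery is quantifiable.  See `docs/methods.md` for the model details
and design choices.

## Worked example

```sh
python analysis/01_simulate.py --seed 1   # synthetic 45-plot study
python analysis/02_analyze.py             # full analysis bundle
python analysis/03_report.py              # human-readable summary
python analysis/04_recovery.py --seed 1   # recovery & calibration
```

The simulated study prints:

```
wrote 45 plot observations to results/synthetic/dataset.csv
balanced design: True; cells: 15 x 3 blocks
enzyme log-domain rule satisfied: True
```

and the analysis step:

```
analyzed 45 plots -> results/analysis
mean microbial vector angle: 39.14 deg (100% N-limited)
mean root vector angle: 4.47 deg (91% N-limited)
significant ANOVA terms (alpha 0.05): 1 of 45
```

The microbial vector angle below 45° and the root angle above 4.09° say
both the rhizosphere microbes and the fine roots of this synthetic
stand are relatively N-limited — by construction, since the generator's
default enzyme stoichiometry (ln-activity C:N:P = 1 : 1.30 : 1.08) and
root N:P ≈ 13 encode an N-limited system.  The recovery driver then
verifies the pipeline against the known truth:

```
1. noise-free recovery: max |error| = 1.07e-14 over 210 cell-quantities
2. RE(TN) at cv=0.10: mean 30.109% (target 30, MC SE 0.192, 100 datasets)
3. root TN-TP correlation: achieved 0.712 (target 0.7, n=6000)
4. null ANOVA type-I error: 0.036 (nominal 0.05, 500 replicates)
```

The same pipeline runs on real data via the CLI:

```sh
rhizostoich analyze --input mydata.csv --out results/   # wide or long CSV
rhizostoich report --bundle results/
```

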