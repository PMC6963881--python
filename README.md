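# chromaval

Statistics for HPLC method validation and drug-stability studies, built for
analytical chemists who validate chromatographic assays to ICH Q2(R1) and
follow a drug's degradation over time. The motivating application is the
quantification of ampicillin in total parenteral nutrition (TPN) admixtures —
a difficult oil-in-water matrix — and the assessment of how fast the drug
degrades in different admixture compositions, but every computation is
general.

## What it computes

**System suitability** (`chromaval.peakmetrics`) — from peak descriptors of
replicate injections: capacity factor k′ = t_R/t₀ − 1, theoretical plates
N = 5.54·(t_R/W½)², asymmetry factor As = W₅%/(2F) (< 1 fronting, > 1
tailing), and %RSD repeatability of retention time and peak area, judged
against configurable limits (defaults k′ > 2, N > 2000, 0.8 ≤ As ≤ 1.5,
RSD < 5%).

**Calibration** (`chromaval.calibration`) — ordinary least squares over all
replicate points, an F-test for variance homogeneity between the lowest and
highest levels (F_calc = s²_high/s²_low vs the 99%-confidence critical F;
with triplicates F_crit = 99), and — when the data are heteroscedastic —
weighted least squares under the six empirical weights 1/y^0.5, 1/y, 1/y²,
1/x^0.5, 1/x, 1/x². Coefficients come from the weighted normal equations
with weights normalized to Σw = n:

    a_w = (Σwxy − n·X̄wȲw) / (Σwx² − n·X̄w²),    b_w = Ȳw − a_w·X̄w

Each candidate line back-calculates every calibration point; the percent
relative error %RE = 100·(C_exp − C_nominal)/C_nominal is summed in absolute
value over the curve and the scheme with the smallest Σ|%RE| is selected.
Detection limits follow as LOD = 3.3·S_y/a and LOQ = 10·S_y/a with S_y the
residual standard error (intercept-SD variant available).

**Accuracy / precision / robustness** (`chromaval.validation_metrics`) —
relative error ε_r = (C_nominal − C̄_determined)/C_nominal·100 (negative ε_r
= over-estimation), %RSD of replicate determinations, and percent relative
differences of suitability metrics under deliberate method perturbations,
each with its acceptance limit (5%, 5%, 10% by default).

**Degradation kinetics** (`chromaval.kinetics`) — first-order fits
ln(P_t) = ln(P₀) − k_obs·t by least squares on (t, ln content), with
half-life t₀.₅ = 0.693/k. A reference dataset of ampicillin content in
three TPN compositions (HEN high-energy, HEL high-electrolyte, LEL
low-electrolyte; 0–144 h at 4 °C) ships with the package.

**Synthetic data** (`chromaval.synthetic_data`) — seeded generators for
heteroscedastic calibration series, noisy exponential decay courses, and raw
chromatographic traces with skewed peaks, plus a threshold-crossing peak
measurer.

**Pipeline & CLI** (`chromaval.pipeline`, `chromaval.cli`) — run every stage
from a YAML config and emit a JSON/markdown/CSV validation report; console
script `chromaval` with subcommands `simulate`, `suitability`, `calibrate`,
`validate`, `kinetics`, `report`, `run-all`.

## Worked example

```python
from chromaval import fit_first_order, load_reference_stability, calibrate
from chromaval.synthetic_data import CalibrationSimSpec, simulate_calibration

for label, s in load_reference_stability().items():
    f = fit_first_order(s)
    print(f"{label}: k = {f.k:.4f} h^-1, t1/2 = {f.t_half_hours:.2f} h "
          f"({f.t_half_days:.2f} days), R^2 = {f.r_squared:.4f}")

series = simulate_calibration(CalibrationSimSpec(true_slope=1.2e6, sigma1=0.03, seed=42))
summary = calibrate(series)
h = summary.homoscedasticity
print(f"F_calc = {h.f_calc:.0f} vs F_crit = {h.f_crit:.0f} -> heteroscedastic = {h.heteroscedastic}")
print(f"selected weight scheme: {summary.best.scheme}")
print(f"LOD = {summary.limits_best.lod:.3f} mg/mL, LOQ = {summary.limits_best.loq:.3f} mg/mL")
```

prints

```
HEN: k = 0.0023 h^-1, t1/2 = 300.45 h (12.52 days), R^2 = 0.9883
HEL: k = 0.0049 h^-1, t1/2 = 142.44 h (5.93 days), R^2 = 0.9720
LEL: k = 0.0036 h^-1, t1/2 = 192.29 h (8.01 days), R^2 = 0.9570
F_calc = 218 vs F_crit = 99 -> heteroscedastic = True
selected weight scheme: 1/x^2
LOD = 0.102 mg/mL, LOQ = 0.309 mg/mL
```

The kinetic lines say: ampicillin is most stable in the high-energy
admixture (half-life 12.5 days at 4 °C) and degrades three times faster in
the high-electrolyte one (5.9 days), so admixture composition drives the
drug's shelf-life. The calibration lines show a simulated detector whose
noise grows with signal: the F-test flags heteroscedasticity (218 ≫ 99), a
weighted line replaces OLS, and the detection/quantification limits follow
from the selected line.

The same kinetics run from the shell:

```sh
chromaval kinetics --builtin
```

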