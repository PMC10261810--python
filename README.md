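# pcbrisk

Dietary exposure and cancer-risk assessment for the six indicator
non-dioxin-like polychlorinated biphenyls (NDL-PCBs: PCB 28, 52, 101, 138,
153, 180) in dairy products, written for food-safety scientists and risk
assessors who work from per-sample congener concentrations on a milk-fat
basis (ng/g fat).

The package covers the full chain used in residue-survey studies of
fermented dairy products (yogurt, its diluted drink *doogh*, and its dried
concentrate *kashk*):

- **Synthetic survey generation** — per-sample congener tables drawn from
  truncated lognormals that are moment-matched to published group summaries
  (min/max/mean/SD), for exercising analyses when raw data are unpublished.
- **Analytical QC arithmetic** — calibration linearity (OLS, r²),
  blank-based LOD/LOQ (mean + 3·SD / mean + 10·SD), recovery %, RSD %, and
  below-LOD substitution (LOD/2 by default).
- **Group statistics** — survey-style summaries by product/brand,
  normality-gated comparisons (Kolmogorov–Smirnov, then ANOVA/t-test or
  Kruskal–Wallis/Mann–Whitney at α = 0.05), and the EU maximum-level check
  (Σ6 NDL-PCB mean < 40 ng/g fat).
- **Monte Carlo risk assessment** — estimated daily intake and incremental
  lifetime cancer risk with percentile tables and threshold classification.
- **Congener-profile clustering** — unit-variance-scaled profile matrices,
  Euclidean agglomerative clustering (average linkage by default, with
  deterministic tie-breaking), Newick export, and ordered heat maps.

## Model

For one congener at concentration $C$ (ng/g fat), the estimated daily
intake is

$$\mathrm{EDI} = \frac{C \cdot f_{\mathrm{fat}} \cdot IR \cdot EF \cdot ED}{BW \cdot AT} \quad \left[\mathrm{ng\,kg^{-1}\,day^{-1}}\right]$$

with fat fraction $f_{\mathrm{fat}}$ (g fat/g product), intake rate $IR$
(g/day), exposure frequency $EF$ (days/year), duration $ED$ (years), body
weight $BW$ (kg), and averaging time $AT$ (days). The incremental lifetime
cancer risk is

$$\mathrm{ILCR} = \mathrm{EDI} \times 10^{-6} \times SF$$

where $SF = 2\ (\mathrm{mg\,kg^{-1}\,day^{-1}})^{-1}$ is the US EPA oral
slope factor for PCBs and $10^{-6}$ converts ng to mg. Risk is classified
acceptable below $10^{-4}$; mean intake is also compared with the WHO
tolerable daily intake of 10 ng/kg bw/day. Exposure factors are drawn once
per Monte Carlo iteration and shared across congeners; concentrations are
drawn independently per congener.

Because published surveys often omit the numeric exposure factors,
`calibrate_exposure` back-solves the scalar
$f_{\mathrm{fat}} IR\,EF\,ED/(BW\,AT)$ from a reported median EDI, making
reported percentile tables reproducible without inventing parameter values.

## Worked example

```sh
python examples/03_monte_carlo_risk.py
```

prints, for yogurt (20,000 iterations, seed 1, exposure multiplier 0.9761
calibrated from the reference median intake):

```
             PCB28   PCB52  PCB101  PCB138  PCB153   PCB180    total
percentile
5           0.0432  0.0493  0.0609  0.4077  3.2305   8.5031  12.8569
50          0.0857  0.1353  0.0857  0.4842  4.0133   9.2723  14.2541
75          0.1145  0.1836  0.1038  0.5352  4.6872   9.8511  14.9507
95          0.1398  0.2245  0.1221  0.5826  5.4812  10.4408  15.9963
dominant congener: PCB180 (65.4% of mean intake)
mean EDI 14.302 ng/kg/day; below TDI(10): False
mean ILCR 2.860e-05 -> acceptable (threshold 1e-4)
```

Rows are intake percentiles in ng/kg bw/day; PCB180 carries about two
thirds of the total intake, and the mean lifetime cancer risk (2.9 × 10⁻⁵)
sits well below the 10⁻⁴ acceptability threshold even though this product's
calibrated intake exceeds the WHO TDI. The other example scripts
(`examples/01`–`05`) cover survey generation, group statistics and the EU
limit, congener clustering, and QC arithmetic.

A thin CLI wraps the same library calls:

```sh
pcbrisk simulate --seed 1 --out survey.csv
pcbrisk summarize survey.csv --level product
pcbrisk reproduce --seed 1 --out reference_run
```

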