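# Methods

## Scope and data model

The package analyses surveys of the six indicator NDL-PCB congeners
(PCB 28, 52, 101, 138, 153, 180, fixed in ascending IUPAC order) in three
fermented dairy products (yogurt, doogh, kashk) sold under five brands
(A–E). The unit of observation is one sample: product type, brand, and six
concentrations in ng per g of milk fat. The bundled reference tables
(`pcbrisk.datasets`) hold the published group summaries of a 3 × 40-sample
Tehran market survey — per-congener min/max/mean/SD overall, per product
and per brand, the analytical QC figures, and the Monte Carlo EDI
percentile tables — and serve as calibration targets and demo inputs; the
underlying raw samples were never published.

## Synthetic concentration generator

Concentrations of persistent lipophilic residues are strictly positive and
right-skewed, so each congener is modelled as a lognormal, truncated to the
published [min, max] window. Key choices:

- **Moment matching after truncation.** Matching the untruncated lognormal
  to (mean, SD) and then truncating biases the mean by up to ~8% for the
  narrow printed windows, so the generator instead solves for (μ, σ) such
  that the *truncated* distribution has exactly the requested mean (the
  truncated mean is strictly increasing in μ, so a 1-D Brent root suffices
  at fixed σ) and an SD as close as achievable (outer search over σ).
- **Printed SDs can be unattainable.** A unimodal density on [L, U] cannot
  be more dispersed than roughly the uniform SD, (U−L)/√12; several printed
  SDs exceed that bound for their window (e.g. kashk PCB180: SD 1.10 on a
  2.60-wide window whose uniform SD is 0.75), presumably reflecting clumped
  small-n data. The fit then returns the closest achievable SD. No
  downstream check depends on the generated SDs; means are matched to
  ~1e-9.
- **Feasibility floor.** The σ search is restricted to parameters keeping
  at least 1% of the lognormal's mass inside the window. This keeps
  rejection sampling ≤ ~100 redraws per accepted value and avoids a
  numerical cliff where the mean match degrades; tail CDF differences are
  computed in log space (`log_ndtr`) so the fit is stable for extreme σ.
- **Rejection sampling.** Draws outside the window are redrawn; windows
  retaining < 0.01% mass raise a generation error. Sampling, not inverse
  CDF, keeps the draw mechanism identical to the unconstrained case.
- **Labeled random streams.** One `SeedSequence`-derived child stream per
  (group, congener) under a single root seed: tables are bit-reproducible,
  and adding a stream never perturbs the others.
- **Brand labels.** The brand-by-product sampling design of the reference
  survey is unpublished, so `generate_survey` assigns brands as equal
  contiguous shares of each product's samples; brand labels are labels for
  grouping operations, not a second concentration model. Between-congener
  correlation is likewise not modelled — it is not estimable from the
  printed per-congener tables.

Defaults mirror the reference survey: 40 samples per product across five
brands. The large-n calibration checks use 100,000 samples per product, a
size chosen so Monte Carlo error (±0.01 on the grand total) is negligible
against the ±0.15 acceptance band while keeping runs under a few seconds.

## QC arithmetic

Calibration lines are ordinary least squares of response on concentration
with r² the squared Pearson correlation; the "average blank value"
detection limits are operationalized as the standard IUPAC convention
LOD = mean + 3·SD and LOQ = mean + 10·SD of ≥3 blanks; recovery is
100·measured/spiked; RSD is the sample-SD coefficient of variation. All SDs
package-wide use the n−1 denominator, consistent with small-n survey
summaries. Below-LOD values default to LOD/2 substitution — the pattern
that several published survey minima (0.04, 0.06 ng/g) are half the
corresponding LODs (0.08, 0.12 ng/g) supports this convention; LOD and
zero substitution are available. Values between LOD and LOQ are retained
as reported.

## Group statistics and tests

Summaries report per-congener and Σ6-total min/max/mean/SD per group; the
total is the per-sample sum, so the overall total mean equals the sum of
per-congener means by construction. The comparison pipeline gates on
normality: a plain Kolmogorov–Smirnov test per group against a normal with
moment-estimated parameters at α = 0.05 (a Lilliefors correction would be
stricter; the plain test is deliberately conservative toward the
parametric branch), then ANOVA/t-test if all groups pass, else
Kruskal–Wallis/Mann–Whitney. Significance is declared at p < 0.05. A
constant data vector across groups has no defined test and raises. Under a
normal null (3 groups × 40), the gated procedure's type-I error stays at
the nominal 5% because the KS gate almost always selects ANOVA.

## Monte Carlo exposure and risk

`run_mcs` draws the six exposure factors jointly once per iteration
(shared across congeners — the same consumer), multiplies each congener's
independent concentration draw by the common factor, and sums for the
total, which induces the expected positive correlation among congener
intakes. Percentiles (5/50/75/95) use linear interpolation between order
statistics (`numpy.percentile` default). Default iterations: 10,000;
fewer than 1,000 warns. The ILCR conversion `EDI × 1e-6 × SF` makes the
ng→mg step explicit; classification uses the mean by default (any
percentile is configurable) with a strict inequality against 1e-4.

Exposure parameters accept point, uniform, positive truncated-normal, or
arithmetic-moment-matched lognormal families. Because the reference survey
published only parameter definitions (body weight spanning 15–70 kg for
children and adults), no numeric defaults are shipped; the calibrated mode
back-solves the scalar multiplier from a reported median EDI instead. The
reported median intakes (yogurt 14.3, doogh 1.01, kashk 0.509 ng/kg/day)
are reproduced this way to within ~1% Monte Carlo error; the full
published percentile tables are *not* independently reproducible, and the
reported "95th-percentile" congener values are used only as a rank order.
One internal inconsistency of the source tables is left to the user: the
yogurt median intake (14.3 ng/kg/day) exceeds the WHO TDI of 10 while the
survey text calls average exposure far below it; the package reports both
comparisons and does not arbitrate.

## Profile clustering

Profile matrices put congeners in rows and samples (or group means) in
columns. Rows are scaled to unit variance by default — the congeners span
two orders of magnitude, and raw Euclidean distances would reduce to
PCB180's profile; raw and z-score scaling are available, and constant rows
are left unscaled and flagged. For z-scored rows the squared Euclidean
distance is 2(n−1)(1−r) in the Pearson correlation r, licensing the
correlation reading of the dendrogram.

Agglomeration is implemented directly via Lance–Williams updates
(single/complete/average/Ward on Euclidean distances) because
deterministic tie-breaking is part of the contract: among equidistant
pairs, the one with the lexicographically smallest cluster representatives
merges first. The implementation is cross-checked in the tests against
scipy's linkage (cophenetic distances) and against a from-raw-members
brute-force oracle on small instances. Newick export places a node created
at merge height h at ultrametric height h/2 (leaves of a height-h merge
are h apart along the tree).

## Pipeline and reproducibility

`run_pipeline` chains generate/read → censor-substitute → summarize →
compare → Monte Carlo → risk classification → clustering → report. Every
text artifact carries a provenance comment (package version, SHA-256
config hash excluding the output location, seed); identical config + seed
reproduce every table byte-for-byte. Concentration models for the Monte
Carlo stage are refit from the observed sample moments of each product
group, so the pipeline works identically on synthetic and user-supplied
CSVs.

## Known limitations

- Generated SDs undershoot printed SDs wherever those exceed the
  window-feasible maximum (see above); means, ranges and totals are exact.
- The synthetic generator emulates marginal per-congener structure only:
  no between-congener correlation, no brand-specific concentration model,
  no measurement error or censoring process. Passing tests demonstrate the
  analysis chain's correctness on data with the published marginal
  structure, not distributional fidelity of real dairy surveys.
- The plain KS gate with estimated parameters is anti-conservative as a
  normality test; it is used as a branch selector, not as an inferential
  claim.
- Published p-values of the reference survey are not reproducible (raw
  data unpublished); only test mechanics are validated, via null
  simulation.
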