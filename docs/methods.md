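# Methods

## The NO-donor / NO / O2 kinetic model

Diazeniumdiolate (NONOate) donors decompose by first-order kinetics,
releasing a fixed stoichiometry of NO per donor molecule; free NO is removed
by autooxidation. The coupled system, in micromolar and seconds, is

    d[D]/dt   = -k1 [D]                          k1 = ln 2 / t_half
    d[NO]/dt  =  k1 [D] e_NO  -  s k [O2] [NO]^2
    d[O2]/dt  = -k [O2] [NO]^2
    dC/dt     =  s k [O2] [NO]^2

where `e_NO` is moles of NO per mole of donor, `k = 2e-6 uM^-2 s^-1` is the
third-order autooxidation rate constant (2×10^6 M^-2 s^-1), `s` is the NO:O2
consumption stoichiometry, and `C` accumulates oxidized NO. O2 is not held
constant; one O2 is consumed per `s` NO oxidized.

**Stoichiometry `s`.** The aqueous autooxidation 4NO + O2 → 4NO2- gives
`-d[NO]/dt = 4k[NO]^2[O2]`, i.e. `s = 4`, which is the default. A rate law
written without the factor (`s = 1`) overestimates steady-state NO by a
factor of 2; with `s = 4` the closed-form quasi-steady state reproduces both
reference conversions (165 uM Sper/NO → ≈3 uM NO in a 3 h assay; 100 uM
DETA/NO → ≈0.6 uM plateau). `s` is configurable (1, 2, 4).

**Built-in donors.** DEA/NO (t1/2 = 16 min, 1.5 equiv), Sper/NO (230 min,
2 equiv), DETA/NO (57 h, 2 equiv). DETA/NO half-lives between ~22 h and 57 h
are quoted in different settings; 57 h is the default used for the
steady-state conversions and is exposed as a parameter. Half-lives are used
as configured, with no temperature correction.

**Numerics.** `scipy.solve_ivp` with LSODA, rtol 1e-8, atol 1e-9 uM, on a
user-chosen output grid (10 s default). Excursions below -1e-6 uM abort with
an error; smaller ones are clipped to 0. Mass balance
`e_NO (dose - [D]) = [NO] + C` holds to ~1e-15 relative in practice and is
asserted at 1e-3 in the tests. Internal units of uM and seconds keep the
state variables O(1)-O(100) and the system non-stiff at these tolerances.

**[NO]_ss summarization.** "Steady-state NO" is operationalized as the
trapezoidal time-average of [NO] over the assay window (default: the full
assay — 3 h for enzyme assays, 12 h for lysate assays), with the peak also
reported. The time-average is the quantity that reproduces both printed
reference values; a plateau readout would differ only for the slow donors,
where the two nearly coincide.

**Quasi-steady-state oracle.** Setting production = consumption gives
`[NO]_qss = sqrt(k1 [D] e_NO / (s k [O2]))`. For slow donors (release slow
compared with the NO relaxation time ~1/(2 s k [O2] [NO]_ss), i.e. minutes)
the ODE solution tracks this closed form within a few percent after the
initial transient; the tests assert 10%. This is an independent analytic
check, not the implementation.

## NO-coupled enzyme activity

Reversible inhibition acts instantaneously on the conversion rate — NO
binding at the catalytic iron is fast compared with the assay timescale, so
no binding kinetics are modelled. The inhibited fraction is logistic in
log10[NO] with half-inhibition at `no_ic50` (default 1 uM) and Hill slope 4
(steep, threshold-like — chosen so activity switches between ~1.65 uM NO,
where the enzyme is inhibited, and ~0.6 uM, where it has recovered).
Product formation obeys `dP/dt = k_conv (1 - f([NO])) (1 - P)` with
`k_conv = 1.28e-3 s^-1` (≥99% conversion in 1 h uninhibited). The equation
is integrated in closed form, `P = 1 - exp(-∫ k_eff dt)`, by trapezoidal
quadrature of the effective rate on the NO grid, so the product fraction is
exactly monotone and bounded by construction.

Regime classification uses hourly checkpoints: `full_activity` if P ≥ 0.95
at the first checkpoint; `inhibition_recovery` if inhibited early but
P ≥ 0.95 by the last; `full_inhibition` otherwise. The absolute product
level under sustained inhibition (e.g. the plateau under continuous 300 uM
Sper/NO) depends on enzyme kinetics that are not identifiable from the
available observations; only the regime pattern is claimed, not that level.

## Assay quantification

* **4PL fitting.** `Y = Bottom + (Top - Bottom)/(1 + 10^((LogIC50 - X)·Hill))`
  with X = log10(dose), fitted by bounded Levenberg-Marquardt
  (`curve_fit`; Hill ∈ [-10, 10], LogIC50 within the dose range ± 2
  decades). Start values: response extremes for the asymptotes, the dose
  nearest mid-response for LogIC50, slope sign from a linear probe.
  Inhibition curves fit with negative Hill. Constant responses raise an
  unidentifiability error. At X = LogIC50 the fitted curve passes through
  (Top+Bottom)/2 by construction.
* **MALDI fractions.** Each adduct's intensity over the summed intensity of
  all adducts (5mC ~2424.6, 5hmC ~2440.6, 5fC ~2438.6, 5caC ~2454.6 m/z).
  Peak picking from raw spectra is out of scope; input is an
  already-integrated intensity table.
* **Linear calibration.** OLS of signal on standard concentration, inverted
  for unknowns; negative inversions are reported as 0 with a below-range
  flag.

## Differential methylation (oxRRBS stage)

Per replicate, `beta_BS` reads 5mC+5hmC and `beta_oxBS` reads 5mC;
`beta_5hmC = max(0, beta_BS - beta_oxBS)` (standard oxBS subtraction;
clipping is flagged and reportable as a QC rate). Replicates with either
assay below `min_coverage` (default 10) are masked.

A site is a DMP/DhMP when `p < alpha` and `|delta beta| > delta`
(defaults 0.05 and 0.1); hyper vs hypo is the sign of treated - control. No
multiple-testing correction enters the call — the definition is a raw p
threshold plus an effect-size filter — but a BH-FDR column is emitted for
transparency.

**Choice of test.** The default is a pooled count test: replicate counts are
summed per condition, and 5mC (a single binomial proportion per condition,
from the oxBS counts) is tested by Fisher's exact test, while 5hmC (a
difference of two binomial proportions per condition) is tested by a
two-sample z with delta-method standard errors. The alternative `welch`
test — Welch's t on per-replicate betas — is provided but is not the
default because with two replicates per condition it has ~2 degrees of
freedom: at coverage 50 and delta beta = 0.3 its sensitivity is ~34% versus
~99% for the pooled test (Monte Carlo, 2000 sites). With so few replicates,
count-based testing is what dedicated methylation callers use; Welch
becomes preferable when enough replicates exist for between-replicate
variance to be estimable.

**Annotation.** CpG classes by distance from islands: island (inside),
shore (≤2 kb), shelf (2-4 kb), open sea (beyond) — community-standard
distances. Coordinates are 0-based half-open; strand is ignored (CpG sites
treated as strand-symmetric). Feature labels resolve overlaps by precedence
promoter > 5'UTR > 3'UTR > exon > intron > enhancer > super_enhancer, with
intergenic as the fallback; enhancer overlaps are additionally flagged.
Sites on chromosomes absent from the island track default to open sea and
are flagged unannotated. When only TSS tracks exist, promoters should be
constructed as TSS -1500/+500 before input; the package consumes explicit
BED intervals.

The promoter-methylation/expression check is a Spearman rank correlation
over genes shared between a promoter-beta table and an expression table
(≥10 genes required).

## Synthetic-data generators

All generators are pure functions of a spec that includes the seed
(`numpy.random.default_rng`), so outputs are byte-identical across runs.

* **Dose-response**: 4PL truth (Bottom 0, Top 100, IC50 165 uM, Hill -1)
  plus Gaussian noise (sd = 5% of Top) at 8 log-spaced doses over the
  assayed 15-1200 uM range, in triplicate — the assay's biological
  replication. With single measurements this design does not bracket either
  asymptote tightly enough to pin all four free parameters (median relative
  IC50 error ~20%); triplicates bring it to ~11%.
* **oxRRBS methylome**: sites on one synthetic chromosome laid out so that
  the emitted island/feature BEDs reproduce each site's intended CpG class
  and feature exactly (island sites inside 1 kb islands spaced 20 kb apart;
  shore/shelf sites at 1-2 kb / 2-4 kb offsets; open-sea sites in a
  separate region). Class mix is open-sea-dominant (60%), 5mC baselines
  rise from islands (0.10) to open sea (0.55) with ±0.05 per-site jitter,
  5hmC baselines are small (0.03-0.05). Coverage is Poisson (mean 50) per
  assay and replicate; methylated counts are Binomial(total, beta). Planted
  effects shift the target beta of randomly chosen eligible sites (those
  with room for the full ±0.3 shift) in the treated condition;
  `effect_classes` restricts placement, e.g. to open sea. Truth tables
  record per-site class, feature, betas and planted direction.
* **Expression**: `log expr = intercept + slope·beta + N(0, sd)` per gene
  with slope ≤ 0 (default -3), emulating promoter methylation repressing
  transcription.

What the generators do **not** emulate: read-level artifacts (bisulfite
conversion failure, mapping bias, fragment-length effects), spatial
correlation between neighbouring CpGs, biological replicate heterogeneity
beyond binomial sampling, and the empirical genome-wide distribution of
effect sizes. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated sampling assumptions, not
performance on real sequencing data.

## Problem sizes and reproducibility

The test suite and the acceptance script use 1000-site methylomes (5000 for
the expression check, to yield ~500 promoter genes), 100 seeds for the noisy
4PL recovery, and 10-60 s ODE output grids — sizes at which every Monte
Carlo estimate above is stable to a few percent while the whole suite runs
in seconds. The null DMP call rate has expectation ~0.04 under the defaults;
single-seed realizations at 1000 sites scatter by ±0.01.

## Known limitations

* The kinetic model omits S-nitrosation, metal-nitrosyl side reactions,
  cellular NO consumption and diffusion; it describes a well-mixed aqueous
  assay.
* The inhibition model is phenomenological (logistic in log[NO]); it does
  not model DNIC formation kinetics or distinguish TET paralogs.
* The 5hmC pooled test is a normal approximation; at very low coverage its
  p-values are approximate where the 5mC Fisher test is exact.
* DMP calling is per-site on raw betas; no smoothing or regional
  aggregation is performed.
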