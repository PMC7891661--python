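# Methods

## Release-rate estimation

An incubation places `n` crustacean specimens in a jar of volume `V`
(default 0.5 L) of 0.2 µm filtered seawater and samples analyte
concentrations at 0, 0.5, 1, 1.5, 2, 3, 5 and 8 h. The model is constant
release up to an analyte-specific plateau:

    c(t) = c₀ + r · min(t, t_plateau) · n / (24 V)

with `r` in nmol individual⁻¹ d⁻¹. The regression window ends at the last
still-increasing time point: scanning the replicate-mean series of every
monitored analyte, the first point that fails to exceed its predecessor by
more than `tol`·predecessor (default `tol = 0`, the strictest reading of
"did not further increase") closes the window at the previous point. The
window never shrinks below the first three time points, the minimum for a
slope with an error estimate.

Each replicate jar is fitted independently by OLS (`scipy.stats.linregress`;
two-sided t test on the slope, n−2 df) and summarized as mean ± SD across
jars; pooling all points into a single fit is available
(`pool_replicates=True`) but not default, since per-jar fits propagate
between-jar variability into the reported SD. A fit is accepted only when
R² ≥ 0.60 and p ≤ 0.05; per-individual and per-biomass rates are defined
only for accepted fits.

Controls (no animals) are checked for drift: if their slope is significant
(p ≤ 0.05) it is subtracted from the jar slopes. How controls entered the
original rate calculations is not documented for this kind of experiment;
drift subtraction is this package's choice and can be disabled.

Normalizations: per-individual = slope·V·24/n (nmol ind⁻¹ d⁻¹); per-biomass
= slope·V·24/(B·10³) in µmol (g C)⁻¹ d⁻¹, with B the summed specimen biomass
from ellipsoid biovolume V = (4/3)πab² (a = prosome length/2, b =
diameter/2) times 0.08 pg C µm⁻³. Bulk release = per-individual × copepod
abundance (ind L⁻¹, a required user input — regional abundances are
literature values, not measured here); turnover = bulk release / seasonal
mean concentration.

## Duplicate precision and outliers

Signed percent differences dᵢ = 200(x₁−x₂)/(x₁+x₂) of duplicate pairs are
summarized by the percentile-spread precision (P84.135 − P15.865)/2 — the
robust analogue of one standard deviation, exact for a Gaussian — and the
median as bias. Signed (not absolute) differences are used; the exact
variant from the clinical-chemistry literature the method descends from is
not uniquely pinned down, so the functions are small and substitutable.
Outliers among the dᵢ use a plain Z-score with threshold 1.5, computed once
on the full set; a zero-spread set has no outliers. Because the percentile
spread is itself robust, removing Z-flagged values lowers the statistic in
expectation but may wiggle it slightly upward on a single small set
(percentile interpolation); the tests check the expectation, not a
pointwise inequality.

## Radiotracer rates

Net DPM = mean over replicate filters (or wicks) minus the killed control,
clamped at zero with a warning (blanks occasionally exceed low-activity
samples). Conversion to rate:

    rate [nmol L⁻¹ d⁻¹] = net / (SA · 2.22×10¹² / 10⁶) / V / (t/24)

with SA in Ci mmol⁻¹ (¹⁴C-taurine 0.060, ³H-leucine 120). DPM are treated as
already efficiency-corrected; there is no counter-efficiency parameter.
Both assimilation and respiration are multiplied by the external
isotope-dilution factor (measured + added)/added ≥ 1. Uptake = assimilation
+ respiration; efficiency = 100·assimilation/uptake, reported missing (not
zero) at zero uptake; turnover = uptake / ambient concentration; biomass
production = 1.55 µg C per nmol leucine, applied to the dilution-corrected
rate.

The forward simulator is the exact inverse: expected filter DPM =
true rate / dilution factor · V · (t/24) · DPM-per-nmol + blank, since only
the added fraction of the ambient-plus-added pool is labeled. Realized DPM
are Poisson draws around the expectation (counting statistics), so the
estimator is exactly unbiased and the noise-free round trip is exact to
machine precision.

## Single-cell activity

Grain areas measure assimilation only: respired label leaves the cell and
the hybridization protocol's permeabilization and washes flush
non-incorporated tracer. The grain-area calibration is least squares
through the origin (no grains ⇒ no assimilation) of the community bulk
assimilation, in amol L⁻¹ d⁻¹, on the total grain area per liter; a single
paired observation reduces to the exact ratio and closes the loop
bulk → per-cell rates → bulk to machine precision. Calibration is
per-dataset by default; pooling datasets is the caller's choice by
concatenating pairs. Activity classes default to edges 0.1, 10 and 80
amol cell⁻¹ d⁻¹, with rates below 0.1 reported as a separate sub-detection
class; both the cell-count shares and the rate-sum shares sum to 100%.
Taxon bulk assimilation = mean positive-cell rate × positive-cell abundance
× 10³ mL L⁻¹ × 10⁻⁹ nmol amol⁻¹.

## Elemental budget

Taurine carries 2 C, 1 N and 1 S atoms. Carbon flux = assimilation × 2 ×
12.011 × 10⁻³ µg C L⁻¹ d⁻¹; its share of the leucine-derived biomass
production is the C contribution; the N and S contributions follow from
the cellular atomic ratios C:N = 4:1 and C:S = 26:1, giving N = 2C and
S = 13C identically with the default constants. Group or seasonal summaries
are means of per-sample ratios, not ratios of means — the former reproduces
conventional seasonal reporting; `mean_of_ratios` makes the choice
explicit and the alternative is one line. Supply–demand closure divides
the copepod bulk release by the prokaryotic bulk uptake; a ratio ≥ 1 means
the animals alone could sustain the measured consumption.

## Synthetic data and what it does (not) show

The generators emulate: multiplicative lognormal analytical noise on
concentrations (CV default 2%, matching duplicate precision of 1–3%),
Poisson counting noise on DPM, multinomial taxon composition with
binomial substrate positivity and lognormal per-cell rates. Seasonal
presets follow a coastal temperate annual cycle (fall bloom maxima in
release, concentration and assimilation efficiency; winter efficiency above
summer above spring), with per-individual release, assimilation,
respiration and leucine incorporation set to the seasonal means such a
system exhibits and copepod abundances back-computed from the bulk rates.
Ground truth is always emitted in a sidecar record.

Not emulated: copepod feeding and excretion physiology (release is a
constant-rate + hard-plateau abstraction), bacterial re-uptake inside
incubation jars (0.2 µm filtration minimizes it; the plateau time is a free
parameter instead), day-to-day field variability, probe coverage biases,
and grain-area image segmentation. Passing tests therefore demonstrate that
the estimators invert their stated measurement models and that the
arithmetic chain is correct — not that the measurement models capture every
feature of field data.

## Numerical choices and problem sizes

Degenerate inputs: constant concentration series return slope 0, R² 0 and
fail QC rather than erroring; zero uptake flags efficiency as missing; zero
abundance gives zero bulk release and zero turnover; negative net DPM
clamps to 0 with a warning. Seeds are threaded through
`numpy.random.default_rng`; scenario sub-seeds are drawn below 2³¹.
Simulation-based checks use 100 experiments for release-rate recovery
(median relative error ≤ 10% at 5% noise), 1000 pure-noise series for QC
specificity (false-pass ≤ 10%), and 10³ Poisson draws for tracer
unbiasedness — sizes chosen so each check resolves its threshold with
comfortable Monte-Carlo margin while the whole suite runs in seconds.

## Known limitations

Bivalve (e.g. *Mytilus*) release experiments are out of scope: filtration
makes jar concentrations non-monotone and the constant-release model does
not apply. Biomass uses a single carbon factor with no species-level
allometry. No Michaelis–Menten kinetics: rates are single-point estimates
at a saturating addition. The ³H-taurine specific activity used for
single-cell incubations has no default and must be supplied.
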