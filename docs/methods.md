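# Methods

## Natural-abundance correction

A GC-MS fragment with elemental composition `{C:c, H:h, O:o, …}` observed
in a ¹³C tracer experiment produces intensities at nominal mass shifts
m+0 … m+M. Two processes generate shifts: tracer incorporation (the
signal) and natural heavy isotopes (a nuisance that must be removed
before labeling fractions are interpreted).

The per-atom isotope distributions (shift, abundance) live in an editable
tab-separated table shipped with the package (IUPAC representative
values: ¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O/¹⁸O 0.00038/0.00205,
plus S, Si, P). The natural mass-shift distribution of a fragment is the
convolution of its atoms' distributions, computed by exponentiation-by-
squaring on the truncated polynomial — truncation during convolution is
exact for the retained coefficients because all shifts are non-negative.

The correction matrix for `n` labeled positions has columns
`A[:, j] = conv(naturalMID(fragment minus j tracer atoms),
Binomial(j, purity))`, shifted so that with perfect tracer purity the
column is the residual fragment's natural MID offset by `j`. Positions
drawn from the tracer that are *not* heavy are treated as light with no
natural abundance (their isotopic origin is the tracer batch, not
nature). Tracer purity defaults to 1.0: the labeling model used
downstream handles dietary dilution entirely through the enrichment
parameter `p`, so purity is a separate, opt-in knob.

**Truncation.** Rows are kept up to `M = n_label + 6`. The fully labeled
column only retains the rows above `n_label`, so the headroom must cover
the residual fragment's whole heavy-isotope tail; six extra rows keep the
per-column truncated mass below 1e-6 for fragments up to 30 carbons
(three rows would leave ~1e-3 for a C30 fragment). The remaining deficit
per column is reported on the matrix object.

**Deconvolution.** `A·x ≈ v` is solved by non-negative least squares by
default — negative isotopologue fractions are unphysical and NNLS is
robust to measurement noise — with the Moore–Penrose pseudo-inverse as an
alternative (small negative round-off clipped, ill-conditioning warned).
The solution is renormalized to sum 1 and carries the fit residual.
Correctness is checked two independent ways: against brute-force
enumeration of every per-atom isotope assignment for small fragments
(≤ 1e-12 per entry), and by round-trips `correct(A·x) = x` (1e-10
noiseless; 5e-3 under 1e-4 additive noise).

**Scope.** Only nominal (unit-Da) shifts are modeled; high-resolution
fine structure that separates e.g. ¹³C from ¹⁵N at the same nominal mass
is out of scope. Fragment formulas are user input and may include
derivatization atoms (TMS silicon and carbons); the shipped defaults are
underivatized carbon skeletons (lactate C3H6O3, pyruvate C3H4O3, 2HG
C5H8O5, citrate C6H8O7) and are labeled as an assumption, not an
instrument fact.

## Single-pool labeling model

For a metabolite pool of size `X^T` at metabolic steady state, fed from a
precursor with tracer enrichment `p`, the tracked labeled amount `X^L`
follows

    X^L / X^T = p · (1 − exp(−f_x · t / X^T)).

Assumptions: constant pool and flux over the labeling window, a single
well-mixed pool per metabolite, and all label mass concentrated in one
tracked isotopologue (m+3 for the three-carbon glycolytic products, m+2
for 2HG and citrate via acetyl-CoA/2-oxoglutarate). `p` is the dietary
tracer fraction (0.5 for 50% ¹³C₆-glucose) with no internal-dilution
adjustment; pools are accepted in normalized-intensity units, so `f_x`
is a relative flux (intensity·h⁻¹). Single-timepoint estimation at
t = 2 h; multi-timepoint fitting is not implemented.

The closed-form inverse is `f_x = −(X^T/t)·ln(1 − (X^L/X^T)/p)`,
computed with `expm1`/`log1p` throughout. Enrichment within 1e-9 of `p`
(or above) yields an infinite, flagged estimate: clipping saturated
samples to a finite value would bias group means, so they are excluded
from downstream statistics with a logged count instead.

**Numerical limit of the inversion.** The round trip
`estimate(forward(f))` is exact to 1e-10 relative only while
`f·t/X^T ≲ 15`. Beyond that the forward fraction sits within ~3e-7·p of
the asymptote, and rounding it to an IEEE double destroys most of the
residual's bits: at `f·t/X^T = 20` the best any inversion can recover is
~3e-9 relative. This is a property of passing the fraction through a
64-bit float, not of the algorithm; the tests document both regimes.

## Cohort statistics

Normalization divides each intensity by the sample's wet mass and by its
internal-standard response factor `IS / IS_ref`; `IS_ref` defaults to
the cohort median, making units cohort-relative (a fixed reference pins
them across cohorts). Fold changes divide by the control-group mean, so
control centers at 1.

Univariate testing is the equal-variance two-sample Student's *t*
(two-tailed), with Welch's correction behind a flag; the Bonferroni
family size `m` defaults to the number of metabolites tested and is
echoed in every output row. Zero pooled variance with distinct means is
reported as a flagged degenerate result (|t| = ∞, p = 0) rather than an
error. Missing values: pairwise deletion per metabolite for t-tests,
listwise for PCA (logged).

PCA mean-centers and, by default, autoscales columns to unit variance
(the common choice for targeted panels of metabolites with very
different absolute intensities); `center_only` is available, and no log
transform is applied by default. Scores come from a full SVD; component
signs follow a deterministic convention (the largest-magnitude loading
of each component is positive) so results are reproducible across runs
and libraries.

## Synthetic-data generator

The generator emulates the study family's designs: two genotypes with 5–6
replicate pools of ~15 mid-L3 larvae each (nominal pool mass 25 mg, CV
10%), per-metabolite baselines on a realistic relative-intensity scale,
multiplicative group effects, and log-normal measurement noise (default
CV 10%; the mutant preset uses 5%, typical of a well-tuned targeted GC-MS
panel). Intensities are positive and right-skewed, hence the
multiplicative log-normal noise model.

Each sample also draws an instrument-response factor (CV 5%) that scales
all of its metabolite intensities *and* its internal-standard intensity;
this is what makes IS normalization meaningful and the normalization
scale-equivariance property hold by construction.

The lactate→2HG coupling is phenomenological, not mechanistic (no rate
equations for lactate-dependent L2HGDH inhibition are available):
`ln 2HG = ln(baseline·multiplier) + slope·δ_lac + ε`, where `δ_lac` is
the lactate log-deviation (sd σ_L from the CV) and `ε ~ N(0, σ_E)`. The
implied within-group Pearson r is `s·σ_L / √(s²σ_L² + σ_E²)`, so the
residual sd can be chosen to hit a target correlation exactly; presets
use r ≈ 0.973. The analytic value refers to log-space within-group
correlation; at CV ≤ 10% the level-space value differs negligibly, and
pooling two genotypes with shared elevated multipliers pushes the
observed r higher still, as in real mutant-plus-control scatter plots.

Labeling experiments draw each sample's pool log-normally around the
configured `X^T`, compute the true enrichment from the forward model *at
that pool* (so the emitted pool is exactly what the model saw, and the
noiseless chain recovers `f_x` to machine precision), place all label
mass in the tracked isotopologue, apply the fragment's correction matrix
to obtain the observable MID, and multiply each channel by log-normal
noise. The raw tables thus exercise the correction and flux stages
end to end.

What the generator does **not** emulate: chromatographic artifacts,
detector saturation, batch drift, missing peaks, partial-labeling
intermediate isotopologues, and any mechanistic lactate–L2HGDH kinetics.
Passing tests therefore demonstrate correctness of the computational
chain under the stated statistical structure, not robustness to every
failure mode of real spectra.

Determinism: all draws flow from the single config seed in a fixed
order; identical configs yield byte-identical tables.

## Pipeline and formats

Delimited text throughout: UTF-8, comma, "." decimals, LF endings, empty
fields for missing values. Wide sample tables carry `sample_id, group,
mass_mg, is_intensity` plus one column per metabolite; the long dialect
uses `mass_mg`/`is_intensity` as reserved metabolite names. Isotopologue
tables are long format (`sample_id, group, metabolite, fragment_formula,
tracer_element, m_shift, intensity`). The `run` command executes both
tracks from one YAML config (unknown keys rejected, paths checked before
any computation), logs package version, config hash, seed and per-stage
record counts, and exits 0/2/3 for success/validation error/computation
error.

## Problem sizes

The test suite and acceptance script use: 375 fragment/label
combinations for the enumeration oracle, 121-point log grid for the
inversion, n = 25 per group for flux recovery (CV 5%), 100 seeds for PCA
separation, and n = 10,000 samples for generator fidelity — sizes at
which the Monte-Carlo bands quoted in the tests are comfortably stable
on a laptop-class single core.
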