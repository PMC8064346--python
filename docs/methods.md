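# Methods

## Scope and model

The package quantifies leaf anatomy from three kinds of already-reduced
inputs: epidermal censuses (counts of stomata, pavement cells and trichomes
over a known area), replicate thickness measurements from cross-sections,
and hand-labeled RGB rasters of semithin sections. It does **not** segment
raw micrographs — automatic segmentation of mesophyll tissue is error-prone
enough to distort the biology, so labeling is assumed to be done by an
operator in an image editor, and the software only counts.

### Epidermal indices

Densities are stored as raw counts plus the surveyed area (mm²) and divided
on demand, so a unit mistake surfaces as an absurd density rather than
cancelling silently. The stomatal index SI = 100·SD/(SD+E) is undefined
when SD + E = 0 and the package raises rather than returning 0: a surface
with no stomata (SI = 0) and a census with no data are different things.
The stomatal pore index SPI = SD·SL²·10⁻⁴ uses the mean pore length in µm;
the 10⁻⁴ converts µm² to mm² so the index is an areal percentage. With
SD = 0 the SPI is 0 and no pore length is needed.

### Tissue ratios

CTR = 100·PTT/LT and SR = 100·STT/LT are ratios of mean thicknesses.
Preconditions enforce 0 ≤ tissue ≤ LT per value and
mean(PTT) + mean(STT) ≤ mean(LT) per profile. A leaf without palisade
(all-zero PTT, as in *V. major*) is valid.

### Aggregation

All summaries are mean ± s.e.m. with the sample (n−1) standard deviation;
the s.e.m. is omitted at n = 1. Under k-fold replication of a sample the
s.e.m. therefore shrinks by exactly √((n−1)/(kn−1)), the finite-n form of
the 1/√k law, and the tests assert that exact factor.

### Airspace estimation

The estimator is a color histogram: each pixel is assigned to the unique
legend class within `match_tolerance` per channel, and

    airspace % = 100 × intercellular / (intercellular + cell).

Epidermis, ignore and unresolved pixels are excluded — the epidermis is not
part of the mesophyll. Because no geometry is used, the estimate is
invariant under pixel permutation, additive over image tiles, and
equivariant under recoloring both image and legend; the tests check all
three, plus exact agreement with a naive per-pixel loop oracle on images up
to 64×64. No stereological correction from 2-D section porosity to 3-D
volume fraction is attempted.

Class colors are only conventional (any distinct quadruple works); the
defaults are green (0,255,0), grey (128,128,128), blue (0,0,255), yellow
(255,255,0), overridable via a JSON legend file. The legend is rejected if
2×tolerance reaches the minimum pairwise per-channel (Chebyshev) distance
between colors, so no pixel can ever match two classes. The default is
tolerance 0 with `unresolved_policy="error"`: hand-labeled images with
anti-aliased edges fail loudly instead of being silently misclassified, and
the user chooses between `ignore` (off-legend pixels counted separately as
`unresolved`) and `nearest` (snap to the closest color). How boundary
pixels were treated in the original hand-labeling workflow is unknown, so
the conservative default seemed right. RGBA and palette rasters are
converted to RGB (alpha dropped); grayscale rasters are rejected because
the legend is chromatic.

## Synthetic generators

The generators exist so every stage can be tested against known ground
truth, since no labeled micrographs are publicly deposited.

`generate_section` paints blue epidermis bands top and bottom, fills the
interior cell-green and carves grey ellipses (random centers, radii
uniform between the configured bounds) until the grey/(grey+green)
fraction first reaches the target. The returned ground truth is the
*realized* fraction recounted from the finished pixels, so estimator
recovery can be asserted without tolerance; the overshoot is bounded by
(max blob area)/(interior area). All blobs for a given seed come from one
RNG stream, so raising the target only extends the same sequence — the
realized fraction is monotone in the target. The geometry is deliberately
crude (no connected spongy network, no cell walls): the estimator is a
histogram, so only the area fraction matters, and passing tests say
nothing about how well a human can label real sections.

`generate_census` rounds density×area to counts (`exact`) or draws Poisson
counts with those means (`poisson`), emulating field-to-field sampling
variation but not operator miscounting or spatially clustered stomata.
`generate_section_profile` scales the target-consistent mean thicknesses by
independent multiplicative Gaussian factors 1 + cv·z per replicate,
redrawing any triple that violates non-negativity or PTT+STT ≤ LT, so every
generated profile is internally consistent by construction.

Default study conditions mirror the reference dataset's scale: 1 mm²
census fields, three thickness replicates, 512×512 sections; the fixture
porosity 0.628 mirrors the lowest-porosity species.

## Statistics

Pearson r, OLS fits and one-way ANOVA + Tukey HSD are delegated to
scipy.stats (`pearsonr`, `linregress`, `f_oneway`, `tukey_hsd`); Tukey
p-value conventions are therefore scipy's. Correlation requires n ≥ 3 pairs
and nonzero variance; groups require n ≥ 2 each. Star tiers are
*** p < 0.0001, ** p ≤ 0.005, * p ≤ 0.05, "ns" above that.

The reference correlation (adaxial trichome density vs adaxial stomatal
index over four taxa) computes to r = −0.766; the published summary rounds
this to −0.7, so the test asserts r ≤ −0.7 rather than equality. The
published per-contrast epidermis p-values cannot be reproduced because the
per-replicate thickness data were never printed; instead the ANOVA layer is
validated by Monte-Carlo calibration — under a Gaussian null (3 groups of
n = 6, 1000 replicates) the empirical type-I error must sit within a 3σ
binomial band of α = 0.05.

## Reference dataset and its quirks

`vincaleaf.reference` bundles the published per-species trait values. Two
caveats: (1) the epidermal cell densities E behind the SI column were never
published, so SI cells cannot be independently recomputed — test fixtures
back-compute E from the printed SI where one is needed; (2) the printed
derived values are inconsistently rounded at the second decimal (the
variegate's abaxial SPI recomputes to 1.0188 but is printed 1.01, while
other cells round half-up), so all recomputation checks use an absolute
±0.02 band and the package itself computes at full precision, rounding only
for display (2 dp, half-even).

## Determinism and I/O

Measurement CSVs are long-format (one value per row) to preserve
replicates; wide tables are output views. JSON outputs carry full
precision, sorted keys and no timestamps; a provenance record stores the
seed, legend, tolerance and input SHA-256 prefixes. Two runs with identical
inputs and seed are byte-identical, and the tests assert it.

## Problem sizes used in the test suite

Synthetic sections in tests are 96–256 px square (the generator default is
512), the classification oracle runs on rasters ≤ 64×64, the Poisson census
calibration uses 1000 replicates, and the ANOVA null calibration 400
replicates in the unit suite and 1000 in the acceptance suite. These sizes
keep the full-precision recovery properties exercised at every scale the
estimator cares about (the histogram is size-agnostic).

## Known limitations

- 2-D porosity from a single section is a biased proxy for 3-D airspace
  volume fraction; no correction is applied.
- The airspace estimator trusts the labeling; it cannot detect mislabeled
  regions, only off-legend colors.
- Whether vascular bundles should be painted "cell" or "ignore" is a
  labeling convention the package does not impose.
- The correlation layer fits four points in the reference analysis;
  p-values at n = 4 are indicative only.
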