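# Methods

## Scope and data model

`guvmorph` analyses per-vesicle measurements exported from Fiji/ImageJ
("Analyze Particles" / "Measure" Results tables): a cross-section `Area` for
every vesicle, plus ellipse-fit `Major`/`Minor` full axes for deformation
experiments. Image segmentation is out of scope; the measurement table is
the interface. Each table carries a composition tag (the DOPC:cholesterol
ratio of the lipid solution), a condition tag (`t0`, `overnight`, or a field
level `H1`/`H2`/`H3`), and a µm-per-pixel calibration.

Calibration is a **required explicit input** with no default (1.0 meaning
"already in µm"): areas scale with calibration², lengths with calibration,
and a silently wrong scale is the worst failure mode of this kind of
pipeline, so nothing is guessed from the file. A leading unnamed index
column and both `,`/`;` delimiters are accepted, matching ImageJ's export
dialects. Rows whose ellipse fit reports `Major < Minor` (rounding in the
fit) are repaired by swapping with a warning rather than rejected.

## Geometry

Vesicles are treated as circles in projection, `d = 2√(A/π)`. A deformed
vesicle is a prolate spheroid with semi-axes `a ≥ b`; ImageJ reports **full**
axes, so both are halved before entering any formula (the volume
`4/3 π a b²` only reduces to the sphere volume at `a = b = R` for
semi-axes). Volume conservation during elongation defines the rest radius
`R₀ = (a b²)^{1/3}`; the surface-area deformation is
`σ = S_ps/S_s − 1` with `S_s = 4πR₀²` and the prolate closed form
`S_ps = 2πb²(1 + a/(be)·arcsin e)`, `e² = 1 − b²/a²`.

Numerical choices:

* near the sphere (`e² < 1e-10`) the `arcsin(e)/e` ratio is replaced by its
  series `1 + e²/6 + 3e⁴/40`, making `S_ps` continuous at `a = b`;
* `σ` is clipped at 0 against last-ulp round-off, so `σ = 0` exactly at the
  sphere;
* the inverse map `(R₀, σ) → (a, b)` used by the generator solves for the
  aspect ratio `q = a/b` by Brent root-finding on
  `a = R₀ q^{2/3}, b = R₀ q^{-1/3}` (volume-conserving by construction),
  bracket doubled until it encloses the target;
* only the prolate branch is modelled — the field elongates vesicles along
  its axis; oblate shapes do not occur in this configuration.

Tests verify the closed forms against an independent numeric
surface-of-revolution quadrature (relative error < 1e-8 up to aspect ratio
20), volume conservation to 1e-12, monotonicity of σ in aspect ratio, and
inverse-map round trips.

## Distribution fitting

Within a sample, diameters (and σ values) are modelled as lognormal. The fit
is by moments of the log-data, `µ = mean(ln x)`, `s = SD(ln x)` with the
n−1 denominator so the same spread feeds the t/F tests unchanged. This is
the Gaussian MLE on the log scale (up to n vs n−1) and makes the fitted
median the geometric mean of the data. Derived quantities use the standard
closed forms (median `e^µ`, mode `e^{µ−s²}`, quantiles with standard-normal
z — the band describes the population, not an estimator, so t-quantiles
would be wrong here). Histograms are presentation-only; no binning enters
any fit. The total apparent membrane area `A_s = Σ 4π(d_i/2)²` is computed
from the raw diameters, which keeps it additive across merged tables.

## Inference

All tests operate on the natural logarithm of the data, where lognormal
samples are normal. The default two-sample t-test is the pooled (Student)
variant — the classical companion of the F-test run on the same data — with
Welch available by flag. Two-sided p-values; the F-test doubles the smaller
tail. Significance is reported against α = 0.005, a deliberately strict
threshold; no multiple-testing correction is applied on top of it (the
pairwise p-values are reported raw, with group sizes and variant in the
same row for auditability). Zero-variance groups are flagged as degenerate
rather than producing silent NaNs.

The minimum detectable ratio (MDR) between group medians uses the
t-quantile approximation
`MDR = exp[(t_{1−α/2,df} + t_{power,df}) · s_log · √(1/n₁+1/n₂)]`,
df = n₁+n₂−2, with t rather than normal quantiles for exactness at moderate
n. Power analysis uses the conventional α = 0.05 (two-sided) even though
significance reporting uses 0.005 — the run log records both. Calibration
tests confirm the type-I error rate to ±1% and that simulated power at the
computed MDR hits the 80% target to ±0.03.

## Magnet model

The field device holds two identical cuboid magnets coaxially, poles
aligned, so their on-axis fields add at the midpoint. The single-magnet
on-axis field is the surface-charge closed form (each face contributes
`Br/(4π)` times its solid angle). "Distance between the magnets" is read as
**face-to-face separation**, the sample sitting at `separation/2` from each
face; with the catalogue N42 magnet (15×15×8 mm) at the upper-grade
remanence Br = 1.32 T this reproduces the device's strong and intermediate
levels (47.6 mT at 4 cm, 4.67 mT at 10 cm) within ~1%. At the weakest
setting (13 cm) the model gives 2.26 mT where 2.0 mT is quoted — a ~13%
gap that no N42-grade remanence closes; Br is deliberately *not* tuned to
force agreement, and the weak level is treated as informative. Field
homogeneity over the ~1 cm² observation window is an assumption of the
device design, not modelled; only the midpoint on-axis value is computed.
The model is verified against an independent solid-angle quadrature oracle
(relative error < 1e-6) and the point-dipole far field.

## Synthetic generator

The generator emulates the statistical structure of the study populations,
not their mechanism:

* **t0 size laws** — lognormal diameters with medians 12.1/14.5/17.3/21.5 µm
  and counts 247/190/279/394 for 100:0/85:15/71:29/60:40; log-SDs
  0.40/0.45/0.50/0.55, widening with cholesterol content (the dominant
  compositional effect on the distribution shape).
* **overnight laws** — medians 16.1/11.9/12.3/13.4 µm and counts
  129/491/389/289. The overnight log-SDs are not directly observable from
  the summary quantities, so they are derived from the overnight/pristine
  total-surface ratios (82/198/66/20 %), which pin down `E[d²] = m²e^{2s²}`
  per group; this closes the scenario on published anchors only.
  Overnight populations are independent draws, not a fusion/fission
  simulation — the analysis measures distributions, not mechanisms, and a
  mechanistic model would add unverifiable assumptions.
* **deformation laws** — σ lognormal with medians 0.01/0.03/0.10 for
  H1/H2/H3 and common log-SD 0.6, 50 vesicles per composition per level,
  rest radii lognormal (median 15 µm, s 0.45). These place the 99th
  percentile of σ at the strongest field near 0.4 (the largest observed
  deformations) and give a minimum detectable median-σ ratio near 1.4 —
  the two anchors available for this arm of the study. Both compositions
  share the σ law, encoding the finding that cholesterol does not alter
  deformability.
* **noise** — multiplicative lognormal on lengths (1% SD by default), so
  axes stay positive; ellipse areas get an independent 1% factor.
* **seeding** — one global integer seed; each table draws from a substream
  keyed by `(seed, crc32("composition|condition"))`, so tables are
  individually and jointly reproducible, and identical seeds give
  byte-identical CSVs.

What passing tests on these populations shows: the pipeline recovers known
lognormal truths at the study's sample sizes, its tests are calibrated, and
its conclusions-reproduction is self-consistent. What it does not show:
robustness to segmentation errors, detection-limit censoring of small
vesicles, out-of-focus bias, or non-lognormal tails — real-data features
the generator deliberately does not model.

## Problem sizes in the verification suite

The statistical acceptance checks use 5000 null replicates (type-I error),
2000 power replicates, 200 recovery replicates at the full study counts, and
50 end-to-end workflow replicates with a 500-replicate Monte-Carlo power
oracle per comparison — sizes at which every asserted band is ≥3 binomial
standard errors wide.

## Known limitations

* The pipeline never sees images; garbage segmentation in, garbage out.
* Lognormality is assumed, not tested; a goodness-of-fit layer would be a
  natural extension.
* The deformation analysis assumes equilibrium prolate shapes; dipole-chain
  aggregation of vesicles at high fields (visible in raw images) is not
  modelled, nor are bending moduli estimated.
* The magnet model is on-axis midpoint only; off-axis gradients are not
  computed.
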