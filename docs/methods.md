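# Methods

## Spectral processing

Raw reflectance spectra are trimmed to 300–700 nm, spurious negative
readings (instrument noise near the white-standard baseline) are set to
zero, and everything is linearly interpolated onto a uniform 1 nm grid.
Linear rather than spline interpolation: floral reflectance is smooth
at this resolution and linear interpolation cannot overshoot.  Values
above 1 (white-standard overshoot) are kept — only negatives are
clamped.  Cleaning is idempotent.  Input files in percent are detected
by any value exceeding 1.5 and rescaled to proportions; the heuristic
can be overridden with an explicit `units=` argument.

## Visual phenotypes

Receptor sensitivities are generated from the Govardovskii A1 pigment
nomogram (α plus β band) at each phenotype's λmax and normalized to
unit peak; because the β band skews the summed curve up to ~2 nm short
of the nominal peak, the template is recentred by a fixed-point
correction so the realized peak sits at the requested λmax.  Curves can
instead be loaded from a CSV (e.g. measured sensitivities including
ocular-media or oil-droplet filtering).

Default phenotypes (editable in `data/viewers.yaml`, every field
overridable in `build_viewer`):

| viewer | λmax (nm) | model | threshold | densities | Weber |
|---|---|---|---|---|---|
| bee | 344, 436, 544 | hexagon | 0.11 hexagon units | — | — |
| bird_VS | 416, 478, 542, 607 | RNL | 1 JND | 1:2:2:4 | 0.1 |
| bird_UVS | 372, 456, 544, 609 | RNL | 1 JND | 1:2:2:4 | 0.1 |

The bee is the honeybee trichromat; the birds are the average
violet-sensitive and ultraviolet-sensitive avian phenotypes of the
visual-ecology literature.  Hummingbirds are best described as VS, so
`bird_VS` is the default bird; `bird_UVS` exists for robustness checks
(on the calibrated synthetic study the two give the same qualitative
cell ordering).

The D65 daylight table ships as spectral power and is converted to
relative quanta (multiplied by wavelength, peak-normalized) because
photoreceptors count photons.  Integration is by the trapezoid rule on
the 1 nm grid.  The adaptation background defaults to a flat
achromatic reflectance of 0.3 — a neutral grey of foliage-like albedo.
The flat background makes the achromatic fixed point exact (a stimulus
equal to the background has q = 1 in every receptor and zero
saturation in both spaces); a measured green-foliage spectrum can be
passed instead.  Noise in the RNL model is Weber-type: proportional to
the Weber fraction, independent of stimulus intensity, with the
densest cone class attaining e = ω exactly.

## Discriminability

A pair is discriminable iff its color distance strictly exceeds the
viewer's threshold — a pair at exactly 0.11 hexagon units or exactly
1 JND is *not* discriminable, since the thresholds delimit the region
where discrimination fails.  Species-level summaries are unweighted
means of population fractions, with the standard error undefined
(NaN, no error bar) for species represented by a single population.
Study-wide means are reported both across populations and across
species means, since the two differ whenever species contribute
unequal numbers of populations.

## Synthetic flora

The generator emulates the design of a field survey — species
classified by pollination system, 1–3 populations per species, 15
flowers per population — with two reflectance archetypes:

* **gaussian_peak** (bee-pollinated and mixed systems): baseline +
  Gaussian band, species base parameters drawn uniformly from center
  380–560 nm, width 35–60 nm, amplitude 0.4–0.8, baseline 0.02–0.06,
  with a 30% chance of a UV reflectance bump.
* **longpass_sigmoid** (bird-pollinated): baseline + sigmoid long-pass
  edge, inflection 600–640 nm, steepness 10–20 nm, amplitude 0.5–0.8,
  baseline 0.01–0.04, never UV-reflecting.  Jitterless renders of these
  "red" archetypes have bee-hexagon saturation below 0.1 — they are
  effectively achromatic to bees.

Intrapopulation variation perturbs archetype parameters with
independent normal jitter, truncated to keep reflectance valid.  The
default calibration (`DEFAULT_JITTER`) targets the qualitative regime
of real mountain-meadow data — bee fractions mostly below 10%, bird
fractions above 50% for bird flowers, with the two bee-viewer cells
statistically indistinguishable: gaussian_peak SDs (center 6 nm, width
3 nm, amplitude 0.06, baseline 0.01) and longpass_sigmoid SDs
(inflection 5 nm, steepness 4 nm, amplitude 0.10, baseline 0.04).  The
relatively large long-pass baseline jitter is what gives bees their
small but nonzero perceived variation in red flowers, since the edge
position itself is nearly invisible to them.

Two further layers create the nested variance structure the mixed
model assumes: population archetypes drift from their species
archetype by `population_drift` (default 0.5) times the jitter SDs,
and each population draws a mean-1 log-normal multiplier on its jitter
SDs (`population_variability`, default sigma 0.5).  The multiplier
encodes that populations genuinely differ in overall variability; and
because it acts on every parameter at once it induces the positive
cross-viewer correlation of perceived variation seen in field data.

What the generator does **not** emulate: real pigment absorption
shapes (flavonoid/carotenoid/anthocyanin mixtures), phylogenetic
correlation between species, covariation between floral traits, or
measurement noise from probe geometry.  Tests passing on synthetic
data therefore validate the modeling and inference machinery, not
claims about any particular flora.

## Inference

The factorial mixed model is fit by maximum likelihood (REML off, so
likelihood-ratio tests between fixed-effect specifications are valid):
response ~ visual_system × pollination_system with random intercepts
for species and for population nested in species.  LRT χ² statistics
use df = difference in fixed-effect parameter counts; main effects are
tested against the additive model (type-II style), the interaction
against the additive model as well.  Planned contrasts compare
pollination systems within each visual system on model cell means;
their t ratios use residual degrees of freedom n_obs − rank(X) — a
documented package choice (no Satterthwaite/Kenward–Roger
approximation), reported in the `df` column of every contrast table.
Contrast p-values are unadjusted, matching the reporting of single
planned contrasts per viewer; downstream multiplicity adjustment is
the caller's decision.

Fractions are analyzed untransformed on [0, 1] (a logit option
exists but is off by default).  At the default design size — 62
populations × 2 viewers — the interaction LRT holds its nominal level:
over 500 null simulations from the model's own data-generating process
the type-I rate at α = 0.05 stays within [0.03, 0.07] (slightly
anticonservative, as expected for ML-based LRTs with ~31 groups).

Saturation is analyzed at the population-mean level by default
(per-flower retained as an option).  Bee saturation is the hexagon
origin distance; the bird analogue is not standard, and here it is
defined as the RNL distance from the stimulus to the adaptation
background — the achromatic point of the adapted space.  Because
hexagon units and JNDs have very different spreads, the saturation
model z-standardizes the response within each visual system by default
so one space's variance cannot swamp the other's contrasts; raw-scale
analysis is available with `standardize=False`.

Mixed pollination systems are handled by named regrouping schemes
(`BeeBird->Bee`, `BeeBird->Bird`, `mixed->Bee`) that fold species into
the pure classes and drop the rest; `main` keeps only pure Bee and
Bird species.  The cross-space regression of bird-perceived on
bee-perceived variation compares slope-only, + pollination system, and
+ interaction candidates by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k
counting all estimated parameters including the residual variance.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng` seeds;
  studies, populations and pipeline runs are bit-reproducible.
  Derived seeds stay below 2³¹.
* The RNL distance is implemented by the general n-receptor
  combinatorial formula (products of the noises of the receptors left
  out of each pair, normalized by the (n−1)-subset products); the test
  suite cross-checks it against an independent Mahalanobis-form
  implementation restricted to the chromatic subspace.
* Degenerate inputs fail loudly: spectra not covering 300–700 nm,
  backgrounds with zero catch, non-positive densities/Weber fractions,
  empty or unpaired analysis cells all raise with the offending item
  named.
* Problem sizes in the test suite are scaled to what the analysis
  needs: oracle checks use populations of n ≤ 8 where exhaustive
  enumeration is transparent, calibration uses 500 simulations at the
  62-population design, and end-to-end checks run the full 930-flower
  study once at a fixed seed.

## Known limitations

* Hexagon and RNL models are chromatic only; no achromatic/luminance
  channel, so brightness-only variation is invisible to both modeled
  viewers.
* Avian oil-droplet filtering is not modeled from first principles;
  if it matters, load filtered sensitivity curves from file.
* The LRT reference distribution is asymptotic χ²; with few species
  the interaction test runs ~1 point anticonservative.
* Fraction discriminable is a proportion analyzed with a Gaussian
  LMM, as is conventional for this design; near the 0/1 boundaries the
  logit option is more defensible.
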