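# Methods

## Spectral processing and alpha-opic metrics

Raw spectrometer samples arrive on an irregular wavelength grid within
350–800 nm. They are reduced to the canonical 380–780 nm, 1 nm grid by
conservative (flux-preserving) rebinning: the samples define a
piecewise-linear spectral density, negative values (instrument noise) are
clamped to zero and counted, data outside 380–780 nm are discarded, and each
destination value is the exact mean of the density over its band
(half-width bands at the grid edges). With that convention the trapezoid
rule on the grid reproduces the integral of the clamped input over
380–780 nm to floating-point precision, and any band aligned with the bin
edges conserves energy exactly. Sub-bin structure is necessarily lost: no
401-sample representation can conserve energy over intervals finer than its
bins, so band queries resolve to bin-edge resolution.

Photopic illuminance is `K_m · Σ E(λ)V(λ)Δλ` with `K_m = 683.002 lm·W⁻¹`
(SI definition) and Δλ = 1 nm. The five alpha-opic irradiances use spectral
sensitivities reconstructed from the Govardovskii (2000) A1 pigment
nomogram at the class's pigment peak (S 420, M 530, L 558 nm; rhodopsin
498 nm; melanopsin 480 nm), filtered by a standard-observer ocular-media
density template (plus a macular template for the cones), converted from
quantal to energy units and peak-normalised. The resulting peaks
(S-cone-opic 451, M 542, L 567, rhodopic 512, melanopic 496 nm) sit within
a few nanometres of the officially tabulated functions; EDI values computed
from arbitrary spectra may deviate from official-calculator values at the
percent level, which is irrelevant to the package's inferential use but
should be kept in mind when comparing absolute EDIs across toolkits.

Equivalent daylight illuminances divide each alpha-opic irradiance by the
alpha-opic irradiance of the embedded daylight reference (the standard D65
tabulation at 10 nm, interpolated to 1 nm) per lux of that reference. All
normalisation constants are computed from the embedded tables at import, so
the defining identity EDI(D65) = illuminance(D65) holds exactly for every
class; the test suite asserts it to 0.1%.

## Quality control

An observation is retained iff the pupil value is present, detection
confidence ≥ 0.6, the diameter lies in the physical 1–9 mm range
(inclusive), and the paired spectrum is not saturated. Exclusions are
counted with a fixed precedence (confidence → range → saturation) so that a
frame violating several rules is counted once; a missing pupil or missing
confidence counts as confidence 0. The published per-rule percentages may
have been computed with overlaps; fixing a precedence makes the accounting
exactly conservative (retained + excluded = total).

Participant exclusion uses the per-participant loss fraction. The
scree-style threshold search evaluates candidate thresholds
0.50, 0.55, …, 0.95, counts participants with loss strictly above each
candidate, and adopts the smallest candidate above 0.50 at which stepping
to the next candidate removes the fewest additional participants (ties
resolve to the smallest such threshold, making the choice deterministic).
Participants with loss exactly at the adopted threshold are retained
(strict inequality).

## Mixed models and Bayes factors

All hypothesis tests are random-intercept linear mixed models fitted by
maximum likelihood. Crossed random intercepts (participant, sex, optionally
iris colour) are expressed as variance components on a single trivial
group, which statsmodels profiles efficiently; a two-level factor such as
sex is modelled literally as a random intercept for formula fidelity, and
boundary fits (variance component at zero) are accepted and flagged rather
than treated as errors. Because single gradient-based optimisers
occasionally stall on these profiled likelihoods, each model is fitted with
two optimisers and the best-likelihood solution kept.

Model comparison uses the BIC approximation to the Bayes factor,
`log10 BF10 = (BIC_null − BIC_full)/(2 ln 10)` with
`BIC = k ln n − 2 logLik`, `k` counting fixed coefficients, variance
components and the residual variance. The approximation is deterministic,
free of prior Monte-Carlo error, and applies unchanged to non-nested
comparisons (melanopic vs photopic predictor, log vs linear light, the
predictor matrices), at the cost of not reproducing prior-dependent BF
magnitudes; consumers should read the outputs categorically. Categories
follow the conventional bands (BF 3/10/30/100); a value exactly on a
boundary takes the weaker category, and negative values mirror the scale
with a `null-` prefix. BIC antisymmetry makes every comparison matrix
exactly antisymmetric and path-independent (additive through intermediate
models).

Light metrics enter the models log10-transformed by default, floored at
0.01 lx so that dark frames (which are excluded from field analyses anyway)
cannot produce −∞. Age enters in raw years, untransformed. Diagnostics
report residual-vs-fitted linear and quadratic coefficients (the quadratic
term flags the curvature that linear-light models exhibit), the slope of
|residual| on fitted values (heteroscedasticity), and pairwise predictor
correlations with variance inflation factors. The autocorrelation check
computes the standard sample ACF per participant on the nominal 10 s
cadence, dropping pairs that span gaps, and averages across participants;
constant series are flagged as undefined.

## Age analyses

Field observations fall into half-open mEDI bins [1,10), [10,100),
[100,1000), [1000,∞) lx; the in-laboratory dark adaptation forms its own
cluster regardless of residual light, and field frames below 1 lx mEDI are
excluded from the cluster analysis. Per-participant medians and IQRs use
linear-interpolation (type-7) quantiles. Cluster age regressions are plain
OLS of the medians on age in years, with t-based 95% CIs; slopes are also
reported per decade (×10, CIs scaled identically). Zero-residual fits are
flagged degenerate rather than reporting spurious zero-width intervals.

The per-individual dose–response fit requires at least 10 observations
spanning at least 2 decades of mEDI; dark frames enter at the 0.01 lx
floor (the floor is configurable since instrument floors differ). The
pupil-range regression uses participants with ≥ 20 valid observations
including the dark condition, without which the upper end of the range is
censored.

The Watson–Yellott unified formula is included as a reference predictor:
`D_SD(F) = 7.75 − 5.75·(F/846)^0.41/((F/846)^0.41 + 2)` driven by corneal
flux density `F = L·a·M(e)` (luminance × field area in deg² × monocular
attenuation 0.1), age-corrected by
`D = D_SD + (y − 28.58)(0.02132 − 0.009562·D_SD)`. It is luminance-based by
construction and therefore blind to spectral composition — precisely the
gap the melanopic analyses address.

## Synthetic-data generator

The generator emulates the study conditions so that every downstream stage
is testable offline.

*Spectra* are physical: Planckian radiators stand in for daylight (CCT
uniform 5000–7500 K above 1000 lx), and indoor scenes below 1000 lx mix
RGBW-LED spectra (Gaussian primaries at 630/527/467 nm, FWHM 25 nm, plus a
two-Gaussian phosphor white), triphosphor fluorescent combs, and daylight
(probabilities 0.4/0.3/0.3). Each spectrum is rescaled to its target
illuminance exactly; illuminances are drawn log-uniformly over
0.5–100,000 lx. The laboratory programme reproduces the protocol: four
colour phases in seeded random order, 1 min each at 10, 100 and the
colour's maximum illuminance (red 480, blue 250, green/white 1000 lx),
interleaved with five 20 s dark gaps below 0.2 lx — 13 min 40 s in total —
and a separate 10 min dark adaptation below 0.2 lx.

*Pupil model.* Two calibrations, both read from the published regression
coefficients and stored in `synth.CALIBRATION`, exist because the
continuous (per-individual) and clustered (per-bin) parameterisations are
not mutually consistent on real data:

- log-linear mode: `D = β₀(age) + β₁(age)·log10(mEDI)`, with (β₀, β₁)
  interpolated linearly between the young anchor (18 y: 6.28 mm,
  −0.998 mm/log-unit) and the old anchor (87 y: 3.83 mm, −0.463);
- cluster mode: `D = β₀c + β₁c·age` per light cluster (dark 8.13 mm,
  −0.0408 mm/yr; 1–10 lx 6.16, −0.0374; 10–100 lx 4.32, −0.0198;
  100–1000 lx 3.55, −0.0141; >1000 lx 2.57, −0.0080).

A Gaussian per-participant intercept (default σ = 0.3 mm) adds
inter-individual variability, and the modelled diameter is clipped to the
physical 1–9 mm range. Observation noise is heteroscedastic: in log-linear
mode σ falls linearly from 0.5 mm at 1 lx to 0.15 mm at 10⁴ lx mEDI; in
cluster mode σ is 0.20 mm in darkness (controlled adaptation), 0.50 in the
dimmest field bin and 0.40/0.30/0.20 in the brighter bins — encoding the
observation that pupil variability shrinks as light level rises while
controlled dark adaptation is tight. No quantitative noise magnitudes are
published; these values are package choices, fixed here.

*Quality fields.* A configurable fraction of frames (default 0.4337)
receives detection confidence below 0.6; spectra saturate with probability
0.0141; pupil misestimates outside 1–9 mm occur with probability 0.0016.
Ages default to uniform on [18, 87] (maximising regression power rather
than reproducing the study's young-skewed distribution); sex is balanced;
iris colours follow the study frequencies (30/20/49%).

*What passing tests do and do not show.* The generator produces i.i.d.
samples given light level: it encodes no light history, no task or gaze
structure, no weather, and no temporal autocorrelation beyond what the
light sequence induces, whereas real field data are strongly
autocorrelated. Recovery of the calibrated coefficients therefore
demonstrates the correctness of the pipeline's accounting and estimators
under the stated noise model, not robustness to the serial dependence and
selection effects of real recordings. One known consequence of the
Planckian daylight approximation: its melanopic DER spans ~0.86–1.05
across 5000–7500 K, slightly wider than real daylight, which caps the
synthetic field illuminance↔mEDI Pearson correlation at ≈ 0.998 (the study
reports 0.999 on real field data).

## Problem sizes and numerical choices

Hypothesis-battery checks run 20 replicates of 25-participant cohorts with
30 field observations each (plus 8-participant laboratory cohorts), sizes
at which every directional expectation is stable; cluster-regression
recovery uses 83 participants with 60 dark and 30-per-bin field
observations, matching the study's cohort size. Default seeds make every
generator call reproducible; identical configuration and seed yield
byte-identical observation tables. Degenerate inputs fail loudly: empty
observation tables, rank-deficient fixed designs (reported with the
collinear terms), mismatched observation sets in a comparison, constant
series in the ACF, and insufficient light span in dose–response fits all
raise with diagnostics rather than returning numbers.
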