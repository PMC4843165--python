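# Methods

This note documents the models behind `sharkvis`, the choices made where
the design was genuinely open, and what the synthetic fixtures do and do
not establish about real measurements.

## Visual pigment templates

Pigment absorbance is generated from the Govardovskii et al. (2000)
rhodopsin/porphyropsin templates: an alpha band that is a
sum-of-exponentials function of x = lambda_max/lambda plus a Gaussian beta
band in the UV, with the published A1 and A2 coefficient sets (coefficients
are copied, not refit). Curves are normalized by the template maximum
located on a dense 0.01 nm grid around lambda_max, so normalization does
not depend on the caller's sampling grid. Validity is restricted to
lambda_max in 330–650 nm.

Two documented properties of this parameterization matter downstream:

* the summed alpha+beta curve peaks a fraction of a nm away from
  lambda_max (it is not analytically normalized), which is why
  normalization uses a dense search;
* for A2 pigments with lambda_max below ~445 nm the beta band merges into
  the alpha band and the global template peak sits a few nm blue of
  lambda_max. Peak-tracking is therefore only asserted for A1 over
  400–550 nm and A2 over 450–550 nm.

The measured half-maximum range of the catshark rod (440–540 nm) is
broader than the A1 template at 484 nm predicts (the template gives
~430–528 nm). The package does not force the template to reproduce the
measured breadth; the 440–540 nm figure is asserted only of a
measured-curve stand-in fixture built as a broad Gaussian with half-max
crossings at exactly those wavelengths.

## MSP fitting

Scans are the interleaving of a down-scan on even nanometres and a return
scan on odd nanometres (350–700 nm). Fitting is two-stage:

1. **Initial peak.** An unnormalized Gaussian (amplitude, centre, width,
   offset) is least-squares fit to the 40 samples on each side of the raw
   argmax plus the argmax itself (81 points; the per-side count is a
   parameter). Its analytic maximum — the centre — is the initial
   estimate. On the asymmetric template this centre sits ~2 nm blue of
   lambda_max (481.94 nm for a noise-free 484 nm template, confirmed
   against a global-optimizer fit); this bias is harmless because stage 2
   searches +/-30 nm around it.
2. **Template sliding.** The scan is normalized by the fitted Gaussian
   peak value (amplitude + offset), which is robust to a single noisy
   maximum sample, and candidate lambda_max values are scanned at 0.1 nm
   steps for both chromophores; the global least-squares minimum wins.
   Chromophore ties (residual difference < 1e-9) resolve to A1, the
   marine-elasmobranch default. Baseline correction is assumed done by the
   instrument; a linear endpoint detrend is available as a flag.

Under the study's noise conditions (Gaussian absorbance noise, sd 0.05,
50 replicates) the mean recovered lambda_max is within ~0.01 nm of truth
with a replicate SD of ~0.35 nm — comfortably inside the +/-3 nm
uncertainty quoted for the measurement. Synthetic-scan noise is truncated
at zero because absorbance is nonnegative; at sd 0.05 this truncation only
touches the long-wave tail and does not measurably bias recovery.

## Underwater light

Downwelling irradiance follows the diffuse-attenuation law
E_d(lambda, z) = E_d(lambda, 0) exp(-Kd(lambda) z). This is a stated
simplification: no radiative-transfer solving, no scattering phase
functions, no Raman or water-column fluorescence. Background spacelight is
k·E_d with k = 0.01 by default — a proportional model that preserves the
spectral shape, which is all the contrast analysis consumes (k cancels in
no quantity of interest except absolute catch, where it sits against the
detection threshold).

Two Kd tables are packaged (5 nm tabulation, linearly interpolated,
replaceable by CSV), built from a smoothed pure-water absorption backbone
plus constituent terms:

* **blue** (oligotrophic): pure water + weak CDOM
  (0.45 exp(-(lambda-300)/35) m^-1); attenuation minimum at ~470 nm, so
  the 30 m spectrum peaks at 470 nm and narrows with depth.
* **blue-green** (productive): stronger CDOM, chlorophyll absorption at
  440 nm, an accessory-pigment band (chlorophyll shoulder/phycobilins) at
  625 nm and a minor 675 nm band; attenuation minimum at ~505 nm with a
  sharply narrowed depth spectrum (FWHM ~34 nm at 30 m).

The surface spectrum defaults to a spectrally flat quantal spectrum at a
nominal 1e18 photons m^-2 s^-1 nm^-1 (a daylight-shaped 6500 K option is
provided). The analyses are ratio-based, so the absolute level matters
only against the minimum-catch threshold.

## Fluorescence

Skin fluorescence is linear in the exciting light; an excitation-emission
matrix (photons emitted per excitation photon per nm) applied to the
incident spectrum gives the emitted radiance. Invariants enforced on
every EEM: nonnegativity, the Stokes constraint (no emission at or below
the excitation wavelength; anti-Stokes entries are zeroed with a warning),
and a quantum-efficiency bound of at most one emitted photon per absorbed
photon.

Patch radiance toward the viewer is Lambertian:
(reflectance x E_d + fluoresced emission)/pi. The 1/pi cancels in every
contrast ratio.

Species EEM fixtures are Gaussian mixtures with components placed to
reproduce the measured behaviour: a dominant deep-UV extract band, a blue
band emitting at 455 nm under 355 nm excitation with a 500 nm shoulder,
and the green skin band emitting at 525–535 nm under 390/470 nm
excitation. Absolute quantum efficiencies are not published; the fixtures
scale the matrix so the peak quantum yield is 0.1 (configurable), and
every conclusion drawn from them is a ratio or an argmax, which this
scaling cannot affect. The beige patch carries the full EEM amplitude and
a 0.30–0.40 reflectance ramp; the dark patch carries 5% of the EEM
amplitude and 0.05–0.07 reflectance. The ">100x" brighter fluorescent
spots reported for live animals are not asserted of these fixtures.

## Contrast and the optimal-pigment locus

A rod monochromat can only compare photon catches, so detection is a
luminosity task: Weber contrast C = (Q_t - Q_b)/Q_b of quantum catches
(Michelson is available by flag), with a threshold model requiring
|C| >= 0.02 and a background catch of at least 1e6 photons per integration
time (both nominal, both configurable; the catch floor is meaningful only
relative to the surface amplitude above).

The optimal-pigment locus scans lambda_max over 400–550 nm at 1 nm. The
ranking implements the intensity-reduction logic of the
sensitivity-hypothesis analysis: ambient light is notionally dimmed until
detection fails, and since Weber contrast is intensity-invariant, the
pigment that survives longest is — among pigments whose contrast clears
threshold — the one with the largest background catch, i.e. the pigment
whose absorbance envelope best overlaps the spacelight. Operationally:
argmax |C|, with near-ties (relative 1e-9) broken by larger background
catch, then by lowest lambda_max. For a spectrally neutral (gray) target
the contrast is exactly flat in lambda_max (the gray-world null), every
pigment ties, and the locus reduces to spacelight matching; for
structured targets it reduces to plain argmax |C|. This resolves the
tension between defining the optimum purely by contrast (which the
gray-target case makes degenerate) and the matched-pigment behaviour the
depth analysis exhibits.

## Camera and rendering

The shark-eye rig is modelled as a filter stack (an idealized Wratten
44A-style 490/90 nm band-pass, a 575 nm short-pass and a 400 nm long-pass,
cut filters as logistic steps with a 10 nm transition) over a
representative Gaussian-channel RGB cinema sensor; all curves are
CSV-replaceable and none is a bit-match of a specific production sensor.
The resulting blue channel peaks at 474 nm and covers ~63% of the 484 nm
pigment's half-max band. The fluorescence rig is a royal-blue LED behind
a 450/70 nm band-pass for excitation and a hard 514 nm long-pass on the
sensor.

Human-view rendering integrates radiance against the CIE 1931 2-degree
observer and converts through the linear sRGB (D65) matrix and the
standard piecewise transfer curve, clipping to [0, 255] with an
out-of-gamut flag. The colour-matching functions are the Wyman–Sloan–
Shirley (2013) piecewise-Gaussian analytic fits, rescaled to share equal
integrals on the working grid (the CIE equal-energy convention), so an
equal-energy spectrum maps to chromaticity (1/3, 1/3) by construction.

Patch pairs are displayed with the beige patch normalized to white and
the dark patch scaled identically, so the displayed gray encodes the
beige/dark intensity ratio. For the trichromatic observer the
normalization is channel-wise (von Kries-style); under deep-water light
with no red photons the red channel is zero and stays zero — beige then
renders cyan-white, which is faithful rather than a defect. Monochromat
lightness is the quantum catch itself; metamerism (equal catch, equal
lightness) holds by construction.

## Origins counting

Minimum origins are computed by Sankoff small parsimony with the root
fixed to the non-fluorescent state (outgroups — bony fishes and
chimaeras — are non-fluorescent, which makes "origin" well defined). Both
reported quantities use the fixed root: the minimum total changes, and
the minimum number of 0->1 transitions among reconstructions achieving
it, computed in one pass with lexicographic (changes, gains) pair costs
(pairs add componentwise and lexicographic order is translation-
invariant, so the Sankoff recursion is unchanged). Gain and loss costs
are unit by default and exposed as parameters; the fixture count of 3 is
stable under a doubled loss cost. The packaged tree is a 15-tip
family-level topology (three fluorescent families, ten examined
non-fluorescent families, two outgroups) shipped as editable newick +
state CSV. The DP is cross-checked against exhaustive enumeration of
internal labelings in the tests and in the analysis driver.

## What the fixtures do not show

Synthetic scans, Gaussian-mixture EEMs, linear-ramp reflectances and the
idealized optics demonstrate that the pipeline's inferences are correct
under the stated models and noise; they do not validate instrument
calibration, real skin spectra (which have structure no Gaussian mixture
captures), real water (which varies far beyond two Kd tables), or any
behavioural claim. Problem sizes throughout (50 scans per recovery run,
1 nm search grids, 15-tip exhaustive cross-checks) were chosen so every
analysis reruns from scratch in seconds.
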