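# sharkvis

Spectral modelling of catshark biofluorescence and what a catshark's own
eye makes of it.

Two catsharks — the swell shark (*Cephaloscyllium ventriosum*) and the
chain catshark (*Scyliorhinus retifer*) — carry green-fluorescent skin
patterns and, as pure rod monochromats, a single visual pigment apiece
(lambda_max 484 and 488 nm). `sharkvis` implements the analysis chain that
connects those two facts: it fits visual-pigment templates to
microspectrophotometry scans, models the blue-shifted underwater light
field and the skin's excitation–emission fluorescence, computes the
quantum-catch luminosity contrast a monochromat can use, renders the
animal to human, shark and filtered-camera observers, and counts the
minimum number of times fluorescence evolved on the elasmobranch family
tree. It is written for visual ecologists who want each of those stages
as a tested, seedable library component rather than a one-off script.

## The models in brief

* **Pigment templates.** Govardovskii A1/A2 templates: alpha band
  S(x) = 1/[exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D] with
  x = lambda_max/lambda, plus a Gaussian beta band; normalized to 1 at
  lambda_max.
* **MSP fitting.** Interleaved even/odd nm scans; a Gaussian fit to the
  40 raw points on either side of the peak gives the initial estimate;
  lambda_max then comes from sliding A1/A2 templates and least squares.
* **Light field.** E_d(lambda, z) = E_d(lambda, 0) exp(-Kd(lambda) z),
  with packaged oligotrophic "blue" and productive "blue-green" Kd
  tables; spacelight is k·E_d.
* **Fluorescence.** Emission(em) = sum_ex EEM(ex, em)·E(ex)·dex, with
  Stokes and quantum-efficiency constraints enforced; patch radiance is
  (R·E_d + emission)/pi.
* **Contrast.** Quantum catch Q = integral S(lambda)·L(lambda) dlambda;
  Weber contrast (Q_t - Q_b)/Q_b against a receptor-noise threshold; an
  optimal-pigment locus over lambda_max 400–550 nm.
* **Origins.** Sankoff parsimony with lexicographic (changes, gains)
  costs and the root fixed to non-fluorescent.

## Worked example

```python
import numpy as np
from sharkvis import (VisualPigmentTemplate, fit_template, water_type,
                      depth_detectability_profile)
from sharkvis.synth import gen_msp_scan, gen_patch_pair

# recover lambda_max from 50 noisy synthetic scans of the 484 nm pigment
fits = [fit_template(gen_msp_scan(484.0, "A1", 0.05, seed=s)).lambda_max_hat
        for s in range(1, 51)]
print(round(np.mean(fits), 2))          # 483.99  (truth 484, +/-3 nm band)

# does fluorescence help a conspecific see the pattern at 30 m?
beige, dark = gen_patch_pair("C_ventriosum")
pig = VisualPigmentTemplate(484.0)
on,  = depth_detectability_profile(beige, dark, water_type("blue"), [30.0], pig)
off, = depth_detectability_profile(beige.without_fluorescence(),
                                   dark.without_fluorescence(),
                                   water_type("blue"), [30.0], pig)
print(round(on.weber, 3), round(off.weber, 3))   # 4.902 4.854
```

The mean recovered lambda_max (483.99 nm) sits within the measurement's
+/-3 nm uncertainty, and the beige/dark Weber contrast at 30 m is larger
with fluorescence (4.902) than with the same patches silenced (4.854):
fluorescence adds green photons exactly where the dimming blue
background cannot, so the pattern stands out more, not less, at depth.

## Analysis scripts

The numbered drivers under `analysis/` run the full study and write
tables to `results/`:

| script | what it computes |
| --- | --- |
| `01_fit_visual_pigments.py` | lambda_max recovery for both species (50 scans each) |
| `02_skin_fluorescence.py` | species EEMs and emission peaks under 355/390/470 nm excitation |
| `03_light_and_contrast.py` | light with depth, contrast with/without fluorescence, optimal-pigment locus |
| `04_appearance_rendering.py` | patch renders for shark/human/camera observers; camera-pigment match |
| `05_fluorescence_origins.py` | parsimony origins of fluorescence on the family tree |

A `sharkvis` CLI exposes the same stages as subcommands (`template`,
`fit-msp`, `light`, `fluoresce`, `contrast`, `camera`, `render`,
`origins`, `make-fixtures`, `run`); see `sharkvis --help`.

## Layout

```
src/sharkvis/      library: spectra, pigments, msp, light, fluorescence,
                   contrast, camera, colorimetry, origins, synth, scene, cli
src/sharkvis/data/ fixture constants (YAML), family tree (newick), states
analysis/          numbered narrative drivers
tests/             pytest suite (unit, property, end-to-end)
docs/methods.md    model assumptions, parameter choices, limitations
```
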