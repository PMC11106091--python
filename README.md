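# octafractal

Fractal analysis of the macular microvasculature on en-face OCTA slabs, for
studying peripheral retinal ischemia in diabetic macular edema (DME).

In DME, capillary dropout in the retinal periphery (seen as non-perfusion
areas, NPAs, on fluorescein angiography) is accompanied by measurable
changes in the *macular* capillary network. This package quantifies those
changes with two complementary statistics computed on the skeletonized
vessel network of each capillary plexus (superficial, SCP; deep, DCP):

- **Fractal dimension (FD)** — the slope of log N(ε) vs log(1/ε) from
  multi-origin box counting of the skeleton; FD ∈ [0, 2] measures how
  completely the network fills the macula. Capillary loss lowers FD.
- **Lacunarity (LAC)** — the gliding-box statistic Λ(r) = ⟨M²⟩/⟨M⟩² of
  window mass M, summarized as the mean of 1 − 1/Λ(r) ∈ [0, 1); it measures
  the gappiness of the network. Ischemia raises LAC.

A cohort layer compares NPA vs well-perfused eyes (Welch t-tests) and
correlates FD/LAC with the extent of peripheral non-perfusion, coded as the
number of affected peripheral quadrants (0–4).

Because the underlying patient images are not public, the package ships a
**calibrated synthetic cohort generator**: capillary-mesh-like textures with
a foveal avascular zone and quadrant-count-dependent ischemic dropout, whose
measured group statistics reproduce the published cohort structure. All
estimators are validated against closed forms (filled square, line,
Sierpinski carpet) and exact brute-force oracles. See `docs/methods.md` for
the full model description.

## Worked example

```bash
python analysis/01_synthesize_cohort.py
python analysis/02_fractal_features.py
python analysis/03_cohort_statistics.py
```

which prints (seed 0, shipped defaults):

```
cohort written to .../results/cohort
  50 eyes: 30 NPA / 20 well-perfused
  NPA quadrant counts: {1: 6, 2: 4, 3: 9, 4: 11}
  image size 256 px, seed 0
features for 100 slabs -> .../results/features.csv
  DCP: FD 1.34±0.43 (NPA) vs 1.89±0.00 (well-perfused); LAC 0.52±0.20 vs 0.12±0.00
  SCP: FD 1.31±0.45 (NPA) vs 1.89±0.00 (well-perfused); LAC 0.54±0.21 vs 0.13±0.00
groups: 30 NPA vs 20 well-perfused eyes
  ...
  SCP FD                 NPA     1.31±  0.45  WP     1.89±  0.00  p=1.1e-07 *
  SCP LAC                NPA     0.54±  0.21  WP     0.13±  0.00  p=1.3e-11 *
  ...
correlations with NPA quadrant count (0-4):
  FD_SCP   r=-0.92  p=1e-20  (n=50)
  LAC_SCP  r=+0.99  p=9.7e-40  (n=50)
```

Reading: eyes with peripheral non-perfusion show a markedly lower macular
FD and higher LAC than well-perfused eyes at both plexuses, and both
statistics track the number of non-perfused quadrants — the qualitative
pattern the cohort generator is calibrated to. The starred rows are
significant at 0.05 (Welch, two-sided).

The same stages are available as a CLI for single images or whole cohort
folders:

```bash
octafractal synth-cohort --n 50 --seed 7 --out mycohort
octafractal analyze --in mycohort/eye001/eye001_SCP.png --plexus SCP
octafractal run --in mycohort --out myrun        # features + report + manifest
```

## Layout

```
src/octafractal/      library: slab_io, preprocess, fractal, synthetic_data,
                      cohort_analysis, pipeline, config, cli
analysis/             numbered narrative drivers over the library
tests/                pytest suite incl. brute-force oracles
scripts/acceptance.py end-to-end recomputation of the headline numbers
docs/methods.md       model, conventions, calibration, limitations
```
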