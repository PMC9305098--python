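# focalsf

Focal structure–function analysis of glaucomatous visual-field loss.

`focalsf` maps every location of a 30–2 visual-field test to an
individualized peripapillary region of interest — a wedge on the en-face
OCT-A capillary map and an arc on the 3.5-mm circumpapillary RNFL ring —
via a parametric nerve-fiber bundle trajectory model fitted to each eye's
fovea–disc geometry. From those regions it extracts focal capillary
density (fCD) and focal RNFL thickness (fRNFL-T), compares univariate and
combined regression models of focal visual-field deviation (fVFD) per
location (Pearson correlation, AIC, likelihood-ratio tests), and fits a
segmented (broken-stick) regression on a random-intercept mixed model with
a Davies test for the existence of a slope change.

Because no patient cohort ships with the package, a synthetic-cohort
generator produces complete input bundles (angiograms, ring profiles,
visual-field exams, eye geometry) with a known broken-stick
structure–function link, per-subject random intercepts, and
trajectory-aligned damage, so every pipeline stage is testable closed-loop.

## Layout

| module | role |
| --- | --- |
| `focalsf.vf_data` | 30–2 grid, perimetry ingest, reliability (QC) filter |
| `focalsf.octa_preproc` | binarization, Frangi large-vessel isolation/removal, scale normalization to 4.11 mm / 960 px |
| `focalsf.trajectory` | trajectory atlas (config-driven), eye registration, VF-location → disc-entry angle, wedge/arc ROIs |
| `focalsf.focal_metrics` | fCD, fRNFL-T, global metrics, analysis-table assembly |
| `focalsf.sf_models` | per-location models Mv / Mt / Mv:t, AIC + LRT comparisons, significance maps, global fits |
| `focalsf.segmented_mixed` | broken-stick fit on a random-intercept LMM (Muggeo-style linearization + profile CIs), Davies test |
| `focalsf.synthetic` | synthetic cohorts with ground truth; lightweight record generators for statistical simulation |
| `focalsf.pipeline` / `focalsf.cli` | end-to-end runner, provenance logging, CLI |

The trajectory coefficient tables live in a versioned JSON config
(`focalsf/data/trajectory_default.json`); alternative atlases are drop-in
replacements via `--trajectory-config`.

## CLI

```bash
# generate a synthetic cohort bundle
focalsf simulate --n-subjects 46 --seed 0 --out-dir sim/

# full pipeline: QC -> preprocess -> map -> metrics -> fits -> segmented
focalsf run-all --in-dir sim/ --out-dir results/ --target-px 350

# individual stages
focalsf preprocess-octa --in sim/octa_S001.png --meta sim/octa_S001.json --out-dir pre/
focalsf fit --table results/records.csv --out-dir fits/
focalsf segmented --table results/records.csv --predictor fCD --out seg_fcd.json
```

`run-all` writes `records.csv` (subject × location analysis table),
`location_fits.csv` / `model_comparisons.csv`, `segmented.json`
(slope-before / fVFD-at-breakpoint / slope-change with 95% CIs),
`summary.json`, and `provenance.json` with input hashes and parameters.
Reruns on identical inputs are byte-identical.

## Conventions

- All downstream processing uses right-eye orientation; left-eye exams are
  mirrored at ingest.
- Field coordinates: x positive temporal, y positive superior. The retinal
  projection reflects through fixation (superior field ↔ inferior retina).
- Disc-centered polar frame: angle 0 along the fovea–disc axis pointing
  nasally, counterclockwise positive (superior hemiretina > 0).
- The angular scale couples the en-face frame and the trajectory model
  through one constant: 4.11 mm per 15°, i.e. 0.274 mm/deg
  (`focalsf.config`).
- Segmented regression defaults to regressing the structural value on fVFD
  (breakpoint in dB); the opposite orientation is available via
  `orientation="fvfd_on_struct"`.
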