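# meniscoq

Quantitative MRI relaxometry of the knee meniscus: pixelwise T1rho and T2
mapping with zonal analysis and observer-agreement statistics.

The knee meniscus is not a homogeneous tissue. Its surface layer, its deep
core, and its avascular inner ("white"), intermediate ("red-white") and
vascularized outer ("red") zones differ in collagen organisation and
proteoglycan content, and those compositional gradients show up as zonal
differences in the T1rho and T2 relaxation times measured by quantitative
MRI. `meniscoq` is a pipeline for resolving those differences from
multi-spin-lock-time (TSL) and multi-echo-time (TE) magnitude image series:

1. **Rigid coregistration** of every frame of a relaxometry series to its
   first frame (normalized cross-correlation, deterministic grid +
   Nelder-Mead optimization, bilinear resampling).
2. **Pixelwise monoexponential fitting** of `S(t) = S0 · exp(−t/T)`, where
   `t` is TSL (yielding T1rho) or TE (yielding T2), with a log-linear
   initialization and nonlinear least-squares refinement. Pixels that
   cannot be fitted carry a relaxation time of 0 and are excluded from all
   statistics.
3. **Zonal partition** of meniscus ROIs: a *horizontal* split into the
   superficial zone (the first pixel layer along the meniscal surface) and
   the deep zone (the remainder), and for the anterior/posterior horns a
   *vertical* split into white / red-white / red thirds by normalized
   geodesic distance from the free edge to the periphery.
4. **Zonal statistics**: per-zone mean ± SD of the valid relaxation times
   and two-sided Mann-Whitney comparisons between zones.
5. **Observer agreement**: ICC(2,1) with the Fleiss interpretation bands
   (poor < 0.40, fair 0.40–0.59, good 0.60–0.74, excellent > 0.74) and
   Bland-Altman bias/limits-of-agreement, for segmentation pixel counts and
   zonal means across observers and sessions.

Because raw clinical series are rarely shareable, the package ships a
**synthetic phantom generator**: crescent-shaped menisci with
zone-dependent ground-truth relaxation times, Rician magnitude noise,
optional inter-frame rigid motion, and simulated observer boundary jitter.
Every stage of the pipeline is validated end to end against this phantom's
known truth.

## Worked example

Recover a zonal mean from simulated pixels (the core measurement loop):

```python
import numpy as np
from meniscoq import fit_pixels
from meniscoq.phantom import TSL_MS, simulate_decay_pixels

# 2,000 superficial-zone pixels, ground truth T1rho = 84.3 ms, SNR 50
signals = simulate_decay_pixels(84.3, 2000, TSL_MS, s0=500.0,
                                noise_sigma=10.0, seed=2024)
s0, t1rho, rss, valid = fit_pixels(signals, np.asarray(TSL_MS))
print(f"{t1rho[valid].mean():.2f} ms over {valid.sum()} valid pixels")
```

```
84.88 ms over 2000 valid pixels
```

The fitted mean sits within a percent of the 84.3 ms ground truth;
the small positive offset is the expected Rician noise-floor bias of
magnitude-image fitting, quantified (not corrected) by this package.

Run a complete synthetic study from the command line:

```sh
meniscoq run-all --out study/ --seed 1
```

which writes `zonal_summaries.csv`, `zonal_comparisons.csv` (superficial
vs deep and white/red-white/red comparisons with Mann-Whitney p-values),
`agreement_pixel_counts.csv`, `agreement_horizontal.csv`,
`agreement_vertical.csv` (ICC tables), `bland_altman_pixel_counts.csv`,
and a `manifest.json` with the seed, config hash and per-segment pixel
accounting. The same seed always reproduces byte-identical reports.
`meniscoq simulate --out phantom/ --seed 1` exports the raw phantom (NIfTI
series, PNG masks, ground-truth JSON) for use with external tools.

## Layout

- `src/meniscoq/image_io.py` — series/mask/report I/O (DICOM, NIfTI, PNG,
  JSON polygons, CSV)
- `src/meniscoq/registration.py` — rigid 2D coregistration
- `src/meniscoq/relaxometry.py` — monoexponential map fitting
- `src/meniscoq/zones.py` — horizontal and vertical zonal partition
- `src/meniscoq/stats.py` — zonal summaries and Mann-Whitney comparisons
- `src/meniscoq/agreement.py` — ICC and Bland-Altman
- `src/meniscoq/phantom.py` — synthetic study generator
- `src/meniscoq/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, parameters, design decisions, limitations
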