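# spreadquant

Automated quantification of extracellular-matrix-dependent **cell spreading**
from fluorescence time-lapse movies, and of **focal-adhesion (FA)
composition** in fixed dual-stained cells.

When a suspended cell lands on an adhesive substrate (e.g. fibronectin), it
spreads: its substrate-contact area grows rapidly, then plateaus. How it
spreads is as informative as how much — unstimulated epithelial cells spread
*anisotropically* (lobed, angular outlines with constant protrusion and
retraction), whereas cells in which the Rap1 GTPase pathway is activated
spread *isotropically* (uniform protrusion around the periphery, round
outlines, little retraction). `spreadquant` turns single-channel movies of
such cells into per-cell kinetic and shape read-outs, and quantifies the
protein composition of focal adhesions in fixed immunostained cells.

## What it computes

Live-cell mode (watershed segmentation → overlap tracking → metrics):

- **Spread area** A(t): pixel count of the segmented cell mask per frame.
- **Spreading rate** *m*: least-squares slope of A(t) over the first 30 min
  of imaging, in area per hour.
- **Protrusion / retraction**: differencing consecutive binary masks gives
  pixels gained (+1) and lost (−1); both are also expressed as fractions of
  the cell area in the second frame. The identity
  `A(t+1) = A(t) + P − R` holds exactly.
- **Circle ratio**: A divided by the area of the circle whose radius is the
  distance from the cell centroid to the most distant boundary pixel;
  1 for a perfect disk, smaller for angular cells.
- **σ_n**: standard deviation of the centroid-to-boundary distances divided
  by their mean — a scale-free irregularity measure.
- **Δσ_n**: mean absolute frame-to-frame change in σ_n — a shape-remodelling
  rate.

Fixed-cell mode (outline threshold → punctum watershed → normalisation):

- camera background (mean intensity outside the cell) subtracted from the
  whole image; cellular background = mean corrected intensity inside the
  cell excluding FA pixels;
- **normalised FA intensity** = total corrected FA intensity / cellular
  background (dimensionless, exposure-robust);
- cross-channel ratios (e.g. vinculin/paxillin, pY118-paxillin/paxillin)
  using the paxillin-derived FA mask for both channels, and
  cross-experiment standardisation to a reference condition.

Tracking links objects between frames by maximal mask overlap and bridges
detection gaps of up to five frames; tracks can be flagged by manual
validation decisions. A seeded synthetic-data generator produces
ground-truthed spreading movies (isotropic/anisotropic), multi-cell field
movies, and FA scenes with closed-form intensity truth, so every stage is
testable without microscopy data.

## Worked example

```python
from spreadquant import (SpreadingSimParams, simulate_spreading_movie,
                         analyze_movie)

for mode in ("isotropic", "anisotropic"):
    params = SpreadingSimParams(mode=mode, seed=7, n_frames=19,
                                shape=(256, 256), initial_radius=25,
                                growth_rate=40.0, plateau_area=9000.0)
    movie, truth = simulate_spreading_movie(params)
    frame_df, track_df, labels, tracks = analyze_movie(movie)
    t = track_df.iloc[0]
    cr = frame_df.circle_ratio.mean()
    rf = (frame_df.retraction_px / frame_df.area_px).mean()
    print(f"{mode:12s} m={t.m:8.1f} px^2/h   circle_ratio={cr:.3f}   "
          f"delta_sigma_n={t.delta_sigma_n:.4f}   retraction_frac={rf:.4f}")
```

prints

```
isotropic    m=  2205.0 px^2/h   circle_ratio=0.972   delta_sigma_n=0.0012   retraction_frac=0.0000
anisotropic  m=  2201.1 px^2/h   circle_ratio=0.595   delta_sigma_n=0.0264   retraction_frac=0.0638
```

Both cells spread at the same rate (the generator planted the same growth
law), but the isotropic cell stays round (circle ratio 0.97), keeps a
stable shape (Δσ_n ≈ 0.001) and never retracts, while the anisotropic cell
is angular (0.60), remodels continuously (Δσ_n ≈ 0.026) and retracts ~6% of
its area per 5-min frame — the quantitative signature separating the two
spreading phenotypes.

The same pipeline is available from the shell:

```sh
spreadquant simulate spreading --mode anisotropic --seed 7 --out movie.tif
spreadquant run --input movie.tif --interval 5 --out-dir results/
spreadquant fa --primary pax.tif --secondary py118.tif --outline phal.tif \
    --exclude 256,256,60 --out fa.csv
```

`run` writes `labels.tif`, `frame_metrics.csv` (one row per cell per
frame), `track_metrics.csv` (one row per track: *m*, Δσ_n, length,
validation flag) and a `manifest.json` recording every threshold consumed.
Exit codes: 0 success, 2 input error, 3 stage failure.

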