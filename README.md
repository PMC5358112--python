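# membratrack

Cell segmentation, tracking and motility quantification for time-lapse
confocal movies of epithelia whose fluorescence is concentrated on the cell
membranes — the signal produced by membrane-GFP reporters such as mT/mG
activated in the ureteric-bud epithelium of the developing kidney.  Given a
calibrated multi-page TIFF movie (µm/pixel and min/frame supplied by the
user), the pipeline outputs per-frame label masks, cell tracks, a wind-rose
summary of migration direction vs. speed, and left/right regional cell-count
and mean-area time series.  A synthetic epithelium generator with exact
ground truth makes everything testable without microscopy data.

## Method

Each frame is processed as follows:

1. **Hessian ridge enhancement.**  The frame is min–max rescaled to [0, 1]
   and, for each scale σ ∈ {1, 2} px, smoothed with a Gaussian; the 2×2
   Hessian H is formed by central finite differences and the bright-ridge
   response is the γ-normalized negative principal curvature
   σ² · max(0, −λ₁), with |λ₁| ≥ |λ₂| the eigenvalues of H.  The output is
   the maximum over scales: membranes (thin bright lines) score high, the
   slowly varying cytoplasm scores ≈ 0.
2. **Gap closing.**  Grayscale morphological closing of the ridge map with a
   disk (radius 2) bridges short membrane breaks without brightening cell
   interiors.
3. **h-minima + marker-controlled watershed.**  On the resulting relief
   (membranes high, interiors low), regional minima shallower than
   h = 0.10 × (relief range) are removed by morphological reconstruction;
   the surviving minima seed a watershed flood (4-connectivity, Meyer
   ordering, fully deterministic ties) whose basins are the cells.
   Watershed-line pixels are absorbed into regions so cell areas tile the
   tissue; regions under 30 px² are merged into their longest-boundary
   neighbour.
4. **Tracking.**  Tracks start from the first frame's centroids.  Each
   subsequent frame is associated by solving the minimum-cost assignment
   (Hungarian algorithm) over centroid distances, with pairs beyond a 15 px
   gate forbidden; unmatched tracks survive up to 2 missed frames, unmatched
   detections found new tracks.
5. **Motility read-outs.**  Per-track net displacement vectors (one vote per
   cell) are binned into a 16-sector wind rose whose spoke length is the
   proportion of cells moving in that direction and whose nested bands give
   the speed distribution; regional time series count cells and average
   areas (µm²) left and right of a configurable split.

## Worked example

```python
import numpy as np
from membratrack import (PipelineConfig, SceneParams, analyse_stack,
                         generate_scene, evaluate_tracking)

scene = generate_scene(SceneParams(), seed=1)          # 49 cells, 20 frames
result = analyse_stack(scene.frames, PipelineConfig())

tracks = result["tracks"]
rose = result["windrose"]
score = evaluate_tracking(tracks, scene.gt_tracks)
print(f"tracks          : {len(tracks)}")
print(f"link accuracy   : {score.link_accuracy:.3f} ({score.n_reproduced}/{score.n_gt_links} links)")
print(f"modal direction : {rose.modal_sector_center_deg:.0f} deg "
      f"(proportion {rose.proportions.max():.2f})")
speeds = [v.speed_um_per_min for v in result["vectors"] if not v.degenerate]
print(f"mean net speed  : {np.mean(speeds):.3f} um/min")
```

prints

```
tracks          : 49
link accuracy   : 1.000 (931/931 links)
modal direction : 0 deg (proportion 0.94)
mean net speed  : 0.087 um/min
```

All 49 simulated cells are segmented and followed through all 20 frames
(931/931 true frame-to-frame links reproduced), and the wind rose correctly
reports the imposed rightward (0°) collective drift: 94 % of cells net-move
into the sector centred on 0°, at a mean net speed of 0.087 µm/min given the
scene's 0.5 µm pixels and 5 min frame interval.

The same pipeline is available from the shell:

```sh
membratrack simulate --preset hex49 --seed 1 --out scene/
membratrack run --input scene/frames.tif --pixel-size 0.5 --dt 5 --output-dir out/
membratrack evaluate --pred out/ --gt scene/
```

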