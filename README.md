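# dielvision

Time-lapse image analysis of **diel plant growth and nutation** — a
library and CLI for quantifying how plant organs (flowers, stems,
cladodes) grow and move across day/night cycles in a controlled growth
chamber, plus a ground-truthed synthetic chamber simulator to validate
every stage of the pipeline.

## The problem

Circadian and diel rhythms in plant growth are easy to miss or
misattribute when sampling is sparse (aliasing). A camera in a growth
chamber capturing a frame every few minutes produces thousands of
grayscale images per experiment; turning them into growth and movement
time series requires:

1. **Segmentation** — isolate the organ as a bright blob: configurable
   preprocessing (averaging, median, Laplacian, sharpening, grayscale
   morphology; at most four operations), global histogram thresholding
   (Otsu, Kapur maximum-entropy, or Kittler–Illingworth minimum-error),
   8-connected blob extraction, and interval filters on area,
   compactness, length and perimeter.
2. **Shape features** — area *A*, perimeter *p*, principal-axis length
   and angle, centre of gravity *GC* = (cX, cY), and the derived
   descriptors
   - compactness  C = p² / (4πA)  (1 for a circle),
   - motion vector  MV_i = √((cX_i − cX_o)² + (cY_i − cY_o)²), the
     centroid displacement from its first-frame origin (the nutation
     read-out),
   - growth velocity  v_j = (l_{j+1} − l_j)/Δt (may be negative when an
     organ turns toward the camera).
3. **Adaptive-ROI tracking** — a growing, nutating organ escapes any
   fixed analysis window; after every frame the region of interest is
   recomputed as the blob's circumscribed rectangle expanded by margins
   (MGX, MGY), the maximum expected per-frame growth/displacement per
   axis.
4. **Illumination-transition correction** — dual day/night illumination
   and cameras put an abrupt gray-level step at every period transition
   into every pixel-counting variable. At each transition the subsequent
   samples are offset so the step equals the mean within-period step of
   the period just ended; within-period differences are untouched.
5. **Rhythm read-outs** — accumulated growth (positive increments only),
   binary per-interval growth patterns for area vs. length (8 h
   intervals by default; intervals with length growth but no area growth
   mark proximo-distal/lateral decoupling), and organ ranking by
   visibility, occlusion and movement activity.
6. **Metric calibration** — a 10 × 10 grid of 5 mm-radius circles imaged
   at known camera distances gives a per-plane mm/pixel scale,
   interpolated linearly to the sample distance.

## Worked example

Simulate one day at 6 images/hour (16 h light / 8 h dark) of a growing,
nutating elliptical organ with day/night gray-level jumps and noise,
track it, correct the transitions and accumulate growth:

```python
from datetime import datetime
import numpy as np
from dielvision import (ExperimentPlan, OrganModel, IlluminationModel,
                        PipelineConfig, simulate_sequence, track_sequence,
                        build_schedule, correct_transitions, accumulate_growth)

plan = ExperimentPlan(t_i=datetime(2026, 3, 1, 8), t_f=datetime(2026, 3, 2, 8),
                      images_per_hour=6)
organ = OrganModel(initial_semiaxes=(20, 14), growth_rate_x=0.3,
                   growth_rate_y=0.3, nutation_amplitude=4,
                   nutation_period=144, center=(160, 150))
illum = IlluminationModel(noise_sd=5.0, jump_emulation=True,
                          apparent_size_jump_px=1.0)
frames, truth = simulate_sequence(organ, illum, plan, seed=7, size=(300, 320))
track = track_sequence(frames, (120, 110, 200, 190), PipelineConfig(),
                       mgx=6, mgy=6)
corrected = correct_transitions(track.series("area"), build_schedule(plan))
acc = accumulate_growth(corrected)
```

Output of the accompanying print statements:

```
frames: 144 (48 night)
measured area: 877 -> 11621 px^2
accumulated growth: 10437 px^2 (ground truth 10352 px^2)
recovery error: 0.82 %
peak nutation displacement (MV): 8.00 px (true 2a = 8 px)
```

The accumulated growth recovers the generator's true pixel growth to
within 1% despite the noise and the day/night measurement jumps, and the
peak motion vector equals twice the nutation amplitude (the cosine
oscillation starts at its crest, so the far swing lies 2a from the
first-frame origin).

The same flow is available from the shell:

```sh
dielvision simulate --plan plan.yaml --organ organ.yaml --out run/ --seed 7
dielvision analyze  --images run/ --roi 120,110,80,80 --out analysis/
dielvision calibrate --images grid_100.png --images grid_110.png \
                     --distances 100,110 --out calibration.json
```

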